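"""Exception hierarchy shared across the package."""


class MpmQuantError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(MpmQuantError):
    """Shapes or grid dimensions are inconsistent."""


class UnsupportedFormatError(MpmQuantError):
    """An image file decodes to something the pipeline cannot consume."""


class PlacementError(MpmQuantError):
    """Phantom object placement failed after bounded retries."""


class GenerationError(MpmQuantError):
    """A phantom could not reach its generation target."""


class NoNucleiError(MpmQuantError):
    """A sample yielded no nuclei; it must be flagged, never averaged as zero."""


class InsufficientDataError(MpmQuantError):
    """Fewer values than a statistic requires."""


class ConfigError(MpmQuantError):
    """A run configuration failed validation."""


class PipelineError(MpmQuantError):
    """A run-level failure (e.g. no sample in a group could be processed)."""
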