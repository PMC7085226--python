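"""Image containers and file I/O for multiphoton microscopy data.

Images are single-channel 8- or 16-bit rasters. By display convention the
two-photon autofluorescence (TPAF) channel is rendered red and the
second-harmonic-generation (SHG) channel green, so RGB files are demuxed by
that convention on read. All quantification happens on raw intensities;
display rescaling is confined to :func:`render_overlay`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

from .errors import DimensionError, UnsupportedFormatError

__all__ = [
    "ChannelRole",
    "MpmImage",
    "BinaryMask",
    "read_image",
    "write_mask",
    "assemble_montage",
    "render_overlay",
]


class ChannelRole(str, enum.Enum):
    """Which multiphoton channel an image carries."""

    TPAF = "TPAF"
    SHG = "SHG"


#: RGB channel index used when extracting a role from a color image.
_ROLE_TO_RGB_INDEX = {ChannelRole.TPAF: 0, ChannelRole.SHG: 1}


@dataclass
class MpmImage:
    """A single-channel multiphoton image.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities.
    channel_role
        Whether the image is a TPAF or an SHG acquisition.
    bit_depth
        8 or 16; intensities must fit in ``[0, 2**bit_depth - 1]``.
    pixel_size_um
        Optional microns-per-pixel metadata; pass-through only, all
        measurements in this package are in pixel units.
    provenance
        Free-text source identifier (file path, phantom seed, ...).
    """

    pixels: np.ndarray
    channel_role: ChannelRole
    bit_depth: int = 8
    pixel_size_um: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.channel_role = ChannelRole(self.channel_role)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise DimensionError(
                f"expected a non-empty 2-D grid, got shape {self.pixels.shape}"
            )
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        lo, hi = self.pixels.min(), self.pixels.max()
        if lo < 0 or hi > self.max_value:
            raise ValueError(
                f"intensities [{lo}, {hi}] out of range for {self.bit_depth}-bit"
            )
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class BinaryMask:
    """A {0, 255} mask co-registered with its source image."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise DimensionError(
                f"expected a non-empty 2-D grid, got shape {self.pixels.shape}"
            )
        bad = np.setdiff1d(np.unique(self.pixels), [0, 255])
        if bad.size:
            raise ValueError(f"mask contains values other than 0/255: {bad[:5]}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def foreground_fraction_pct(self) -> float:
        return 100.0 * float(np.count_nonzero(self.pixels)) / self.pixels.size


def read_image(path: str | Path, channel_role: ChannelRole | str) -> MpmImage:
    """Read a TIFF/PNG raster as an :class:`MpmImage`.

    Grayscale files are taken as-is. 3-channel files are demuxed by the
    display convention (TPAF=red, SHG=green). Float pixels or more than
    three channels are rejected.
    """
    path = Path(path)
    role = ChannelRole(channel_role)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder-specific failures
        raise IOError(f"could not read image file {path}: {exc}") from exc

    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.floating):
        raise UnsupportedFormatError(f"{path}: float pixels are not supported")
    if arr.ndim == 3:
        if arr.shape[2] > 3:
            raise UnsupportedFormatError(
                f"{path}: {arr.shape[2]} channels; at most 3 (RGB) supported"
            )
        arr = arr[:, :, _ROLE_TO_RGB_INDEX[role]]
    elif arr.ndim != 2:
        raise UnsupportedFormatError(f"{path}: unsupported dimensionality {arr.ndim}")

    if arr.dtype.itemsize == 1:
        bit_depth = 8
    elif arr.dtype.itemsize == 2:
        bit_depth = 16
    else:
        raise UnsupportedFormatError(f"{path}: unsupported dtype {arr.dtype}")
    return MpmImage(arr, role, bit_depth=bit_depth, provenance=str(path))


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    """Write a mask as an 8-bit single-channel TIFF with values {0, 255}."""
    tifffile.imwrite(Path(path), mask.pixels.astype(np.uint8))


def read_mask(path: str | Path) -> BinaryMask:
    """Read back a mask written by :func:`write_mask`."""
    arr = np.asarray(iio.imread(Path(path)))
    return BinaryMask(arr)


def assemble_montage(
    tiles: list[MpmImage], grid_rows: int, grid_cols: int
) -> MpmImage:
    """Assemble row-major tiles into one large-area image, no blending.

    Tile (r, c) occupies block (r, c) of the output unchanged; all tiles
    must agree in shape, bit depth and channel role.
    """
    if grid_rows * grid_cols != len(tiles):
        raise DimensionError(
            f"{len(tiles)} tiles cannot fill a {grid_rows}x{grid_cols} grid"
        )
    first = tiles[0]
    for t in tiles[1:]:
        if t.shape != first.shape:
            raise DimensionError("tiles differ in shape")
        if t.bit_depth != first.bit_depth or t.channel_role != first.channel_role:
            raise DimensionError("tiles differ in bit depth or channel role")
    rows = [
        np.hstack([t.pixels for t in tiles[r * grid_cols : (r + 1) * grid_cols]])
        for r in range(grid_rows)
    ]
    return MpmImage(
        np.vstack(rows),
        first.channel_role,
        bit_depth=first.bit_depth,
        pixel_size_um=first.pixel_size_um,
        provenance=f"montage {grid_rows}x{grid_cols}",
    )


def _rescale_to_u8(pixels: np.ndarray) -> np.ndarray:
    x = pixels.astype(np.float64)
    lo, hi = x.min(), x.max()
    if hi == lo:
        # flat channel: render black (zero) rather than inventing contrast
        return np.zeros(x.shape, dtype=np.uint8) if lo == 0 else np.full(
            x.shape, 255, dtype=np.uint8
        )
    return np.round(255.0 * (x - lo) / (hi - lo)).astype(np.uint8)


def render_overlay(tpaf: MpmImage, shg: MpmImage) -> np.ndarray:
    """Pseudo-color overlay: TPAF in red, SHG in green, blue always zero.

    Each channel is min-max rescaled to 8-bit independently, for display
    only — quantification never uses the rescaled values.
    """
    if tpaf.shape != shg.shape:
        raise DimensionError(f"shape mismatch {tpaf.shape} vs {shg.shape}")
    rgb = np.zeros((*tpaf.shape, 3), dtype=np.uint8)
    rgb[:, :, 0] = _rescale_to_u8(tpaf.pixels)
    rgb[:, :, 1] = _rescale_to_u8(shg.pixels)
    return rgb
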