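import dataclasses

import numpy as np
import pytest

from mpmquant import CohortSpec, GroupParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def small_cohort_spec(master_seed: int = 0, n_per_group: int = 3) -> CohortSpec:
    """A light-weight cohort for pipeline-level tests: small images, few nuclei."""
    spec = CohortSpec(master_seed=master_seed, image_shape=(160, 160), n_nuclei=4)
    return dataclasses.replace(
        spec,
        pre=dataclasses.replace(spec.pre, n_samples=n_per_group),
        post=dataclasses.replace(spec.post, n_samples=n_per_group),
    )
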