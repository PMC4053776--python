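import numpy as np
import pytest

from incismir.simulate import SimulationConfig, generate_cohort_pair


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced-probe-density study conditions for fast end-to-end tests.

    The methylation and expression layers keep their default structure; the
    copy-number track is thinned (400 probes per chromosome), which keeps
    segmentation cheap while preserving the planted methylation machinery.
    """
    return SimulationConfig(probes_per_chrom=400, seed=7)


@pytest.fixture(scope="session")
def small_pair(small_cfg):
    return generate_cohort_pair(small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
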