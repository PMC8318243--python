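import numpy as np
import pytest

import multlearn as ml


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-patient planted-signal cohort with its ground truth, TS set."""
    cfg = ml.SyntheticConfig(n_patients=200, n_genes=100, seed=1)
    cohort, truth = ml.generate_cohort(cfg)
    cohort, _ = ml.filter_cohort(cohort)
    return cohort.with_ts(truth.ts), truth


@pytest.fixture(scope="session")
def tiny_settings():
    """Trimmed optimization depth for unit tests of the training stages."""
    return ml.MultSettings(bo_n_init=3, bo_n_iter=3, ncs_max_stall=3,
                           ncs_c_max=5, kmeans_n_init=3,
                           denoiser_patience=30, denoiser_max_iter=150)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
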