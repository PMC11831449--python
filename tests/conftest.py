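import numpy as np
import pytest

from topf.dataio import RunConfig
from topf.synthdata import CohortTable, GenerativeSpec, generate_clip, generate_cohort

# single-candidate grid: skips the inner search where hyperparameters are
# irrelevant to what is being tested
FAST_GRID = {"ridge": [{"alpha": 1.0}]}


@pytest.fixture(scope="session")
def cohort20() -> CohortTable:
    return generate_cohort(20, 10, seed=11)


@pytest.fixture(scope="session")
def cohort60() -> CohortTable:
    return generate_cohort(60, 30, seed=7)


@pytest.fixture(scope="session")
def small_clip(cohort20):
    spec = GenerativeSpec(
        n_subjects=20, n_rois=5, n_trs=60, shared_fraction=0.4,
        noise_sd=1.0, seed=3,
    )
    return generate_clip(cohort20, spec)


@pytest.fixture(scope="session")
def signal_clip(cohort60):
    """Clip with a planted binary-phenotype effect in the first 6 ROIs."""
    spec = GenerativeSpec(
        n_subjects=60, n_rois=30, n_trs=100, shared_fraction=0.3,
        predictive_rois=tuple(range(6)), effect_size=1.5, noise_sd=1.0, seed=5,
    )
    return generate_clip(cohort60, spec)


@pytest.fixture()
def fast_config() -> RunConfig:
    return RunConfig(
        phenotype="sex_label", task="classification", n_pcs=1,
        estimator="ridge", k_outer=5, k_inner=3, n_repeats=1, seed=13,
        grids=FAST_GRID,
    )


def rank1_series(n_subjects: int, n_trs: int, seed: int = 0) -> np.ndarray:
    """Noise-free rank-1 subjects × TRs matrix with positive amplitudes."""
    rng = np.random.default_rng(seed)
    g = rng.standard_normal(n_trs)
    g = (g - g.mean()) / g.std()
    amps = rng.uniform(0.5, 2.0, size=n_subjects)
    return np.outer(amps, g), amps, g
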