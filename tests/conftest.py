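import numpy as np
import pytest

from connfp.io import STRUCTURAL, ConnectomeMatrix
from connfp.simulate import SyntheticParams, simulate_cohort


def random_connectome(
    rng: np.random.Generator,
    n: int = 10,
    subject_id: str = "s",
    timepoint: int = 1,
    modality: str = STRUCTURAL,
) -> ConnectomeMatrix:
    """A random symmetric non-negative connectome for unit tests."""
    w = rng.random((n, n))
    w = np.triu(w, k=1)
    w = w + w.T
    return ConnectomeMatrix(
        subject_id=subject_id, timepoint=timepoint, modality=modality, weights=w
    )


@pytest.fixture(scope="session")
def strong_fingerprint_cohort():
    """Small cohort with a dominant structural fingerprint (fast, no BOLD)."""
    params = SyntheticParams(
        n_subjects=8, n_nodes=30, alpha_sc=2.0, sigma_sc=0.1, seed=11
    )
    return simulate_cohort(params, timeseries=False)


@pytest.fixture(scope="session")
def small_cohort_with_ts():
    """Default-regime cohort, small enough for per-test FC computation."""
    params = SyntheticParams(
        n_subjects=6, n_nodes=20, n_timepoints=400, n_latent=5, seed=3
    )
    return simulate_cohort(params)
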