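import numpy as np
import pytest

from dyadsync import SimConfig, simulate_cohort
from dyadsync.evaluation import permutation_p_values


@pytest.fixture(scope="session")
def small_cohort():
    """A small study-like cohort with planted dyadic coupling."""
    cfg = SimConfig(n_dyads=6, n_alone=6, duration_s=300.0,
                    dyad_coupling=0.5, seed=101)
    cohort, truth = simulate_cohort(cfg)
    return cohort, truth, cfg


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no shared structure at all (pure channel noise)."""
    cfg = SimConfig(n_dyads=6, n_alone=8, duration_s=240.0,
                    stimulus_coupling=0.0, dyad_coupling=0.0,
                    social_gain=1.0, seed=202)
    cohort, truth = simulate_cohort(cfg)
    return cohort, truth, cfg


@pytest.fixture(scope="session")
def null_permutation_pvalues():
    """Group-permutation p-values over 500 independent null cohorts.

    Shared between the type-I-rate and uniformity checks so the cohorts are
    simulated only once.
    """
    return permutation_p_values(n_cohorts=500, n_perm=500, seed=811)


def make_series(values, fs_hz=1.0, channels=None, mask=None, sid="s"):
    from dyadsync import SubjectSeries

    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if channels is None:
        channels = [f"ch{i}" for i in range(values.shape[1])]
    return SubjectSeries(subject_id=sid, fs_hz=fs_hz, values=values,
                        channel_names=channels, missing_mask=mask)
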