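"""Monte-Carlo evaluation experiments for the pipeline.

Each function here generates synthetic cohorts with known ground truth,
runs one analysis path end to end, and summarizes how well the method
behaves: type-I error of the resampling tests under null cohorts, recovery
of planted structure (synchrony ordering, shared response components,
latent dimensionality), calibration of surrogate nulls, and predictive
accuracy for connection ratings. The same runners back the test suite and
the reproduction script, so every reported number is recomputed from
scratch.

Problem sizes are scaled for repeated simulation: null calibrations use
cohorts of 12-20 subjects viewing 240 s of stimulus, and the recovery
experiments use 8-60 subjects at 300-600 s; these sizes keep Monte-Carlo
error on rates near +/-0.01 at 500 replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import impressions as _imp
from . import inference as _inf
from . import prediction as _pred
from . import preprocess as _pre
from . import srm as _srm
from . import synchrony as _sync
from .synthetic import SimConfig, simulate_cohort, random_orthonormal

__all__ = [
    "bootstrap_type_one_error",
    "permutation_type_one_error",
    "cluster_type_one_error",
    "bootstrap_coverage",
    "surrogate_null_calibration",
    "surrogate_planted_exceedance",
    "synchrony_ordering",
    "spearman_power",
    "prediction_accuracy",
    "planted_srm_data",
    "srm_noiseless_recovery",
    "srm_noisy_recovery",
    "select_k_recovery",
    "cluster_localization",
]


def _null_config(seed: int, n_dyads: int = 0, n_alone: int = 12,
                 duration_s: float = 240.0) -> SimConfig:
    """A cohort with no shared structure at all (pure channel noise)."""
    return SimConfig(
        n_dyads=n_dyads,
        n_alone=n_alone,
        duration_s=duration_s,
        stimulus_coupling=0.0,
        dyad_coupling=0.0,
        social_gain=1.0,
        seed=seed,
    )


def _spread_config(seed: int, n_dyads: int, n_alone: int = 0,
                   duration_s: float = 300.0) -> SimConfig:
    """Study-like cohort with per-dyad coupling spread driving connection."""
    return SimConfig(
        n_dyads=n_dyads,
        n_alone=n_alone,
        duration_s=duration_s,
        dyad_coupling_range=(0.0, 0.9),
        seed=seed,
    )


# --------------------------------------------------------------------------
# type-I calibration of the resampling tests
# --------------------------------------------------------------------------

def bootstrap_type_one_error(
    n_cohorts: int = 500,
    n_boot: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    channel: str = "joy",
) -> float:
    """Fraction of null cohorts where the subject-wise bootstrap rejects.

    Cohorts have no stimulus drive and no dyadic coupling, so the mean
    pairwise synchrony is zero in truth; a calibrated test rejects at rate
    ``alpha``.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_cohorts):
        cohort, _ = simulate_cohort(_null_config(int(rng.integers(2**31))))
        table = _sync.all_pairs_synchrony(cohort, channel)
        res = _inf.subject_bootstrap(
            table, n_boot=n_boot, seed=int(rng.integers(2**31))
        )
        hits += res.p_value < alpha
    return hits / n_cohorts


def permutation_type_one_error(
    n_cohorts: int = 500,
    n_perm: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    channel: str = "joy",
) -> float:
    """Fraction of null cohorts where the group permutation test rejects.

    Null cohorts contain a dyad group and an alone group drawn from the
    same noise distribution (no coupling, no social gain), so the group
    difference is null by construction.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_cohorts):
        cohort, _ = simulate_cohort(
            _null_config(int(rng.integers(2**31)), n_dyads=6, n_alone=8)
        )
        table = _sync.all_pairs_synchrony(cohort, channel)
        res = _inf.group_permutation(
            table,
            _sync.PairingScheme.true_dyads(cohort),
            _sync.PairingScheme.alone_all_pairs(cohort),
            n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        hits += res.p_value < alpha
    return hits / n_cohorts


def permutation_p_values(
    n_cohorts: int = 500,
    n_perm: int = 500,
    seed: int = 0,
    channel: str = "joy",
) -> np.ndarray:
    """Null p-values of the group permutation test (for uniformity checks)."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_cohorts)
    for i in range(n_cohorts):
        cohort, _ = simulate_cohort(
            _null_config(int(rng.integers(2**31)), n_dyads=6, n_alone=8)
        )
        table = _sync.all_pairs_synchrony(cohort, channel)
        res = _inf.group_permutation(
            table,
            _sync.PairingScheme.true_dyads(cohort),
            _sync.PairingScheme.alone_all_pairs(cohort),
            n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        out[i] = res.p_value
    return out


def _all_pairs_dynamic(cohort, subjects, channel, window_s=30.0):
    """Moving-window synchrony matrix for every pair among ``subjects``."""
    from itertools import combinations

    pairs = list(combinations(subjects, 2))
    rows = []
    for a, b in pairs:
        rows.append(
            _sync.dynamic_synchrony(
                cohort.series[a], cohort.series[b], channel, window_s=window_s
            )["r"].to_numpy()
        )
    return np.vstack(rows), pairs


def cluster_type_one_error(
    n_cohorts: int = 500,
    n_perm: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    channel: str = "joy",
) -> float:
    """Family-wise false-positive rate of the cluster permutation test.

    Each null cohort's alone group is split into two arbitrary halves; a
    calibrated test reports at least one significant cluster in about
    ``alpha`` of cohorts.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_cohorts):
        cohort, _ = simulate_cohort(_null_config(int(rng.integers(2**31))))
        subjects = cohort.alone_subjects()
        half = len(subjects) // 2
        dyn_all, pairs = _all_pairs_dynamic(cohort, subjects, channel)
        res = _inf.cluster_permutation_subjectwise(
            dyn_all,
            pairs,
            subjects[:half],
            subjects[half:],
            n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        hits += len(res.significant(alpha)) > 0
    return hits / n_cohorts


def bootstrap_coverage(
    n_cohorts: int = 200,
    n_boot: int = 500,
    seed: int = 0,
    n_truth_cohorts: int = 300,
    channel: str = "joy",
) -> float:
    """Coverage of the bootstrap 95% CI for the population mean synchrony.

    The population value is itself estimated by averaging the mean pairwise
    synchrony over many independent cohorts at the same configuration.
    """
    rng = np.random.default_rng(seed)

    def cfg(s):
        return SimConfig(
            n_dyads=0, n_alone=12, duration_s=240.0,
            stimulus_coupling=0.4, dyad_coupling=0.0, social_gain=1.0, seed=s,
        )

    truth_means = []
    for _ in range(n_truth_cohorts):
        cohort, _ = simulate_cohort(cfg(int(rng.integers(2**31))))
        table = _sync.all_pairs_synchrony(cohort, channel)
        truth_means.append(np.tanh(np.mean(np.arctanh(table["r"]))))
    truth = float(np.mean(truth_means))

    covered = 0
    for _ in range(n_cohorts):
        cohort, _ = simulate_cohort(cfg(int(rng.integers(2**31))))
        table = _sync.all_pairs_synchrony(cohort, channel)
        res = _inf.subject_bootstrap(table, n_boot=n_boot, seed=int(rng.integers(2**31)))
        covered += res.ci_low <= truth <= res.ci_high
    return covered / n_cohorts


# --------------------------------------------------------------------------
# circular-shift surrogates
# --------------------------------------------------------------------------

def surrogate_null_calibration(
    n_cohorts: int = 200,
    n_surrogates: int = 200,
    seed: int = 0,
    channel: str = "joy",
) -> float:
    """Fraction of *null* cohorts whose observed mean synchrony falls inside
    the surrogate central 95% interval (nominal: 0.95)."""
    rng = np.random.default_rng(seed)
    inside = 0
    for _ in range(n_cohorts):
        cohort, _ = simulate_cohort(_null_config(int(rng.integers(2**31))))
        res = _inf.circular_shift_null(
            cohort.series, channel, n_surrogates=n_surrogates,
            seed=int(rng.integers(2**31)),
        )
        inside += res.ci_low <= res.observed_stat <= res.ci_high
    return inside / n_cohorts


def surrogate_planted_exceedance(
    n_cohorts: int = 50,
    n_surrogates: int = 200,
    seed: int = 0,
    stimulus_coupling: float = 0.7,
    channel: str = "joy",
) -> float:
    """Fraction of stimulus-driven cohorts whose observed mean synchrony
    exceeds the surrogate 95th percentile."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_cohorts):
        cfg = SimConfig(
            n_dyads=0, n_alone=12, duration_s=240.0,
            stimulus_coupling=stimulus_coupling, dyad_coupling=0.0,
            social_gain=1.0, seed=int(rng.integers(2**31)),
        )
        cohort, _ = simulate_cohort(cfg)
        res = _inf.circular_shift_null(
            cohort.series, channel, n_surrogates=n_surrogates,
            seed=int(rng.integers(2**31)),
        )
        hits += res.observed_stat > np.percentile(res.null_distribution, 95)
    return hits / n_cohorts


# --------------------------------------------------------------------------
# planted-structure recovery
# --------------------------------------------------------------------------

def synchrony_ordering(
    n_cohorts: int = 100,
    seed: int = 0,
    n_dyads: int = 6,
    n_alone: int = 8,
    channel: str = "joy",
) -> pd.DataFrame:
    """Mean synchrony per pairing scheme over study-like cohorts.

    With dyadic coupling planted, the expected ordering is
    true dyads > pseudo dyads > alone pairs.
    """
    rng = np.random.default_rng(seed)
    sums = {"true_dyads": 0.0, "pseudo_dyads": 0.0, "alone_all_pairs": 0.0}
    for _ in range(n_cohorts):
        cfg = SimConfig(
            n_dyads=n_dyads, n_alone=n_alone, duration_s=300.0,
            dyad_coupling_range=(0.0, 0.9), seed=int(rng.integers(2**31)),
        )
        cohort, _ = simulate_cohort(cfg)
        for builder in (
            _sync.PairingScheme.true_dyads,
            _sync.PairingScheme.pseudo_dyads,
            _sync.PairingScheme.alone_all_pairs,
        ):
            scheme = builder(cohort)
            table = _sync.group_synchrony(cohort, scheme, channel)
            sums[scheme.name] += float(table["r"].mean())
    return pd.DataFrame(
        {
            "scheme": list(sums),
            "mean_synchrony": [sums[k] / n_cohorts for k in sums],
        }
    )


def spearman_power(
    n_cohorts: int = 100,
    seed: int = 0,
    n_dyads: int = 28,
    alpha: float = 0.05,
    channel: str = "joy",
) -> float:
    """Fraction of cohorts with a significantly positive joy-synchrony /
    connection Spearman association.

    Cohorts plant per-dyad coupling spread, and connection ratings follow
    the planted coupling, so the association is positive in truth.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_cohorts):
        cohort, _ = simulate_cohort(_spread_config(int(rng.integers(2**31)), n_dyads))
        scheme = _sync.PairingScheme.true_dyads(cohort)
        table = _sync.group_synchrony(cohort, scheme, channel)
        conn = cohort.connection.groupby("dyad_id")["rating"].mean()
        dyads = [cohort.dyad_id_of(a) for a, _ in scheme.pairs]
        res = _pred.spearman_assoc(
            table["r"].to_numpy(), conn.loc[dyads].to_numpy(),
            n_boot=100, seed=int(rng.integers(2**31)),
        )
        hits += (res["rho"] > 0) and (res["p"] < alpha)
    return hits / n_cohorts


def prediction_accuracy(seed: int = 0, n_dyads: int = 30) -> float:
    """Leave-one-dyad-out ridge accuracy on one study-like cohort.

    Builds the full per-dyad feature table (emotion synchronies, EDA
    synchrony, spatial and impression similarity) and predicts the dyad's
    mean connection rating out-of-dyad.
    """
    cohort, _ = simulate_cohort(_spread_config(seed, n_dyads))
    features = _pred.dyad_feature_table(cohort, seed=seed)
    cols = [c for c in features.columns
            if c not in ("dyad_id", "episode", "mean_connection")]
    res = _pred.loo_dyad_ridge(
        features[cols],
        features["mean_connection"].to_numpy(),
        features["dyad_id"].to_numpy(),
        seed=seed,
    )
    return res.accuracy_r


def planted_srm_data(
    k: int,
    n_subjects: int = 8,
    n_channels: int = 20,
    n_time: int = 600,
    amplitude: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Data with an exact shared-response structure planted.

    Returns (series_list, true_shared, true_maps); each subject is
    ``W_i S + noise`` with random orthonormal ``W_i``. Component j of ``S``
    has standard deviation ``amplitude * 0.75**j`` — the distinct variances
    both mimic dominant-versus-secondary affective components and make the
    components identifiable (a shared-response fit is only determined up to
    rotation when latent variances are equal). ``amplitude**2 /
    noise_sd**2`` is the leading component's signal-to-noise ratio.
    """
    rng = np.random.default_rng(seed)
    kernel = np.hanning(11)
    kernel /= np.sqrt((kernel**2).sum())
    shared = np.vstack(
        [np.convolve(rng.standard_normal(n_time), kernel, "same") for _ in range(k)]
    )
    # orthogonalize and centre the rows so the planted components satisfy
    # the identification conditions exactly (uncorrelated trajectories with
    # distinct variances); smooth random rows are otherwise sample-correlated
    shared -= shared.mean(axis=1, keepdims=True)
    shared = np.linalg.qr(shared.T)[0].T * np.sqrt(n_time)
    shared *= amplitude * 0.75 ** np.arange(k)[:, None]
    data, maps = [], []
    for _ in range(n_subjects):
        w = random_orthonormal(n_channels, k, rng)
        maps.append(w)
        x = (w @ shared).T
        if noise_sd:
            x = x + noise_sd * rng.standard_normal((n_time, n_channels))
        data.append(x)
    return data, shared, maps


def srm_noiseless_recovery(seed: int = 0, k: int = 2) -> dict:
    """Fit a noiseless planted model; report objective and matched |corr|."""
    data, shared, _ = planted_srm_data(k, noise_sd=0.0, amplitude=1.0, seed=seed)
    model = _srm.fit_srm(data, k, n_iter=500, tol=1e-15, seed=seed, standardize="center")
    matches = _srm.match_components(model.shared, shared)
    return {
        "objective": float(model.objective_trace[-1]),
        "min_abs_corr": float(matches["abs_r"].min()),
        "orthonormality_error": model.orthonormality_error(),
        "trace_non_increasing": bool(
            np.all(np.diff(model.objective_trace)
                   <= 1e-9 * np.maximum(model.objective_trace[:-1], 1.0))
        ),
    }


def srm_noisy_recovery(seed: int = 0, k: int = 2, snr: float = 4.0) -> dict:
    """Recovery of planted trajectories at a given signal-to-noise ratio."""
    data, shared, _ = planted_srm_data(
        k, amplitude=float(np.sqrt(snr)), noise_sd=1.0, seed=seed
    )
    model = _srm.fit_srm(data, k, n_iter=200, seed=seed)
    matches = _srm.match_components(model.shared, shared)
    return {
        "mean_abs_corr": float(matches["abs_r"].mean()),
        "orthonormality_error": model.orthonormality_error(),
    }


def select_k_recovery(seed: int = 0, k_true_values=(1, 2, 3), k_max: int = 5) -> dict:
    """Chosen dimensionality per planted k (and for a pure-noise cohort)."""
    out = {}
    for k_true in k_true_values:
        data, _, _ = planted_srm_data(k_true, seed=seed + k_true)
        out[k_true] = _srm.select_k(data, k_max=k_max, seed=seed)
    rng = np.random.default_rng(seed)
    noise = [rng.standard_normal((600, 20)) for _ in range(8)]
    out["noise"] = _srm.select_k(noise, k_max=k_max, seed=seed)
    return out


def cluster_localization(
    n_runs: int = 20,
    seed: int = 0,
    epoch=(200.0, 260.0),
    n_perm: int = 500,
    alpha: float = 0.05,
) -> float:
    """Fraction of runs where the cluster test finds the planted epoch.

    Dyad-group subjects receive an extra shared joy-channel signal only
    inside ``epoch``; a hit is a significant cluster overlapping the epoch.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_runs):
        cfg = _null_config(int(rng.integers(2**31)), n_dyads=6, n_alone=12,
                           duration_s=400.0)
        cohort, _ = simulate_cohort(cfg)
        t = np.arange(cfg.n_samples) / cfg.fs_hz
        window = (t >= epoch[0]) & (t <= epoch[1])
        burst = np.sin(2 * np.pi * t / 15.0) * window
        joy_rng = np.random.default_rng(int(rng.integers(2**31)))
        for sid in cohort.dyad_subjects():
            s = cohort.series[sid]
            j = s.channel_names.index("joy")
            s.values[:, j] += 2.0 * burst + 0.2 * joy_rng.standard_normal(t.size)
        dyad_subjects = cohort.dyad_subjects()
        alone_subjects = cohort.alone_subjects()
        dyn_all, pairs = _all_pairs_dynamic(
            cohort, dyad_subjects + alone_subjects, "joy"
        )
        res = _inf.cluster_permutation_subjectwise(
            dyn_all, pairs, dyad_subjects, alone_subjects,
            n_perm=n_perm, seed=int(rng.integers(2**31)),
        )
        hits += any(
            c.p_value < alpha and c.end_s >= epoch[0] and c.start_s <= epoch[1]
            for c in res.clusters
        )
    return hits / n_runs
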