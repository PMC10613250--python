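"""Nonparametric significance machinery for synchrony analyses.

Pairwise intersubject correlations are not independent observations — every
pair shares a subject with many other pairs — so inference resamples
*subjects*, not pairs:

* :func:`subject_bootstrap` resamples subjects with replacement and rebuilds
  the implied pair set (dropping duplicate-subject self-pairs) to put a
  confidence interval on the mean synchrony and test it against zero;
* :func:`group_permutation` shuffles subjects between the two viewing
  groups, re-deriving each group's pair structure from the permuted
  assignment, to compare mean synchrony between groups;
* :func:`circular_shift_null` rotates each subject's series by an
  independent random offset, which preserves each series' autocorrelation
  exactly while destroying cross-subject temporal alignment;
* :func:`cluster_permutation` finds epochs where two groups' moving-window
  synchrony differs, controlling the family-wise error with a max-cluster
  permutation null.

Correlations are averaged on the Fisher-z scale and back-transformed.
All p-values use the add-one rule (b + 1) / (B + 1), so they are never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import InvalidArgumentError, SubjectSeries

__all__ = [
    "ResamplingResult",
    "ClusterResult",
    "Cluster",
    "fisher_z",
    "fisher_z_inv",
    "circular_shift",
    "subject_bootstrap",
    "circular_shift_null",
    "group_permutation",
    "cluster_permutation",
    "cluster_permutation_subjectwise",
]


def fisher_z(r):
    """Fisher z-transform, ``z = atanh(r)``; requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise InvalidArgumentError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def fisher_z_inv(z):
    """Inverse Fisher transform, ``r = tanh(z)``."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def circular_shift(x: np.ndarray, offset: int) -> np.ndarray:
    """Rotate a series circularly: ``y[t] = x[(t + offset) mod T]``.

    The rotation is a bijection of time indices, so every circular moment —
    in particular the circular lag-1 autocorrelation — is preserved exactly
    while any alignment with another series is destroyed.
    """
    return np.roll(x, -int(offset), axis=0)


@dataclass
class ResamplingResult:
    """Observed statistic plus its resampling distribution.

    ``ci_low``/``ci_high`` bound the central 95% of the resampling
    distribution; ``p_value`` uses the add-one exceedance rule.
    """

    observed_stat: float
    null_distribution: np.ndarray
    p_value: float
    ci_low: float
    ci_high: float
    n_resamples: int
    seed: int | None = None

    def __post_init__(self) -> None:
        assert 0 < self.p_value <= 1
        assert self.ci_low <= self.ci_high


@dataclass
class Cluster:
    start_s: float
    end_s: float
    mass: float
    p_value: float


@dataclass
class ClusterResult:
    """Clusters of consecutive supra-threshold group differences."""

    clusters: list
    cluster_alpha: float
    n_permutations: int
    t_values: np.ndarray = None
    times: np.ndarray = None
    seed: int | None = None

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c.p_value < alpha]


def _add_one_p(count: int, n: int) -> float:
    return (count + 1) / (n + 1)


def _z_matrix(table: pd.DataFrame, subjects: list) -> np.ndarray:
    """Symmetric matrix of Fisher-z synchrony values (NaN where no pair)."""
    index = {s: i for i, s in enumerate(subjects)}
    n = len(subjects)
    z = np.full((n, n), np.nan)
    for a, b, r in table[["subject_a", "subject_b", "r"]].itertuples(index=False):
        if a in index and b in index:
            i, j = index[a], index[b]
            z[i, j] = z[j, i] = np.arctanh(np.clip(r, -0.999999, 0.999999))
    return z


def subject_bootstrap(
    table: pd.DataFrame,
    subjects: list | None = None,
    n_boot: int = 5000,
    seed: int | None = None,
    use_fisher_z: bool = True,
) -> ResamplingResult:
    """Subject-wise bootstrap of the mean pairwise synchrony.

    Each iteration resamples subjects with replacement and averages the
    synchrony of every implied pair present in ``table`` (self-pairs from
    duplicated subjects are dropped). Returns a percentile confidence
    interval and a two-sided p-value for the mean against zero.
    """
    if subjects is None:
        subjects = sorted(set(table["subject_a"]) | set(table["subject_b"]))
    subjects = list(subjects)
    n = len(subjects)
    if n < 3:
        raise InvalidArgumentError("subject bootstrap needs at least 3 subjects")
    z = _z_matrix(table, subjects)
    if not use_fisher_z:
        z = np.tanh(z)
    observed = float(np.nanmean(z[np.triu_indices(n, 1)]))

    rng = np.random.default_rng(seed)
    iu0, iu1 = np.triu_indices(n, 1)
    boot = np.empty(n_boot)
    done = 0
    while done < n_boot:
        b = min(500, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        gathered = z[idx[:, iu0], idx[:, iu1]]
        gathered[idx[:, iu0] == idx[:, iu1]] = np.nan
        with np.errstate(invalid="ignore"):
            means = np.nanmean(gathered, axis=1)
        # iterations whose resample produced no valid pair are redrawn
        ok = ~np.isnan(means)
        take = means[ok][: n_boot - done]
        boot[done : done + take.size] = take
        done += take.size

    n_low = int((boot <= 0).sum())
    n_high = int((boot >= 0).sum())
    p = min(1.0, 2 * min(_add_one_p(n_low, n_boot), _add_one_p(n_high, n_boot)))
    lo, hi = np.percentile(boot, [2.5, 97.5])
    if use_fisher_z:
        observed, lo, hi, boot = (
            float(np.tanh(observed)),
            float(np.tanh(lo)),
            float(np.tanh(hi)),
            np.tanh(boot),
        )
    return ResamplingResult(observed, boot, p, float(lo), float(hi), n_boot, seed)


def circular_shift_null(
    series_set: dict | list,
    channel: str,
    n_surrogates: int = 5000,
    seed: int | None = None,
) -> ResamplingResult:
    """Circular-shift surrogate test of mean pairwise synchrony.

    Each surrogate rotates every subject's series by an independent uniform
    offset in [1, T-1] and recomputes the mean pairwise correlation
    (Fisher-z averaged). The one-sided p-value is the add-one exceedance of
    the observed mean over the surrogate distribution.
    """
    if n_surrogates < 100:
        raise InvalidArgumentError("need at least 100 surrogates")
    if isinstance(series_set, dict):
        series_set = list(series_set.values())
    X = np.column_stack([s.channel(channel) for s in series_set])
    if np.isnan(X).any():
        raise InvalidArgumentError("surrogate test requires fully observed series")
    T, n = X.shape
    if T < 100:
        raise InvalidArgumentError("series must have at least 100 samples")
    if n < 2:
        raise InvalidArgumentError("need at least two subjects")
    X = X - X.mean(axis=0)
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        raise InvalidArgumentError("constant series in the set")
    X = X / norms
    iu = np.triu_indices(n, 1)

    def mean_sync(M: np.ndarray) -> float:
        r = np.clip((M.T @ M)[iu], -0.999999, 0.999999)
        return float(np.tanh(np.mean(np.arctanh(r))))

    observed = mean_sync(X)
    rng = np.random.default_rng(seed)
    null = np.empty(n_surrogates)
    for b in range(n_surrogates):
        shifts = rng.integers(1, T, size=n)
        null[b] = mean_sync(
            np.column_stack([circular_shift(X[:, j], s) for j, s in enumerate(shifts)])
        )
    p = _add_one_p(int((null >= observed).sum()), n_surrogates)
    lo, hi = np.percentile(null, [2.5, 97.5])
    return ResamplingResult(observed, null, p, float(lo), float(hi), n_surrogates, seed)


def group_permutation(
    table: pd.DataFrame,
    scheme1,
    scheme2,
    n_perm: int = 5000,
    seed: int | None = None,
) -> ResamplingResult:
    """Subject-wise permutation test of a group difference in mean synchrony.

    The test statistic is the difference of the two groups' mean Fisher-z
    synchrony, each computed over its own pair structure (e.g. true-dyad
    pairs versus all alone-group pairs). Subjects are shuffled across the
    fixed design — who occupies which seat — and the pair structures are
    re-derived from the permuted assignment, which requires ``table`` to
    contain the synchrony of *every* pair of subjects across both groups
    (see :func:`dyadsync.synchrony.all_pairs_synchrony`). Two-sided p-value.
    """
    subs1, subs2 = scheme1.subjects, scheme2.subjects
    if len(subs1) < 3 or len(subs2) < 3:
        raise InvalidArgumentError("each group needs at least 3 subjects")
    if set(subs1) & set(subs2):
        raise InvalidArgumentError("groups must be disjoint")
    union = list(subs1) + list(subs2)
    index = {s: i for i, s in enumerate(union)}
    z = _z_matrix(table, union)

    def slot_pairs(scheme):
        i = np.array([index[a] for a, _ in scheme.pairs])
        j = np.array([index[b] for _, b in scheme.pairs])
        return i, j

    i1, j1 = slot_pairs(scheme1)
    i2, j2 = slot_pairs(scheme2)
    required = np.concatenate([z[i1, j1], z[i2, j2]])
    if np.isnan(required).any():
        raise InvalidArgumentError("table lacks synchrony values for scheme pairs")

    def stat(assign: np.ndarray) -> float:
        return float(
            z[assign[i1], assign[j1]].mean() - z[assign[i2], assign[j2]].mean()
        )

    observed = stat(np.arange(len(union)))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = stat(rng.permutation(len(union)))
    if np.isnan(null).any():
        raise InvalidArgumentError(
            "table must cover all cross-group pairs for label shuffling"
        )
    p = _add_one_p(int((np.abs(null) >= abs(observed)).sum()), n_perm)
    lo, hi = np.percentile(null, [2.5, 97.5])
    return ResamplingResult(observed, null, p, float(lo), float(hi), n_perm, seed)


# --------------------------------------------------------------------------
# cluster-based permutation test on moving-window synchrony
# --------------------------------------------------------------------------

def _welch_t(m1: np.ndarray, m2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-timepoint Welch t-statistic and degrees of freedom.

    ``m1``/``m2`` are (n_pairs, n_times) matrices of Fisher-z windowed
    synchrony. NaN entries (masked windows) are omitted per timepoint.
    """
    n1 = (~np.isnan(m1)).sum(axis=0).astype(float)
    n2 = (~np.isnan(m2)).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        mu1, mu2 = np.nanmean(m1, axis=0), np.nanmean(m2, axis=0)
        v1 = np.nanvar(m1, axis=0, ddof=1)
        v2 = np.nanvar(m2, axis=0, ddof=1)
        se2 = v1 / n1 + v2 / n2
        t = (mu1 - mu2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, df


def _crit_interp(df_grid: np.ndarray, alpha: float):
    """Interpolable critical-value table over a grid of Welch dfs."""
    crit = stats.t.ppf(1 - alpha / 2, df_grid)
    return lambda df: np.interp(df, df_grid, crit)


def _extract_clusters(t: np.ndarray, crit: np.ndarray) -> list:
    """Maximal runs of consecutive supra-threshold samples with a common sign.

    Returns a list of (start_index, end_index_exclusive, mass).
    """
    with np.errstate(invalid="ignore"):
        supra = np.abs(t) > crit
    supra &= np.isfinite(t)
    clusters = []
    i, n = 0, t.size
    while i < n:
        if not supra[i]:
            i += 1
            continue
        j = i
        sign = np.sign(t[i])
        while j < n and supra[j] and np.sign(t[j]) == sign:
            j += 1
        clusters.append((i, j, float(t[i:j].sum())))
        i = j
    return clusters


def _max_mass(t: np.ndarray, crit: np.ndarray) -> float:
    clusters = _extract_clusters(t, crit)
    return max((abs(m) for _, _, m in clusters), default=0.0)


def _cluster_test_core(
    z_all: np.ndarray,
    rows1_fn,
    rows2_fn,
    n_assignments: int,
    cluster_alpha: float,
    n_perm: int,
    seed: int | None,
    times: np.ndarray,
) -> ClusterResult:
    """Shared core: observed clusters vs a max-cluster permutation null.

    ``rows1_fn(assignment)`` returns the row indices of group 1 under a
    permuted assignment of the ``n_assignments`` exchangeable units.
    """
    df_grid = np.concatenate([np.linspace(1.0, 30.0, 291), np.linspace(31.0, 1000.0, 200)])
    crit_of = _crit_interp(df_grid, cluster_alpha)

    identity = np.arange(n_assignments)
    t_obs, df_obs = _welch_t(z_all[rows1_fn(identity)], z_all[rows2_fn(identity)])
    crit_obs = crit_of(df_obs)
    observed = _extract_clusters(t_obs, crit_obs)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n_assignments)
        t_p, df_p = _welch_t(z_all[rows1_fn(perm)], z_all[rows2_fn(perm)])
        null_max[b] = _max_mass(t_p, crit_of(df_p))

    clusters = [
        Cluster(
            start_s=float(times[i]),
            end_s=float(times[j - 1]),
            mass=mass,
            p_value=_add_one_p(int((null_max >= abs(mass)).sum()), n_perm),
        )
        for i, j, mass in observed
    ]
    return ClusterResult(
        clusters=clusters,
        cluster_alpha=cluster_alpha,
        n_permutations=n_perm,
        t_values=t_obs,
        times=times,
        seed=seed,
    )


def _to_z_matrix_rows(dyn: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(np.asarray(dyn, dtype=float), -0.999999, 0.999999))


def cluster_permutation(
    dyn_group1: np.ndarray,
    dyn_group2: np.ndarray,
    cluster_alpha: float = 0.05,
    n_perm: int = 5000,
    seed: int | None = None,
    times: np.ndarray | None = None,
) -> ClusterResult:
    """Cluster-based permutation test between two groups of windowed synchrony.

    Inputs are (n_pairs, n_times) matrices of moving-window correlations on
    a common time grid. Values are Fisher-z transformed; a Welch t-statistic
    is computed at every timepoint; samples exceeding the two-sided critical
    value at ``cluster_alpha`` are grouped into maximal consecutive
    same-sign runs whose mass is the summed t. The null is the maximum
    absolute cluster mass over permutations of the pair (row) labels.
    """
    d1 = np.atleast_2d(np.asarray(dyn_group1, dtype=float))
    d2 = np.atleast_2d(np.asarray(dyn_group2, dtype=float))
    if d1.shape[1] != d2.shape[1]:
        raise InvalidArgumentError("time grids of the two groups differ")
    if times is None:
        times = np.arange(d1.shape[1], dtype=float)
    elif len(times) != d1.shape[1]:
        raise InvalidArgumentError("times length does not match the time grid")
    z_all = _to_z_matrix_rows(np.vstack([d1, d2]))
    n1 = d1.shape[0]
    n_rows = z_all.shape[0]
    return _cluster_test_core(
        z_all,
        rows1_fn=lambda perm: perm[:n1],
        rows2_fn=lambda perm: perm[n1:],
        n_assignments=n_rows,
        cluster_alpha=cluster_alpha,
        n_perm=n_perm,
        seed=seed,
        times=np.asarray(times, dtype=float),
    )


def cluster_permutation_subjectwise(
    dyn_all: np.ndarray,
    pairs: list,
    subjects1: list,
    subjects2: list,
    cluster_alpha: float = 0.05,
    n_perm: int = 5000,
    seed: int | None = None,
    times: np.ndarray | None = None,
) -> ClusterResult:
    """Cluster test with subjects (not pairs) as the exchangeable units.

    ``dyn_all`` holds one row of windowed synchrony per unordered pair among
    the union of the two groups, with ``pairs`` naming each row. Each
    permutation shuffles subjects between the groups and takes the
    within-group pair rows of the permuted assignment, which matches the
    subject-level exchangeability of a co-viewing design.
    """
    dyn_all = np.atleast_2d(np.asarray(dyn_all, dtype=float))
    union = list(subjects1) + list(subjects2)
    if set(subjects1) & set(subjects2):
        raise InvalidArgumentError("groups must be disjoint")
    index = {s: i for i, s in enumerate(union)}
    n = len(union)
    pair_row = np.full((n, n), -1, dtype=int)
    for row, (a, b) in enumerate(pairs):
        i, j = index[a], index[b]
        pair_row[i, j] = pair_row[j, i] = row
    n1 = len(subjects1)
    iu1 = np.triu_indices(n1, 1)
    iu2 = np.triu_indices(n - n1, 1)
    if times is None:
        times = np.arange(dyn_all.shape[1], dtype=float)
    z_all = _to_z_matrix_rows(dyn_all)

    def rows_of(members: np.ndarray, iu) -> np.ndarray:
        rows = pair_row[members[iu[0]], members[iu[1]]]
        if np.any(rows < 0):
            raise InvalidArgumentError("dyn_all lacks a row for a required pair")
        return rows

    return _cluster_test_core(
        z_all,
        rows1_fn=lambda perm: rows_of(perm[:n1], iu1),
        rows2_fn=lambda perm: rows_of(perm[n1:], iu2),
        n_assignments=n,
        cluster_alpha=cluster_alpha,
        n_perm=n_perm,
        seed=seed,
        times=np.asarray(times, dtype=float),
    )
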