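"""Deterministic shared response model (SRM) for facial action-unit series.

Jointly factorizes every subject's channels-by-time matrix as
``X_i ~ W_i S`` where ``S`` (k x time) is a latent trajectory common to all
subjects and each ``W_i`` (channels x k) is a subject-specific map with
orthonormal columns — each subject may express the same latent affective
trajectory through a different spatial configuration of facial muscles.

The fit is alternating least squares: given the maps, the optimal shared
trajectory is the average projection ``S = (1/N) sum_i W_i^T X_i``; given
``S``, each map solves an orthogonal Procrustes problem,
``W_i = U V^T`` from the SVD of ``X_i S^T``. Both half-steps are exact
minimizers, so the summed squared residual is non-increasing.

The model is identified only up to a joint rotation/sign flip of the latent
space: for any orthogonal R, ``{W_i R, R^T S}`` fits equally well.
Evaluation against a planted truth therefore matches components greedily by
absolute correlation (:func:`match_components`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .containers import (
    InvalidArgumentError,
    SubjectSeries,
    UndefinedCorrelationError,
)

__all__ = [
    "SRMModel",
    "fit_srm",
    "select_k",
    "spatial_similarity",
    "trajectory_rating_correlation",
    "match_components",
]


@dataclass
class SRMModel:
    """Fitted shared response model.

    ``subject_maps`` maps subject_id -> (channels x k) orthonormal-column
    matrix; ``shared`` is the common (k x time) latent trajectory matrix;
    ``objective_trace`` records the summed squared residual after each
    alternating iteration.
    """

    subject_maps: dict
    shared: np.ndarray
    k: int
    objective_trace: np.ndarray
    subject_ids: list = field(default_factory=list)

    def orthonormality_error(self) -> float:
        """Largest entry of ``|W_i^T W_i - I|`` over subjects."""
        k = self.k
        return max(
            float(np.abs(w.T @ w - np.eye(k)).max()) for w in self.subject_maps.values()
        )


def _as_matrix(series, standardize: str | None) -> np.ndarray:
    """Channels-by-time matrix, optionally standardized per channel."""
    if isinstance(series, SubjectSeries):
        x = series.values.T.copy()
    else:
        x = np.asarray(series, dtype=float).T.copy()  # (time, channels) input
    if standardize in ("center", "zscore"):
        x -= x.mean(axis=1, keepdims=True)
    if standardize == "zscore":
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        x /= sd
    elif standardize not in ("center", None):
        raise InvalidArgumentError("standardize must be 'zscore', 'center', or None")
    return x


def fit_srm(
    series_list,
    k: int,
    n_iter: int = 50,
    tol: float = 1e-6,
    seed: int = 0,
    standardize: str | None = "zscore",
) -> SRMModel:
    """Fit the shared response model by alternating least squares.

    Parameters
    ----------
    series_list : list of SubjectSeries or (time x channels) arrays
        All subjects must share the same number of time samples.
    k : int
        Latent dimensionality; ``1 <= k <= n_channels`` and ``k <= time``.
    n_iter, tol :
        Stop after ``n_iter`` iterations or when the relative change of the
        objective falls below ``tol``.
    seed : int
        Seeds the random orthonormal initialization of the maps.
    standardize : 'zscore' | 'center' | None
        Per-subject channel standardization applied before fitting.
        z-scoring puts action units with different evidence scales on equal
        footing; 'center' (or None) preserves an exact low-rank structure
        when one is present.
    """
    xs = [_as_matrix(s, standardize) for s in series_list]
    n_channels, n_time = xs[0].shape
    for x in xs:
        if x.shape != (n_channels, n_time):
            raise InvalidArgumentError("all subjects must share time length and channels")
    if not 1 <= k <= n_channels:
        raise InvalidArgumentError(f"need 1 <= k <= {n_channels}, got k={k}")
    if n_time < k:
        raise InvalidArgumentError("time length must be at least k")

    ids = [
        s.subject_id if isinstance(s, SubjectSeries) else f"subject{i}"
        for i, s in enumerate(series_list)
    ]
    rng = np.random.default_rng(seed)
    ws = []
    for _ in xs:
        q, r = np.linalg.qr(rng.standard_normal((n_channels, k)))
        ws.append(q * np.sign(np.diag(r)))

    def objective(s: np.ndarray) -> float:
        return float(sum(((x - w @ s) ** 2).sum() for x, w in zip(xs, ws)))

    trace = []
    prev = np.inf
    shared = np.zeros((k, n_time))
    for _ in range(n_iter):
        shared = np.mean([w.T @ x for x, w in zip(xs, ws)], axis=0)
        for i, x in enumerate(xs):
            u, _, vt = np.linalg.svd(x @ shared.T, full_matrices=False)
            ws[i] = u @ vt
        obj = objective(shared)
        trace.append(obj)
        if prev - obj <= tol * max(prev, 1e-300) and np.isfinite(prev):
            break
        prev = obj

    # canonical orientation: rotate the latent space to its principal axes
    # so the shared trajectories are uncorrelated and ordered by variance,
    # then fix each trajectory's sign by its largest-magnitude sample.
    # The objective is invariant to this joint rotation; the convention
    # resolves the indeterminacy whenever the latent variances are distinct.
    evals, evecs = np.linalg.eigh(shared @ shared.T / n_time)
    rot = evecs[:, np.argsort(evals)[::-1]]
    shared = rot.T @ shared
    ws = [w @ rot for w in ws]
    signs = np.sign(shared[np.arange(k), np.argmax(np.abs(shared), axis=1)])
    signs[signs == 0] = 1.0
    shared = shared * signs[:, None]
    ws = [w * signs[None, :] for w in ws]

    return SRMModel(
        subject_maps=dict(zip(ids, ws)),
        shared=shared,
        k=k,
        objective_trace=np.asarray(trace),
        subject_ids=ids,
    )


def _heldout_reconstruction_score(xs_test: list, ws: list) -> float:
    """Mean correlation between each subject's held-out data and the
    shared-response reconstruction built from the *other* subjects.

    The projection of the other subjects' held-out data through their
    fitted maps estimates the shared trajectories on unseen time; mapping
    those through subject i's own fitted map predicts subject i's data.
    The score is rotation-invariant, so it measures how much genuinely
    shared structure the latent space carries rather than how it happens
    to be rotated.
    """
    projections = np.stack([w.T @ x for x, w in zip(xs_test, ws)])  # (N, k, T)
    n = projections.shape[0]
    scores = []
    for i in range(n):
        shared_minus = projections[np.arange(n) != i].mean(axis=0)
        pred = (ws[i] @ shared_minus).ravel()
        actual = xs_test[i].ravel()
        ps, as_ = pred.std(), actual.std()
        if ps == 0 or as_ == 0:
            scores.append(0.0)
            continue
        scores.append(float(np.corrcoef(pred, actual)[0, 1]))
    return float(np.mean(scores))


def select_k(
    series_list,
    k_max: int,
    k_min: int = 1,
    n_iter: int = 50,
    tol_fit: float = 1e-6,
    seed: int = 0,
    standardize: str | None = "zscore",
    score_tol: float = 0.02,
    return_scores: bool = False,
):
    """Choose the latent dimensionality by held-out shared-response similarity.

    For each candidate k the model is fit on the first half of the episode
    and scored on the second half by leave-one-subject-out reconstruction
    similarity (:func:`_heldout_reconstruction_score`): how well the shared
    response estimated from everyone else's unseen data, mapped through a
    subject's own fitted spatial map, correlates with that subject's unseen
    data. Each genuinely shared component raises the score; a component
    fitted to noise injects the other subjects' noise into the prediction
    and lowers it slightly, so the score peaks at the true dimensionality.
    The smallest k whose score is within ``score_tol`` of the maximum is
    returned, which also sends a pure-noise cohort to ``k_min``.

    This held-out criterion is used instead of the in-sample mean pairwise
    similarity of projected component timecourses because the latter is
    structurally biased toward k = 1 on nested latent structure (averaging
    per-component similarities always favours keeping only the strongest
    component), and because rotation indeterminacy spreads a single true
    component across all fitted components, inflating in-sample scores at
    every k.
    """
    n_time = (
        series_list[0].n_samples
        if isinstance(series_list[0], SubjectSeries)
        else np.asarray(series_list[0]).shape[0]
    )
    if k_min < 1 or k_max < k_min:
        raise InvalidArgumentError("need 1 <= k_min <= k_max")
    half = n_time // 2

    def split(s):
        v = s.values if isinstance(s, SubjectSeries) else np.asarray(s, dtype=float)
        return v[:half], v[half:]

    trains, tests = zip(*(split(s) for s in series_list))
    # held-out matrices standardized with their own statistics; the maps are
    # scale-free (orthonormal) so this only affects channel weighting
    xs_test = [_as_matrix(t, standardize) for t in tests]

    ks = list(range(k_min, k_max + 1))
    scores = []
    for k in ks:
        model = fit_srm(
            list(trains), k, n_iter=n_iter, tol=tol_fit, seed=seed, standardize=standardize
        )
        ws = [model.subject_maps[sid] for sid in model.subject_ids]
        scores.append(_heldout_reconstruction_score(xs_test, ws))
    scores = np.asarray(scores)
    best = scores.max()
    chosen = ks[int(np.argmax(scores >= best - score_tol))]
    if return_scores:
        return chosen, pd.DataFrame({"k": ks, "score": scores})
    return chosen


def spatial_similarity(model: SRMModel, component: int, pairing) -> pd.DataFrame:
    """Pearson similarity of two subjects' spatial maps for one component.

    For each pair in ``pairing`` (a PairingScheme or list of id pairs),
    correlates the subjects' weight vectors (column ``component`` of their
    maps) across channels.
    """
    if not 0 <= component < model.k:
        raise InvalidArgumentError(f"component must be in [0, {model.k})")
    pairs = getattr(pairing, "pairs", pairing)
    rows = []
    for a, b in pairs:
        wa = model.subject_maps[a][:, component]
        wb = model.subject_maps[b][:, component]
        if np.ptp(wa) == 0 or np.ptp(wb) == 0:
            raise UndefinedCorrelationError(f"constant weight vector in pair ({a}, {b})")
        rows.append((a, b, float(np.corrcoef(wa, wb)[0, 1])))
    return pd.DataFrame(rows, columns=["subject_a", "subject_b", "r"])


def trajectory_rating_correlation(
    model: SRMModel, dense_ratings: pd.DataFrame
) -> pd.DataFrame:
    """Correlate each shared trajectory with each dense emotion rating.

    ``dense_ratings`` has a ``time_s`` column plus one column per emotion on
    the same 1 Hz grid as the model's shared trajectories. Returns one row
    per (component, emotion) with the correlation of the raw trajectory and
    of the linearly detrended trajectory.
    """
    emotions = [c for c in dense_ratings.columns if c != "time_s"]
    n_time = model.shared.shape[1]
    if len(dense_ratings) != n_time:
        raise InvalidArgumentError("rating grid length does not match the trajectories")
    rows = []
    for comp in range(model.k):
        traj = model.shared[comp]
        traj_dt = _signal.detrend(traj)
        for emotion in emotions:
            rating = dense_ratings[emotion].to_numpy()
            rows.append(
                (
                    comp,
                    emotion,
                    float(np.corrcoef(traj, rating)[0, 1]),
                    float(np.corrcoef(traj_dt, rating)[0, 1]),
                )
            )
    return pd.DataFrame(rows, columns=["component", "emotion", "r_raw", "r_detrended"])


def match_components(estimated: np.ndarray, truth: np.ndarray) -> pd.DataFrame:
    """Greedy absolute-correlation assignment of estimated to true components.

    Both inputs are (k x time). Returns one row per true component with the
    matched estimated component index, the signed correlation, and its
    absolute value. Used to evaluate a rotation/sign-unidentified fit.
    """
    k_est, k_true = estimated.shape[0], truth.shape[0]
    corr = np.zeros((k_est, k_true))
    for i in range(k_est):
        for j in range(k_true):
            corr[i, j] = np.corrcoef(estimated[i], truth[j])[0, 1]
    rows = []
    available = set(range(k_est))
    order = np.argsort(-np.abs(corr).max(axis=0))  # strongest truths first
    for j in order:
        best = max(available, key=lambda i: abs(corr[i, j]), default=None)
        if best is None:
            break
        available.discard(best)
        rows.append((j, best, float(corr[best, j]), float(abs(corr[best, j]))))
    return pd.DataFrame(
        rows, columns=["true_component", "estimated_component", "r", "abs_r"]
    ).sort_values("true_component", ignore_index=True)
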