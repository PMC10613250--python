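"""Associating synchrony with social connection and out-of-dyad prediction.

Builds one feature row per dyad (per episode): the dyad's synchrony on each
emotion-evidence channel, its electrodermal synchrony, the spatial
similarity of its shared-response maps, its impression similarity, and the
dyad's mean self-reported connection. Association is assessed with a
Spearman rank correlation (dyad-level bootstrap CI); prediction uses an
L2-penalized regression evaluated with leave-one-dyad-out cross-validation
and a nested search over the regularization strength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Ridge
from sklearn.model_selection import GroupKFold
from sklearn.preprocessing import StandardScaler

from .containers import Cohort, InvalidArgumentError, UndefinedCorrelationError
from . import preprocess as _pre
from . import synchrony as _sync
from . import srm as _srm
from . import impressions as _imp

__all__ = [
    "PREDICTION_EMOTIONS",
    "spearman_assoc",
    "loo_dyad_ridge",
    "RidgePredictionResult",
    "dyad_feature_table",
]

#: emotion channels whose synchrony enters the connection prediction
PREDICTION_EMOTIONS = ["joy", "anger", "surprise", "fear", "sadness", "disgust"]


def spearman_assoc(
    feature: np.ndarray,
    connection: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
) -> dict:
    """Spearman rank correlation with a dyad-level bootstrap CI.

    One observation per dyad. Returns a dict with keys ``rho``, ``p``
    (asymptotic two-sided), ``ci_low``, ``ci_high`` (percentile bootstrap
    over dyads).
    """
    feature = np.asarray(feature, dtype=float)
    connection = np.asarray(connection, dtype=float)
    n = feature.size
    if n < 5:
        raise InvalidArgumentError("need at least 5 dyads")
    if np.ptp(feature) == 0 or np.ptp(connection) == 0:
        raise UndefinedCorrelationError("constant input has no rank ordering")
    rho, p = stats.spearmanr(feature, connection)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if np.ptp(feature[idx]) == 0 or np.ptp(connection[idx]) == 0:
            boot[b] = np.nan
            continue
        boot[b] = stats.spearmanr(feature[idx], connection[idx]).statistic
    lo, hi = np.nanpercentile(boot, [2.5, 97.5])
    return {"rho": float(rho), "p": float(p), "ci_low": float(lo), "ci_high": float(hi)}


@dataclass
class RidgePredictionResult:
    """Out-of-dyad predictions and their overall accuracy."""

    predictions: pd.DataFrame  # dyad_id, episode, actual, predicted, alpha
    accuracy_r: float
    alphas_searched: tuple


def loo_dyad_ridge(
    features: pd.DataFrame,
    connection: np.ndarray,
    dyad_ids: np.ndarray,
    alphas: tuple = (0.1, 1.0, 10.0),
    inner_folds: int = 5,
    seed: int | None = None,
    episode: np.ndarray | None = None,
) -> RidgePredictionResult:
    """Leave-one-dyad-out ridge prediction of mean connection ratings.

    All rows of a dyad (across episodes) leave the training set together.
    Within each training fold, a nested ``inner_folds``-fold grouped
    cross-validation (dyads stay together) picks the penalty from
    ``alphas`` by mean squared error; features are z-scored with
    training-fold statistics only; the intercept is unpenalized. The
    overall accuracy is the Pearson correlation between actual and
    predicted values pooled across all held-out folds.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(connection, dtype=float)
    dyad_ids = np.asarray(dyad_ids)
    unique_dyads = pd.unique(dyad_ids)
    if len(unique_dyads) < inner_folds + 1:
        raise InvalidArgumentError(
            f"need more dyads ({len(unique_dyads)}) than inner folds ({inner_folds})"
        )
    if episode is None:
        episode = np.ones(len(y), dtype=int)

    rng = np.random.default_rng(seed)
    rows = []
    for held_out in unique_dyads:
        test = dyad_ids == held_out
        train = ~test
        X_tr, y_tr, groups_tr = X[train], y[train], dyad_ids[train]

        # nested grouped CV for the penalty; group order shuffled for
        # reproducible but non-systematic fold assignment
        order = {g: i for i, g in enumerate(rng.permutation(pd.unique(groups_tr)))}
        fold_groups = np.array([order[g] for g in groups_tr])
        inner = GroupKFold(n_splits=inner_folds)
        mse = np.zeros(len(alphas))
        for tr_idx, va_idx in inner.split(X_tr, y_tr, groups=fold_groups):
            scaler = StandardScaler().fit(X_tr[tr_idx])
            Xi, Xv = scaler.transform(X_tr[tr_idx]), scaler.transform(X_tr[va_idx])
            for a_i, alpha in enumerate(alphas):
                model = Ridge(alpha=alpha).fit(Xi, y_tr[tr_idx])
                mse[a_i] += ((model.predict(Xv) - y_tr[va_idx]) ** 2).sum()
        best_alpha = alphas[int(np.argmin(mse))]

        scaler = StandardScaler().fit(X_tr)
        model = Ridge(alpha=best_alpha).fit(scaler.transform(X_tr), y_tr)
        preds = model.predict(scaler.transform(X[test]))
        for ep, actual, pred in zip(episode[test], y[test], preds):
            rows.append((held_out, ep, float(actual), float(pred), best_alpha))

    predictions = pd.DataFrame(
        rows, columns=["dyad_id", "episode", "actual", "predicted", "alpha"]
    )
    actual = predictions["actual"].to_numpy()
    predicted = predictions["predicted"].to_numpy()
    if np.ptp(actual) == 0 or np.ptp(predicted) == 0:
        raise UndefinedCorrelationError("constant predictions or targets")
    accuracy = float(np.corrcoef(actual, predicted)[0, 1])
    return RidgePredictionResult(predictions, accuracy, tuple(alphas))


def dyad_feature_table(
    cohort: Cohort,
    srm_k: int = 2,
    include_spatial: bool = True,
    include_impressions: bool = True,
    include_eda: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """One feature row per dyad for the connection analyses.

    Columns: per-emotion synchrony for joy, anger, surprise, fear, sadness,
    disgust; ``eda_synchrony`` (on preprocessed EDA); ``spatial_similarity``
    (component-1 shared-response maps); ``impression_similarity``; and
    ``mean_connection`` — the average of the two members' 1-9 reports.
    """
    scheme = _sync.PairingScheme.true_dyads(cohort)
    out = pd.DataFrame({"dyad_id": [cohort.dyad_id_of(a) for a, _ in scheme.pairs]})
    out["episode"] = cohort.episode

    for emotion in PREDICTION_EMOTIONS:
        table = _sync.group_synchrony(cohort, scheme, emotion)
        out[f"sync_{emotion}"] = table["r"].to_numpy()

    if include_eda:
        eda_1hz = {
            sid: _pre.eda_preprocess(raw) for sid, raw in cohort.eda.items()
        }
        table = _sync.group_synchrony(cohort, scheme, "eda", series=eda_1hz)
        out["eda_synchrony"] = table["r"].to_numpy()

    if include_spatial:
        dyad_subjects = cohort.dyad_subjects()
        au_cols = [c for c in next(iter(cohort.series.values())).channel_names
                   if c.startswith("au")]
        series = []
        for sid in dyad_subjects:
            s = cohort.series[sid]
            idx = [s.channel_names.index(c) for c in au_cols]
            series.append(type(s)(sid, s.fs_hz, s.values[:, idx], au_cols,
                                  s.missing_mask.copy()))
        model = _srm.fit_srm(series, k=srm_k, seed=seed)
        sim = _srm.spatial_similarity(model, 0, scheme)
        out["spatial_similarity"] = sim["r"].to_numpy()

    if include_impressions:
        demeaned = _imp.demean_within_subject(cohort.impressions)
        embedding = _imp.fit_embedding(demeaned)
        sim = _imp.impression_similarity(embedding, cohort.roster)
        out = out.merge(sim, on="dyad_id", how="left")

    conn = cohort.connection.groupby("dyad_id")["rating"].mean().rename("mean_connection")
    out = out.merge(conn, on="dyad_id", how="left")
    return out
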