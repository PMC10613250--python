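"""Character-impression embedding and per-dyad impression similarity.

After each episode every subject rates a fixed set of characters on several
social-impression questions (0-100 scale). Ratings are demeaned within
subject to remove individual scale use, embedded with a principal components
analysis of the question space (each subject-by-character rating vector is
one sample), and dyad similarity is the per-character Pearson correlation of
the two members' component scores, averaged over characters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import (
    InvalidArgumentError,
    SchemaError,
    UndefinedCorrelationError,
)

__all__ = [
    "ImpressionEmbedding",
    "demean_within_subject",
    "fit_embedding",
    "impression_similarity",
]

logger = logging.getLogger(__name__)

_COLS = ["subject_id", "character_id", "question_id", "rating"]


@dataclass
class ImpressionEmbedding:
    """PCA embedding of the impression-rating space.

    ``loadings`` is (questions x retained components); ``scores`` has one
    row per (subject, character) with the retained component scores;
    ``explained_variance_ratio`` covers *all* components, of which the first
    ``n_components`` are retained.
    """

    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame
    n_components: int
    var_target: float


def _check_table(table: pd.DataFrame) -> None:
    missing = set(_COLS) - set(table.columns)
    if missing:
        raise SchemaError(f"impression table lacks columns {sorted(missing)}")


def demean_within_subject(table: pd.DataFrame) -> pd.DataFrame:
    """Subtract each subject's per-question mean across characters.

    Removes idiosyncratic scale use (a subject who rates everyone high)
    while preserving the relative ordering of characters within a subject.
    """
    _check_table(table)
    n_char = table.groupby("subject_id")["character_id"].nunique()
    if (n_char < 2).any():
        raise InvalidArgumentError(
            "demeaning needs at least 2 characters per subject"
        )
    out = table.copy()
    means = out.groupby(["subject_id", "question_id"])["rating"].transform("mean")
    out["rating"] = out["rating"] - means
    return out


def fit_embedding(demeaned: pd.DataFrame, var_target: float = 0.90) -> ImpressionEmbedding:
    """Principal components of the question space.

    Treats each (subject, character) rating vector as one sample and retains
    the smallest number of components whose cumulative explained variance
    reaches ``var_target``; all rows are projected to scores.
    """
    if not 0 < var_target <= 1:
        raise InvalidArgumentError("var_target must lie in (0, 1]")
    _check_table(demeaned)
    wide = demeaned.pivot_table(
        index=["subject_id", "character_id"],
        columns="question_id",
        values="rating",
        sort=True,
    )
    if wide.isna().any().any():
        raise SchemaError("incomplete subject x character x question grid")
    if wide.shape[1] < 2:
        raise InvalidArgumentError("need at least 2 questions")
    pca = PCA()
    all_scores = pca.fit_transform(wide.to_numpy())
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    n_keep = int(np.searchsorted(cum, var_target - 1e-12) + 1)
    n_keep = min(n_keep, len(evr))
    comp_names = [f"pc{i + 1}" for i in range(n_keep)]
    loadings = pd.DataFrame(
        pca.components_[:n_keep].T, index=wide.columns, columns=comp_names
    )
    scores = pd.DataFrame(
        all_scores[:, :n_keep], index=wide.index, columns=comp_names
    ).reset_index()
    return ImpressionEmbedding(
        loadings=loadings,
        explained_variance_ratio=evr,
        scores=scores,
        n_components=n_keep,
        var_target=var_target,
    )


def impression_similarity(
    embedding: ImpressionEmbedding,
    roster: pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-dyad impression similarity in the embedding space.

    For each character, correlates the two dyad members' retained component
    score vectors (``method`` is ``"pearson"`` or ``"cosine"``), then
    averages over characters — one value per dyad. Characters whose score
    vector is constant for a member are dropped with a warning.
    """
    if method not in ("pearson", "cosine"):
        raise InvalidArgumentError("method must be 'pearson' or 'cosine'")
    comp_cols = [c for c in embedding.scores.columns if c.startswith("pc")]
    if len(comp_cols) < 2 and method == "pearson":
        raise InvalidArgumentError(
            "pearson similarity needs at least 2 retained components"
        )
    scores = embedding.scores.set_index(["subject_id", "character_id"])[comp_cols]
    dyads = roster[roster["group"] == "dyad"]
    rows = []
    for dyad_id, members in dyads.groupby("dyad_id"):
        a, b = sorted(members["subject_id"])
        sims = []
        for character in scores.loc[a].index:
            va = scores.loc[(a, character)].to_numpy()
            vb = scores.loc[(b, character)].to_numpy()
            if method == "pearson":
                if va.std() == 0 or vb.std() == 0:
                    logger.warning(
                        "dropping character %s for dyad %s: zero-variance scores",
                        character,
                        dyad_id,
                    )
                    continue
                sims.append(float(np.corrcoef(va, vb)[0, 1]))
            else:
                na, nb = np.linalg.norm(va), np.linalg.norm(vb)
                if na == 0 or nb == 0:
                    logger.warning(
                        "dropping character %s for dyad %s: zero-norm scores",
                        character,
                        dyad_id,
                    )
                    continue
                sims.append(float(va @ vb / (na * nb)))
        if not sims:
            raise UndefinedCorrelationError(
                f"no character with defined similarity for dyad {dyad_id}"
            )
        rows.append((dyad_id, float(np.mean(sims))))
    return pd.DataFrame(rows, columns=["dyad_id", "impression_similarity"])
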