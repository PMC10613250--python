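"""Shared in-memory containers and exceptions for the dyadic synchrony pipeline.

The pipeline operates on per-subject multichannel time series (facial
action-unit evidence, emotion evidence, electrodermal activity) sampled at a
stated rate, together with a cohort roster that records who watched alone and
who watched in a dyad.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SubjectSeries",
    "Cohort",
    "InvalidArgumentError",
    "SchemaError",
    "UndefinedCorrelationError",
    "AU_CHANNELS",
    "EMOTION_CHANNELS",
    "NEGATIVE_EMOTIONS",
]

#: canonical facial action-unit channel names (20 continuous evidence scores)
AU_CHANNELS = [f"au{i:02d}" for i in range(1, 21)]

#: canonical emotion-evidence channel names
EMOTION_CHANNELS = ["joy", "anger", "surprise", "fear", "sadness", "disgust", "contempt"]

#: emotions whose elementwise maximum defines the negative-valence channel
NEGATIVE_EMOTIONS = ["anger", "fear", "disgust", "sadness", "contempt"]


class InvalidArgumentError(ValueError):
    """An argument violates a precondition of an operation."""


class SchemaError(KeyError):
    """A required channel or column is absent from the input."""


class UndefinedCorrelationError(ValueError):
    """A correlation is requested on data with zero variance."""


@dataclass
class SubjectSeries:
    """One subject's time-by-channel matrix at a fixed sampling rate.

    Parameters
    ----------
    subject_id : str
        Identifier matching the cohort roster.
    fs_hz : float
        Sampling rate in Hz; must be positive.
    values : ndarray, shape (n_samples, n_channels)
        Channel values. Rows flagged in ``missing_mask`` may contain NaN.
    channel_names : list of str
        One name per column of ``values``.
    missing_mask : ndarray of bool, shape (n_samples,), optional
        True marks a sample where acquisition failed (e.g. no face detected).
        Defaults to all-False.
    """

    subject_id: str
    fs_hz: float
    values: np.ndarray
    channel_names: list[str]
    missing_mask: np.ndarray = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.fs_hz <= 0:
            raise InvalidArgumentError(f"fs_hz must be positive, got {self.fs_hz}")
        if self.values.shape[1] != len(self.channel_names):
            raise SchemaError(
                f"{self.values.shape[1]} columns but {len(self.channel_names)} channel names"
            )
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape[0], dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != (self.values.shape[0],):
            raise InvalidArgumentError(
                "missing_mask length must equal the number of samples"
            )
        if np.isnan(self.values[~self.missing_mask]).any():
            raise InvalidArgumentError("NaN values outside masked samples")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (left edge of each sampling interval)."""
        return np.arange(self.n_samples) / self.fs_hz

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a 1-d array (NaN where masked)."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise SchemaError(f"channel {name!r} not present") from None
        out = self.values[:, idx].copy()
        out[self.missing_mask] = np.nan
        return out

    def missing_fraction(self) -> float:
        if self.n_samples == 0:
            raise InvalidArgumentError("empty series")
        return float(self.missing_mask.mean())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.channel_names)
        df.insert(0, "time_s", self.times)
        return df


@dataclass
class Cohort:
    """Roster of subjects with their per-subject series and rating tables.

    Attributes
    ----------
    roster : DataFrame with columns (subject_id, group, dyad_id)
        ``group`` is ``"dyad"`` or ``"alone"``; ``dyad_id`` is empty for the
        alone group.
    series : dict subject_id -> SubjectSeries
        Facial channels (action units + emotion evidence) at the facial rate.
    eda : dict subject_id -> SubjectSeries
        Raw electrodermal activity, possibly at a higher rate.
    impressions : DataFrame (subject_id, character_id, question_id, rating)
        Post-episode character impression ratings on a 0-100 scale.
    connection : DataFrame (subject_id, dyad_id, rating)
        Post-episode partner-connection ratings on a 1-9 scale (dyads only).
    episode : int
        Episode label carried through downstream tables.
    """

    roster: pd.DataFrame
    series: dict = field(default_factory=dict)
    eda: dict = field(default_factory=dict)
    impressions: pd.DataFrame = None
    connection: pd.DataFrame = None
    episode: int = 1

    def __post_init__(self) -> None:
        required = {"subject_id", "group", "dyad_id"}
        if not required.issubset(self.roster.columns):
            raise SchemaError(f"roster must have columns {sorted(required)}")
        bad = set(self.roster["group"]) - {"dyad", "alone"}
        if bad:
            raise InvalidArgumentError(f"unknown group labels: {sorted(bad)}")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.roster["subject_id"])

    def dyad_subjects(self) -> list[str]:
        return list(self.roster.loc[self.roster["group"] == "dyad", "subject_id"])

    def alone_subjects(self) -> list[str]:
        return list(self.roster.loc[self.roster["group"] == "alone", "subject_id"])

    def dyad_pairs(self) -> list[tuple[str, str]]:
        """True dyad pairs, each sorted internally and listed by dyad_id."""
        pairs = []
        dyads = self.roster[self.roster["group"] == "dyad"]
        for _, members in dyads.groupby("dyad_id"):
            ids = sorted(members["subject_id"])
            if len(ids) != 2:
                raise InvalidArgumentError(
                    f"dyad {members['dyad_id'].iloc[0]!r} has {len(ids)} members"
                )
            pairs.append((ids[0], ids[1]))
        return pairs

    def dyad_id_of(self, subject_id: str) -> str:
        row = self.roster.loc[self.roster["subject_id"] == subject_id]
        if row.empty:
            raise SchemaError(f"subject {subject_id!r} not in roster")
        return row["dyad_id"].iloc[0]
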