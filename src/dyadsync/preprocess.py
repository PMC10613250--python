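"""Conversion of raw channel tables into analysis-ready 1 Hz series.

Covers valence-channel construction, block-mean downsampling with missing
data, the face-coverage quality-control rule, electrodermal-activity
conditioning (log transform, zero-phase bandpass, downsampling), and the
densification of sparse crowd emotion ratings.

Order matters: the valence channels use an elementwise maximum, which does
not commute with block averaging, so valence is always computed at the
native rate before downsampling.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal

from .containers import (
    NEGATIVE_EMOTIONS,
    Cohort,
    InvalidArgumentError,
    SchemaError,
    SubjectSeries,
    UndefinedCorrelationError,
)

__all__ = [
    "downsample",
    "valence_channels",
    "qc_face_coverage",
    "qc_report",
    "eda_preprocess",
    "densify_ratings",
]

logger = logging.getLogger(__name__)


def downsample(series: SubjectSeries, to_hz: float) -> SubjectSeries:
    """Downsample by block means over non-missing samples.

    Each output bin at rate ``to_hz`` averages the input samples whose time
    falls inside it, ignoring missing samples; a bin whose samples are all
    missing is masked in the output. The input/output rate ratio need not be
    an integer.
    """
    if to_hz <= 0:
        raise InvalidArgumentError("to_hz must be positive")
    if to_hz > series.fs_hz:
        raise InvalidArgumentError("to_hz may not exceed the input rate")
    n_in = series.n_samples
    bins = np.floor(np.arange(n_in) / series.fs_hz * to_hz).astype(int)
    n_out = bins[-1] + 1 if n_in else 0
    n_ch = series.values.shape[1]

    valid = ~series.missing_mask
    vals = np.where(valid[:, None], series.values, 0.0)
    sums = np.zeros((n_out, n_ch))
    counts = np.bincount(bins[valid], minlength=n_out).astype(float)
    for c in range(n_ch):
        sums[:, c] = np.bincount(bins, weights=vals[:, c], minlength=n_out)
    out_mask = counts == 0
    means = np.full((n_out, n_ch), np.nan)
    means[~out_mask] = sums[~out_mask] / counts[~out_mask, None]
    return SubjectSeries(
        subject_id=series.subject_id,
        fs_hz=to_hz,
        values=means,
        channel_names=list(series.channel_names),
        missing_mask=out_mask,
    )


def valence_channels(series: SubjectSeries) -> SubjectSeries:
    """Positive/negative valence channels from the emotion-evidence channels.

    Positive valence is the joy channel unchanged; negative valence is the
    elementwise maximum over anger, fear, disgust, sadness, and contempt.
    """
    required = ["joy"] + NEGATIVE_EMOTIONS
    for name in required:
        if name not in series.channel_names:
            raise SchemaError(f"required emotion channel {name!r} missing")
    idx = [series.channel_names.index(n) for n in NEGATIVE_EMOTIONS]
    negative = series.values[:, idx].max(axis=1)
    positive = series.values[:, series.channel_names.index("joy")]
    return SubjectSeries(
        subject_id=series.subject_id,
        fs_hz=series.fs_hz,
        values=np.column_stack([positive, negative]),
        channel_names=["positive", "negative"],
        missing_mask=series.missing_mask.copy(),
    )


def qc_face_coverage(series: SubjectSeries, max_missing_frac: float = 0.10) -> bool:
    """Keep/exclude decision from the face-detection failure rate.

    Returns True (keep) unless the missing fraction *strictly* exceeds
    ``max_missing_frac`` — a subject missing exactly the cutoff fraction is
    kept. Depends only on the missing mask, never on the values.
    """
    return series.missing_fraction() <= max_missing_frac


def qc_report(cohort: Cohort, max_missing_frac: float = 0.10) -> pd.DataFrame:
    """Per-subject QC table with columns (subject_id, missing_frac, decision)."""
    rows = []
    for sid, s in cohort.series.items():
        frac = s.missing_fraction()
        rows.append((sid, frac, "keep" if frac <= max_missing_frac else "exclude"))
    return pd.DataFrame(rows, columns=["subject_id", "missing_frac", "decision"])


def eda_preprocess(
    raw: SubjectSeries,
    low_hz: float = 0.005,
    high_hz: float = 5.0,
    out_hz: float = 1.0,
    log_before_filter: bool = True,
    order: int = 4,
) -> SubjectSeries:
    """Condition a raw skin-conductance series for synchrony analysis.

    Log-transforms the strictly positive conductance, applies a zero-phase
    Butterworth bandpass (``low_hz``-``high_hz``), removes the residual DC
    offset left by edge transients, and block-averages down to ``out_hz``.
    If the input rate cannot represent ``high_hz`` the upper edge is clipped
    just below Nyquist with a logged warning.

    ``log_before_filter=False`` instead bandpasses the raw conductance first
    and then applies a signed log, ``sign(x) * log1p(|x|)`` — the filtered
    series is zero-centred so a plain log would be undefined.
    """
    x = raw.values[:, 0].astype(float)
    if x.size == 0:
        raise InvalidArgumentError("empty series")
    nonpos = np.flatnonzero(x <= 0)
    if nonpos.size:
        raise InvalidArgumentError(
            f"EDA must be strictly positive; first offending index {nonpos[0]}"
        )
    fs = raw.fs_hz
    nyquist = fs / 2.0
    if high_hz >= nyquist:
        high_hz = 0.99 * nyquist
        logger.warning(
            "high_hz clipped to %.4f Hz (input rate %.3f Hz)", high_hz, fs
        )
    if low_hz <= 0 or low_hz >= high_hz:
        raise InvalidArgumentError("need 0 < low_hz < high_hz")

    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    if log_before_filter:
        y = signal.sosfiltfilt(sos, np.log(x))
    else:
        y = signal.sosfiltfilt(sos, x)
        y = np.sign(y) * np.log1p(np.abs(y))
    y = y - y.mean()  # the bandpass has zero DC gain; this removes edge leakage

    filtered = SubjectSeries(
        subject_id=raw.subject_id, fs_hz=fs, values=y, channel_names=["eda"]
    )
    if out_hz < fs:
        return downsample(filtered, out_hz)
    return filtered


def densify_ratings(
    sparse: pd.DataFrame,
    duration_s: float,
    window_s: float = 30.0,
    out_hz: float = 1.0,
) -> pd.DataFrame:
    """Dense emotion-rating trajectories from sparse crowd ratings.

    ``sparse`` has columns (time_s, subject_id, emotion, rating). Ratings
    are averaged across subjects at each rated timepoint, linearly
    interpolated to ``out_hz``, and smoothed with a centered moving average
    of width ``window_s`` (truncated at the edges). Returns a DataFrame with
    a ``time_s`` column plus one column per emotion.
    """
    required = {"time_s", "subject_id", "emotion", "rating"}
    if not required.issubset(sparse.columns):
        raise SchemaError(f"ratings table must have columns {sorted(required)}")
    if (sparse["time_s"] < 0).any() or (sparse["time_s"] > duration_s).any():
        raise InvalidArgumentError("rating timepoints outside the stimulus duration")

    n_out = int(round(duration_s * out_hz))
    grid = np.arange(n_out) / out_hz
    half = window_s / 2.0
    out = {"time_s": grid}
    for emotion, grp in sparse.groupby("emotion", sort=True):
        means = grp.groupby("time_s")["rating"].mean()
        if len(means) < 2:
            raise InvalidArgumentError(
                f"need >= 2 rating timepoints for emotion {emotion!r}"
            )
        dense = np.interp(grid, means.index.to_numpy(), means.to_numpy())
        # centered moving average, truncated at the edges
        smoothed = np.empty_like(dense)
        for i, t in enumerate(grid):
            sel = (grid >= t - half) & (grid <= t + half)
            smoothed[i] = dense[sel].mean()
        out[emotion] = smoothed
    return pd.DataFrame(out)
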