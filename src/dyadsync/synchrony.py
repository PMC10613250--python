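"""Pairwise intersubject synchrony: global, time-resolved, and lagged.

Synchrony between two viewers is the Pearson correlation of their
same-channel time series over an episode. Three pairing schemes are
supported: true dyads (pairs who physically watched together), pseudo dyads
(pairs drawn from the dyad group who did not watch together), and all pairs
of solo viewers. Missing samples are handled by pairwise deletion over the
joint mask; correlations that are undefined because one input has zero
variance raise rather than silently propagating NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import (
    Cohort,
    InvalidArgumentError,
    SubjectSeries,
    UndefinedCorrelationError,
)

__all__ = [
    "PairingScheme",
    "pair_count",
    "pseudo_pair_count",
    "global_synchrony",
    "dynamic_synchrony",
    "sliding_corr",
    "crosscorr_offset",
    "group_synchrony",
    "all_pairs_synchrony",
]

MIN_JOINT_SAMPLES = 30


def pair_count(n: int) -> int:
    """Number of unordered pairs among ``n`` subjects: n(n-1)/2."""
    if n < 0 or int(n) != n:
        raise InvalidArgumentError("n must be a non-negative integer")
    return n * (n - 1) // 2


def pseudo_pair_count(n: int, n_true_pairs: int) -> int:
    """Number of pseudo-dyad pairs: all pairs minus the true dyads.

    ``n`` subjects in the dyad group form n(n-1)/2 unordered pairs, of which
    ``n_true_pairs`` watched together; the remainder are pseudo dyads.
    """
    if n % 2 != 0:
        raise InvalidArgumentError("dyad-group size n must be even")
    if n_true_pairs > n // 2:
        raise InvalidArgumentError("n_true_pairs cannot exceed n/2")
    return pair_count(n) - n_true_pairs


@dataclass
class PairingScheme:
    """A named list of unordered subject pairs.

    ``name`` is one of ``true_dyads``, ``pseudo_dyads``, ``alone_all_pairs``.
    Use the classmethods to derive a scheme from a cohort roster; they
    validate the structural invariants (no self-pairs; true dyads share a
    dyad_id; pseudo dyads are dyad-group members with different dyad_ids).
    """

    name: str
    pairs: list

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a == b:
                raise InvalidArgumentError(f"self-pair {a!r}")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for a, b in self.pairs:
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)

    @classmethod
    def true_dyads(cls, cohort: Cohort) -> "PairingScheme":
        return cls("true_dyads", cohort.dyad_pairs())

    @classmethod
    def pseudo_dyads(cls, cohort: Cohort) -> "PairingScheme":
        subjects = cohort.dyad_subjects()
        dyad_of = dict(zip(cohort.roster["subject_id"], cohort.roster["dyad_id"]))
        pairs = [
            (a, b)
            for a, b in combinations(subjects, 2)
            if dyad_of[a] != dyad_of[b]
        ]
        return cls("pseudo_dyads", pairs)

    @classmethod
    def alone_all_pairs(cls, cohort: Cohort) -> "PairingScheme":
        return cls("alone_all_pairs", list(combinations(cohort.alone_subjects(), 2)))


def _joint_values(
    a: SubjectSeries, b: SubjectSeries, channel: str
) -> tuple[np.ndarray, np.ndarray]:
    if a.n_samples != b.n_samples:
        raise InvalidArgumentError("series lengths differ")
    x, y = a.channel(channel), b.channel(channel)
    joint = ~(a.missing_mask | b.missing_mask)
    if joint.sum() < MIN_JOINT_SAMPLES:
        raise InvalidArgumentError(
            f"fewer than {MIN_JOINT_SAMPLES} joint non-missing samples"
        )
    return x[joint], y[joint]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise UndefinedCorrelationError("zero variance in an input series")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def global_synchrony(a: SubjectSeries, b: SubjectSeries, channel: str) -> float:
    """Pearson correlation of one channel over the jointly unmasked samples."""
    return _pearson(*_joint_values(a, b, channel))


def sliding_corr(x: np.ndarray, y: np.ndarray, window: int, step: int = 1) -> np.ndarray:
    """Centered moving-window Pearson correlation of two clean 1-d arrays.

    Windows are truncated at the edges; one value per ``step`` samples.
    Windows in which either input is constant yield NaN (masked).
    Vectorized with prefix sums so that large batch computations stay fast.
    """
    n = x.size
    centers = np.arange(0, n, step)
    lo = np.maximum(centers - window // 2, 0)
    hi = np.minimum(centers + (window - window // 2), n)

    def csum(v: np.ndarray) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(v)])

    sx, sy = csum(x), csum(y)
    sxx, syy, sxy = csum(x * x), csum(y * y), csum(x * y)
    cnt = (hi - lo).astype(float)
    ex = (sx[hi] - sx[lo]) / cnt
    ey = (sy[hi] - sy[lo]) / cnt
    vx = (sxx[hi] - sxx[lo]) / cnt - ex**2
    vy = (syy[hi] - syy[lo]) / cnt - ey**2
    cov = (sxy[hi] - sxy[lo]) / cnt - ex * ey
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(vx * vy)
    tiny = 1e-12 * max(float(np.var(x)), float(np.var(y)), 1.0)
    r[(vx <= tiny) | (vy <= tiny)] = np.nan
    return np.clip(r, -1.0, 1.0)


def dynamic_synchrony(
    a: SubjectSeries,
    b: SubjectSeries,
    channel: str,
    window_s: float = 30.0,
    step_s: float = 1.0,
) -> pd.DataFrame:
    """Moving-window synchrony time series for one channel.

    Returns a DataFrame with columns ``time_s`` (window centers) and ``r``.
    Windows are centered on each step and truncated at the series edges;
    windows with zero variance in either input are NaN. Missing samples are
    dropped pairwise within each window.
    """
    if step_s <= 0:
        raise InvalidArgumentError("step_s must be positive")
    if window_s < 3:
        raise InvalidArgumentError("window_s must be at least 3 s")
    if a.n_samples != b.n_samples:
        raise InvalidArgumentError("series lengths differ")
    fs = a.fs_hz
    n = a.n_samples
    if n < window_s * fs:
        raise InvalidArgumentError("series shorter than one window")
    window = int(round(window_s * fs))
    step = max(1, int(round(step_s * fs)))
    x, y = a.channel(channel), b.channel(channel)
    joint = ~(a.missing_mask | b.missing_mask)
    centers = np.arange(0, n, step)
    times = centers / fs
    if joint.all():
        r = sliding_corr(x, y, window, step)
        return pd.DataFrame({"time_s": times, "r": r})
    out = np.full(centers.size, np.nan)
    for i, c in enumerate(centers):
        lo = max(c - window // 2, 0)
        hi = min(c + (window - window // 2), n)
        sel = joint[lo:hi]
        if sel.sum() < 3:
            continue
        xs, ys = x[lo:hi][sel], y[lo:hi][sel]
        if xs.std() == 0 or ys.std() == 0:
            continue
        out[i] = np.corrcoef(xs, ys)[0, 1]
    return pd.DataFrame({"time_s": times, "r": out})


def crosscorr_offset(
    a: SubjectSeries,
    b: SubjectSeries,
    channel: str,
    max_lag_s: float = 3.0,
    step_s: float = 0.1,
) -> tuple[pd.DataFrame, float]:
    """Lagged cross-correlation profile and its peak lag.

    Computes the Pearson correlation between ``a`` at time t and ``b`` at
    time t + lag for lags in [-max_lag_s, +max_lag_s] sampled every
    ``step_s``; the series must be sampled at least at 1/step_s. Ties in the
    profile are broken toward the smaller absolute lag. A positive returned
    lag means ``b`` trails ``a``.
    """
    fs = a.fs_hz
    if fs < 1.0 / step_s - 1e-9:
        raise InvalidArgumentError("series rate too low for the requested lag step")
    if a.n_samples < 2 * max_lag_s * fs:
        raise InvalidArgumentError("series shorter than twice the maximum lag")
    step = max(1, int(round(step_s * fs)))
    max_shift = int(round(max_lag_s * fs))
    x, y = a.channel(channel), b.channel(channel)
    joint = ~(a.missing_mask | b.missing_mask)
    lags = np.arange(-max_shift, max_shift + 1, step)
    rs = np.empty(lags.size)
    for i, lag in enumerate(lags):
        if lag >= 0:
            xs, ys = x[: x.size - lag], y[lag:]
            sel = joint[: x.size - lag] & joint[lag:]
        else:
            xs, ys = x[-lag:], y[: y.size + lag]
            sel = joint[-lag:] & joint[: y.size + lag]
        rs[i] = _pearson(xs[sel], ys[sel])
    profile = pd.DataFrame({"lag_s": lags / fs, "r": rs})
    # argmax with ties broken toward lag 0
    order = np.lexsort((np.abs(lags), -rs))
    best_lag = float(lags[order[0]] / fs)
    return profile, best_lag


def group_synchrony(
    cohort: Cohort,
    scheme: PairingScheme,
    channel: str,
    excluded: list | None = None,
    series: dict | None = None,
) -> pd.DataFrame:
    """Global synchrony for every pair of a pairing scheme.

    Returns one row per pair with columns (subject_a, subject_b,
    pairing_scheme, channel, episode, r). ``series`` overrides
    ``cohort.series`` (e.g. to use preprocessed valence or EDA series).
    Raises if the scheme touches a QC-excluded subject.
    """
    excluded = set(excluded or ())
    bad = sorted(excluded & set(scheme.subjects))
    if bad:
        raise InvalidArgumentError(f"scheme includes QC-excluded subjects: {bad}")
    data = series if series is not None else cohort.series
    rows = [
        (a, b, scheme.name, channel, cohort.episode,
         global_synchrony(data[a], data[b], channel))
        for a, b in scheme.pairs
    ]
    return pd.DataFrame(
        rows,
        columns=["subject_a", "subject_b", "pairing_scheme", "channel", "episode", "r"],
    )


def all_pairs_synchrony(
    cohort: Cohort,
    channel: str,
    subjects: list | None = None,
    series: dict | None = None,
) -> pd.DataFrame:
    """Global synchrony for every unordered pair among ``subjects``.

    Used by the resampling machinery, which needs correlations between
    subjects irrespective of group membership.
    """
    data = series if series is not None else cohort.series
    subjects = list(subjects) if subjects is not None else cohort.subject_ids
    rows = [
        (a, b, "all_pairs", channel, cohort.episode,
         global_synchrony(data[a], data[b], channel))
        for a, b in combinations(subjects, 2)
    ]
    return pd.DataFrame(
        rows,
        columns=["subject_a", "subject_b", "pairing_scheme", "channel", "episode", "r"],
    )
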