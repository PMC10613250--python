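"""Synthetic cohort generator with planted, exported ground truth.

Emulates the statistical structure of a co-viewing experiment: a
stimulus-locked affective drive shared by every viewer, an additional
dyad-specific shared component present only in pairs who watched together,
subject-specific orthonormal channel-mixing maps for the facial action units,
event-based electrodermal activity, impression ratings with a dyad-level
correlation, and partner-connection ratings driven by the planted
shared-experience strength.

Every quantity used in generation is returned in a :class:`GroundTruth`
object so that recovery tests can compare estimates against the truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    AU_CHANNELS,
    EMOTION_CHANNELS,
    Cohort,
    InvalidArgumentError,
    SubjectSeries,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_stimulus",
    "simulate_cohort",
    "random_orthonormal",
    "scr_kernel",
    "write_cohort",
    "read_cohort",
]

#: relative gains of the five negative-emotion channels on the fear-like latent
_NEGATIVE_GAINS = {
    "anger": 1.0,
    "fear": 0.9,
    "disgust": 0.8,
    "sadness": 0.7,
    "contempt": 0.6,
}


@dataclass
class SimConfig:
    """Parameters of one simulated cohort.

    Defaults mirror the design of the co-viewing study being emulated:
    28 analyzed dyads, 21 solo viewers, one 45-minute episode at 1 Hz,
    20 action-unit channels. Couplings are unitless gains applied to
    unit-variance latent trajectories, so ``noise_sd=1`` means the
    channel-level signal-to-noise ratio equals the squared coupling.

    ``dyad_coupling_range``, when set, draws each dyad's coupling uniformly
    from the given interval instead of using the scalar ``dyad_coupling`` —
    this plants between-dyad variation in shared-experience strength, which
    the connection ratings then track through ``connection_slope``.

    ``social_gain`` multiplies the stimulus coupling of dyad-group subjects:
    social facilitation amplifies stimulus-driven expressiveness in company,
    which makes pseudo dyads (co-viewing-group members who did not watch
    together) more synchronized than solo viewers even though they share
    nothing beyond the stimulus. Set it to 1 to remove the effect.
    """

    n_dyads: int = 28
    n_alone: int = 21
    duration_s: float = 2700.0
    fs_hz: float = 1.0
    n_aus: int = 20
    stimulus_coupling: float = 0.5
    dyad_coupling: float = 0.3
    noise_sd: float = 1.0
    eda_event_rate: float = 3.0  # nonspecific SCR events per minute
    impression_dyad_corr: float = 0.5
    connection_slope: float = 5.0  # rating units per unit of dyad coupling
    seed: int = 0
    dyad_coupling_range: tuple | None = None
    social_gain: float = 1.3
    eda_fs_hz: float = 4.0
    n_characters: int = 13
    n_questions: int = 8

    def __post_init__(self) -> None:
        for name in ("stimulus_coupling", "dyad_coupling", "noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidArgumentError(f"{name} must be finite")
        if self.n_dyads == 0 and self.n_alone == 0:
            raise InvalidArgumentError("cohort must contain at least one subject")
        if self.n_dyads < 0 or self.n_alone < 0:
            raise InvalidArgumentError("group sizes must be non-negative")
        n_samples = self.duration_s * self.fs_hz
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise InvalidArgumentError("duration_s * fs_hz must be an integer")
        # at least two sliding windows (30 s) worth of samples
        if n_samples < 60 * self.fs_hz:
            raise InvalidArgumentError("duration_s must cover >= 60 s of samples")
        if not -1.0 <= self.impression_dyad_corr <= 1.0:
            raise InvalidArgumentError("impression_dyad_corr must lie in [-1, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs_hz))


@dataclass
class GroundTruth:
    """Everything planted by :func:`simulate_cohort`.

    ``stimulus`` holds the two unit-variance latent emotion trajectories
    (columns ``joy`` and ``fear``); ``mixing_maps`` the per-subject
    orthonormal channel maps (n_aus x 2, columns in the order joy, fear);
    ``dyad_coupling`` and ``true_connection_mean`` the per-dyad planted
    values; ``dyad_latents`` the dyad-specific shared trajectories.
    """

    stimulus: pd.DataFrame
    mixing_maps: dict = field(default_factory=dict)
    dyad_coupling: dict = field(default_factory=dict)
    true_connection_mean: dict = field(default_factory=dict)
    dyad_latents: dict = field(default_factory=dict)


def random_orthonormal(n_rows: int, n_cols: int, rng: np.random.Generator) -> np.ndarray:
    """Random matrix with orthonormal columns via QR of a Gaussian draw.

    The sign of each column is fixed so the output is a deterministic
    function of the Gaussian draw.
    """
    if n_cols > n_rows:
        raise InvalidArgumentError("cannot have more orthonormal columns than rows")
    q, r = np.linalg.qr(rng.standard_normal((n_rows, n_cols)))
    return q * np.sign(np.diag(r))


def _event_trajectory(
    n_samples: int,
    fs_hz: float,
    onsets_s: np.ndarray,
    event_width_s: float,
    smooth_s: float,
) -> np.ndarray:
    """Sum of boxcar events convolved with a Hann smoothing kernel."""
    traj = np.zeros(n_samples)
    width = max(1, int(round(event_width_s * fs_hz)))
    for onset in onsets_s:
        lo = int(round(onset * fs_hz))
        traj[max(lo, 0) : min(lo + width, n_samples)] += 1.0
    n_smooth = max(1, int(round(smooth_s * fs_hz)))
    if n_smooth > 1:
        kernel = np.hanning(n_smooth + 2)[1:-1]
        kernel /= kernel.sum()
        traj = np.convolve(traj, kernel, mode="same")
    return traj


def simulate_stimulus(
    duration_s: float,
    n_events: int,
    seed: int = 0,
    fs_hz: float = 1.0,
    event_width_s: float = 20.0,
    smooth_s: float = 10.0,
    onsets_s: list | None = None,
) -> pd.DataFrame:
    """Latent stimulus-locked emotion trajectories (joy-like and fear-like).

    Each channel is a sum of ``n_events`` boxcar events of width
    ``event_width_s`` at uniformly random onsets, convolved with a Hann
    kernel of width ``smooth_s``; trajectories are nonnegative and smooth.
    ``onsets_s`` overrides the random onsets (applied to both channels) for
    controlled constructions.

    Returns a DataFrame with columns ``time_s``, ``joy``, ``fear``.
    """
    if duration_s <= 0:
        raise InvalidArgumentError("duration_s must be positive")
    if n_events < 0:
        raise InvalidArgumentError("n_events must be non-negative")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * fs_hz))
    out = {"time_s": np.arange(n_samples) / fs_hz}
    for name in ("joy", "fear"):
        if onsets_s is not None:
            onsets = np.asarray(onsets_s, dtype=float)
        else:
            onsets = rng.uniform(0, max(duration_s - event_width_s, 0), size=n_events)
        out[name] = _event_trajectory(n_samples, fs_hz, onsets, event_width_s, smooth_s)
    return pd.DataFrame(out)


def scr_kernel(fs_hz: float, rise_s: float = 1.0, decay_s: float = 4.0) -> np.ndarray:
    """Skin-conductance-response kernel: difference of exponentials.

    ``h(t) = exp(-t/decay) - exp(-t/rise)``, truncated at five decay
    constants and peak-normalized to 1.
    """
    t = np.arange(0, 5 * decay_s, 1.0 / fs_hz)
    h = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = h.max()
    if peak <= 0:
        raise InvalidArgumentError("decay_s must exceed rise_s")
    return h / peak


def _scr_train(
    n_samples: int, fs_hz: float, rate_per_min: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson impulse train with Uniform(0.5, 1.5) amplitudes."""
    p = rate_per_min / 60.0 / fs_hz
    events = rng.random(n_samples) < p
    train = np.zeros(n_samples)
    train[events] = rng.uniform(0.5, 1.5, size=int(events.sum()))
    return train


def _unit_sd(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return x / sd if sd > 0 else x


def _smooth_noise(
    rng: np.random.Generator, shape: tuple, fs_hz: float, width_s: float
) -> np.ndarray:
    """Temporally autocorrelated unit-variance noise (Hann-smoothed white).

    Facial-evidence and electrodermal residuals are smooth, not white —
    expressions unfold over seconds — and that autocorrelation is exactly
    why the inference machinery resamples subjects and uses circular-shift
    surrogates. ``width_s`` sets the smoothing kernel width; the kernel is
    L2-normalized so the marginal variance stays 1.
    """
    white = rng.standard_normal(shape)
    n = max(1, int(round(width_s * fs_hz)))
    if n <= 1:
        return white
    kernel = np.hanning(n + 2)[1:-1]
    kernel /= np.sqrt((kernel**2).sum())
    from scipy.signal import fftconvolve

    return fftconvolve(white, kernel[:, None] if white.ndim == 2 else kernel,
                       mode="same", axes=0)


def simulate_cohort(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Generate one cohort episode plus its planted ground truth.

    Facial channels of subject ``i`` follow
    ``X_i = M_i (c_stim * S + c_dyad * D_d) + noise`` where ``S`` is the
    stimulus-locked latent pair (joy-like, fear-like), ``D_d`` is a smooth
    latent pair shared only within true dyads, and ``M_i`` is a random
    orthonormal mixing map. Emotion-evidence channels are built from the
    same latents (joy from the joy-like latent, the five negative emotions
    from the fear-like latent, surprise from an even mixture). EDA is a sum
    of SCR-shaped responses to stimulus-locked, dyad-shared, and private
    Poisson events on top of a slowly drifting positive tonic level.
    Connection ratings are ``3 + connection_slope * coupling_d`` plus noise,
    rounded and clipped to the 1-9 scale.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_samples
    fs = cfg.fs_hz

    # --- stimulus-locked latents, scaled to unit variance -------------------
    n_events = max(1, int(cfg.duration_s // 150))
    stim = simulate_stimulus(
        cfg.duration_s,
        n_events,
        seed=int(rng.integers(2**31)),
        fs_hz=fs,
    )
    s_joy = _unit_sd(stim["joy"].to_numpy())
    s_fear = _unit_sd(stim["fear"].to_numpy())
    stimulus = pd.DataFrame(
        {"time_s": stim["time_s"], "joy": s_joy, "fear": s_fear}
    )

    # --- roster --------------------------------------------------------------
    rows = []
    for d in range(cfg.n_dyads):
        dyad_id = f"d{d + 1:02d}"
        for m in ("a", "b"):
            rows.append((f"sub-{dyad_id}{m}", "dyad", dyad_id))
    for a in range(cfg.n_alone):
        rows.append((f"sub-s{a + 1:02d}", "alone", ""))
    roster = pd.DataFrame(rows, columns=["subject_id", "group", "dyad_id"])

    truth = GroundTruth(stimulus=stimulus)

    # --- per-dyad shared latents and couplings -------------------------------
    def smooth_noise() -> np.ndarray:
        raw = rng.standard_normal(n_samples)
        n_smooth = max(1, int(round(10.0 * fs)))
        kernel = np.hanning(n_smooth + 2)[1:-1]
        kernel /= np.sqrt((kernel**2).sum())
        return _unit_sd(np.convolve(raw, kernel, mode="same"))

    dyad_ids = [f"d{d + 1:02d}" for d in range(cfg.n_dyads)]
    for dyad_id in dyad_ids:
        if cfg.dyad_coupling_range is not None:
            lo, hi = cfg.dyad_coupling_range
            coupling = float(rng.uniform(lo, hi))
        else:
            coupling = float(cfg.dyad_coupling)
        truth.dyad_coupling[dyad_id] = coupling
        truth.dyad_latents[dyad_id] = np.vstack([smooth_noise(), smooth_noise()])

    # --- per-subject facial series -------------------------------------------
    stim_latent = np.vstack([s_joy, s_fear])  # 2 x T
    channel_names = list(AU_CHANNELS[: cfg.n_aus]) + list(EMOTION_CHANNELS)
    series: dict[str, SubjectSeries] = {}
    eda_series: dict[str, SubjectSeries] = {}
    n_eda = int(round(cfg.duration_s * cfg.eda_fs_hz))
    kernel_scr = scr_kernel(cfg.eda_fs_hz)

    # stimulus-locked SCR events are common to every viewer
    common_train = _scr_train(n_eda, cfg.eda_fs_hz, cfg.eda_event_rate / 3, rng)
    dyad_trains = {
        dyad_id: _scr_train(n_eda, cfg.eda_fs_hz, cfg.eda_event_rate / 3, rng)
        for dyad_id in dyad_ids
    }

    for _, row in roster.iterrows():
        sid, group, dyad_id = row["subject_id"], row["group"], row["dyad_id"]
        if group == "dyad":
            coupling = truth.dyad_coupling[dyad_id]
            dyad_latent = truth.dyad_latents[dyad_id]
            stim_gain = cfg.stimulus_coupling * cfg.social_gain
        else:
            coupling = 0.0
            dyad_latent = np.zeros((2, n_samples))
            stim_gain = cfg.stimulus_coupling

        latent = stim_gain * stim_latent + coupling * dyad_latent
        mix = random_orthonormal(cfg.n_aus, 2, rng)
        truth.mixing_maps[sid] = mix
        # per-subject residual smoothness: expressive dynamics differ across
        # people, which puts subject-level structure into the pairwise
        # correlations exactly as the subject-wise resampling assumes
        noise_width = float(rng.uniform(2.0, 12.0))
        aus = (mix @ latent).T + cfg.noise_sd * _smooth_noise(
            rng, (n_samples, cfg.n_aus), fs, noise_width
        )

        emo = np.empty((n_samples, len(EMOTION_CHANNELS)))
        emo_noise = cfg.noise_sd * _smooth_noise(
            rng, (n_samples, len(EMOTION_CHANNELS)), fs, noise_width
        )
        for j, name in enumerate(EMOTION_CHANNELS):
            if name == "joy":
                emo[:, j] = latent[0] + emo_noise[:, j]
            elif name == "surprise":
                emo[:, j] = (latent[0] + latent[1]) / np.sqrt(2) + emo_noise[:, j]
            else:
                emo[:, j] = _NEGATIVE_GAINS[name] * latent[1] + emo_noise[:, j]

        series[sid] = SubjectSeries(
            subject_id=sid,
            fs_hz=fs,
            values=np.hstack([aus, emo]),
            channel_names=channel_names,
        )

        # --- EDA: tonic drift plus SCR responses to three event sources -----
        phase = rng.uniform(0, 2 * np.pi)
        t_eda = np.arange(n_eda) / cfg.eda_fs_hz
        tonic = 2.0 + 0.3 * np.sin(2 * np.pi * t_eda / 300.0 + phase)
        private_train = _scr_train(n_eda, cfg.eda_fs_hz, cfg.eda_event_rate / 3, rng)
        driver = (
            stim_gain * common_train
            + coupling * (dyad_trains[dyad_id] if group == "dyad" else 0.0)
            + private_train
        )
        phasic = np.convolve(driver, kernel_scr)[:n_eda]
        eda_series[sid] = SubjectSeries(
            subject_id=sid,
            fs_hz=cfg.eda_fs_hz,
            values=tonic + phasic,
            channel_names=["eda"],
        )

    # --- impression ratings --------------------------------------------------
    profile = rng.normal(50.0, 15.0, size=(cfg.n_characters, cfg.n_questions))
    rho = cfg.impression_dyad_corr
    shared_dev = {
        dyad_id: rng.normal(0.0, 10.0, size=(cfg.n_characters, cfg.n_questions))
        for dyad_id in dyad_ids
    }
    imp_rows = []
    for _, row in roster.iterrows():
        sid, group, dyad_id = row["subject_id"], row["group"], row["dyad_id"]
        own = rng.normal(0.0, 10.0, size=(cfg.n_characters, cfg.n_questions))
        if group == "dyad" and rho != 0.0:
            dev = np.sign(rho) * np.sqrt(abs(rho)) * shared_dev[dyad_id] + np.sqrt(
                1 - abs(rho)
            ) * own
        else:
            dev = own
        ratings = np.clip(profile + dev, 0.0, 100.0)
        for c in range(cfg.n_characters):
            for q in range(cfg.n_questions):
                imp_rows.append((sid, f"char{c + 1:02d}", f"q{q + 1}", ratings[c, q]))
    impressions = pd.DataFrame(
        imp_rows, columns=["subject_id", "character_id", "question_id", "rating"]
    )

    # --- connection ratings --------------------------------------------------
    conn_rows = []
    for dyad_id in dyad_ids:
        coupling = truth.dyad_coupling[dyad_id]
        true_mean = float(np.clip(3.0 + cfg.connection_slope * coupling, 1.0, 9.0))
        truth.true_connection_mean[dyad_id] = true_mean
        for m in ("a", "b"):
            rating = int(np.clip(round(true_mean + rng.normal(0.0, 0.7)), 1, 9))
            conn_rows.append((f"sub-{dyad_id}{m}", dyad_id, rating))
    connection = pd.DataFrame(conn_rows, columns=["subject_id", "dyad_id", "rating"])

    cohort = Cohort(
        roster=roster,
        series=series,
        eda=eda_series,
        impressions=impressions,
        connection=connection,
    )
    return cohort, truth


# --------------------------------------------------------------------------
# on-disk representation (delimited tables + JSON ground truth)
# --------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir, truth: GroundTruth | None = None) -> None:
    """Write a cohort as delimited tables (one facial and one EDA table per
    subject, plus roster/ratings tables); ground truth goes to JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.roster.to_csv(outdir / "roster.csv", index=False)
    cohort.impressions.to_csv(outdir / "impressions.csv", index=False)
    cohort.connection.to_csv(outdir / "connection.csv", index=False)
    for sid, s in cohort.series.items():
        s.to_frame().to_csv(outdir / f"{sid}_facial.csv", index=False)
    for sid, s in cohort.eda.items():
        s.to_frame().to_csv(outdir / f"{sid}_eda.csv", index=False)
    if truth is not None:
        payload = {
            "stimulus": truth.stimulus.to_dict(orient="list"),
            "mixing_maps": {k: v.tolist() for k, v in truth.mixing_maps.items()},
            "dyad_coupling": truth.dyad_coupling,
            "true_connection_mean": truth.true_connection_mean,
        }
        (outdir / "ground_truth.json").write_text(json.dumps(payload))


def read_cohort(indir) -> Cohort:
    """Read back a cohort written by :func:`write_cohort`."""
    indir = Path(indir)
    roster = pd.read_csv(indir / "roster.csv", keep_default_na=False)
    series, eda = {}, {}
    for _, row in roster.iterrows():
        sid = row["subject_id"]
        df = pd.read_csv(indir / f"{sid}_facial.csv")
        dt = np.diff(df["time_s"].to_numpy()[:2])[0] if len(df) > 1 else 1.0
        series[sid] = SubjectSeries(
            subject_id=sid,
            fs_hz=1.0 / dt,
            values=df.drop(columns="time_s").to_numpy(),
            channel_names=[c for c in df.columns if c != "time_s"],
        )
        df_e = pd.read_csv(indir / f"{sid}_eda.csv")
        dt_e = np.diff(df_e["time_s"].to_numpy()[:2])[0] if len(df_e) > 1 else 1.0
        eda[sid] = SubjectSeries(
            subject_id=sid,
            fs_hz=1.0 / dt_e,
            values=df_e["eda"].to_numpy(),
            channel_names=["eda"],
        )
    return Cohort(
        roster=roster,
        series=series,
        eda=eda,
        impressions=pd.read_csv(indir / "impressions.csv"),
        connection=pd.read_csv(indir / "connection.csv"),
    )
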