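"""Rule-based sleep staging from EEG/EMG telemetry.

The classifier reimplements tiered rule-based scoring of rodent telemetry:
signals are binned in 10-s epochs, each bin gets FFT band powers over five
ranges (delta 0.5-4, theta 4-8, alpha 8-12, sigma 12-16, beta 16-24 Hz), an
EEG amplitude tier (low <= 50% of the recording reference maximum, else high)
and an EMG tier (basal <= 33%, intermediate 33-66%, high > 66% of reference).
Stages are assigned on 30-s epochs:

* Wake -- intermediate or high EMG, with or without locomotor activity, EEG
  variable;
* Light sleep -- low-amplitude EEG, intermediate EMG, no locomotion;
* REM (paradoxical) sleep -- high-frequency (theta-dominant) low-amplitude
  EEG, basal EMG, no locomotion, and only entered from a sleep stage (the
  running prior informs the assignment);
* Deep sleep -- high-amplitude EEG enriched in the delta band, basal-to-
  intermediate EMG, no locomotion.

Ambiguous or artifact-bearing epochs are left Unscored.  The reference
"maximum" for tier stratification is the 99th percentile of the per-bin
amplitude envelope, which is robust to artifacts (a literal maximum would be
artifact-dominated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import LightsSchedule
from . import stats_core

__all__ = [
    "BANDS", "STAGES", "UNSCORED", "EPOCH_S", "BIN_S",
    "TelemetryRecording", "BinFeatures", "TierThresholds", "EpochFeatures",
    "Hypnogram", "bin_epochs", "stratify_tiers", "aggregate_epoch",
    "classify_epoch", "score_recording", "summarize_architecture",
    "architecture_stats", "hypnogram_to_frame", "accuracy",
]

BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 16.0),
    "beta": (16.0, 24.0),
}
BAND_NAMES = tuple(BANDS)
STAGES = ("Wake", "Light", "REM", "Deep")
UNSCORED = "Unscored"
EPOCH_S = 30
BIN_S = 10
SLEEP_STAGES = frozenset({"Light", "REM", "Deep"})


@dataclass
class TelemetryRecording:
    """Time-aligned physiological channels for one animal.

    ``eeg``/``emg`` are sampled traces at ``fs`` Hz (arbitrary but consistent
    amplitude units); ``activity`` (locomotor counts) and ``temperature``
    (deg C) are per 10-s bin.  ``start_hour`` is the clock time of the first
    sample in fractional hours.
    """

    animal_id: str
    eeg: np.ndarray
    emg: np.ndarray
    fs: float
    activity: np.ndarray
    temperature: np.ndarray
    lights: LightsSchedule = field(default_factory=LightsSchedule)
    start_hour: float = 4.5

    @property
    def duration_s(self) -> float:
        return len(self.eeg) / self.fs

    @property
    def n_bins(self) -> int:
        return int(len(self.eeg) // (self.fs * BIN_S))

    def bin_clock_hours(self) -> np.ndarray:
        return (self.start_hour + (np.arange(self.n_bins) * BIN_S) / 3600.0) % 24.0


@dataclass
class BinFeatures:
    """Per-10-s-bin features for a whole recording (arrays of length n_bins)."""

    band_power: np.ndarray        # (n_bins, 5) in BAND_NAMES order
    eeg_amplitude: np.ndarray     # peak |EEG| per bin
    emg_level: np.ndarray         # EMG RMS envelope per bin
    locomotion: np.ndarray        # bool per bin
    artifact: np.ndarray          # bool per bin


@dataclass(frozen=True)
class TierThresholds:
    eeg_reference: float
    emg_reference: float


@dataclass(frozen=True)
class EpochFeatures:
    """30-s epoch features: medians of the epoch's three 10-s bins, with
    majority-voted booleans (ties are resolved to Unscored downstream)."""

    band_power: np.ndarray
    eeg_tier: str                 # "low" | "high"
    emg_tier: str                 # "basal" | "intermediate" | "high"
    locomotion: bool
    artifact: bool
    valid: bool = True


@dataclass
class Hypnogram:
    """Per-30-s-epoch stage labels; Unscored is the ambiguity/artifact sink."""

    stages: np.ndarray
    start_hour: float = 4.5
    lights: LightsSchedule = field(default_factory=LightsSchedule)
    epoch_s: int = EPOCH_S

    def __len__(self) -> int:
        return len(self.stages)

    def epoch_clock_hours(self) -> np.ndarray:
        return (self.start_hour
                + (np.arange(len(self.stages)) * self.epoch_s) / 3600.0) % 24.0

    @property
    def unscored_fraction(self) -> float:
        return float(np.mean(self.stages == UNSCORED))


def bin_epochs(recording: TelemetryRecording) -> BinFeatures:
    """Per-10-s-bin FFT band powers, amplitude/EMG envelopes and flags.

    FFT per bin uses a Hann window with no overlap; band power is the
    periodogram summed over half-open [low, high) frequency intervals.
    Artifact bins are those with a sample beyond 6x the bin's robust SD
    (1.4826 * MAD) or with zero variance (flat line).
    """
    fs = recording.fs
    if fs < 48:
        raise ValueError("sampling rate must be >= 48 Hz to resolve the "
                         "16-24 Hz band")
    bin_len = int(round(fs * BIN_S))
    n_bins = len(recording.eeg) // bin_len
    if n_bins * EPOCH_S // BIN_S == 0 or n_bins < EPOCH_S // BIN_S:
        raise ValueError("recording shorter than one 30-s epoch")

    eeg = np.asarray(recording.eeg, dtype=float)[: n_bins * bin_len]
    emg = np.asarray(recording.emg, dtype=float)[: n_bins * bin_len]
    eeg_b = eeg.reshape(n_bins, bin_len)
    emg_b = emg.reshape(n_bins, bin_len)

    window = np.hanning(bin_len)
    spec = np.fft.rfft(eeg_b * window, axis=1)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(bin_len, d=1.0 / fs)
    band_power = np.empty((n_bins, len(BAND_NAMES)))
    for j, name in enumerate(BAND_NAMES):
        lo, hi = BANDS[name]
        mask = (freqs >= lo) & (freqs < hi)
        band_power[:, j] = power[:, mask].sum(axis=1)

    eeg_amp = np.abs(eeg_b).max(axis=1)
    emg_level = np.sqrt((emg_b ** 2).mean(axis=1))

    med = np.median(eeg_b, axis=1, keepdims=True)
    mad = np.median(np.abs(eeg_b - med), axis=1)
    robust_sd = 1.4826 * mad
    flat = eeg_b.var(axis=1) < 1e-12
    spike = eeg_amp > 6.0 * np.where(robust_sd > 0, robust_sd, np.inf)
    artifact = spike | flat

    activity = np.asarray(recording.activity)[:n_bins]
    locomotion = activity > 0

    return BinFeatures(band_power, eeg_amp, emg_level, locomotion, artifact)


def stratify_tiers(bins: BinFeatures,
                   reference: TierThresholds | None = None,
                   percentile: float = 99.0) -> TierThresholds:
    """Reference maxima for tier stratification.

    The reference "maximum" is the given percentile (default 99th) of the
    per-bin envelope over the whole recording, excluding artifact bins; tier
    cut points are scale-free fractions of it (EEG low <= 50%; EMG thirds).
    """
    if reference is not None:
        return reference
    ok = ~bins.artifact
    if not ok.any():
        raise ValueError("no artifact-free bins to derive reference maxima")
    eeg_ref = float(np.percentile(bins.eeg_amplitude[ok], percentile))
    emg_ref = float(np.percentile(bins.emg_level[ok], percentile))
    if eeg_ref <= 0 or emg_ref <= 0:
        raise ValueError("zero reference maximum")
    return TierThresholds(eeg_ref, emg_ref)


def eeg_tier(amplitude: float, ref: TierThresholds) -> str:
    return "low" if amplitude <= 0.5 * ref.eeg_reference else "high"


def emg_tier(level: float, ref: TierThresholds) -> str:
    frac = level / ref.emg_reference
    if frac <= 1.0 / 3.0:
        return "basal"
    if frac <= 2.0 / 3.0:
        return "intermediate"
    return "high"


def aggregate_epoch(bins: BinFeatures, epoch_index: int,
                    ref: TierThresholds) -> EpochFeatures:
    """Aggregate three consecutive 10-s bins into 30-s epoch features."""
    bins_per_epoch = EPOCH_S // BIN_S
    i0 = epoch_index * bins_per_epoch
    i1 = i0 + bins_per_epoch
    if i1 > len(bins.eeg_amplitude):
        raise IndexError("epoch extends past the recording")
    bp = np.median(bins.band_power[i0:i1], axis=0)
    amp = float(np.median(bins.eeg_amplitude[i0:i1]))
    emg = float(np.median(bins.emg_level[i0:i1]))
    loco = int(bins.locomotion[i0:i1].sum()) * 2 > bins_per_epoch
    artifact = bool(bins.artifact[i0:i1].any())
    return EpochFeatures(bp, eeg_tier(amp, ref), emg_tier(emg, ref),
                         bool(loco), artifact)


def classify_epoch(epoch: EpochFeatures, prior_stage: str) -> str:
    """Apply the stage rule table to one epoch given the running prior.

    REM requires the prior stage to be a sleep stage (Light, Deep or REM);
    a REM-like epoch following Wake is left Unscored.  Artifact-bearing or
    rule-unmatched epochs are Unscored.
    """
    if epoch.artifact or not epoch.valid:
        return UNSCORED
    bp = epoch.band_power
    delta = bp[BAND_NAMES.index("delta")]
    theta = bp[BAND_NAMES.index("theta")]
    delta_dominant = bool(delta > np.delete(bp, BAND_NAMES.index("delta")).max())

    if epoch.locomotion and epoch.emg_tier in ("intermediate", "high"):
        return "Wake"
    if epoch.emg_tier == "high":
        return "Wake"
    if (not epoch.locomotion and epoch.eeg_tier == "high" and delta_dominant
            and epoch.emg_tier in ("basal", "intermediate")):
        return "Deep"
    if (not epoch.locomotion and epoch.eeg_tier == "low"
            and epoch.emg_tier == "intermediate"):
        return "Light"
    if epoch.emg_tier == "intermediate":
        return "Wake"   # EEG variable
    if (not epoch.locomotion and epoch.emg_tier == "basal"
            and epoch.eeg_tier == "low" and theta > delta):
        if prior_stage in SLEEP_STAGES:
            return "REM"
        return UNSCORED
    return UNSCORED


def score_recording(recording: TelemetryRecording,
                    reference: TierThresholds | None = None) -> Hypnogram:
    """Score a recording into a 30-s hypnogram with a running prior stage."""
    bins = bin_epochs(recording)
    ref = stratify_tiers(bins, reference)
    n_epochs = len(bins.eeg_amplitude) // (EPOCH_S // BIN_S)
    labels = np.empty(n_epochs, dtype=object)
    prior = "Wake"
    for i in range(n_epochs):
        feats = aggregate_epoch(bins, i, ref)
        stage = classify_epoch(feats, prior)
        labels[i] = stage
        if stage != UNSCORED:
            prior = stage
    return Hypnogram(labels, recording.start_hour, recording.lights)


def _window_minutes(hyp: Hypnogram, start_clock: float) -> dict:
    """Stage minutes within the 4-h window beginning at start_clock."""
    hours = hyp.epoch_clock_hours()
    rel = (hours - start_clock) % 24.0
    in_window = rel < 4.0
    expected = int(4 * 3600 / hyp.epoch_s)
    n_found = int(in_window.sum())
    if n_found < expected:
        raise ValueError(
            f"recording does not cover the 4-h window starting at clock hour "
            f"{start_clock:.2f} ({n_found}/{expected} epochs present)")
    sel = hyp.stages[in_window]
    out = {}
    for st in STAGES + (UNSCORED,):
        out[st] = float((sel == st).sum() * hyp.epoch_s / 60.0)
    return out


def summarize_architecture(hyp: Hypnogram,
                           lights: LightsSchedule | None = None) -> pd.DataFrame:
    """Stage minutes in the first 4 h of the active and resting periods.

    Stage minutes plus unscored minutes sum to 240 in each window.
    """
    lights = lights if lights is not None else hyp.lights
    rows = []
    for period, start in (("active", lights.lights_off),
                          ("resting", lights.lights_on)):
        mins = _window_minutes(hyp, start)
        for st, m in mins.items():
            rows.append({"period": period, "stage": st, "minutes": m})
    return pd.DataFrame(rows)


def architecture_stats(summaries: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Age x stress ANOVA per stage x period, with gated LSD pairs.

    ``summaries`` is tidy with columns animal, age, stress, period, stage,
    minutes.  Each sleep stage in each period is tested separately; pairwise
    Fisher's LSD contrasts (control vs stress within each age, and young vs
    aged within control) are computed when the omnibus interaction or a main
    effect is significant.
    """
    anova_rows, lsd_rows = [], []
    for (period, stage), grp in summaries.groupby(["period", "stage"]):
        if stage == UNSCORED:
            continue
        res = stats_core.two_way_anova(grp["minutes"], grp["age"], grp["stress"],
                                       names=("age", "stress"))
        for fac in res.factors:
            anova_rows.append({"period": period, "stage": stage,
                               "factor": fac.name, "F": fac.f, "df1": fac.df_num,
                               "df2": fac.df_den, "p": fac.p,
                               "significant": fac.p <= alpha})
        gated = any(f.p <= alpha for f in res.factors)
        if gated and not res.degenerate:
            cells = {f"{a}-{s}": grp.loc[(grp.age == a) & (grp.stress == s),
                                         "minutes"].to_numpy()
                     for a in ("young", "aged") for s in ("control", "stress")}
            for pair in (("young-control", "young-stress"),
                         ("aged-control", "aged-stress"),
                         ("young-control", "aged-control")):
                pw = stats_core.fishers_lsd(cells, res.mse_within, res.df_error,
                                            pair)
                lsd_rows.append({"period": period, "stage": stage,
                                 "pair": " vs ".join(pair),
                                 "mean_diff": pw.mean_diff, "t": pw.t,
                                 "p": pw.p, "significant": pw.p <= alpha})
    return {"anova": pd.DataFrame(anova_rows), "lsd": pd.DataFrame(lsd_rows)}


def hypnogram_to_frame(hyp: Hypnogram) -> pd.DataFrame:
    """Serialize a hypnogram as (epoch_start_s, clock_hour, stage)."""
    n = len(hyp)
    return pd.DataFrame({
        "epoch_start_s": np.arange(n) * hyp.epoch_s,
        "clock_hour": hyp.epoch_clock_hours(),
        "stage": hyp.stages,
    })


def accuracy(scored: Hypnogram, truth: Hypnogram) -> float:
    """Per-epoch agreement with ground truth (Unscored counts as disagreement)."""
    n = min(len(scored), len(truth))
    return float(np.mean(scored.stages[:n] == truth.stages[:n]))
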