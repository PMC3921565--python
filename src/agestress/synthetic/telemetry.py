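"""Synthetic EEG/EMG/temperature/activity telemetry with ground truth.

The generator first draws a ground-truth hypnogram at the 30-s scoring
resolution from a diurnally modulated Markov stage program (REM entered only
from sleep states), then synthesizes signal per epoch, which avoids label
ambiguity at stage boundaries:

* EEG -- per true stage: Deep is a high-amplitude 0.5-4 Hz-dominant
  oscillation; REM a low-amplitude 4-8 Hz-dominant oscillation; Light is
  low-amplitude broadband; Wake higher-amplitude broadband.  Units are
  arbitrary but internally consistent (no electrode gain is modeled).
* EMG -- white noise at a stage-appropriate tier (basal in REM, basal-to-
  intermediate in Deep, intermediate in Light, intermediate/high in Wake).
* Locomotor activity -- nonzero counts only in Wake bins.
* Temperature -- 24-h circadian sinusoid peaking mid-active-period, AR(1)
  noise, a per-animal baseline offset, and an additive stress-hyperthermia
  offset during the resting period for stressed animals (large in young,
  small in aged).

Artifacts (large-amplitude spike bursts) are injected at a configured
per-epoch rate and recorded in the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..design import CohortDesign, LightsSchedule
from ..sleep import (BIN_S, EPOCH_S, Hypnogram, STAGES, TelemetryRecording)

__all__ = ["StageProgram", "default_stage_program", "TemperatureModel",
           "gen_hypnogram", "gen_temperature_bins", "gen_telemetry",
           "TelemetryTruth"]

_STAGE_IDX = {s: i for i, s in enumerate(STAGES)}


@dataclass
class StageProgram:
    """Markov stage-transition program with diurnal and group modulation.

    ``transitions`` maps period ("active"/"resting") to a 4x4 row-stochastic
    matrix over (Wake, Light, REM, Deep).  ``modifiers`` maps
    (age_group, stress_group) to {period: {stage: propensity multiplier}}
    applied to target-stage columns before row renormalization; structural
    zeros (REM from Wake) are preserved, so REM is entered only from sleep.
    """

    transitions: dict
    modifiers: dict = field(default_factory=dict)

    def __post_init__(self):
        for period, mat in self.transitions.items():
            m = np.asarray(mat, dtype=float)
            if m.shape != (4, 4) or (m < 0).any():
                raise ValueError(f"bad transition matrix for {period}")
            if not np.allclose(m.sum(axis=1), 1.0):
                raise ValueError(f"rows must sum to 1 for {period}")
            if m[_STAGE_IDX["Wake"], _STAGE_IDX["REM"]] != 0:
                raise ValueError("REM may only be entered from sleep states")
            self.transitions[period] = m

    def matrix(self, period: str, age: str, stress: str) -> np.ndarray:
        m = self.transitions[period].copy()
        mods = self.modifiers.get((age, stress), {}).get(period, {})
        for stage, mult in mods.items():
            m[:, _STAGE_IDX[stage]] *= mult
        m[_STAGE_IDX["Wake"], _STAGE_IDX["REM"]] = 0.0
        return m / m.sum(axis=1, keepdims=True)


def default_stage_program() -> StageProgram:
    """Default program: wake-dominant active period, sleep-dominant resting
    period; aged animals get less resting deep sleep; stressed young get a
    wake-shifted, REM/deep-poor resting period and extra active-period deep
    sleep; stressed aged get elevated resting REM only."""
    active = [
        # Wake  Light  REM   Deep
        [0.86, 0.11, 0.00, 0.03],   # from Wake
        [0.35, 0.45, 0.05, 0.15],   # from Light
        [0.25, 0.15, 0.55, 0.05],   # from REM
        [0.10, 0.15, 0.05, 0.70],   # from Deep
    ]
    resting = [
        [0.55, 0.38, 0.00, 0.07],
        [0.10, 0.55, 0.06, 0.29],
        [0.12, 0.15, 0.68, 0.05],
        [0.03, 0.13, 0.06, 0.78],
    ]
    modifiers = {
        ("aged", "control"): {"resting": {"Deep": 0.55}},
        ("aged", "stress"): {"resting": {"Deep": 0.55, "REM": 1.8}},
        ("young", "stress"): {"resting": {"Wake": 2.8, "REM": 0.40, "Deep": 0.45},
                              "active": {"Deep": 2.2}},
    }
    return StageProgram({"active": active, "resting": resting}, modifiers)


def gen_hypnogram(n_epochs: int, age: str, stress: str,
                  program: StageProgram, rng: np.random.Generator,
                  start_hour: float = 4.5,
                  lights: LightsSchedule | None = None) -> Hypnogram:
    """Draw a ground-truth hypnogram from the stage program."""
    lights = lights if lights is not None else LightsSchedule()
    labels = np.empty(n_epochs, dtype=object)
    hours = (start_hour + np.arange(n_epochs) * EPOCH_S / 3600.0) % 24.0
    active = lights.is_active(hours)
    cum = {p: np.cumsum(program.matrix(p, age, stress), axis=1)
           for p in ("active", "resting")}
    u = rng.random(n_epochs)
    state = _STAGE_IDX["Wake"] if active[0] else _STAGE_IDX["Deep"]
    for i in range(n_epochs):
        row = cum["active" if active[i] else "resting"][state]
        state = int(np.searchsorted(row, u[i], side="right"))
        state = min(state, 3)
        labels[i] = STAGES[state]
    return Hypnogram(labels, start_hour, lights)


@dataclass
class TemperatureModel:
    """Circadian sinusoid + AR(1) noise + stress-hyperthermia offset."""

    baseline: float = 37.0
    amplitude: float = 0.4          # deg C, half peak-to-trough
    peak_hour: float = 10.5         # mid-active-period under the default lights
    animal_sd: float = 0.08         # per-animal baseline spread
    ar_phi: float = 0.9
    ar_sd: float = 0.05
    stress_offsets: dict = field(
        default_factory=lambda: {"young": 0.6, "aged": 0.1})
    offset_period: str = "resting"  # clock window carrying the offset


def gen_temperature_bins(n_bins: int, start_hour: float, age: str, stress: str,
                         model: TemperatureModel, rng: np.random.Generator,
                         lights: LightsSchedule | None = None) -> np.ndarray:
    lights = lights if lights is not None else LightsSchedule()
    hours = (start_hour + np.arange(n_bins) * BIN_S / 3600.0) % 24.0
    temp = (model.baseline
            + rng.normal(0.0, model.animal_sd)
            + model.amplitude * np.cos(2 * np.pi * (hours - model.peak_hour) / 24.0))
    from scipy.signal import lfilter

    innov = rng.normal(0.0, model.ar_sd, n_bins)
    noise = lfilter([1.0], [1.0, -model.ar_phi], innov)
    temp = temp + noise
    if stress == "stress":
        offset = model.stress_offsets.get(age, 0.0)
        in_window = (lights.is_active(hours) if model.offset_period == "active"
                     else ~lights.is_active(hours))
        temp = temp + offset * in_window
    return temp


# per-stage EEG synthesis parameters: (oscillation amp mean, sd, f range, noise sd)
_EEG_PARAMS = {
    "Deep": (100.0, 10.0, (1.0, 3.0), 9.0),
    "REM": (30.0, 3.0, (5.5, 7.5), 6.0),
    "Light": (0.0, 0.0, None, 11.0),
    "Wake": (0.0, 0.0, None, 18.0),
}
# per-stage EMG noise SD options (choice weights in second tuple)
_EMG_PARAMS = {
    "Wake": ((40.0, 20.0), (0.7, 0.3)),
    "Light": ((20.0,), (1.0,)),
    "REM": ((4.0,), (1.0,)),
    "Deep": ((8.0,), (1.0,)),
}


@dataclass
class TelemetryTruth:
    """Generated recording plus its ground truth."""

    recording: TelemetryRecording
    hypnogram: Hypnogram
    artifact_epochs: np.ndarray   # bool per epoch


def _synth_epoch_eeg(stage: str, bin_len: int, fs: float,
                     rng: np.random.Generator) -> np.ndarray:
    amp_mean, amp_sd, f_range, noise_sd = _EEG_PARAMS[stage]
    out = rng.normal(0.0, noise_sd, 3 * bin_len)
    if f_range is not None:
        t = np.arange(3 * bin_len) / fs
        f = rng.uniform(*f_range)
        amp = max(rng.normal(amp_mean, amp_sd), 0.3 * amp_mean)
        out += amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return out


def gen_telemetry(design: CohortDesign,
                  stage_program: StageProgram | None = None,
                  seed: int = 0, *,
                  duration_h: float = 8.0,
                  fs: float = 100.0,
                  start_hour: float = 4.5,
                  artifact_rate: float = 0.02,
                  temperature: TemperatureModel | None = None
                  ) -> list[TelemetryTruth]:
    """Generate one recording per animal with ground-truth hypnograms.

    ``artifact_rate`` is the per-30-s-epoch probability of an injected
    spike-burst artifact (marked in the ground truth).  Durations that are not
    a multiple of the epoch length are truncated.
    """
    if fs < 64:
        raise ValueError("sampling rate must be >= 64 Hz")
    program = stage_program if stage_program is not None else default_stage_program()
    temp_model = temperature if temperature is not None else TemperatureModel()
    n_epochs = int(duration_h * 3600 // EPOCH_S)
    bin_len = int(round(fs * BIN_S))
    bins_per_epoch = EPOCH_S // BIN_S
    out = []
    root = np.random.SeedSequence([int(seed), 0x7E1E])
    children = root.spawn(len(design.animals))
    for animal, child in zip(design.animals, children):
        rng = np.random.Generator(np.random.PCG64(child))
        hyp = gen_hypnogram(n_epochs, animal.age_group, animal.stress_group,
                            program, rng, start_hour, design.lights)
        artifact = rng.random(n_epochs) < artifact_rate
        eeg = np.empty(n_epochs * bins_per_epoch * bin_len)
        emg = np.empty_like(eeg)
        activity = np.zeros(n_epochs * bins_per_epoch, dtype=int)
        for i, stage in enumerate(hyp.stages):
            sl = slice(i * bins_per_epoch * bin_len, (i + 1) * bins_per_epoch * bin_len)
            seg = _synth_epoch_eeg(stage, bin_len, fs, rng)
            if artifact[i]:
                # spike burst in every bin of the epoch
                for b in range(bins_per_epoch):
                    pos = b * bin_len + rng.integers(0, bin_len, 4)
                    seg[pos] += rng.choice([-1.0, 1.0], 4) * 1500.0
            eeg[sl] = seg
            sds, wts = _EMG_PARAMS[stage]
            for b in range(bins_per_epoch):
                sd = rng.choice(sds, p=wts) * rng.normal(1.0, 0.08)
                emg[sl][b * bin_len:(b + 1) * bin_len] = rng.normal(0, abs(sd), bin_len)
            if stage == "Wake":
                for b in range(bins_per_epoch):
                    if rng.random() < 0.6:
                        activity[i * bins_per_epoch + b] = 1 + rng.poisson(2.5)
        temp = gen_temperature_bins(n_epochs * bins_per_epoch, start_hour,
                                    animal.age_group, animal.stress_group,
                                    temp_model, rng, design.lights)
        rec = TelemetryRecording(animal.animal_id, eeg, emg, fs, activity,
                                 temp, design.lights, start_hour)
        out.append(TelemetryTruth(rec, hyp, artifact))
    return out
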