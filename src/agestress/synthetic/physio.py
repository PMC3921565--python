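"""Synthetic corticosterone values and field-potential sweeps.

CORT values are normal draws per group around configurable means (defaults
produce the expected pattern: a large stress response in young, a blunted one
in aged, both well inside the species' active-period range), censored at the
20 ng/ml quantification limit.

Field sweeps are a stimulus artifact followed by an alpha-function EPSP whose
amplitude follows a sigmoid of stimulus step; the aged-control curve is
scaled down (planted input/output depression).  Paired-pulse sweeps scale the
second response by a delay-dependent facilitation factor, identical across
groups.  Voltage units are arbitrary but consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..design import CohortDesign
from ..physiology import CORT_DETECTION_LIMIT, FieldSweep

__all__ = ["CortModel", "gen_cort", "FieldPotentialModel", "gen_fp_sweeps",
           "AnimalSweeps"]


@dataclass
class CortModel:
    means: dict = field(default_factory=lambda: {
        ("young", "control"): 110.0,
        ("young", "stress"): 320.0,
        ("aged", "control"): 70.0,
        ("aged", "stress"): 190.0,
    })
    sd: float = 70.0
    detection_limit: float = CORT_DETECTION_LIMIT


def gen_cort(design: CohortDesign, seed: int = 0,
             model: CortModel | None = None) -> pd.DataFrame:
    """Per-animal serum CORT (ng/ml) with censoring at the detection limit."""
    model = model if model is not None else CortModel()
    for cell, m in model.means.items():
        if m < 0:
            raise ValueError(f"negative mean for {cell}")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(
        [int(seed), 0xC0]) ))
    rows = []
    for a in design.animals:
        v = float(rng.normal(model.means[(a.age_group, a.stress_group)], model.sd))
        censored = v < model.detection_limit
        rows.append({"animal_id": a.animal_id, "age": a.age_group,
                     "stress": a.stress_group,
                     "cort_ng_ml": model.detection_limit if censored else v,
                     "censored": censored})
    return pd.DataFrame(rows)


@dataclass
class FieldPotentialModel:
    n_steps: int = 10
    delays_ms: tuple = (50, 100, 150, 200)
    fs: float = 10000.0
    sweep_ms: float = 60.0
    stim_ms: float = 5.0
    tau_ms: float = 3.0              # EPSP alpha-function time constant
    amax: float = 1.0                # max EPSP amplitude, young baseline
    aged_control_scale: float = 0.6  # planted I/O depression
    animal_sd: float = 0.12          # per-animal Amax spread (multiplicative)
    sweep_noise: float = 0.005        # additive noise SD relative to amax
    sigmoid_mid: float = 5.5
    sigmoid_width: float = 1.2
    facilitation: dict = field(default_factory=lambda: {
        50: 1.45, 100: 1.30, 150: 1.18, 200: 1.08})
    pp_triplicates: int = 3

    def step_amplitude(self, step: int, amax: float) -> float:
        return amax / (1.0 + np.exp(-(step - self.sigmoid_mid) / self.sigmoid_width))


@dataclass
class AnimalSweeps:
    animal_id: str
    io: dict                 # step -> FieldSweep
    pp: dict                 # delay_ms -> list of (first, second) sweep pairs
    truth: dict              # planted amax, per-step amplitudes, facilitation


def _epsp_sweep(amp: float, model: FieldPotentialModel,
                rng: np.random.Generator, meta: dict) -> FieldSweep:
    n = int(round(model.sweep_ms / 1000.0 * model.fs))
    t = np.arange(n) / model.fs
    v = np.zeros(n)
    stim = model.stim_ms / 1000.0
    # stimulus artifact: 0.5 ms biphasic square
    art = (t >= stim) & (t < stim + 0.5e-3)
    v[art] = 5.0 * model.amax * np.where(t[art] < stim + 0.25e-3, 1.0, -1.0)
    tau = model.tau_ms / 1000.0
    onset = stim + 1.0e-3
    tp = t - onset
    rise = tp > 0
    v[rise] += -amp * (tp[rise] / tau) * np.exp(1.0 - tp[rise] / tau)
    v += rng.normal(0.0, model.sweep_noise * model.amax, n)
    return FieldSweep(t, v, stim, meta)


def gen_fp_sweeps(design: CohortDesign, seed: int = 0,
                  model: FieldPotentialModel | None = None) -> list[AnimalSweeps]:
    """One slice per animal: an I/O series over steps 1..n and triplicate
    paired-pulse sweep pairs at each delay."""
    model = model if model is not None else FieldPotentialModel()
    if model.n_steps < 10:
        raise ValueError("need at least 10 stimulus steps for the I/O curve")
    children = np.random.SeedSequence([int(seed), 0xF9]).spawn(len(design.animals))
    out = []
    for animal, child in zip(design.animals, children):
        rng = np.random.Generator(np.random.PCG64(child))
        scale = (model.aged_control_scale
                 if (animal.age_group, animal.stress_group) == ("aged", "control")
                 else 1.0)
        amax = model.amax * scale * max(rng.normal(1.0, model.animal_sd), 0.4)
        io = {}
        amps = {}
        for step in range(1, model.n_steps + 1):
            amp = model.step_amplitude(step, amax)
            amps[step] = amp
            io[step] = _epsp_sweep(amp, model, rng, {"step": step})
        third = max(amps.values()) / 3.0
        pp_step = min(amps, key=lambda s: abs(amps[s] - third))
        pp = {}
        for delay in model.delays_ms:
            fac = model.facilitation[delay]
            pairs = []
            for _ in range(model.pp_triplicates):
                a1 = amps[pp_step]
                pairs.append((
                    _epsp_sweep(a1, model, rng, {"delay_ms": delay, "pulse": 1}),
                    _epsp_sweep(fac * a1, model, rng,
                                {"delay_ms": delay, "pulse": 2}),
                ))
            pp[delay] = pairs
        out.append(AnimalSweeps(animal.animal_id, io, pp, {
            "amax": amax, "amplitudes": amps, "pp_step": pp_step,
            "facilitation": dict(model.facilitation)}))
    return out
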