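"""Cohort roster and lights schedule.

The study design is a 2 x 2 factorial: age (young ~3 mo vs aged ~21 mo F344
rats) crossed with acute restraint (control vs 3-h restraint).  Group sizes
default to the study's: 9-12 animals per group for telemetry/maze assays, and
a 37-animal subset (10/8/10/9) for the gene panel.  Animals live on a reverse
12:12 light cycle (lights off 04:30, lights on 16:30), so the active period is
the dark phase starting at 04:30.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LightsSchedule", "Animal", "CohortDesign", "gen_design",
           "DEFAULT_GROUP_SIZES", "DEFAULT_PANEL_SIZES"]

AGE_GROUPS = ("young", "aged")
STRESS_GROUPS = ("control", "stress")

#: animals per (age, stress) cell for telemetry / maze assays
DEFAULT_GROUP_SIZES = {
    ("young", "control"): 11,
    ("young", "stress"): 10,
    ("aged", "control"): 10,
    ("aged", "stress"): 9,
}

#: animals per cell entering the gene-panel assay (37 total)
DEFAULT_PANEL_SIZES = {
    ("young", "control"): 10,
    ("young", "stress"): 8,
    ("aged", "control"): 10,
    ("aged", "stress"): 9,
}


@dataclass(frozen=True)
class LightsSchedule:
    """Reverse 12:12 light/dark cycle; clock times are fractional hours."""

    lights_off: float = 4.5   # 04:30, active (dark) period begins
    lights_on: float = 16.5   # 16:30, resting (light) period begins

    def is_active(self, clock_hour) -> np.ndarray:
        """True where the clock hour (mod 24) falls in the dark/active phase."""
        h = np.asarray(clock_hour, dtype=float) % 24.0
        off, on = self.lights_off, self.lights_on
        if off < on:
            return (h >= off) & (h < on)
        return (h >= off) | (h < on)


@dataclass(frozen=True)
class Animal:
    animal_id: str
    age_group: str
    stress_group: str


@dataclass(frozen=True)
class CohortDesign:
    """Roster of animals with per-assay group sizes."""

    animals: tuple[Animal, ...]
    panel_sizes: dict = field(default_factory=lambda: dict(DEFAULT_PANEL_SIZES))
    seed: int = 0
    lights: LightsSchedule = field(default_factory=LightsSchedule)

    def group(self, age: str, stress: str) -> list[Animal]:
        return [a for a in self.animals
                if a.age_group == age and a.stress_group == stress]

    def group_sizes(self) -> dict:
        return {(ag, st): len(self.group(ag, st))
                for ag in AGE_GROUPS for st in STRESS_GROUPS}

    def panel_animals(self) -> list[Animal]:
        """The subset of animals entering the gene-panel assay (first n of
        each cell in roster order, emulating the post-QC subset)."""
        out = []
        for (ag, st), n in self.panel_sizes.items():
            cell = self.group(ag, st)
            if n > len(cell):
                raise ValueError(f"panel size {n} exceeds cell size for ({ag}, {st})")
            out.extend(cell[:n])
        return out

    @property
    def age_labels(self) -> np.ndarray:
        return np.array([a.age_group for a in self.animals], dtype=object)

    @property
    def stress_labels(self) -> np.ndarray:
        return np.array([a.stress_group for a in self.animals], dtype=object)


def gen_design(seed: int = 0, group_sizes: dict | None = None,
               panel_sizes: dict | None = None,
               lights: LightsSchedule | None = None) -> CohortDesign:
    """Deterministic roster for a seed, with optional size overrides."""
    sizes = dict(DEFAULT_GROUP_SIZES if group_sizes is None else group_sizes)
    panel = dict(DEFAULT_PANEL_SIZES if panel_sizes is None else panel_sizes)
    for cell, n in sizes.items():
        if n < 1:
            raise ValueError(f"zero-size group {cell}")
    for cell, n in panel.items():
        if n < 1:
            raise ValueError(f"zero-size panel group {cell}")
        if n > sizes.get(cell, 0):
            raise ValueError(f"panel size exceeds group size for {cell}")
    animals = []
    for ag in AGE_GROUPS:
        for st in STRESS_GROUPS:
            for i in range(sizes[(ag, st)]):
                animals.append(Animal(f"{ag[0].upper()}{st[0].upper()}{i + 1:02d}",
                                      ag, st))
    return CohortDesign(tuple(animals), panel, int(seed),
                        lights if lights is not None else LightsSchedule())
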