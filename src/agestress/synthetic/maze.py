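"""Biased-correlated-random-walk swim-trial generator.

Trajectories are discrete-time correlated random walks at the tracking rate
(10 Hz) with a reflective pool boundary and a tunable drift ("goal bias")
toward the platform -- the simplest model spanning chance-to-perfect
performance.  Per-animal swim speeds are drawn around the observed group
means (young 33.7, aged 28.5 cm/s).  Training trials end at platform contact
or the 60-s limit; probe trials last exactly 60 s with the platform removed
and always start in the quadrant opposite the goal quadrant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..design import CohortDesign
from ..watermaze import MazeConfig, SwimTrial, TRIAL_LIMIT_S

__all__ = ["SwimPerformance", "gen_swim_trials", "simulate_swim"]


@dataclass
class SwimPerformance:
    """Group-level swim parameters.

    ``training_bias`` maps age group to per-day goal-bias values (improving
    across days); ``probe_bias`` maps (age, stress) to the probe-trial bias
    toward the former platform location.  The young-stress probe bias is
    depressed (planted stress deficit); aged probe biases are stress-
    insensitive, emulating the hypo-responsive aged phenotype.
    """

    speed_mean: dict = field(default_factory=lambda: {"young": 33.7, "aged": 28.5})
    # per-animal SD implied by the reported group standard errors
    # (SE ~1 cm/s at n ~20 per age group)
    speed_sd: float = 5.0
    heading_noise: float = 0.55     # rad, per-step wrapped-normal SD
    dt: float = 0.1                 # 10 Hz tracking
    training_bias: dict = field(default_factory=lambda: {
        "young": (0.18, 0.20, 0.22),
        "aged": (0.08, 0.12, 0.17),
    })
    probe_bias: dict = field(default_factory=lambda: {
        ("young", "control"): 0.14,
        ("young", "stress"): 0.035,
        ("aged", "control"): 0.075,
        ("aged", "stress"): 0.075,
    })


def simulate_swim(start: tuple[float, float], speed: float, goal_bias: float,
                  config: MazeConfig, rng: np.random.Generator, *,
                  with_platform: bool, duration_s: float = TRIAL_LIMIT_S,
                  heading_noise: float = 0.55, dt: float = 0.1):
    """One correlated random walk; returns (t, x, y, found_platform)."""
    px, py = config.platform_center
    cx, cy = config.pool_center
    r_max = config.pool_radius - 2.0
    n_max = int(round(duration_s / dt))
    xs = np.empty(n_max + 1)
    ys = np.empty(n_max + 1)
    xs[0], ys[0] = start
    # initial heading toward the pool center
    heading = math.atan2(cy - start[1], cx - start[0])
    found = False
    n = n_max
    for i in range(n_max):
        gx, gy = px - xs[i], py - ys[i]
        gnorm = math.hypot(gx, gy)
        hx, hy = math.cos(heading), math.sin(heading)
        if gnorm > 1e-9 and goal_bias > 0:
            dx = (1.0 - goal_bias) * hx + goal_bias * gx / gnorm
            dy = (1.0 - goal_bias) * hy + goal_bias * gy / gnorm
        else:
            dx, dy = hx, hy
        heading = math.atan2(dy, dx) + rng.normal(0.0, heading_noise)
        step = speed * dt
        nx = xs[i] + step * math.cos(heading)
        ny = ys[i] + step * math.sin(heading)
        if math.hypot(nx - cx, ny - cy) > r_max:
            # turn toward the pool center instead of hitting the wall,
            # keeping the full step length (speed is preserved)
            heading = (math.atan2(cy - ys[i], cx - xs[i])
                       + rng.normal(0.0, 0.5))
            nx = xs[i] + step * math.cos(heading)
            ny = ys[i] + step * math.sin(heading)
            rad = math.hypot(nx - cx, ny - cy)
            if rad > r_max:   # started outside the margin: clamp inward
                nx = cx + (nx - cx) * (r_max / rad)
                ny = cy + (ny - cy) * (r_max / rad)
        xs[i + 1], ys[i + 1] = nx, ny
        if with_platform and math.hypot(nx - px, ny - py) <= config.platform_radius:
            found = True
            n = i + 1
            break
    t = np.arange(n + 1) * dt
    return t, xs[:n + 1], ys[:n + 1], found


def gen_swim_trials(design: CohortDesign, config: MazeConfig | None = None,
                    performance: SwimPerformance | None = None,
                    seed: int = 0, *, n_days: int = 3,
                    trials_per_day: int = 3) -> list[SwimTrial]:
    """Spatial training (3 days x 3 trials) plus one probe trial per animal."""
    config = config if config is not None else MazeConfig()
    perf = performance if performance is not None else SwimPerformance()
    drops = config.drop_points()
    non_goal = [q for q in drops if q != config.goal_quadrant]
    root = np.random.SeedSequence([int(seed), 0x5A1]).spawn(len(design.animals))
    trials = []
    for animal, child in zip(design.animals, root):
        rng = np.random.Generator(np.random.PCG64(child))
        speed = max(float(rng.normal(perf.speed_mean[animal.age_group],
                                     perf.speed_sd)), 15.0)
        day_bias = perf.training_bias[animal.age_group]
        for day in range(1, n_days + 1):
            for k in range(trials_per_day):
                start_q = non_goal[(day + k) % len(non_goal)]
                t, x, y, found = simulate_swim(
                    drops[start_q], speed, day_bias[min(day - 1, len(day_bias) - 1)],
                    config, rng, with_platform=True,
                    heading_noise=perf.heading_noise, dt=perf.dt)
                trials.append(SwimTrial(animal.animal_id, "spatial", day, k,
                                        t, x, y, found))
        bias = perf.probe_bias[(animal.age_group, animal.stress_group)]
        t, x, y, _ = simulate_swim(
            drops[config.opposite_quadrant()], speed, bias, config, rng,
            with_platform=False, heading_noise=perf.heading_noise, dt=perf.dt)
        trials.append(SwimTrial(animal.animal_id, "probe", n_days + 1, 0,
                                t, x, y, False))
    return trials
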