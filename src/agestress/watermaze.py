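"""Morris water-maze trajectory metrics and group statistics.

The pool is a 190-cm-diameter circle with a 15-cm-diameter escape platform in
one quadrant; tracked positions are (t, x, y) polylines.  Metrics are defined
directly on the polyline with no smoothing: latency to first platform entry,
path length (whole pool or goal quadrant), swim speed, probe-trial platform
crossings (with a re-entry debounce) and goal-quadrant path length.  The
printed kinematic check -- mean drop-to-platform distance over swim speed --
is :func:`straight_line_latency`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats_core

__all__ = ["MazeConfig", "SwimTrial", "TrialMetrics", "latency", "path_length",
           "swim_speed", "straight_line_latency", "platform_crossings",
           "trial_metrics", "maze_stats", "TRIAL_LIMIT_S"]

TRIAL_LIMIT_S = 60.0

QUADRANT_CENTER_ANGLES = {"NE": 45.0, "NW": 135.0, "SW": 225.0, "SE": 315.0}


@dataclass(frozen=True)
class MazeConfig:
    """Pool and platform geometry (cm).  The four quadrants are the sectors
    about the pool center, with the goal quadrant centered on the platform;
    drop points sit near the wall at each quadrant's mid-angle."""

    pool_center: tuple[float, float] = (0.0, 0.0)
    pool_radius: float = 95.0
    platform_radius: float = 7.5
    goal_quadrant: str = "NE"
    platform_offset: float = 47.5    # radial distance of platform center
    # chosen so the mean drop-to-platform distance is 91.44 cm
    drop_radius: float = 85.2714

    def __post_init__(self):
        if self.platform_offset + self.platform_radius > self.pool_radius:
            raise ValueError("platform disc extends outside the pool")
        if self.goal_quadrant not in QUADRANT_CENTER_ANGLES:
            raise ValueError(f"unknown quadrant {self.goal_quadrant}")

    @property
    def platform_center(self) -> tuple[float, float]:
        a = math.radians(QUADRANT_CENTER_ANGLES[self.goal_quadrant])
        return (self.pool_center[0] + self.platform_offset * math.cos(a),
                self.pool_center[1] + self.platform_offset * math.sin(a))

    def drop_points(self) -> dict[str, tuple[float, float]]:
        out = {}
        for q, deg in QUADRANT_CENTER_ANGLES.items():
            a = math.radians(deg)
            out[q] = (self.pool_center[0] + self.drop_radius * math.cos(a),
                      self.pool_center[1] + self.drop_radius * math.sin(a))
        return out

    def opposite_quadrant(self) -> str:
        opp = {"NE": "SW", "SW": "NE", "NW": "SE", "SE": "NW"}
        return opp[self.goal_quadrant]

    def mean_drop_to_platform_distance(self) -> float:
        px, py = self.platform_center
        d = [math.hypot(x - px, y - py) for x, y in self.drop_points().values()]
        return float(np.mean(d))

    def quadrant_of(self, x, y) -> np.ndarray:
        ang = np.degrees(np.arctan2(np.asarray(y) - self.pool_center[1],
                                    np.asarray(x) - self.pool_center[0])) % 360.0
        # sector boundaries at 0/90/180/270 with NE = [0, 90)
        labels = np.array(["NE", "NW", "SW", "SE"], dtype=object)
        return labels[(ang // 90).astype(int)]


@dataclass
class SwimTrial:
    """One tracked swim: (t, x, y) samples plus trial identity."""

    animal_id: str
    trial_type: str            # "local" | "spatial" | "probe"
    day: int
    trial_index: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    found_platform: bool = False

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) >= 2 and not (np.diff(self.t) > 0).all():
            raise ValueError("timestamps must be strictly increasing")


def _platform_distances(trial: SwimTrial, config: MazeConfig) -> np.ndarray:
    px, py = config.platform_center
    return np.hypot(trial.x - px, trial.y - py)


def latency(trial: SwimTrial, config: MazeConfig) -> float:
    """Seconds from start to the first sample inside the platform disc
    (training trials only); the 60-s trial limit if never reached."""
    if trial.trial_type == "probe":
        raise ValueError("latency is undefined on probe trials (no platform)")
    inside = _platform_distances(trial, config) <= config.platform_radius
    idx = np.flatnonzero(inside)
    if idx.size == 0:
        return TRIAL_LIMIT_S
    return float(min(trial.t[idx[0]] - trial.t[0], TRIAL_LIMIT_S))


def path_length(trial: SwimTrial, region: str = "pool",
                config: MazeConfig | None = None) -> float:
    """Polyline length in cm; ``region="quadrant"`` keeps only segments whose
    midpoint lies in the goal quadrant."""
    if len(trial.t) < 2:
        raise ValueError("need at least 2 samples")
    dx = np.diff(trial.x)
    dy = np.diff(trial.y)
    seg = np.hypot(dx, dy)
    if region == "pool":
        return float(seg.sum())
    if region == "quadrant":
        if config is None:
            raise ValueError("quadrant mode needs a MazeConfig")
        mx = (trial.x[:-1] + trial.x[1:]) / 2.0
        my = (trial.y[:-1] + trial.y[1:]) / 2.0
        in_goal = config.quadrant_of(mx, my) == config.goal_quadrant
        return float(seg[in_goal].sum())
    raise ValueError(f"unknown region {region!r}")


def swim_speed(trial: SwimTrial) -> float:
    """Mean swim speed = path length / elapsed swim time (cm/s)."""
    elapsed = float(trial.t[-1] - trial.t[0])
    if elapsed <= 0:
        raise ValueError("zero elapsed swim time")
    return path_length(trial) / elapsed


def straight_line_latency(distance_cm: float, speed_cm_s: float) -> float:
    """Minimum straight-line latency (s, reported to 0.1 s) for a given
    drop-to-platform distance and swim speed."""
    if speed_cm_s <= 0:
        raise ValueError("speed must be positive")
    if distance_cm < 0:
        raise ValueError("distance must be nonnegative")
    return round(distance_cm / speed_cm_s, 1)


def platform_crossings(trial: SwimTrial, config: MazeConfig) -> int:
    """Entries into the former platform disc on a probe trial.

    After an entry, the animal must move more than one platform diameter from
    the platform center before a new entry counts (re-entry debounce against
    boundary jitter).
    """
    if trial.trial_type != "probe":
        raise ValueError("platform crossings are a probe-trial metric")
    d = _platform_distances(trial, config)
    r_in = config.platform_radius
    r_out = 2.0 * config.platform_radius   # one platform diameter from center
    count = 0
    armed = True
    for di in d:
        if armed and di <= r_in:
            count += 1
            armed = False
        elif not armed and di > r_out:
            armed = True
    return count


@dataclass(frozen=True)
class TrialMetrics:
    animal_id: str
    trial_type: str
    day: int
    trial_index: int
    latency_s: float | None
    path_length_cm: float
    mean_speed_cm_s: float
    platform_crossings: int | None
    goal_quadrant_path_cm: float | None


def trial_metrics(trial: SwimTrial, config: MazeConfig) -> TrialMetrics:
    is_probe = trial.trial_type == "probe"
    return TrialMetrics(
        animal_id=trial.animal_id,
        trial_type=trial.trial_type,
        day=trial.day,
        trial_index=trial.trial_index,
        latency_s=None if is_probe else latency(trial, config),
        path_length_cm=path_length(trial),
        mean_speed_cm_s=swim_speed(trial),
        platform_crossings=platform_crossings(trial, config) if is_probe else None,
        goal_quadrant_path_cm=(path_length(trial, "quadrant", config)
                               if is_probe else None),
    )


def metrics_frame(trials, config: MazeConfig) -> pd.DataFrame:
    return pd.DataFrame([trial_metrics(tr, config).__dict__ for tr in trials])


def maze_stats(metrics: pd.DataFrame, design, alpha: float = 0.05) -> dict:
    """Group statistics over per-trial metrics.

    Training metrics (per-animal day means of latency and path length) go to
    the mixed age x day repeated-measures ANOVA; probe metrics (platform
    crossings and goal-quadrant path) to the between-subjects age x stress
    ANOVA with the young control-vs-stress LSD pair when gated.
    """
    age_of = {a.animal_id: a.age_group for a in design.animals}
    stress_of = {a.animal_id: a.stress_group for a in design.animals}
    out = {}

    training = metrics[metrics.trial_type == "spatial"]
    rm_rows = []
    if len(training):
        for metric in ("latency_s", "path_length_cm"):
            day_means = (training.pivot_table(index="animal_id", columns="day",
                                              values=metric, aggfunc="mean")
                         .dropna())
            groups = np.array([age_of[a] for a in day_means.index], dtype=object)
            res = stats_core.two_way_rm_anova(day_means.to_numpy(), groups,
                                              names=("age", "day"))
            for fac in res.factors:
                rm_rows.append({"metric": metric, "factor": fac.name,
                                "F": fac.f, "df1": fac.df_num, "df2": fac.df_den,
                                "p": fac.p, "significant": fac.p <= alpha})
    out["training_anova"] = pd.DataFrame(rm_rows)

    probe = metrics[metrics.trial_type == "probe"]
    pr_rows, lsd_rows = [], []
    for metric in ("platform_crossings", "goal_quadrant_path_cm"):
        if not len(probe):
            break
        vals = probe[metric].astype(float).to_numpy()
        ages = np.array([age_of[a] for a in probe.animal_id], dtype=object)
        stresses = np.array([stress_of[a] for a in probe.animal_id], dtype=object)
        res = stats_core.two_way_anova(vals, ages, stresses,
                                       names=("age", "stress"))
        for fac in res.factors:
            pr_rows.append({"metric": metric, "factor": fac.name, "F": fac.f,
                            "df1": fac.df_num, "df2": fac.df_den, "p": fac.p,
                            "significant": fac.p <= alpha})
        if any(f.p <= alpha for f in res.factors) and not res.degenerate:
            cells = {f"{a}-{s}": vals[(ages == a) & (stresses == s)]
                     for a in ("young", "aged") for s in ("control", "stress")}
            for pair in (("young-control", "young-stress"),
                         ("aged-control", "aged-stress")):
                pw = stats_core.fishers_lsd(cells, res.mse_within,
                                            res.df_error, pair)
                lsd_rows.append({"metric": metric, "pair": " vs ".join(pair),
                                 "mean_diff": pw.mean_diff, "t": pw.t,
                                 "p": pw.p, "significant": pw.p <= alpha})
    out["probe_anova"] = pd.DataFrame(pr_rows)
    out["probe_lsd"] = pd.DataFrame(lsd_rows)
    return out


def trials_to_frame(trials) -> pd.DataFrame:
    """Tidy (trial identity, t, x, y) table for CSV export."""
    frames = []
    for tr in trials:
        frames.append(pd.DataFrame({
            "animal_id": tr.animal_id, "trial_type": tr.trial_type,
            "day": tr.day, "trial_index": tr.trial_index,
            "t": tr.t, "x": tr.x, "y": tr.y,
            "found_platform": tr.found_platform,
        }))
    return pd.concat(frames, ignore_index=True)


def trials_from_frame(df: pd.DataFrame) -> list[SwimTrial]:
    out = []
    for (aid, ttype, day, idx), grp in df.groupby(
            ["animal_id", "trial_type", "day", "trial_index"], sort=False):
        out.append(SwimTrial(aid, ttype, int(day), int(idx),
                             grp.t.to_numpy(), grp.x.to_numpy(), grp.y.to_numpy(),
                             bool(grp.found_platform.iloc[0])))
    return out
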