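"""Temperature rhythms, hippocampal field-potential metrics and CORT stats.

Covers three assays:

* body temperature -- hourly binning of telemetry temperature aligned to the
  lights schedule, repeated-measures group x time ANOVA, and recovery of
  stress-induced hyperthermia offsets;
* extracellular field potentials -- EPSP slope extraction (maximum-magnitude
  fixed-width linear fit on the rising phase), input/output curves over
  stimulus steps 1-10 with group x step statistics, the 1/3-of-maximum
  stimulus selection, and paired-pulse facilitation ratios at 50-200 ms
  delays;
* corticosterone -- 2 x 2 age x stress contrasts on per-animal serum values,
  with values below the 20 ng/ml quantification limit included at the limit
  and flagged rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats_core
from .design import LightsSchedule

__all__ = ["hourly_bin", "temperature_stats", "estimate_stress_offset",
           "FieldSweep", "epsp_slope", "io_curve", "io_stats",
           "select_third_max_step", "pp_ratio", "cort_stats",
           "CORT_DETECTION_LIMIT"]

CORT_DETECTION_LIMIT = 20.0
TEMP_PLAUSIBLE = (34.0, 41.0)


def hourly_bin(temperature: np.ndarray, start_hour: float,
               bin_s: float = 10.0) -> pd.DataFrame:
    """Mean temperature per clock hour; implausible samples are flagged out.

    Returns a frame with clock_hour, mean_temp, n_samples, n_outliers; hours
    with no usable samples get NaN means (reported, not imputed).
    """
    temp = np.asarray(temperature, dtype=float)
    hours = np.floor((start_hour + np.arange(len(temp)) * bin_s / 3600.0) % 24.0)
    ok = (temp >= TEMP_PLAUSIBLE[0]) & (temp <= TEMP_PLAUSIBLE[1])
    rows = []
    for h in np.unique(hours):
        m = hours == h
        use = m & ok
        rows.append({
            "clock_hour": float(h),
            "mean_temp": float(temp[use].mean()) if use.any() else float("nan"),
            "n_samples": int(m.sum()),
            "n_outliers": int((m & ~ok).sum()),
        })
    return pd.DataFrame(rows)


def temperature_stats(hourly: pd.DataFrame, group_of: dict,
                      alpha: float = 0.05,
                      lsd_pair: tuple[str, str] | None = None) -> dict:
    """Group x time repeated-measures ANOVA on an animal x hour panel.

    ``hourly`` is tidy with columns animal_id, clock_hour, mean_temp;
    ``group_of`` maps animal to its group label.  Per-timepoint LSD contrasts
    for ``lsd_pair`` are computed when the omnibus group effect or
    interaction is significant, using the between-animal MSE at that hour.
    """
    panel = hourly.pivot_table(index="animal_id", columns="clock_hour",
                               values="mean_temp").dropna()
    groups = np.array([group_of[a] for a in panel.index], dtype=object)
    res = stats_core.two_way_rm_anova(panel.to_numpy(), groups,
                                      names=("group", "time"))
    table = stats_core.anova_table({"temperature": res}, alpha)
    out = {"anova": table, "result": res}
    gated = (res["group"].p <= alpha) or (res["group:time"].p <= alpha)
    lsd_rows = []
    if lsd_pair is not None and gated and not res.degenerate:
        for hour in panel.columns:
            vals = panel[hour].to_numpy()
            cells = {g: vals[groups == g] for g in np.unique(groups)}
            k = len(cells)
            dfe = len(vals) - k
            mse = sum(((v - v.mean()) ** 2).sum() for v in cells.values()) / dfe
            pw = stats_core.fishers_lsd(cells, mse, dfe, lsd_pair)
            lsd_rows.append({"clock_hour": hour, "mean_diff": pw.mean_diff,
                             "t": pw.t, "p": pw.p, "significant": pw.p <= alpha})
    out["lsd"] = pd.DataFrame(lsd_rows)
    return out


def estimate_stress_offset(hourly: pd.DataFrame, group_of: dict,
                           lights: LightsSchedule | None = None,
                           period: str = "resting") -> float:
    """Stress-hyperthermia offset (deg C) within a period's clock hours.

    Estimated as a difference-in-differences: each animal's mean temperature
    in the offset period minus its mean in the other period (cancelling
    per-animal baselines), contrasted stress minus control (cancelling the
    shared circadian profile).
    """
    lights = lights if lights is not None else LightsSchedule()
    h = hourly.clock_hour.to_numpy()
    # classify hour bins by their midpoint and drop bins straddling a lights
    # transition (they mix offset and non-offset samples)
    active = lights.is_active(h + 0.5)
    pure = lights.is_active(h + 0.01) == lights.is_active(h + 0.99)
    in_period = (active if period == "active" else ~active) & pure
    out_period = (~active if period == "active" else active) & pure
    inside = hourly[in_period].groupby("animal_id").mean_temp.mean()
    outside = hourly[out_period].groupby("animal_id").mean_temp.mean()
    contrast = (inside - outside).dropna()
    labels = np.array([group_of[a] for a in contrast.index], dtype=object)
    return float(contrast[labels == "stress"].mean()
                 - contrast[labels == "control"].mean())


@dataclass
class FieldSweep:
    """One voltage sweep with its stimulus onset marked (uniform sampling)."""

    t: np.ndarray            # seconds
    v: np.ndarray
    stim_time: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if len(self.t) != len(self.v):
            raise ValueError("t and v must have equal length")


def epsp_slope(sweep: FieldSweep, window_ms: tuple[float, float] = (1.0, 8.0),
               fit_width_ms: float = 1.0) -> tuple[float, bool]:
    """Maximum-magnitude EPSP slope (V/s) on the rising phase.

    A fixed-width linear fit slides over ``window_ms`` (relative to the
    stimulus, past the stimulus artifact); the signed slope of largest
    magnitude is returned.  Flat sweeps return (0.0, flagged=True).  The
    measure is invariant to a baseline voltage offset.
    """
    dt = sweep.t[1] - sweep.t[0]
    i0 = int(round((sweep.stim_time + window_ms[0] / 1000.0 - sweep.t[0]) / dt))
    i1 = int(round((sweep.stim_time + window_ms[1] / 1000.0 - sweep.t[0]) / dt))
    w = max(int(round(fit_width_ms / 1000.0 / dt)), 2)
    if i0 < 0 or i1 + w > len(sweep.v):
        raise ValueError("slope window extends outside the sweep")
    seg = sweep.v[i0:i1 + w]
    if np.ptp(seg) < 1e-12:
        return 0.0, True
    # least-squares slope of each length-w window, vectorized
    x = (np.arange(w) - (w - 1) / 2.0) * dt
    denom = (x ** 2).sum()
    kernel = x[::-1] / denom
    slopes = np.convolve(seg, kernel, mode="valid")
    best = slopes[np.argmax(np.abs(slopes))]
    return float(best), False


def io_curve(sweeps: dict[int, FieldSweep], n_steps: int = 10,
             **slope_kw) -> pd.DataFrame:
    """EPSP slope per stimulus step (steps 1..n_steps, all required)."""
    missing = [s for s in range(1, n_steps + 1) if s not in sweeps]
    if missing:
        raise ValueError(f"missing stimulus steps: {missing}")
    rows = []
    for step in range(1, n_steps + 1):
        slope, flat = epsp_slope(sweeps[step], **slope_kw)
        rows.append({"step": step, "slope": slope, "flat": flat})
    return pd.DataFrame(rows)


def select_third_max_step(curve: pd.DataFrame) -> int:
    """Stimulus step whose slope magnitude is nearest 1/3 of the maximum."""
    mags = curve.slope.abs().to_numpy()
    target = mags.max() / 3.0
    return int(curve.step.iloc[int(np.argmin(np.abs(mags - target)))])


def io_stats(curves: pd.DataFrame, group_of: dict, alpha: float = 0.05,
             lsd_pair: tuple[str, str] = ("young-control", "aged-control")) -> dict:
    """Group x stimulus-step repeated-measures ANOVA on I/O slopes.

    ``curves`` is tidy with columns animal_id, step, slope.  Per-step LSD
    contrasts for ``lsd_pair`` are run when the interaction or group effect
    is significant.
    """
    panel = curves.pivot_table(index="animal_id", columns="step",
                               values="slope").dropna()
    groups = np.array([group_of[a] for a in panel.index], dtype=object)
    res = stats_core.two_way_rm_anova(np.abs(panel.to_numpy()), groups,
                                      names=("group", "step"))
    out = {"anova": stats_core.anova_table({"io": res}, alpha), "result": res}
    lsd_rows = []
    gated = (res["group"].p <= alpha) or (res["group:step"].p <= alpha)
    if gated and not res.degenerate:
        mat = np.abs(panel.to_numpy())
        for j, step in enumerate(panel.columns):
            vals = mat[:, j]
            cells = {g: vals[groups == g] for g in np.unique(groups)}
            dfe = len(vals) - len(cells)
            mse = sum(((v - v.mean()) ** 2).sum() for v in cells.values()) / dfe
            pw = stats_core.fishers_lsd(cells, mse, dfe, lsd_pair)
            lsd_rows.append({"step": int(step), "mean_diff": pw.mean_diff,
                             "t": pw.t, "p": pw.p, "significant": pw.p <= alpha})
    out["lsd"] = pd.DataFrame(lsd_rows)
    return out


def pp_ratio(first: FieldSweep, second: FieldSweep, **slope_kw) -> tuple[float, bool]:
    """Paired-pulse facilitation: slope(second) / slope(first).

    Returns (ratio, flagged); a near-zero first slope yields (nan, True).
    The ratio is invariant to uniform gain applied to both sweeps.
    """
    s1, flat1 = epsp_slope(first, **slope_kw)
    s2, flat2 = epsp_slope(second, **slope_kw)
    if flat1 or abs(s1) < 1e-12:
        return float("nan"), True
    return float(s2 / s1), flat2


def cort_stats(cort: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Age x stress ANOVA + LSD pairs on serum corticosterone (ng/ml).

    ``cort`` is tidy with columns animal_id, age, stress, cort_ng_ml and an
    optional ``censored`` flag for values at the 20 ng/ml quantification
    limit (included at the limit, not dropped).  If every value is censored
    the design is degenerate and no test is run.
    """
    vals = cort.cort_ng_ml.to_numpy(dtype=float)
    if "censored" in cort.columns and bool(cort.censored.all()):
        return {"anova": pd.DataFrame(), "lsd": pd.DataFrame(),
                "degenerate": True,
                "note": "all values at the quantification limit"}
    ages = cort.age.to_numpy(dtype=object)
    stresses = cort.stress.to_numpy(dtype=object)
    res = stats_core.two_way_anova(vals, ages, stresses, names=("age", "stress"))
    out = {"anova": stats_core.anova_table({"cort": res}, alpha), "result": res,
           "degenerate": res.degenerate}
    lsd_rows = []
    if any(f.p <= alpha for f in res.factors) and not res.degenerate:
        cells = {f"{a}-{s}": vals[(ages == a) & (stresses == s)]
                 for a in ("young", "aged") for s in ("control", "stress")}
        for pair in (("young-control", "young-stress"),
                     ("aged-control", "aged-stress"),
                     ("young-stress", "aged-stress")):
            pw = stats_core.fishers_lsd(cells, res.mse_within, res.df_error, pair)
            lsd_rows.append({"pair": " vs ".join(pair), "mean_diff": pw.mean_diff,
                             "t": pw.t, "p": pw.p, "significant": pw.p <= alpha})
    out["lsd"] = pd.DataFrame(lsd_rows)
    return out
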