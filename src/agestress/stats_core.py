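"""Shared statistical engine for the aging x stress pipeline.

Every omnibus and post-hoc test used by the downstream analysis modules lives
here, so the whole pipeline runs through one audited set of implementations:

* :func:`two_way_anova` -- between-subjects age x stress ANOVA (Type III sums
  of squares, so unbalanced cells of 8-10 animals are handled the way the
  commercial packages the field uses handle them).
* :func:`two_way_rm_anova` -- mixed-design ANOVA with one between-subjects
  factor (group) and one repeated factor (training day, hour, stimulus step),
  partitioning subject variance from residual; uncorrected degrees of freedom
  (no sphericity correction).
* :func:`fishers_lsd` -- protected pairwise t contrasts on the omnibus MSE.
* :func:`students_t` -- pooled-variance two-sample t-test.
* :func:`fdr_correct` -- Benjamini-Hochberg step-up procedure.
* :func:`binomial_agreement_test` -- exact upper-tail binomial probability.
* :func:`effect_size` -- standardized (stress mean - control mean)/pooled SD.

Degenerate inputs (zero within-cell variance) never produce silent NaNs: the
result carries a ``degenerate`` flag and p is reported at its exact limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FactorEffect",
    "AnovaResult",
    "PairwiseResult",
    "EffectSize",
    "two_way_anova",
    "two_way_anova_matrix",
    "two_way_rm_anova",
    "fishers_lsd",
    "students_t",
    "fdr_correct",
    "FdrResult",
    "binomial_agreement_test",
    "effect_size",
    "expected_null_count",
    "anova_table",
]


@dataclass(frozen=True)
class FactorEffect:
    """One row of an ANOVA: a main effect or interaction."""

    name: str
    f: float
    df_num: int
    df_den: int
    p: float


@dataclass(frozen=True)
class AnovaResult:
    """Omnibus ANOVA result.

    ``factors`` holds main effects and the interaction in source order.
    ``mse_within`` and ``df_error`` refer to the error stratum appropriate for
    between-group pairwise contrasts (cell-level residual for the
    between-subjects design; subject-within-group error for the mixed design).
    """

    factors: tuple[FactorEffect, ...]
    mse_within: float
    df_error: int
    degenerate: bool = False

    def __getitem__(self, name: str) -> FactorEffect:
        for fac in self.factors:
            if fac.name == name:
                return fac
        raise KeyError(name)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    mean_diff: float
    t: float
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class EffectSize:
    """Standardized difference (stress mean - control mean) / pooled SD."""

    value: float
    numerator: float
    pooled_sd: float


def _as_labels(x) -> np.ndarray:
    return np.asarray(x, dtype=object)


def _check_p(p: float) -> float:
    return float(min(1.0, max(0.0, p)))


def two_way_anova(values, factor_a, factor_b,
                  names: tuple[str, str] = ("A", "B")) -> AnovaResult:
    """Two-way between-subjects ANOVA with Type III sums of squares.

    Parameters
    ----------
    values : array-like of float, one measurement per subject.
    factor_a, factor_b : array-like of labels, one per subject.
    names : display names for the two factors.

    Raises
    ------
    ValueError
        if a factor has fewer than two levels, or any design cell is empty or
        has fewer than two subjects.
    """
    y = np.asarray(values, dtype=float)
    a = _as_labels(factor_a)
    b = _as_labels(factor_b)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("values and factor labels must have equal length")
    lev_a, lev_b = np.unique(a), np.unique(b)
    if len(lev_a) < 2 or len(lev_b) < 2:
        raise ValueError("each factor needs at least 2 levels")
    cell_vals = {}
    for la in lev_a:
        for lb in lev_b:
            v = y[(a == la) & (b == lb)]
            if v.size == 0:
                raise ValueError(f"empty design cell ({la}, {lb})")
            if v.size < 2:
                raise ValueError(f"design cell ({la}, {lb}) has n < 2")
            cell_vals[(la, lb)] = v

    ss_within = sum(float(((v - v.mean()) ** 2).sum()) for v in cell_vals.values())
    n_total = len(y)
    n_cells = len(cell_vals)
    df_error = n_total - n_cells

    if ss_within <= 1e-12 * max(1.0, float(np.var(y)) * n_total):
        # all cells internally constant: report exact-limit p per effect
        return _degenerate_two_way(cell_vals, lev_a, lev_b, names, df_error)

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": y, "fa": a.astype(str), "fb": b.astype(str)})
    model = smf.ols("y ~ C(fa, Sum) * C(fb, Sum)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=3)
    rows = {
        names[0]: "C(fa, Sum)",
        names[1]: "C(fb, Sum)",
        f"{names[0]}:{names[1]}": "C(fa, Sum):C(fb, Sum)",
    }
    mse = float(tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"])
    factors = []
    for disp, key in rows.items():
        f_val = float(tab.loc[key, "F"])
        df_num = int(tab.loc[key, "df"])
        p = _check_p(float(tab.loc[key, "PR(>F)"]))
        factors.append(FactorEffect(disp, max(f_val, 0.0), df_num,
                                    int(tab.loc["Residual", "df"]), p))
    return AnovaResult(tuple(factors), mse, df_error)


def two_way_anova_matrix(values_matrix, factor_a, factor_b,
                         names: tuple[str, str] = ("A", "B")) -> pd.DataFrame:
    """Type III two-way ANOVA for many response variables sharing one design.

    ``values_matrix`` is (n_variables, n_subjects); the design (sum-to-zero
    coded, identical to :func:`two_way_anova`) is factored once, so p-values
    for hundreds of variables (e.g. genes) come from three projections
    instead of per-variable model fits.  Returns a frame with columns
    ``p_<effect>`` / ``F_<effect>`` per effect (A, B, interaction).
    """
    y = np.atleast_2d(np.asarray(values_matrix, dtype=float))
    a = _as_labels(factor_a)
    b = _as_labels(factor_b)
    if y.shape[1] != len(a) or len(a) != len(b):
        raise ValueError("values_matrix columns must match factor labels")
    lev_a, lev_b = np.unique(a), np.unique(b)
    if len(lev_a) < 2 or len(lev_b) < 2:
        raise ValueError("each factor needs at least 2 levels")
    for la in lev_a:
        for lb in lev_b:
            if ((a == la) & (b == lb)).sum() < 2:
                raise ValueError(f"design cell ({la}, {lb}) has n < 2")

    def sum_code(labels, levels):
        # sum-to-zero contrasts: one column per non-reference level
        cols = []
        for lv in levels[:-1]:
            c = np.where(labels == lv, 1.0, 0.0)
            c[labels == levels[-1]] = -1.0
            cols.append(c)
        return np.column_stack(cols)

    xa = sum_code(a, lev_a)
    xb = sum_code(b, lev_b)
    xab = np.column_stack([xa[:, i] * xb[:, j]
                           for i in range(xa.shape[1])
                           for j in range(xb.shape[1])])
    intercept = np.ones((len(a), 1))
    blocks = {names[0]: xa, names[1]: xb, f"{names[0]}:{names[1]}": xab}

    def sse(x):
        q, _ = np.linalg.qr(x)
        proj = y @ q
        return (y ** 2).sum(axis=1) - (proj ** 2).sum(axis=1)

    x_full = np.column_stack([intercept, xa, xb, xab])
    sse_full = sse(x_full)
    df_err = len(a) - x_full.shape[1]
    out = {}
    for name, block in blocks.items():
        x_red = np.column_stack([v for k, v in
                                 [("i", intercept)] + list(blocks.items())
                                 if k != name])
        df_num = block.shape[1]
        num = (sse(x_red) - sse_full) / df_num
        den = sse_full / df_err
        with np.errstate(divide="ignore", invalid="ignore"):
            f_val = np.where(den > 0, num / den, np.inf)
        p = sps.f.sf(f_val, df_num, df_err)
        out[f"F_{name}"] = np.maximum(f_val, 0.0)
        out[f"p_{name}"] = np.clip(np.nan_to_num(p, nan=0.0), 0.0, 1.0)
    res = pd.DataFrame(out)
    res.attrs["df_error"] = df_err
    return res


def _degenerate_two_way(cell_vals, lev_a, lev_b, names, df_error) -> AnovaResult:
    means = {k: float(v.mean()) for k, v in cell_vals.items()}
    ga = {la: np.mean([means[(la, lb)] for lb in lev_b]) for la in lev_a}
    gb = {lb: np.mean([means[(la, lb)] for la in lev_a]) for lb in lev_b}
    grand = float(np.mean(list(means.values())))
    var_a = float(np.var(list(ga.values())))
    var_b = float(np.var(list(gb.values())))
    var_int = float(np.var([means[(la, lb)] - ga[la] - gb[lb] + grand
                            for la in lev_a for lb in lev_b]))
    factors = []
    for disp, v, dfn in (
        (names[0], var_a, len(lev_a) - 1),
        (names[1], var_b, len(lev_b) - 1),
        (f"{names[0]}:{names[1]}", var_int, (len(lev_a) - 1) * (len(lev_b) - 1)),
    ):
        if v > 1e-12:
            factors.append(FactorEffect(disp, float("inf"), dfn, df_error, 0.0))
        else:
            factors.append(FactorEffect(disp, 0.0, dfn, df_error, 1.0))
    return AnovaResult(tuple(factors), 0.0, df_error, degenerate=True)


def two_way_rm_anova(values, between_factor,
                     names: tuple[str, str] = ("group", "time")) -> AnovaResult:
    """Mixed-design ANOVA: one between-subjects factor, one repeated factor.

    ``values`` is a complete subject x timepoint matrix (no missing cells; no
    imputation is attempted).  Returns the between main effect (tested against
    subject-within-group error), the repeated main effect and the interaction
    (tested against the within-subject residual).  Degrees of freedom are
    uncorrected (no sphericity adjustment).

    The decomposition is the standard mixed-model partition::

        SS_total = SS_group + SS_subj(group) + SS_time + SS_group:time + SS_resid

    with ``SS_subj(group)`` the between-subjects error and ``SS_resid`` the
    within-subjects error.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2:
        raise ValueError("values must be a subjects x timepoints matrix")
    if np.isnan(y).any():
        raise ValueError("missing cells are not supported (complete panels only)")
    n_sub, n_time = y.shape
    if n_time < 2:
        raise ValueError("need at least 2 repeated levels")
    g = _as_labels(between_factor)
    if len(g) != n_sub:
        raise ValueError("between_factor must have one label per subject row")
    groups = np.unique(g)
    if len(groups) < 2:
        raise ValueError("need at least 2 between-subject levels")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_means = {lv: y[g == lv].mean() for lv in groups}
    n_per = {lv: int((g == lv).sum()) for lv in groups}
    time_means = y.mean(axis=0)

    ss_group = n_time * sum(n_per[lv] * (group_means[lv] - grand) ** 2 for lv in groups)
    ss_between_subj = n_time * float(((subj_means - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_group
    ss_time = n_sub * float(((time_means - grand) ** 2).sum())
    # group x time cell means
    ss_inter = 0.0
    for lv in groups:
        cell = y[g == lv].mean(axis=0)
        ss_inter += n_per[lv] * float(
            ((cell - group_means[lv] - time_means + grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_resid = ss_total - ss_group - ss_subj_within - ss_time - ss_inter

    k = len(groups)
    df_group = k - 1
    df_subj = n_sub - k
    df_time = n_time - 1
    df_inter = df_group * df_time
    df_resid = df_subj * df_time

    ms_subj = ss_subj_within / df_subj if df_subj > 0 else np.nan
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan
    degenerate = not (ms_subj > 1e-300) or not (ms_resid > 1e-300)

    def _eff(name, ss, dfn, ms_err, df_err):
        if degenerate or ms_err <= 0:
            msn = ss / dfn
            if msn > 1e-12:
                return FactorEffect(name, float("inf"), dfn, df_err, 0.0)
            return FactorEffect(name, 0.0, dfn, df_err, 1.0)
        f_val = (ss / dfn) / ms_err
        p = _check_p(float(sps.f.sf(f_val, dfn, df_err)))
        return FactorEffect(name, float(max(f_val, 0.0)), dfn, df_err, p)

    factors = (
        _eff(names[0], ss_group, df_group, ms_subj, df_subj),
        _eff(names[1], ss_time, df_time, ms_resid, df_resid),
        _eff(f"{names[0]}:{names[1]}", ss_inter, df_inter, ms_resid, df_resid),
    )
    return AnovaResult(factors, float(ms_subj) if np.isfinite(ms_subj) else 0.0,
                       df_subj, degenerate=degenerate)


def fishers_lsd(cell_values: dict, mse_within: float, df_error: int,
                pair: tuple[str, str]) -> PairwiseResult:
    """Fisher's protected LSD contrast between two groups.

    ``t = (mean_a - mean_b) / sqrt(MSE * (1/n_a + 1/n_b))`` with a two-sided p
    from the t distribution at the omnibus error df.  Gating on a significant
    omnibus effect is the caller's responsibility.
    """
    la, lb = pair
    va = np.asarray(cell_values[la], dtype=float)
    vb = np.asarray(cell_values[lb], dtype=float)
    if va.size < 1 or vb.size < 1:
        raise ValueError("each group needs n >= 1")
    diff = float(va.mean() - vb.mean())
    if mse_within <= 0:
        if abs(diff) < 1e-300:
            return PairwiseResult(la, lb, diff, 0.0, 1.0, degenerate=True)
        return PairwiseResult(la, lb, diff, float("inf") * np.sign(diff), 0.0,
                              degenerate=True)
    se = float(np.sqrt(mse_within * (1.0 / va.size + 1.0 / vb.size)))
    t = diff / se
    p = _check_p(2.0 * float(sps.t.sf(abs(t), df_error)))
    return PairwiseResult(la, lb, diff, t, p)


def students_t(group_a, group_b, labels: tuple[str, str] = ("a", "b")) -> PairwiseResult:
    """Two-sided pooled-variance (Student's) two-sample t-test."""
    va = np.asarray(group_a, dtype=float)
    vb = np.asarray(group_b, dtype=float)
    if va.size < 2 or vb.size < 2:
        raise ValueError("each group needs n >= 2")
    diff = float(va.mean() - vb.mean())
    sp2 = (((va.size - 1) * va.var(ddof=1) + (vb.size - 1) * vb.var(ddof=1))
           / (va.size + vb.size - 2))
    if sp2 <= 0:
        if abs(diff) < 1e-300:
            return PairwiseResult(labels[0], labels[1], diff, 0.0, 1.0)
        return PairwiseResult(labels[0], labels[1], diff,
                              float("inf") * np.sign(diff), 0.0, degenerate=True)
    t, p = sps.ttest_ind(va, vb, equal_var=True)
    return PairwiseResult(labels[0], labels[1], diff, float(t), _check_p(float(p)))


@dataclass(frozen=True)
class FdrResult:
    rejected: np.ndarray
    adjusted: np.ndarray
    q: float


def fdr_correct(p_values, q: float = 0.05) -> FdrResult:
    """Benjamini-Hochberg step-up FDR control.

    Rejects all hypotheses with rank <= the largest i such that
    ``p_(i) <= (i/m) * q``; adjusted values are the usual monotone BH q-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return FdrResult(np.zeros(0, dtype=bool), np.zeros(0), q)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    rej, adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return FdrResult(np.asarray(rej, dtype=bool), np.asarray(adj, dtype=float), q)


def binomial_agreement_test(n_agree: int, n_total: int, p0: float = 0.5) -> float:
    """Exact one-sided upper-tail binomial probability P(X >= n_agree)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_agree <= n_total:
        raise ValueError("n_agree must lie in [0, n_total]")
    return _check_p(float(sps.binom.sf(n_agree - 1, n_total, p0)))


def effect_size(stress_values, control_values) -> EffectSize:
    """(stress mean - control mean) / pooled SD, with (n-1)-weighted variances."""
    vs = np.asarray(stress_values, dtype=float)
    vc = np.asarray(control_values, dtype=float)
    if vs.size < 2 or vc.size < 2:
        raise ValueError("each group needs n >= 2")
    num = float(vs.mean() - vc.mean())
    sp2 = (((vs.size - 1) * vs.var(ddof=1) + (vc.size - 1) * vc.var(ddof=1))
           / (vs.size + vc.size - 2))
    if sp2 <= 0:
        raise ValueError("pooled SD is zero")
    sd = float(np.sqrt(sp2))
    return EffectSize(num / sd, num, sd)


def expected_null_count(n_tests: int, alpha: float = 0.05) -> int:
    """Expected significant count under the global null, rounded half-up."""
    return int(np.floor(n_tests * alpha + 0.5))


def anova_table(results: dict[str, AnovaResult], alpha: float = 0.05) -> pd.DataFrame:
    """Serialize ANOVA results to a tidy stats table."""
    rows = []
    for label, res in results.items():
        for fac in res.factors:
            rows.append({
                "analysis": label, "factor": fac.name, "F": fac.f,
                "df1": fac.df_num, "df2": fac.df_den, "p": fac.p,
                "significant": fac.p <= alpha, "degenerate": res.degenerate,
            })
    return pd.DataFrame(rows)
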