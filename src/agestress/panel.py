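"""Gene-panel (nCounter-style) normalization, QC and factorial contrasts.

The assay counts 171 pre-selected hippocampal-aging transcripts (101 with a
prior "up with age" direction, 70 "down") per lane, alongside 6 positive and
8 negative spike-in controls.  The analysis chain:

1. :func:`normalize` -- per-lane scale factor from positive-control geometric
   means; background (mean + 2 SD of the lane's negative controls) subtracted
   with a floor at zero.
2. :func:`qc_check` -- binding-density / fields-of-view lane gating.
3. :func:`per_gene_tests` -- age x stress ANOVA per gene on log2(x+1) values;
   a gene is "significant" when any of the three effects has p <= alpha, with
   the expected-null count (round-half-up of n_genes * alpha) reported
   alongside.  BH-FDR-adjusted values are reported, but significance calls
   use raw alpha, matching the reporting convention this analysis mirrors.
4. :func:`venn_partition` -- the age contrast tested separately within
   control lanes and within stress lanes (pooled-variance two-sample test),
   classifying each gene as both / control_only / stress_only / neither.
5. :func:`stress_effect_pairs` + :func:`classify_oppositional` -- per-gene
   standardized stress effects within young and within aged; a control-only
   gene is "oppositional" when the two effects have strictly opposite signs.
6. :func:`cv_summary` -- per-gene coefficients of variation within
   age x stress cells, averaged per stress condition.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats_core

__all__ = ["load_registry", "PanelDataset", "NormalizedPanel", "normalize",
           "QcThresholds", "qc_check", "per_gene_tests", "direction_agreement",
           "venn_partition", "stress_effect_pairs", "classify_oppositional",
           "cv_summary", "read_rcc_csv", "write_rcc_csv"]

VENN_CLASSES = ("both", "control_only", "stress_only", "neither")


def load_registry(path=None) -> pd.DataFrame:
    """Gene registry with prior aging direction.

    The packaged default is a synthetic stand-in list (the original panel's
    identifiers are not redistributable here) that preserves the panel
    composition: 171 rat hippocampal-aging genes, 101 prior-up, 70 prior-down.
    """
    if path is None:
        ref = (importlib.resources.files("agestress") / "data" /
               "aging_panel_registry_synthetic.tsv")
        with importlib.resources.as_file(ref) as p:
            reg = pd.read_csv(p, sep="\t")
    else:
        reg = pd.read_csv(path, sep="\t")
    if not {"gene", "prior_direction"} <= set(reg.columns):
        raise ValueError("registry needs 'gene' and 'prior_direction' columns")
    if reg.gene.duplicated().any():
        raise ValueError("duplicate gene ids in registry")
    return reg


@dataclass
class PanelDataset:
    """Gene x lane count matrix with spike-in controls and lane metadata.

    ``counts`` is indexed by gene (endogenous only); ``pos_controls`` /
    ``neg_controls`` carry the spike-in rows; ``lanes`` has one row per lane
    with columns lane_id, animal_id, age, stress, plate, binding_density, fov.
    """

    counts: pd.DataFrame
    pos_controls: pd.DataFrame
    neg_controls: pd.DataFrame
    lanes: pd.DataFrame
    registry: pd.DataFrame

    def __post_init__(self):
        missing = set(self.registry.gene) - set(self.counts.index)
        if missing:
            raise ValueError(f"registry genes missing from counts: "
                             f"{sorted(missing)[:5]}...")

    def lane_ids(self) -> list:
        return list(self.lanes.lane_id)


@dataclass
class NormalizedPanel:
    values: pd.DataFrame           # genes x lanes, normalized counts
    scale_factors: pd.Series
    background: pd.Series
    excluded_lanes: list
    lanes: pd.DataFrame
    registry: pd.DataFrame


def normalize(dataset: PanelDataset) -> NormalizedPanel:
    """Positive-control scaling then negative-control background subtraction.

    Scale factor per lane = (mean over lanes of the positive-control
    geometric means) / (that lane's positive-control geometric mean).  Lanes
    with any zero positive-control count are flagged and excluded.
    Background per lane = mean + 2 SD of the lane's negative controls,
    subtracted from scaled counts with a floor at zero.
    """
    pos = dataset.pos_controls
    bad = (pos <= 0).any(axis=0)
    excluded = list(pos.columns[bad])
    keep = [c for c in pos.columns if c not in excluded]
    if not keep:
        raise ValueError("all lanes excluded by zero positive-control counts")
    geo = np.exp(np.log(pos[keep]).mean(axis=0))
    sf = geo.mean() / geo
    scaled = dataset.counts[keep] * sf
    neg = dataset.neg_controls[keep] * sf
    background = neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)
    values = (scaled - background).clip(lower=0.0)
    lanes = dataset.lanes[dataset.lanes.lane_id.isin(keep)].reset_index(drop=True)
    return NormalizedPanel(values, sf, background, excluded, lanes,
                           dataset.registry)


@dataclass(frozen=True)
class QcThresholds:
    binding_density: tuple[float, float] = (0.1, 2.25)
    fov_fraction_min: float = 0.75
    fov_target: float = 600.0


def qc_check(dataset: PanelDataset,
             thresholds: QcThresholds = QcThresholds()) -> pd.DataFrame:
    """Per-lane pass/fail on binding density and fields-of-view read."""
    lanes = dataset.lanes
    for col in ("binding_density", "fov"):
        if col not in lanes.columns or lanes[col].isna().any():
            raise ValueError(f"missing qc field {col!r}")
    lo, hi = thresholds.binding_density
    bd_ok = lanes.binding_density.between(lo, hi)
    fov_ok = lanes.fov / thresholds.fov_target >= thresholds.fov_fraction_min
    return pd.DataFrame({
        "lane_id": lanes.lane_id,
        "binding_density": lanes.binding_density,
        "fov": lanes.fov,
        "binding_density_ok": bd_ok,
        "fov_ok": fov_ok,
        "pass": bd_ok & fov_ok,
    })


def _log2_matrix(norm: NormalizedPanel) -> pd.DataFrame:
    return np.log2(norm.values + 1.0)


def _lane_mask(lanes: pd.DataFrame, age=None, stress=None) -> pd.Series:
    m = pd.Series(True, index=lanes.index)
    if age is not None:
        m &= lanes.age == age
    if stress is not None:
        m &= lanes.stress == stress
    return m


def per_gene_tests(norm: NormalizedPanel, alpha: float = 0.05) -> pd.DataFrame:
    """Age x stress ANOVA per gene; any-of-three-effects significance rule.

    Returns a per-gene table with raw and BH-adjusted p-values, the observed
    aging direction (sign of aged-control minus young-control mean on the log
    scale) and its agreement with the registry prior.  The expected-null
    significant count is stored in ``result.attrs["expected_null"]``.
    """
    logm = _log2_matrix(norm)
    lanes = norm.lanes
    ages = lanes.age.to_numpy(dtype=object)
    stresses = lanes.stress.to_numpy(dtype=object)
    lane_order = list(lanes.lane_id)
    yc = list(lanes.lane_id[_lane_mask(lanes, "young", "control")])
    ac = list(lanes.lane_id[_lane_mask(lanes, "aged", "control")])
    prior = norm.registry.set_index("gene").prior_direction
    genes = list(norm.registry.gene)
    mat = logm.loc[genes, lane_order].to_numpy(dtype=float)
    res = stats_core.two_way_anova_matrix(mat, ages, stresses,
                                          names=("age", "stress"))
    diff = (logm.loc[genes, ac].mean(axis=1)
            - logm.loc[genes, yc].mean(axis=1)).to_numpy()
    obs_dir = np.where(diff > 0, "up", np.where(diff < 0, "down", "none"))
    table = pd.DataFrame({
        "gene": genes,
        "p_age": res["p_age"].to_numpy(),
        "p_stress": res["p_stress"].to_numpy(),
        "p_interaction": res["p_age:stress"].to_numpy(),
        "age_diff_log2": diff,
        "observed_direction": obs_dir,
        "prior_direction": prior.loc[genes].to_numpy(),
        "agrees_with_prior": obs_dir == prior.loc[genes].to_numpy(),
    })
    table["significant_age"] = table.p_age <= alpha
    table["significant_any"] = (
        (table.p_age <= alpha) | (table.p_stress <= alpha)
        | (table.p_interaction <= alpha))
    for col in ("p_age", "p_stress", "p_interaction"):
        table[col.replace("p_", "q_")] = stats_core.fdr_correct(
            table[col].to_numpy(), q=alpha).adjusted
    table.attrs["alpha"] = alpha
    table.attrs["n_significant"] = int(table.significant_any.sum())
    table.attrs["expected_null"] = stats_core.expected_null_count(len(table), alpha)
    return table


def direction_agreement(gene_table: pd.DataFrame, p0: float = 0.5) -> dict:
    """Direction-of-change agreement with the prior registry.

    Percent agreement among significant and among non-significant genes
    (zero-difference genes are excluded from the denominator and counted),
    plus the exact one-sided binomial p for the non-significant stratum
    against chance agreement p0.
    """
    usable = gene_table[gene_table.observed_direction != "none"]
    n_zero = int(len(gene_table) - len(usable))
    out = {"n_zero_difference_excluded": n_zero}
    for label, sub in (("significant", usable[usable.significant_any]),
                       ("non_significant", usable[~usable.significant_any])):
        n = len(sub)
        k = int(sub.agrees_with_prior.sum())
        out[f"{label}_n"] = n
        out[f"{label}_agree"] = k
        out[f"{label}_pct"] = 100.0 * k / n if n else float("nan")
    ns_n, ns_k = out["non_significant_n"], out["non_significant_agree"]
    out["binomial_p_non_significant"] = (
        stats_core.binomial_agreement_test(ns_k, ns_n, p0) if ns_n else float("nan"))
    return out


def venn_partition(norm: NormalizedPanel, alpha: float = 0.05) -> pd.DataFrame:
    """Within-condition age contrasts and the resulting Venn class per gene.

    The young-vs-aged contrast is a pooled-variance two-sample test run
    separately on control lanes and on stress lanes at the given alpha.
    """
    logm = _log2_matrix(norm)
    lanes = norm.lanes
    cols = {}
    for cond in ("control", "stress"):
        young = list(lanes.lane_id[_lane_mask(lanes, "young", cond)])
        aged = list(lanes.lane_id[_lane_mask(lanes, "aged", cond)])
        ps = []
        for gene in norm.registry.gene:
            res = stats_core.students_t(logm.loc[gene, young],
                                        logm.loc[gene, aged])
            ps.append(res.p)
        cols[f"p_{cond}"] = np.array(ps)
    table = pd.DataFrame({"gene": norm.registry.gene, **cols})
    sig_c = table.p_control <= alpha
    sig_s = table.p_stress <= alpha
    table["venn_class"] = np.select(
        [sig_c & sig_s, sig_c & ~sig_s, ~sig_c & sig_s],
        ["both", "control_only", "stress_only"], default="neither")
    return table


def stress_effect_pairs(norm: NormalizedPanel) -> pd.DataFrame:
    """Standardized stress effect (stress mean - control mean)/pooled SD per
    gene, computed separately within young and within aged lanes (log2 scale)."""
    logm = _log2_matrix(norm)
    lanes = norm.lanes
    sel = {}
    for age in ("young", "aged"):
        for cond in ("control", "stress"):
            sel[(age, cond)] = list(lanes.lane_id[_lane_mask(lanes, age, cond)])
    rows = []
    for gene in norm.registry.gene:
        es = {}
        for age in ("young", "aged"):
            e = stats_core.effect_size(logm.loc[gene, sel[(age, "stress")]],
                                       logm.loc[gene, sel[(age, "control")]])
            es[age] = e.value
        rows.append({"gene": gene, "es_young": es["young"], "es_aged": es["aged"]})
    return pd.DataFrame(rows)


def classify_oppositional(pairs: pd.DataFrame, venn: pd.DataFrame,
                          registry: pd.DataFrame) -> pd.DataFrame:
    """Oppositional-regulation calls for control-only aging genes.

    A gene is oppositional iff its young and aged stress effect sizes have
    strictly opposite signs (a zero effect is a boundary case, counted as not
    oppositional).  The summary fraction and the per-prior-direction quadrant
    breakdown live in ``result.attrs``.
    """
    merged = (pairs.merge(venn[["gene", "venn_class"]], on="gene")
              .merge(registry, on="gene"))
    co = merged[merged.venn_class == "control_only"].copy()
    co["oppositional"] = (co.es_young * co.es_aged) < 0
    co["quadrant"] = np.select(
        [(co.es_young > 0) & (co.es_aged < 0),
         (co.es_young < 0) & (co.es_aged > 0),
         (co.es_young > 0) & (co.es_aged > 0),
         (co.es_young < 0) & (co.es_aged < 0)],
        ["lower_right", "upper_left", "upper_right", "lower_left"],
        default="boundary")
    n = len(co)
    n_opp = int(co.oppositional.sum())
    co.attrs["n_control_only"] = n
    co.attrs["n_oppositional"] = n_opp
    co.attrs["oppositional_fraction"] = n_opp / n if n else float("nan")
    co.attrs["n_zero_boundary"] = int((co.quadrant == "boundary").sum())
    co.attrs["quadrants_by_prior"] = (
        co.groupby(["prior_direction", "quadrant"]).size().to_dict())
    return co


def cv_summary(norm: NormalizedPanel, genes=None) -> dict:
    """Mean +/- SE across genes of per-gene CVs within stress conditions.

    The CV of a gene within a condition is the mean of its within-cell CVs
    (young and aged cells of that condition), so the planted age contrast
    does not inflate the dispersion estimate.  Zero-mean genes are excluded
    and counted.
    """
    lanes = norm.lanes
    if genes is None:
        genes = list(norm.registry.gene)
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene subset")
    out = {}
    for cond in ("control", "stress"):
        cvs, excluded = [], 0
        cells = [list(lanes.lane_id[_lane_mask(lanes, age, cond)])
                 for age in ("young", "aged")]
        for gene in genes:
            cell_cvs = []
            for ids in cells:
                v = norm.values.loc[gene, ids].to_numpy(dtype=float)
                if v.mean() <= 0:
                    continue
                cell_cvs.append(v.std(ddof=1) / v.mean())
            if not cell_cvs:
                excluded += 1
                continue
            cvs.append(float(np.mean(cell_cvs)))
        arr = 100.0 * np.asarray(cvs)
        out[cond] = {
            "mean_cv_pct": float(arr.mean()),
            "se_cv_pct": float(arr.std(ddof=1) / np.sqrt(len(arr))),
            "n_genes": len(arr),
            "n_excluded_zero_mean": excluded,
        }
    return out


def read_rcc_csv(path, lanes: pd.DataFrame, registry: pd.DataFrame) -> PanelDataset:
    """Read an RCC-like CSV (CodeClass, Name, one count column per lane)."""
    df = pd.read_csv(path)
    if not {"CodeClass", "Name"} <= set(df.columns):
        raise ValueError("RCC-like CSV needs CodeClass and Name columns")
    lane_cols = [c for c in df.columns if c not in ("CodeClass", "Name")]
    def _block(code):
        sub = df[df.CodeClass == code].set_index("Name")[lane_cols]
        return sub.astype(float)
    return PanelDataset(_block("Endogenous"), _block("Positive"),
                        _block("Negative"), lanes, registry)


def write_rcc_csv(dataset: PanelDataset, path) -> None:
    blocks = [("Endogenous", dataset.counts), ("Positive", dataset.pos_controls),
              ("Negative", dataset.neg_controls)]
    frames = []
    for code, block in blocks:
        f = block.reset_index(names="Name")
        f.insert(0, "CodeClass", code)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
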