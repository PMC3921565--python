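"""Synthetic gene-panel counts with planted aging/stress structure.

Each gene carries a planted Venn class: "both" genes change with age in
control and stressed subjects alike; "control_only" genes change with age in
controls, while stress shifts young expression age-ward and/or aged
expression young-ward so the age contrast vanishes within stressed lanes
(oppositional shifts in a configured fraction of genes, concordant
contrast-cancelling shifts otherwise); "stress_only" genes show an age
contrast only within stressed lanes; the remainder are null.  Planted age
effects follow each gene's prior direction.

Counts are lane-scale x gene baseline x group effect x multiplicative
lognormal noise calibrated to a target within-cell coefficient of variation;
positive spike-ins follow the usual titration series with per-lane scale, and
negative spike-ins are background Poisson counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..design import CohortDesign
from ..panel import PanelDataset, load_registry

__all__ = ["PanelTruth", "default_panel_truth", "gen_panel_counts",
           "DEFAULT_VENN_COUNTS", "DEFAULT_OPPOSITIONAL_FRACTION",
           "DEFAULT_NOISE_CV"]

DEFAULT_VENN_COUNTS = {"both": 43, "stress_only": 8, "control_only": 42}
DEFAULT_OPPOSITIONAL_FRACTION = 33.0 / 42.0   # 79%
DEFAULT_NOISE_CV = 0.117

POS_EXPECTED = np.array([12000.0, 3000.0, 750.0, 187.5, 46.9, 11.7])
N_NEG = 8


@dataclass
class PanelTruth:
    """Planted per-gene structure plus generator noise settings."""

    genes: pd.DataFrame     # gene, prior_direction, venn_class, age_lfc,
                            # stress_shift_young, stress_shift_aged, oppositional
    noise_cv: float = DEFAULT_NOISE_CV

    def class_counts(self) -> dict:
        return self.genes.venn_class.value_counts().to_dict()


def default_panel_truth(registry: pd.DataFrame | None = None, seed: int = 0,
                        venn_counts: dict | None = None,
                        oppositional_fraction: float = DEFAULT_OPPOSITIONAL_FRACTION,
                        age_lfc: float = 0.8,
                        noise_cv: float = DEFAULT_NOISE_CV) -> PanelTruth:
    """Assign Venn classes / effect sizes across the registry (seeded).

    ``age_lfc`` is the planted log2 fold change of the within-condition age
    contrast for non-null genes ("strong": ~5 within-cell SDs at the default
    noise CV).  Oppositional control-only genes get stress shifts of
    (+lfc/2, -lfc/2) in (young, aged); concordant ones get (1.2 lfc, 0.2 lfc),
    which also cancels the age contrast within stressed lanes.
    """
    reg = registry if registry is not None else load_registry()
    counts = dict(DEFAULT_VENN_COUNTS if venn_counts is None else venn_counts)
    n_genes = len(reg)
    if sum(counts.values()) > n_genes:
        raise ValueError("venn class counts exceed registry size")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(
        [int(seed), 0x9A7])))
    order = rng.permutation(n_genes)
    venn = np.full(n_genes, "neither", dtype=object)
    pos = 0
    for cls in ("both", "stress_only", "control_only"):
        venn[order[pos:pos + counts[cls]]] = cls
        pos += counts[cls]

    prior = reg.prior_direction.to_numpy()
    sign = np.where(prior == "up", 1.0, -1.0)
    lfc = np.where(venn != "neither", sign * age_lfc, 0.0)
    # control_only genes carry no age contrast within stressed lanes
    s_young = np.zeros(n_genes)
    s_aged = np.zeros(n_genes)
    co_idx = np.flatnonzero(venn == "control_only")
    n_opp = int(round(oppositional_fraction * len(co_idx)))
    opp_sel = rng.permutation(co_idx)[:n_opp]
    opp = np.zeros(n_genes, dtype=bool)
    opp[opp_sel] = True
    for i in co_idx:
        if opp[i]:
            s_young[i] = 0.5 * lfc[i]
            s_aged[i] = -0.5 * lfc[i]
        else:
            s_young[i] = 1.2 * lfc[i]
            s_aged[i] = 0.2 * lfc[i]
    so_idx = venn == "stress_only"
    # age contrast appears only under stress: split the shift between groups
    s_young[so_idx] = -0.5 * sign[so_idx] * age_lfc
    s_aged[so_idx] = 0.5 * sign[so_idx] * age_lfc
    lfc[so_idx] = 0.0

    genes = pd.DataFrame({
        "gene": reg.gene, "prior_direction": prior, "venn_class": venn,
        "age_lfc": lfc, "stress_shift_young": s_young,
        "stress_shift_aged": s_aged, "oppositional": opp,
    })
    return PanelTruth(genes, noise_cv)


def gen_panel_counts(design: CohortDesign, truth: PanelTruth | None = None,
                     seed: int = 0, *, baseline_range=(300.0, 4000.0),
                     lane_scale_sd: float = 0.15,
                     neg_mean: float = 4.0) -> tuple[PanelDataset, PanelTruth]:
    """Generate an RCC-like dataset for the design's panel subset.

    Counts are rounded lognormal draws around lane_scale x baseline x
    2^(planted effects); the noise sigma is set so the within-cell CV equals
    ``truth.noise_cv``.  Raises if the noise CV is nonpositive.
    """
    if truth is None:
        truth = default_panel_truth(seed=seed)
    if truth.noise_cv <= 0:
        raise ValueError("noise CV must be positive")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(
        [int(seed), 0x9C0])))
    animals = design.panel_animals()
    n_lanes = len(animals)
    genes = truth.genes
    n_genes = len(genes)

    baseline = np.exp(rng.uniform(np.log(baseline_range[0]),
                                  np.log(baseline_range[1]), n_genes))
    lane_scale = np.exp(rng.normal(0.0, lane_scale_sd, n_lanes))
    sigma = np.sqrt(np.log1p(truth.noise_cv ** 2))

    aged = np.array([a.age_group == "aged" for a in animals])
    stressed = np.array([a.stress_group == "stress" for a in animals])
    lfc = genes.age_lfc.to_numpy()[:, None] * aged[None, :]
    shift = np.where(aged[None, :],
                     genes.stress_shift_aged.to_numpy()[:, None],
                     genes.stress_shift_young.to_numpy()[:, None])
    lfc = lfc + shift * stressed[None, :]
    mu = (baseline[:, None] * np.power(2.0, lfc) * lane_scale[None, :]
          * np.exp(rng.normal(0.0, sigma, (n_genes, n_lanes))))
    counts = np.maximum(np.round(mu), 0.0)

    lane_ids = [f"lane{i + 1:02d}" for i in range(n_lanes)]
    counts_df = pd.DataFrame(counts, index=genes.gene, columns=lane_ids)

    pos = (POS_EXPECTED[:, None] * lane_scale[None, :]
           * np.exp(rng.normal(0.0, 0.05, (len(POS_EXPECTED), n_lanes))))
    pos_df = pd.DataFrame(np.round(pos),
                          index=[f"POS_{c}" for c in "ABCDEF"],
                          columns=lane_ids)
    neg_df = pd.DataFrame(rng.poisson(neg_mean, (N_NEG, n_lanes)).astype(float),
                          index=[f"NEG_{c}" for c in "ABCDEFGH"],
                          columns=lane_ids)

    lanes = pd.DataFrame({
        "lane_id": lane_ids,
        "animal_id": [a.animal_id for a in animals],
        "age": [a.age_group for a in animals],
        "stress": [a.stress_group for a in animals],
        "plate": [i // 12 + 1 for i in range(n_lanes)],
        "binding_density": rng.normal(0.6, 0.04, n_lanes),
        "fov": np.clip(rng.normal(599.7, 0.3, n_lanes), None, 600.0),
    })
    registry = genes[["gene", "prior_direction"]].reset_index(drop=True)
    return PanelDataset(counts_df, pos_df, neg_df, lanes, registry), truth
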