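"""Panel normalization, QC, factorial contrasts and classification tests."""

import numpy as np
import pandas as pd
import pytest

from agestress import panel as P
from agestress.design import gen_design
from agestress.synthetic import (default_panel_truth, gen_panel_counts)


@pytest.fixture(scope="module")
def default_panel():
    design = gen_design(0)
    dataset, truth = gen_panel_counts(design, default_panel_truth(seed=0), 0)
    return dataset, truth


@pytest.fixture(scope="module")
def normalized(default_panel):
    dataset, truth = default_panel
    return P.normalize(dataset), truth


class TestRegistry:
    def test_packaged_registry_composition(self):
        reg = P.load_registry()
        assert len(reg) == 171
        counts = reg.prior_direction.value_counts()
        assert counts["up"] == 101
        assert counts["down"] == 70


class TestNormalize:
    def _tiny(self, counts, pos, neg):
        lanes = pd.DataFrame({
            "lane_id": list(counts.columns),
            "animal_id": list(counts.columns),
            "age": "young", "stress": "control", "plate": 1,
            "binding_density": 0.6, "fov": 599.7,
        })
        registry = pd.DataFrame({"gene": list(counts.index),
                                 "prior_direction": "up"})
        return P.PanelDataset(counts, pos, neg, lanes, registry)

    def test_identical_lanes_unit_scale_factors(self):
        counts = pd.DataFrame({"L1": [100.0, 200], "L2": [100.0, 200]},
                              index=["g1", "g2"])
        pos = pd.DataFrame({"L1": [100.0, 50], "L2": [100.0, 50]},
                           index=["P1", "P2"])
        neg = pd.DataFrame({"L1": [0.0, 0], "L2": [0.0, 0]}, index=["N1", "N2"])
        norm = P.normalize(self._tiny(counts, pos, neg))
        assert np.allclose(norm.scale_factors, 1.0)
        assert np.allclose(norm.values["L1"], norm.values["L2"])

    def test_doubled_lane_gets_half_scale_factor(self):
        counts = pd.DataFrame({"L1": [100.0, 200], "L2": [200.0, 400]},
                              index=["g1", "g2"])
        pos = pd.DataFrame({"L1": [64.0, 16], "L2": [128.0, 32]},
                           index=["P1", "P2"])
        neg = pd.DataFrame({"L1": [0.0, 0], "L2": [0.0, 0]}, index=["N1", "N2"])
        norm = P.normalize(self._tiny(counts, pos, neg))
        # lane geomeans 32 and 64; mean 48 -> factors 1.5 and 0.75 (ratio 2)
        assert norm.scale_factors["L2"] == pytest.approx(
            norm.scale_factors["L1"] / 2.0)
        assert np.allclose(norm.values["L1"], norm.values["L2"])

    def test_scale_factor_formula_oracle(self, default_panel):
        dataset, _ = default_panel
        norm = P.normalize(dataset)
        pos = dataset.pos_controls
        geo = np.exp(np.log(pos).mean(axis=0))
        expected = geo.mean() / geo
        assert np.allclose(norm.scale_factors, expected, atol=1e-9)

    def test_zero_positive_control_lane_excluded(self):
        counts = pd.DataFrame({"L1": [100.0], "L2": [90.0], "L3": [80.0]},
                              index=["g1"])
        pos = pd.DataFrame({"L1": [100.0], "L2": [0.0], "L3": [90.0]},
                           index=["P1"])
        neg = pd.DataFrame({"L1": [0.0], "L2": [0.0], "L3": [0.0]},
                           index=["N1"])
        norm = P.normalize(self._tiny(counts, pos, neg))
        assert norm.excluded_lanes == ["L2"]
        assert list(norm.values.columns) == ["L1", "L3"]

    def test_normalization_idempotent_scale_factors(self, default_panel):
        dataset, _ = default_panel
        norm = P.normalize(dataset)
        rescaled = P.PanelDataset(
            norm.values, dataset.pos_controls * norm.scale_factors,
            dataset.neg_controls * norm.scale_factors,
            dataset.lanes, dataset.registry)
        again = P.normalize(rescaled)
        assert np.allclose(again.scale_factors, 1.0, atol=1e-9)


class TestQc:
    def test_default_synthetic_lanes_pass(self, default_panel):
        dataset, _ = default_panel
        rep = P.qc_check(dataset)
        assert rep["pass"].all()

    def test_out_of_range_binding_density_fails(self, default_panel):
        dataset, _ = default_panel
        lanes = dataset.lanes.copy()
        lanes.loc[0, "binding_density"] = 6.0
        bad = P.PanelDataset(dataset.counts, dataset.pos_controls,
                             dataset.neg_controls, lanes, dataset.registry)
        rep = P.qc_check(bad)
        assert not rep["pass"].iloc[0]
        assert rep["pass"].iloc[1:].all()

    def test_missing_qc_fields_rejected(self, default_panel):
        dataset, _ = default_panel
        lanes = dataset.lanes.drop(columns=["fov"])
        bad = P.PanelDataset(dataset.counts, dataset.pos_controls,
                             dataset.neg_controls, lanes, dataset.registry)
        with pytest.raises(ValueError, match="fov"):
            P.qc_check(bad)


class TestPerGeneTests:
    def test_expected_null_count_is_nine(self, normalized):
        norm, _ = normalized
        table = P.per_gene_tests(norm)
        assert table.attrs["expected_null"] == 9
        assert len(table) == 171

    def test_noiseless_panel_recovers_planted_set_exactly(self):
        design = gen_design(1)
        truth = default_panel_truth(seed=1, noise_cv=1e-6)
        dataset, _ = gen_panel_counts(design, truth, 1, lane_scale_sd=0.0)
        table = P.per_gene_tests(P.normalize(dataset))
        planted = truth.genes.set_index("gene").venn_class != "neither"
        got = table.set_index("gene").significant_any
        assert (got == planted).all()

    def test_significant_set_monotone_in_alpha(self, normalized):
        norm, _ = normalized
        t1 = P.per_gene_tests(norm, alpha=0.01)
        t2 = P.per_gene_tests(norm, alpha=0.10)
        assert set(t1.gene[t1.significant_any]) <= set(t2.gene[t2.significant_any])

    def test_null_panel_significant_count_near_union_bound(self):
        # with no planted structure the any-of-three rule fires at a rate of
        # 1 - (1 - alpha)^3 per gene (the three F tests are ~independent)
        reps = 60
        expected = 171 * (1 - 0.95 ** 3)
        counts = []
        for s in range(reps):
            design = gen_design(1000 + s)
            truth = default_panel_truth(
                seed=s, venn_counts={"both": 0, "stress_only": 0,
                                     "control_only": 0})
            dataset, _ = gen_panel_counts(design, truth, 2000 + s)
            table = P.per_gene_tests(P.normalize(dataset))
            counts.append(table.attrs["n_significant"])
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(reps)
        assert abs(mean - expected) <= 2 * max(se, 1.0)


class TestDirectionAgreement:
    def test_all_agree_gives_full_agreement_and_power_of_half(self):
        table = pd.DataFrame({
            "gene": [f"g{i}" for i in range(6)],
            "observed_direction": ["up"] * 6,
            "prior_direction": ["up"] * 6,
            "agrees_with_prior": [True] * 6,
            "significant_any": [True, True, False, False, False, False],
        })
        out = P.direction_agreement(table)
        assert out["significant_pct"] == 100.0
        assert out["non_significant_pct"] == 100.0
        assert out["binomial_p_non_significant"] == pytest.approx(0.5 ** 4)

    def test_default_cohort_significant_agreement_high(self, normalized):
        norm, _ = normalized
        table = P.per_gene_tests(norm)
        out = P.direction_agreement(table)
        assert out["significant_pct"] >= 90.0


class TestVennPartition:
    def test_noiseless_classes_recovered_exactly(self):
        design = gen_design(3)
        truth = default_panel_truth(seed=3, noise_cv=1e-6)
        dataset, _ = gen_panel_counts(design, truth, 3, lane_scale_sd=0.0)
        venn = P.venn_partition(P.normalize(dataset))
        assert (venn.set_index("gene").venn_class
                == truth.genes.set_index("gene").venn_class).all()

    def test_classes_are_exhaustive_and_exclusive(self, normalized):
        norm, _ = normalized
        venn = P.venn_partition(norm)
        assert set(venn.venn_class) <= set(P.VENN_CLASSES)
        assert len(venn) == 171
        assert not venn.gene.duplicated().any()

    def test_default_cohort_recovers_planted_counts(self, normalized):
        norm, truth = normalized
        venn = P.venn_partition(norm)
        counts = venn.venn_class.value_counts()
        planted = truth.class_counts()
        assert abs(counts.get("control_only", 0) - planted["control_only"]) <= 5
        assert abs(counts.get("both", 0) - planted["both"]) <= 5
        assert abs(counts.get("stress_only", 0) - planted["stress_only"]) <= 5

    def test_null_genes_mostly_neither(self):
        # a null gene lands in "neither" with probability ~(1 - alpha)^2
        rates = []
        for s in range(10):
            design = gen_design(500 + s)
            truth = default_panel_truth(
                seed=s, venn_counts={"both": 0, "stress_only": 0,
                                     "control_only": 0})
            dataset, _ = gen_panel_counts(design, truth, 600 + s)
            venn = P.venn_partition(P.normalize(dataset))
            rates.append(np.mean(venn.venn_class == "neither"))
        assert np.mean(rates) == pytest.approx(0.95 ** 2, abs=0.02)


class TestEffectPairsAndOppositional:
    def test_no_planted_stress_effect_centers_at_zero(self):
        design = gen_design(5)
        truth = default_panel_truth(
            seed=5, venn_counts={"both": 0, "stress_only": 0,
                                 "control_only": 0})
        dataset, _ = gen_panel_counts(design, truth, 5)
        pairs = P.stress_effect_pairs(P.normalize(dataset))
        assert abs(pairs.es_young.mean()) < 0.15
        assert abs(pairs.es_aged.mean()) < 0.15

    def test_planted_signs_recovered_at_low_noise(self):
        design = gen_design(6)
        truth = default_panel_truth(seed=6, noise_cv=0.01)
        dataset, _ = gen_panel_counts(design, truth, 6)
        pairs = P.stress_effect_pairs(P.normalize(dataset)).set_index("gene")
        tg = truth.genes.set_index("gene")
        co = tg[tg.venn_class == "control_only"]
        assert (np.sign(pairs.loc[co.index, "es_young"])
                == np.sign(co.stress_shift_young)).all()
        assert (np.sign(pairs.loc[co.index, "es_aged"])
                == np.sign(co.stress_shift_aged)).all()

    def test_oppositional_rules_on_constructed_pairs(self):
        pairs = pd.DataFrame({
            "gene": ["a", "b", "c"],
            "es_young": [0.5, 0.3, 0.0],
            "es_aged": [-0.4, 0.3, -0.2],
        })
        venn = pd.DataFrame({"gene": ["a", "b", "c"],
                             "venn_class": ["control_only"] * 3})
        registry = pd.DataFrame({"gene": ["a", "b", "c"],
                                 "prior_direction": ["up", "up", "down"]})
        out = P.classify_oppositional(pairs, venn, registry)
        flags = out.set_index("gene").oppositional
        assert bool(flags["a"])          # opposite signs
        assert not bool(flags["b"])      # concordant
        assert not bool(flags["c"])      # zero boundary excluded
        assert out.attrs["n_zero_boundary"] == 1
        assert out.set_index("gene").quadrant["a"] == "lower_right"

    def test_default_cohort_oppositional_fraction_near_planted(self, normalized):
        norm, truth = normalized
        venn = P.venn_partition(norm)
        pairs = P.stress_effect_pairs(norm)
        out = P.classify_oppositional(pairs, venn, norm.registry)
        frac = 100.0 * out.attrs["oppositional_fraction"]
        assert abs(frac - 79.0) <= 10.0


class TestCvSummary:
    def test_constant_matrix_zero_cv(self, normalized):
        norm, _ = normalized
        flat = P.NormalizedPanel(
            pd.DataFrame(100.0, index=norm.values.index,
                         columns=norm.values.columns),
            norm.scale_factors, norm.background, [], norm.lanes, norm.registry)
        out = P.cv_summary(flat)
        assert out["control"]["mean_cv_pct"] == 0.0

    def test_default_cohort_cv_near_target(self, normalized):
        norm, truth = normalized
        co = list(truth.genes.gene[truth.genes.venn_class == "control_only"])
        out = P.cv_summary(norm, co)
        assert abs(out["control"]["mean_cv_pct"] - 11.7) <= 2.0
        assert abs(out["stress"]["mean_cv_pct"] - 11.7) <= 2.0

    def test_cv_invariant_to_lane_scaling(self, normalized):
        norm, _ = normalized
        scaled = P.NormalizedPanel(norm.values * 3.7, norm.scale_factors,
                                   norm.background, [], norm.lanes,
                                   norm.registry)
        a = P.cv_summary(norm)["control"]["mean_cv_pct"]
        b = P.cv_summary(scaled)["control"]["mean_cv_pct"]
        assert a == pytest.approx(b)

    def test_empty_subset_rejected(self, normalized):
        norm, _ = normalized
        with pytest.raises(ValueError, match="empty"):
            P.cv_summary(norm, [])


class TestRccRoundtrip:
    def test_csv_roundtrip_preserves_counts(self, default_panel, tmp_path):
        dataset, _ = default_panel
        path = tmp_path / "panel.csv"
        P.write_rcc_csv(dataset, path)
        back = P.read_rcc_csv(path, dataset.lanes, dataset.registry)
        assert np.allclose(back.counts, dataset.counts)
        assert np.allclose(back.pos_controls, dataset.pos_controls)
        assert np.allclose(back.neg_controls, dataset.neg_controls)
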