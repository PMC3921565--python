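"""End-to-end orchestration: generate a cohort, run all analyses, write tables.

A run is a pure function of its :class:`PipelineConfig` (seed included); the
report directory holds one tidy CSV per figure-style analysis plus a JSON run
report with the config hash and a summary of significant findings.
:func:`recovery_suite` re-runs the generator/analysis loop across seeded
replicates and reports recovered-vs-planted quantities.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import panel as panel_mod
from . import physiology, sleep, watermaze
from .design import CohortDesign, gen_design
from .synthetic import (CortModel, FieldPotentialModel, SwimPerformance,
                        TemperatureModel, default_panel_truth,
                        default_stage_program, gen_cort, gen_fp_sweeps,
                        gen_panel_counts, gen_swim_trials, gen_telemetry)
from .watermaze import MazeConfig

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "recovery_suite"]


def _sizes_to_tuples(sizes: dict | None) -> dict | None:
    """Accept either ("young", "control") or "young-control" keys."""
    if sizes is None:
        return None
    out = {}
    for k, v in sizes.items():
        if isinstance(k, str):
            age, stress = k.split("-")
            out[(age, stress)] = v
        else:
            out[tuple(k)] = v
    return out


def _sizes_to_strings(sizes: dict | None) -> dict | None:
    if sizes is None:
        return None
    return {(k if isinstance(k, str) else "-".join(k)): v
            for k, v in sizes.items()}


@dataclass
class PipelineConfig:
    seed: int = 0
    alpha: float = 0.05
    fdr_q: float = 0.05
    group_sizes: dict | None = None      # keys "age-stress", e.g. "young-control"
    panel_sizes: dict | None = None
    telemetry_duration_h: float = 16.0   # covers one active + one resting window
    telemetry_fs: float = 100.0
    artifact_rate: float = 0.02
    run_sleep: bool = True
    run_maze: bool = True
    run_panel: bool = True
    run_physiology: bool = True
    out_dir: str = "agestress_run"

    def __post_init__(self):
        self.group_sizes = _sizes_to_strings(self.group_sizes)
        self.panel_sizes = _sizes_to_strings(self.panel_sizes)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=True)


@dataclass
class RunReport:
    config_hash: str
    seed: int
    tables: dict
    summary: dict


def _write(df: pd.DataFrame, out: Path, name: str, tables: dict) -> None:
    path = out / name
    df.to_csv(path, index=False)
    tables[name.removesuffix(".csv")] = str(path)


def _stage(name):
    """Wrap a pipeline stage so failures carry the stage name."""
    def deco(fn):
        def inner(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return inner
    return deco


@_stage("sleep")
def _run_sleep(cfg: PipelineConfig, design: CohortDesign, out: Path,
               tables: dict, summary: dict) -> None:
    recs = gen_telemetry(design, default_stage_program(), cfg.seed,
                         duration_h=cfg.telemetry_duration_h,
                         fs=cfg.telemetry_fs, artifact_rate=cfg.artifact_rate)
    arch_rows, acc_rows, hyp_frames = [], [], []
    meta = {a.animal_id: a for a in design.animals}
    temp_frames = []
    for tt in recs:
        hyp = sleep.score_recording(tt.recording)
        acc_rows.append({
            "animal_id": tt.recording.animal_id,
            "accuracy": sleep.accuracy(hyp, tt.hypnogram),
            "unscored_fraction": hyp.unscored_fraction,
        })
        hf = sleep.hypnogram_to_frame(hyp)
        hf.insert(0, "animal_id", tt.recording.animal_id)
        hyp_frames.append(hf)
        a = meta[tt.recording.animal_id]
        try:
            arch = sleep.summarize_architecture(hyp)
        except ValueError:
            arch = None   # recording too short for both windows
        if arch is not None:
            arch["animal_id"] = tt.recording.animal_id
            arch["age"] = a.age_group
            arch["stress"] = a.stress_group
            arch_rows.append(arch)
        tf = physiology.hourly_bin(tt.recording.temperature,
                                   tt.recording.start_hour)
        tf.insert(0, "animal_id", tt.recording.animal_id)
        temp_frames.append(tf)
    acc = pd.DataFrame(acc_rows)
    _write(acc, out, "sleep_scoring_accuracy.csv", tables)
    _write(pd.concat(hyp_frames, ignore_index=True), out, "hypnograms.csv", tables)
    summary["sleep_mean_accuracy"] = float(acc.accuracy.mean())
    summary["sleep_pooled_unscored_pct"] = float(
        100 * acc.unscored_fraction.mean())
    if arch_rows:
        arch_df = pd.concat(arch_rows, ignore_index=True)
        _write(arch_df, out, "sleep_architecture.csv", tables)
        st = sleep.architecture_stats(
            arch_df.rename(columns={"animal_id": "animal"}), cfg.alpha)
        _write(st["anova"], out, "sleep_architecture_anova.csv", tables)
        _write(st["lsd"], out, "sleep_architecture_lsd.csv", tables)
    hourly = pd.concat(temp_frames, ignore_index=True)
    _write(hourly, out, "temperature_hourly.csv", tables)
    # stress contrast within each age group (hyperthermia analysis)
    for age in ("young", "aged"):
        ids = [a.animal_id for a in design.animals if a.age_group == age]
        sub = hourly[hourly.animal_id.isin(ids)]
        group_of = {a.animal_id: a.stress_group for a in design.animals}
        st = physiology.temperature_stats(sub, group_of, cfg.alpha,
                                          lsd_pair=("control", "stress"))
        _write(st["anova"], out, f"temperature_anova_{age}.csv", tables)
        pgrp = st["result"]["group"].p
        summary[f"temperature_stress_p_{age}"] = float(pgrp)


@_stage("watermaze")
def _run_maze(cfg: PipelineConfig, design: CohortDesign, out: Path,
              tables: dict, summary: dict) -> None:
    config = MazeConfig()
    trials = gen_swim_trials(design, config, SwimPerformance(), cfg.seed)
    metrics = watermaze.metrics_frame(trials, config)
    _write(metrics, out, "maze_metrics.csv", tables)
    st = watermaze.maze_stats(metrics, design, cfg.alpha)
    _write(st["training_anova"], out, "maze_training_anova.csv", tables)
    _write(st["probe_anova"], out, "maze_probe_anova.csv", tables)
    _write(st["probe_lsd"], out, "maze_probe_lsd.csv", tables)
    probe = metrics[metrics.trial_type == "probe"]
    age_of = {a.animal_id: a.age_group for a in design.animals}
    young = probe[probe.animal_id.map(age_of) == "young"]
    tr = metrics[metrics.trial_type == "spatial"]
    summary["young_mean_speed_cm_s"] = float(
        tr[tr.animal_id.map(age_of) == "young"].mean_speed_cm_s.mean())
    summary["young_probe_crossings_mean"] = float(
        young.platform_crossings.mean())


@_stage("panel")
def _run_panel(cfg: PipelineConfig, design: CohortDesign, out: Path,
               tables: dict, summary: dict) -> None:
    dataset, truth = gen_panel_counts(design, default_panel_truth(seed=cfg.seed),
                                      cfg.seed)
    qc = panel_mod.qc_check(dataset)
    _write(qc, out, "panel_qc.csv", tables)
    norm = panel_mod.normalize(dataset)
    gene_table = panel_mod.per_gene_tests(norm, cfg.alpha)
    _write(gene_table, out, "panel_gene_stats.csv", tables)
    agree = panel_mod.direction_agreement(gene_table)
    venn = panel_mod.venn_partition(norm, cfg.alpha)
    _write(venn, out, "panel_venn.csv", tables)
    pairs = panel_mod.stress_effect_pairs(norm)
    _write(pairs, out, "panel_effect_pairs.csv", tables)
    opp = panel_mod.classify_oppositional(pairs, venn, norm.registry)
    _write(opp, out, "panel_oppositional.csv", tables)
    co_genes = list(opp.gene)
    cv = panel_mod.cv_summary(norm, co_genes) if co_genes else {}
    summary["panel_n_significant"] = gene_table.attrs["n_significant"]
    summary["panel_expected_null"] = gene_table.attrs["expected_null"]
    summary["panel_direction_agreement"] = agree
    summary["panel_venn_counts"] = venn.venn_class.value_counts().to_dict()
    summary["panel_oppositional_fraction"] = opp.attrs["oppositional_fraction"]
    summary["panel_cv"] = cv
    summary["panel_truth_class_counts"] = truth.class_counts()


@_stage("physiology")
def _run_physio(cfg: PipelineConfig, design: CohortDesign, out: Path,
                tables: dict, summary: dict) -> None:
    cort = gen_cort(design, cfg.seed, CortModel())
    _write(cort, out, "cort_values.csv", tables)
    st = physiology.cort_stats(cort, cfg.alpha)
    _write(st["anova"], out, "cort_anova.csv", tables)
    _write(st["lsd"], out, "cort_lsd.csv", tables)
    sweeps = gen_fp_sweeps(design, cfg.seed, FieldPotentialModel())
    curves = []
    pp_rows = []
    for asw in sweeps:
        c = physiology.io_curve(asw.io)
        c["animal_id"] = asw.animal_id
        curves.append(c)
        for delay, pairs in asw.pp.items():
            ratios = [physiology.pp_ratio(a, b)[0] for a, b in pairs]
            pp_rows.append({"animal_id": asw.animal_id, "delay_ms": delay,
                            "pp_ratio": float(np.nanmean(ratios))})
    curves = pd.concat(curves, ignore_index=True)
    _write(curves, out, "io_curves.csv", tables)
    group_of = {a.animal_id: f"{a.age_group}-{a.stress_group}"
                for a in design.animals}
    io_st = physiology.io_stats(curves, group_of, cfg.alpha)
    _write(io_st["anova"], out, "io_anova.csv", tables)
    _write(io_st["lsd"], out, "io_lsd.csv", tables)
    pp_df = pd.DataFrame(pp_rows)
    _write(pp_df, out, "pp_ratios.csv", tables)
    summary["io_interaction_p"] = float(io_st["result"]["group:step"].p)
    summary["pp_mean_ratio_50ms"] = float(
        pp_df[pp_df.delay_ms == 50].pp_ratio.mean())


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute generation + all enabled analyses; deterministic per seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = gen_design(config.seed, _sizes_to_tuples(config.group_sizes),
                        _sizes_to_tuples(config.panel_sizes))
    tables: dict = {}
    summary: dict = {}
    if config.run_sleep:
        _run_sleep(config, design, out, tables, summary)
    if config.run_maze:
        _run_maze(config, design, out, tables, summary)
    if config.run_panel:
        _run_panel(config, design, out, tables, summary)
    if config.run_physiology:
        _run_physio(config, design, out, tables, summary)
    report = RunReport(config.config_hash(), config.seed, tables, summary)
    with open(out / "report.json", "w") as f:
        json.dump({"config_hash": report.config_hash, "seed": report.seed,
                   "tables": report.tables, "summary": report.summary},
                  f, indent=2, default=str)
    config.to_yaml(out / "config.yaml")
    return report


def recovery_suite(seed: int = 0, n_replicates: int = 20,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Recovered-vs-planted summary across seeded replicates.

    Per replicate: venn class counts, oppositional fraction and control CV
    from a default panel; young group swim-speed mean from a default maze
    cohort.  (Stage accuracy is a slower measure; see the sleep analysis in
    :func:`run_pipeline` or the acceptance script.)
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rows = []
    for i in range(n_replicates):
        rep_seed = int(seed) + i
        design = gen_design(rep_seed)
        dataset, truth = gen_panel_counts(
            design, default_panel_truth(seed=rep_seed), rep_seed)
        norm = panel_mod.normalize(dataset)
        venn = panel_mod.venn_partition(norm, alpha)
        pairs = panel_mod.stress_effect_pairs(norm)
        opp = panel_mod.classify_oppositional(pairs, venn, norm.registry)
        co = list(opp.gene)
        cv = panel_mod.cv_summary(norm, co) if co else None
        counts = venn.venn_class.value_counts().to_dict()
        rows.append({
            "seed": rep_seed,
            "venn_both": counts.get("both", 0),
            "venn_control_only": counts.get("control_only", 0),
            "venn_stress_only": counts.get("stress_only", 0),
            "oppositional_pct": 100.0 * opp.attrs["oppositional_fraction"],
            "control_cv_pct": cv["control"]["mean_cv_pct"] if cv else np.nan,
            "planted_control_only": truth.class_counts().get("control_only", 0),
            "planted_oppositional_pct":
                100.0 * truth.genes.oppositional.sum()
                / max((truth.genes.venn_class == "control_only").sum(), 1),
        })
    return pd.DataFrame(rows)
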