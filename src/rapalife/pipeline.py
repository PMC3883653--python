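"""End-to-end orchestration: simulate → mortality → survival → DE → MDS → enrichment.

A single :class:`PipelineConfig` (YAML-loadable) drives every stage.  All
randomness flows from one global seed, expanded per stage through numpy
``SeedSequence(seed, spawn_key=(stage_index,))`` so adding a stage never
perturbs the random stream of earlier stages.  Identical config + seed yields
byte-identical outputs; the run report lists every output file with its
SHA-256 checksum.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import rapalife
from rapalife import enrichment as enr_mod
from rapalife import mortality as mort_mod
from rapalife import ordination_cluster as ord_mod
from rapalife import survival_stats as surv_mod
from rapalife import synthetic_data as syn_mod
from rapalife import transcriptome_de as de_mod

# fixed per-stage spawn keys; appending new stages keeps old streams intact
STAGE_KEYS = {"cohort": 0, "expression": 1, "gene_sets": 2, "mortality": 3}


def stage_seed(global_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(global_seed, spawn_key=(STAGE_KEYS[stage],))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    seed: int
    output_dir: str
    simulate: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    de_filter: dict = field(default_factory=lambda: {"adjusted_p_max": 0.05,
                                                     "min_percent_change": 15.0})
    mortality_alpha: float = 0.05
    enrichment_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ValueError("config must set a global seed")
        return cls(
            seed=int(raw["seed"]),
            output_dir=raw.get("output_dir", "rapalife_out"),
            simulate=raw.get("simulate", {}),
            inputs=raw.get("inputs", {}),
            de_filter=raw.get("de_filter", {"adjusted_p_max": 0.05,
                                            "min_percent_change": 15.0}),
            mortality_alpha=float(raw.get("mortality_alpha", 0.05)),
            enrichment_alpha=float(raw.get("enrichment_alpha", 0.05)),
        )

    def validate(self) -> None:
        for key, path in self.inputs.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"config input {key!r} refers to a missing file: {path}")


@dataclass
class RunReport:
    version: str
    config: dict
    row_counts: dict
    warnings: list
    manifest: dict  # path -> sha256

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _simulate_stage(cfg: PipelineConfig, out: Path, counts: dict):
    sim = cfg.simulate
    cohort_cfg = sim.get("cohort", {})
    design = syn_mod.default_lifespan_design(
        seed=stage_seed(cfg.seed, "cohort"),
        censor_fraction=float(cohort_cfg.get("censor_fraction", 0.0)))
    cohort_df, cohort_truth = syn_mod.simulate_cohort(design)
    syn_mod.write_survival_csv(cohort_df, out / "survival.csv")

    expr_cfg = dict(sim.get("expression", {}))
    expr_cfg["seed"] = stage_seed(cfg.seed, "expression")
    edesign = syn_mod.ExpressionDesign(**expr_cfg)
    intens, meta, expr_truth = syn_mod.simulate_expression(edesign)
    intens.to_csv(out / "expression.tsv", sep="\t")
    meta.to_csv(out / "sample_metadata.tsv", sep="\t")

    gs_cfg = dict(sim.get("gene_sets", {}))
    gs_cfg["seed"] = stage_seed(cfg.seed, "gene_sets")
    de_labels = (expr_truth.de_direction["female_treated"] != 0)
    catalog, set_truth = syn_mod.simulate_gene_sets(
        list(intens.index), de_labels, **gs_cfg)
    enr_mod.write_gmt(catalog, out / "gene_sets.gmt")

    truth = {
        "responder": {k: bool(v) for k, v in expr_truth.responder.items()},
        "sex_gene": {k: bool(v) for k, v in expr_truth.sex_gene.items() if v},
        "de_direction": {c: {k: int(v) for k, v in col.items() if v != 0}
                         for c, col in expr_truth.de_direction.items()},
        "planted_sets": set_truth.planted_sets,
        "group_hazard": {g: {"family": m.family, "a": m.a, "b": m.b}
                         for g, m in cohort_truth.group_hazard.items()},
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    counts["animals"] = len(cohort_df)
    counts["probes"], counts["samples"] = intens.shape
    counts["gene_sets"] = len(catalog.sets)
    return cohort_df, intens, meta, catalog


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute every stage in dependency order and write a checksummed manifest."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    caught: list[str] = []

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        # ---- inputs: simulate or load -----------------------------------
        if cfg.inputs:
            cohort_df = syn_mod.read_survival_csv(cfg.inputs["survival_csv"])
            matrix = de_mod.read_expression_tsv(cfg.inputs["expression_tsv"],
                                                cfg.inputs["metadata_tsv"])
            intens, meta = matrix.values, matrix.metadata
            catalog = enr_mod.read_gmt(cfg.inputs["gmt"]) if "gmt" in cfg.inputs else None
            counts["animals"] = len(cohort_df)
            counts["probes"], counts["samples"] = intens.shape
        else:
            cohort_df, intens, meta, catalog = _simulate_stage(cfg, out, counts)

        # ---- mortality ---------------------------------------------------
        groups = {g: syn_mod.cohort_from_frame(cohort_df, g)
                  for g in sorted(cohort_df["group"].unique())}
        mort_report: dict = {"groups": {}}
        for g, coh in groups.items():
            sel = mort_mod.select_model(coh, alpha=cfg.mortality_alpha, n_starts=4)
            fit = sel.fits[sel.chosen]
            mort_report["groups"][g] = {
                "chosen_family": sel.chosen,
                "a": fit.model.a, "b": fit.model.b,
                "log_likelihood": fit.log_likelihood,
                "n": fit.n,
            }
        # pooled-sex treated-vs-control parameter tests
        ctrl = [g for g in groups if "control" in g]
        trt = [g for g in groups if g not in ctrl]
        pooled_ctrl = groups[ctrl[0]]
        for g in ctrl[1:]:
            pooled_ctrl = pooled_ctrl.concat(groups[g])
        pooled_trt = groups[trt[0]]
        for g in trt[1:]:
            pooled_trt = pooled_trt.concat(groups[g])
        for par in ("a", "b", "both"):
            cmpres = mort_mod.compare_groups(pooled_ctrl, pooled_trt, par)
            mort_report[f"pooled_test_{par}"] = {
                "statistic": cmpres.statistic, "df": cmpres.df, "p": cmpres.p}
        (out / "mortality_report.json").write_text(
            json.dumps(mort_report, indent=2, sort_keys=True))
        counts["mortality_groups"] = len(groups)

        # ---- survival summaries -----------------------------------------
        surv_report: dict = {"groups": {}, "treated_vs_control": {}}
        km_rows = []
        for g, coh in groups.items():
            summ = surv_mod.survival_summary(coh)
            surv_report["groups"][g] = {
                "mean": summ.mean, "q80": summ.q80, "q50": summ.q50,
                "q10": summ.q10, "max_longest": summ.max_longest,
                "max_top_decile_mean": summ.max_top_decile_mean}
            curve = surv_mod.km_estimate(coh)
            for t, s, r in zip(curve.times, curve.survival, curve.at_risk):
                km_rows.append((g, t, s, r))
        pd.DataFrame(km_rows, columns=["group", "time", "survival", "at_risk"]).to_csv(
            out / "km_curves.tsv", sep="\t", index=False)
        sexes = sorted({g.split("_", 1)[1] for g in groups})
        for sex in sexes:
            c = groups.get(f"control_{sex}")
            t = groups.get(f"rapa_{sex}")
            if c is None or t is None:
                continue
            cox = surv_mod.cox_ph(c, t)
            aft = surv_mod.weibull_aft(c, t)
            surv_report["treated_vs_control"][sex] = {
                "cox_hazard_ratio": cox.hazard_ratio,
                "cox_percent_risk_reduction": cox.percent_risk_reduction,
                "cox_p": cox.p,
                "weibull_time_ratio": aft.time_ratio,
                "weibull_percent_extension": aft.percent_extension,
                "weibull_p": aft.p,
            }
        (out / "survival_report.json").write_text(
            json.dumps(surv_report, indent=2, sort_keys=True))

        # ---- normalize + MDS + subgroups --------------------------------
        matrix = de_mod.ExpressionMatrix(values=intens, metadata=meta)
        norm = de_mod.normalize(matrix)
        mds = ord_mod.classical_mds(norm.values, k=2)
        mds.coordinates.to_csv(out / "mds_coordinates.tsv", sep="\t")
        cm = norm.samples_in_group("control_male")
        tf = norm.samples_in_group("rapa_female")
        tm = norm.samples_in_group("rapa_male")
        sub = ord_mod.assign_subgroups(mds, cm, tf, tm)
        sub.labels.rename("subgroup").rename_axis("sample").to_csv(
            out / "responder_labels.tsv", sep="\t")
        counts["rapa2_males"] = int((sub.labels == "Rapa-2").sum())

        # ---- DE contrasts ------------------------------------------------
        flt = de_mod.DEFilter(**cfg.de_filter)
        cf = norm.samples_in_group("control_female")
        rf = norm.samples_in_group("rapa_female")
        rapa1 = sub.labels.index[sub.labels == "Rapa-1"].tolist()
        rapa2 = sub.labels.index[sub.labels == "Rapa-2"].tolist()
        contrasts = {"rapa_female_vs_control_female": (rf, cf),
                     "rapa_male_vs_control_male": (tm, cm)}
        if len(rapa1) >= 2:
            contrasts["rapa1_male_vs_control_male"] = (rapa1, cm)
        if len(rapa2) >= 2:
            contrasts["rapa2_male_vs_control_male"] = (rapa2, cm)
        tables, de_lists = {}, {}
        for name, (ga, gb) in contrasts.items():
            tab = de_mod.differential_test(norm, ga, gb)
            tab.to_csv(out / f"contrast_{name}.tsv", sep="\t")
            tables[name] = tab
            de_lists[name] = de_mod.filter_de(tab, flt)
            de_mod.write_gene_list(de_lists[name], out / f"de_{name}.tsv")
            counts[f"de_{name}"] = len(de_lists[name])

        # ---- direction-aware overlap ------------------------------------
        key_a = ("rapa2_male_vs_control_male"
                 if "rapa2_male_vs_control_male" in de_lists
                 else "rapa_male_vs_control_male")
        ov = de_mod.overlap(de_lists[key_a], de_lists["rapa_female_vs_control_female"])
        (out / "overlap.json").write_text(json.dumps(ov.__dict__, indent=2, sort_keys=True))

        # ---- enrichment --------------------------------------------------
        if catalog is not None:
            universe = list(norm.values.index)
            harmonized = catalog.harmonized(universe)
            fem = de_lists["rapa_female_vs_control_female"]
            report = enr_mod.enrichment_report(
                list(fem.index), harmonized, tables["rapa_female_vs_control_female"],
                flt, universe)
            report.to_csv(out / "enrichment_female.tsv", sep="\t")
            counts["significant_sets"] = int(report["significant"].sum())

        caught = [str(w.message) for w in wrec]

    manifest = {str(p.relative_to(out)): _sha256(p)
                for p in sorted(out.glob("*")) if p.is_file() and p.name != "run_report.json"}
    report = RunReport(
        version=rapalife.__version__,
        config=cfg.__dict__,
        row_counts=counts,
        warnings=caught,
        manifest=manifest,
    )
    report.to_json(out / "run_report.json")
    return report
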