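"""Config-driven orchestration of the full analysis chain.

``run_pipeline`` executes the fixed stage DAG

    simulate -> harmonize -> twas (single- and multi-tissue, splicing
    comparison) -> ase -> ehr scans (phenome + labs) -> enrichment
    -> cross-ancestry

on synthetic data with known ground truth, persists every intermediate in
the documented plain-text formats, and returns a machine-readable report:
per-stage status and counts, the exact multiplicity thresholds applied,
the genes passing the joint Bonferroni threshold, and precision/recall
against the generator's causal genes. Identical config + seed give an
identical report. A stage failure halts only its downstream dependents.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from grexlink import ase as ase_mod
from grexlink import cross_ancestry as xa
from grexlink import enrichment as enr
from grexlink import grex as grex_mod
from grexlink import io, simulate, twas
from grexlink.harmonize import harmonize_sumstats
from grexlink.types import GrexlinkError, ReferencePanel, SimConfig

logger = logging.getLogger(__name__)

DEFAULTS: dict[str, Any] = {
    "family_alpha": 0.05,
    "condition_limit": 30,
    "min_cases": 100,
    "min_lab_n": 100,
    "min_coverage": 8,
    "gwas_p_threshold": 5e-5,
    "ase_window_bp": 1_000_000,
    "clump_r2": 0.1,
    "clump_window_bp": 250_000,
    "n_boot": 2000,
}

_STAGE_DEPS = {
    "simulate": (),
    "harmonize": ("simulate",),
    "twas": ("harmonize",),
    "ase": ("simulate", "harmonize"),
    "ehr": ("simulate",),
    "enrichment": ("ehr",),
    "cross_ancestry": ("simulate",),
}


def load_config(source) -> dict:
    """Accept a dict, or a path to a YAML config file."""
    if isinstance(source, Mapping):
        return dict(source)
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"pipeline config not found: {path}")
    return yaml.safe_load(path.read_text()) or {}


def _sim_config(cfg: dict) -> SimConfig:
    sim = dict(cfg.get("sim", {}))
    sim.setdefault("seed", cfg.get("seed", 0))
    if "tissues" in sim:
        sim["tissues"] = tuple(sim["tissues"])
    if "maf_range" in sim:
        sim["maf_range"] = tuple(sim["maf_range"])
    return SimConfig(**sim)


def run_pipeline(config, out_dir=None) -> dict:
    """Run every enabled stage and return the report dictionary.

    ``config`` is a dict or YAML path; see ``DEFAULTS`` for analysis
    defaults and :class:`grexlink.types.SimConfig` for generator fields.
    Missing input files named in the config raise before any computation.
    """
    cfg = load_config(config)
    params = {**DEFAULTS, **cfg.get("analysis", {})}
    seed = int(cfg.get("seed", 0))
    for key in ("sumstats_file", "weights_file", "panel_file"):
        if key in cfg and not Path(cfg[key]).exists():
            raise FileNotFoundError(
                f"stage simulate/load: configured {key} does not exist: "
                f"{cfg[key]}")
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    report: dict[str, Any] = {"seed": seed, "stages": {}, "thresholds": {}}
    state: dict[str, Any] = {}
    enabled = cfg.get("stages", list(_STAGE_DEPS))
    failed: set[str] = set()

    def run_stage(name, fn):
        if name not in enabled:
            return
        blocked = [d for d in _STAGE_DEPS[name] if d in failed or
                   (d in enabled and d not in report["stages"])]
        if any(d in failed for d in _STAGE_DEPS[name]):
            report["stages"][name] = {"status": "skipped",
                                      "reason": f"dependency failed: {blocked}"}
            failed.add(name)
            return
        t0 = time.perf_counter()
        try:
            info = fn() or {}
            info["status"] = "ok"
        except Exception as exc:
            logger.exception("stage %s failed", name)
            info = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
            failed.add(name)
        info["seconds"] = round(time.perf_counter() - t0, 3)
        report["stages"][name] = info

    # -- simulate -----------------------------------------------------------
    def _simulate():
        sc = _sim_config(cfg)
        panel = simulate.simulate_reference_panel(sc)
        weights = simulate.simulate_weight_models(sc, panel)
        sp_weights = simulate.simulate_weight_models(sc, panel,
                                                     feature_type="splicing")
        sumstats, gwas_truth = simulate.simulate_gwas(sc, weights, panel)
        state.update(sim_config=sc, panel=panel, weights=weights,
                     sp_weights=sp_weights, sumstats_raw=sumstats,
                     gwas_truth=gwas_truth)
        if out:
            io.write_panel(panel, out / "panel.tsv")
            io.write_weights(weights, out / "weights_expression.tsv")
            io.write_weights(sp_weights, out / "weights_splicing.tsv")
            io.write_sumstats(sumstats, out / "sumstats.tsv")
            io.write_json({"causal_genes": gwas_truth.causal_genes},
                          out / "truth.json")
        return {"n_variants": sc.n_variants, "n_genes": sc.n_genes,
                "n_tissues": len(sc.tissues),
                "causal_genes": gwas_truth.causal_genes}

    run_stage("simulate", _simulate)

    # -- harmonize ----------------------------------------------------------
    def _harmonize():
        harmonized, rep = harmonize_sumstats(state["sumstats_raw"],
                                             state["panel"])
        state["sumstats"] = harmonized
        if out:
            io.write_sumstats(harmonized, out / "sumstats_harmonized.tsv")
            io.write_json(rep.as_dict(), out / "harmonization_report.json")
        return rep.as_dict()

    run_stage("harmonize", _harmonize)

    # -- twas ---------------------------------------------------------------
    def _twas():
        panel, sumstats = state["panel"], state["sumstats"]
        sc = state["sim_config"]
        single = [twas.single_tissue_twas(sumstats, m, panel)
                  for m in state["weights"]]
        single_df = twas.results_table(single)
        by_gene = {}
        for m in state["weights"]:
            by_gene.setdefault(m.gene_id, []).append(m)
        multi_rows = []
        for gene_id, models in sorted(by_gene.items()):
            cor = twas.tissue_correlation(models, panel)
            zs = pd.Series(
                {r.tissue: r.z for r in single
                 if r.gene_id == gene_id and r.testable},
            )
            if zs.empty:
                continue
            cor = cor.loc[zs.index, zs.index]
            res = twas.multi_tissue_combine(
                zs, cor, condition_limit=params["condition_limit"],
                gene_id=gene_id)
            multi_rows.append(vars(res))
        multi_df = pd.DataFrame(multi_rows)
        joint_thr = twas.bonferroni_threshold(sc.n_genes,
                                              params["family_alpha"])
        testable = single_df.loc[single_df["testable"]]
        per_tissue_thr = twas.bonferroni_threshold(
            max(len(testable), 1), params["family_alpha"])
        discovered = sorted(
            multi_df.loc[multi_df["p"] < joint_thr, "gene_id"])
        truth_genes = set(state["gwas_truth"].causal_genes)
        tp = len(set(discovered) & truth_genes)
        precision = tp / len(discovered) if discovered else float("nan")
        recall = tp / len(truth_genes) if truth_genes else float("nan")
        # splicing scan + paired signal comparison
        sp_single = [twas.single_tissue_twas(sumstats, m, panel)
                     for m in state["sp_weights"]]
        sp_df = twas.results_table(sp_single)
        comp = twas.compare_signal_levels(
            single_df.loc[single_df["testable"]],
            sp_df.loc[sp_df["testable"]])
        state.update(single_df=single_df, multi_df=multi_df,
                     discovered=discovered)
        report["thresholds"]["twas_joint_bonferroni"] = joint_thr
        report["thresholds"]["twas_per_tissue_bonferroni"] = per_tissue_thr
        report["discovered_genes"] = discovered
        report["truth_comparison"] = {"precision": precision,
                                      "recall": recall,
                                      "n_discovered": len(discovered),
                                      "n_causal": len(truth_genes)}
        if out:
            single_df.to_csv(out / "twas_single_tissue.tsv", sep="\t",
                             index=False)
            multi_df.to_csv(out / "twas_multi_tissue.tsv", sep="\t",
                            index=False)
            comp.per_gene.to_csv(out / "twas_vs_sptwas.tsv", sep="\t",
                                 index=False)
        return {"n_single_tests": len(single_df),
                "n_multi_tests": len(multi_df),
                "joint_threshold": joint_thr,
                "discovered_genes": discovered,
                "signal_comparison_p": comp.p_wilcoxon}

    run_stage("twas", _twas)

    # -- ase ----------------------------------------------------------------
    def _ase():
        acfg = cfg.get("ase", {})
        table, truth = simulate.simulate_ase(
            state["weights"],
            n_individuals=acfg.get("n_individuals", 200),
            mean_coverage=acfg.get("mean_coverage", 30),
            imbalance_log2_afc=acfg.get("imbalance_log2_afc", 0.0),
            seed=seed + 1)
        windows = simulate.gene_windows(state["weights"], state["panel"])
        tests, per_gene = ase_mod.ase_scan(
            table, state["sumstats"], windows,
            gwas_p_threshold=params["gwas_p_threshold"],
            window_bp=params["ase_window_bp"],
            min_total_reads=params["min_coverage"],
            family_alpha=params["family_alpha"])
        report["thresholds"]["ase_gene_bonferroni"] = \
            per_gene.attrs["alpha_cutoff"]
        if out:
            table.to_csv(out / "ase_counts.tsv", sep="\t", index=False)
            per_gene.to_csv(out / "ase_per_gene.tsv", sep="\t", index=False)
        return {"n_tests": len(tests),
                "n_genes_tested": int(per_gene["tested"].sum()),
                "n_significant": int(per_gene["significant"].sum())}

    run_stage("ase", _ase)

    # -- ehr scans ----------------------------------------------------------
    def _ehr():
        ecfg = cfg.get("ehr", {})
        ehr = simulate.simulate_ehr(
            state["sim_config"], state["panel"], state["weights"],
            n_individuals=ecfg.get("n_individuals", 1500),
            n_phecodes=ecfg.get("n_phecodes", 30),
            n_labs=ecfg.get("n_labs", 12),
            phecode_effects=ecfg.get("phecode_effects"),
            lab_effects=ecfg.get("lab_effects"),
            target_prevalence=ecfg.get("target_prevalence", 0.2),
            seed=seed + 2)
        gene = (state.get("discovered") or [state["weights"][0].gene_id])[0]
        grex = ehr.grex[gene]
        phe = grex_mod.run_phewas(grex, ehr.phecodes, ehr.covariates,
                                  min_cases=params["min_cases"],
                                  categories=ehr.phecode_categories,
                                  family_alpha=params["family_alpha"])
        lab = grex_mod.run_labwas(grex, ehr.labs, ehr.covariates,
                                  min_n=params["min_lab_n"],
                                  categories=ehr.lab_categories,
                                  family_alpha=params["family_alpha"])
        state.update(ehr=ehr, phewas=phe, labwas=lab, scan_gene=gene)
        report["thresholds"]["phewas_bonferroni"] = \
            phe.attrs["bonferroni_threshold"]
        report["thresholds"]["labwas_bonferroni"] = \
            lab.attrs["bonferroni_threshold"]
        if out:
            phe.to_csv(out / "phewas.tsv", sep="\t", index=False)
            lab.to_csv(out / "labwas.tsv", sep="\t", index=False)
            ehr.covariates.to_csv(out / "covariates.csv")
            ehr.phecodes.to_csv(out / "phecodes.csv")
            ehr.labs.to_csv(out / "labs.csv", index=False)
        return {"scan_gene": gene,
                "n_phecodes_tested": phe.attrs["n_tested"],
                "n_labs_tested": lab.attrs["n_tested"],
                "n_phewas_significant": int(phe["significant"].sum())
                if len(phe) else 0,
                "n_labwas_significant": int(lab["significant"].sum())
                if len(lab) else 0}

    run_stage("ehr", _ehr)

    # -- enrichment ---------------------------------------------------------
    def _enrichment():
        results = {}
        for label, scan in (("phewas", state["phewas"]),
                            ("labwas", state["labwas"])):
            if not len(scan):
                continue
            hyper = enr.hypergeom_enrichment(
                scan[["category", "significant"]])
            chi2 = enr.chi2_bootstrap_enrichment(
                scan.assign(z=scan["effect"] / scan["se"])[["category", "z"]],
                n_boot=params["n_boot"], seed=seed + 3)
            if out:
                hyper.to_csv(out / f"enrichment_{label}_hypergeom.tsv",
                             sep="\t", index=False)
                chi2.to_csv(out / f"enrichment_{label}_chi2.tsv",
                            sep="\t", index=False)
            results[label] = {
                "n_categories": len(hyper),
                "top_chi2_category":
                    (chi2.loc[chi2["z_enrich"].idxmax(), "category"]
                     if chi2["z_enrich"].notna().any() else None)}
        return results

    run_stage("enrichment", _enrichment)

    # -- cross-ancestry -----------------------------------------------------
    def _cross_ancestry():
        xcfg = cfg.get("two_ancestry", {})
        pairs = simulate.simulate_two_ancestry_effects(
            n_pairs=xcfg.get("n_pairs", 32),
            alpha=xcfg.get("alpha", 0.87),
            sigma2=xcfg.get("sigma2", 1.0),
            seed=seed + 4)
        fit = xa.fit_cross_ancestry(pairs)
        het = xa.pairwise_heterogeneity(pairs)
        if out:
            pairs.to_csv(out / "paired_effects.tsv", sep="\t", index=False)
            io.write_json(vars(fit), out / "cross_ancestry_fit.json")
        return {"alpha": fit.alpha, "alpha_ci95": list(fit.ci95),
                "sigma2": fit.sigma2, "n_pairs": fit.n_pairs,
                "n_heterogeneous": int(het["het_significant"].sum())}

    run_stage("cross_ancestry", _cross_ancestry)

    if out:
        io.write_json(report, out / "pipeline_report.json")
    return report
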