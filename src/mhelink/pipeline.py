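"""End-to-end orchestration of the four-step integration analysis.

Step 1: QC, variance stabilization and differential testing per omic.
Step 2: correlation-module discovery on the significant serum features.
Step 3: one PLS2 model per module (significant genes -> module compounds).
Step 4: ORA of the differential genes, ranked enrichment of PLS loadings,
pathway-pathway and term-module networks.

Every stage reads and writes plain TSV/JSON contracts so the steps are
independently runnable (see :mod:`mhelink.cli`).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .matrix import OmicsMatrix, check_same_samples, read_groups
from . import cohort as syn
from . import diffexp as de
from . import modules as mc
from . import pls as pm
from . import enrich as en

log = logging.getLogger("mhelink")


@dataclass
class PipelineConfig:
    """Single configuration for a full pipeline run."""

    outdir: str = "mhelink_out"
    seed: int = 2021
    synthetic: dict | None = None          # CohortConfig fields; None => inputs
    inputs: dict | None = None             # genes/metabolites/cytokines/samples paths
    gmt: str | None = None                 # path; None + synthetic => generated sets
    alpha: float = 0.05
    relaxed_alpha: float = 0.10
    lod: float = 0.0
    k_min: int = 2
    k_max: int = 10
    cluster_methods: tuple[str, ...] = ("pam", "kmeans", "hierarchical")
    pls_components: int = 2
    pls_scaling: str = "autoscale"
    jaccard_min: float = 0.10
    n_random_sets: int = 30

    @staticmethod
    def from_file(path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping")
        known = set(PipelineConfig.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cluster_methods" in data:
            data["cluster_methods"] = tuple(data["cluster_methods"])
        return PipelineConfig(**data)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["cluster_methods"] = list(self.cluster_methods)
        return d


def validate_inputs(config: PipelineConfig
                    ) -> tuple[PipelineConfig, list[str]]:
    """Aggregate all validation errors instead of failing on the first."""
    errors: list[str] = []
    if not 0 < config.alpha < 1:
        errors.append(f"alpha must be in (0,1), got {config.alpha}")
    if config.synthetic is None and config.inputs is None:
        errors.append("config needs either a 'synthetic' block or 'inputs' paths")
    if config.synthetic is not None:
        try:
            syn.CohortConfig.from_dict(config.synthetic)
        except (ValueError, TypeError) as exc:
            errors.append(f"synthetic: {exc}")
    if config.inputs is not None:
        needed = {"genes", "metabolites", "cytokines", "samples"}
        missing_keys = needed - set(config.inputs)
        if missing_keys:
            errors.append(f"inputs missing keys: {sorted(missing_keys)}")
        for key in needed & set(config.inputs):
            if not Path(config.inputs[key]).exists():
                errors.append(f"inputs.{key}: no such file {config.inputs[key]}")
    if config.gmt is not None and not Path(config.gmt).exists():
        errors.append(f"gmt: no such file {config.gmt}")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return config, errors


def _load_cohort(config: PipelineConfig
                 ) -> tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix, dict | None]:
    if config.synthetic is not None:
        cc = dict(config.synthetic)
        cc.setdefault("seed", config.seed)
        cohort = syn.generate_full_cohort(cc)
        return cohort.genes, cohort.metabolites, cohort.cytokines, cohort.truth
    paths = config.inputs
    groups = read_groups(paths["samples"])
    genes = OmicsMatrix.from_tsv(paths["genes"], groups, omic="gene")
    metab = OmicsMatrix.from_tsv(paths["metabolites"], groups, omic="metabolite")
    cyto = OmicsMatrix.from_tsv(paths["cytokines"], groups, omic="cytokine")
    errors = []
    for m in (metab, cyto):
        if m.sample_ids != genes.sample_ids:
            errors.append(
                f"{m.omic}: sample ids differ from genes: "
                f"{sorted(set(genes.sample_ids) ^ set(m.sample_ids))}")
    for m in (genes, metab, cyto):
        for grp in (m.case, m.control):
            if (m.groups == grp).sum() < 2:
                errors.append(
                    f"{m.omic}: group {grp!r} has < 2 samples; two-group "
                    "testing requires at least 2 per group")
    if errors:
        raise ValueError("invalid inputs:\n  " + "\n  ".join(errors))
    return genes, metab, cyto, None


@dataclass
class RunReport:
    version: str = __version__
    config: dict = field(default_factory=dict)
    config_hash: str = ""
    steps: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    completed: list[str] = field(default_factory=list)
    failed_step: str | None = None
    error: str | None = None

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True, default=str)


def _hash_config(d: dict) -> str:
    return hashlib.sha256(
        json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_all(config: PipelineConfig) -> RunReport:
    """Execute Steps 1-4, writing all artifacts under ``config.outdir``."""
    config, _ = validate_inputs(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict(),
                       config_hash=_hash_config(config.to_dict()))
    caught: list[str] = []

    def _step(name):
        log.info("step %s", name)
        return time.time()

    try:
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")
            _run_steps(config, outdir, report, _step)
        caught = [str(w.message) for w in wrec]
    except Exception as exc:
        report.error = str(exc)
        log.error("pipeline failed at %s: %s", report.failed_step, exc)
        report.write(outdir / "run_report.json")
        raise
    report.warnings = caught
    report.write(outdir / "run_report.json")
    return report


def _run_steps(config: PipelineConfig, outdir: Path, report: RunReport,
               _step) -> None:
    # ---- inputs ---------------------------------------------------------
    report.failed_step = "load"
    t0 = _step("load")
    genes, metab, cyto, truth = _load_cohort(config)
    check_same_samples(genes, metab, cyto)
    if truth is not None:
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    report.steps["load"] = {
        "n_genes": genes.values.shape[0],
        "n_metabolites": metab.values.shape[0],
        "n_cytokines": cyto.values.shape[0],
        "n_samples": genes.n_samples,
        "n_case": len(genes.case_samples),
        "n_control": len(genes.control_samples),
        "seconds": round(time.time() - t0, 3)}
    report.completed.append("load")

    # ---- Step 1: QC, normalization, differential testing ---------------
    report.failed_step = "step1_diffexp"
    t0 = _step("step1")
    metab_qc, qc_report = de.metabolite_qc_filter(metab, lod=config.lod)
    qc_report.to_csv(outdir / "metabolite_qc.tsv", sep="\t")
    genes_n = de.vst_normalize(genes)
    # targeted metabolite panels are absolutely quantified; per-sample
    # affine calibration is skipped there (glog stabilization only)
    metab_n = de.vst_normalize(metab_qc, calibrate=False)
    gene_table = de.moderated_ttest(genes_n, alpha=config.alpha)
    metab_table = de.moderated_ttest(metab_n, alpha=config.alpha)
    cyto_table = de.wilcoxon_panel(cyto, alpha=config.alpha)
    for name, table in (("diffexp_genes", gene_table),
                        ("diffexp_metabolites", metab_table),
                        ("diffexp_cytokines", cyto_table)):
        table.to_csv(outdir / f"{name}.tsv", sep="\t", float_format="%.6g")
    sig_genes = de.significant_features(gene_table, config.alpha)
    sig_metab = de.significant_features(metab_table, config.alpha)
    sig_cyto = de.significant_features(cyto_table, config.alpha)
    report.steps["step1_diffexp"] = {
        "metabolites_after_qc": int(metab_qc.values.shape[0]),
        "significant_genes": len(sig_genes),
        "significant_metabolites": len(sig_metab),
        "significant_cytokines": len(sig_cyto),
        "gene_prior_d0": gene_table.attrs["d0"],
        "seconds": round(time.time() - t0, 3)}
    report.completed.append("step1_diffexp")

    # ---- Step 2: compound modules --------------------------------------
    report.failed_step = "step2_modules"
    t0 = _step("step2")
    serum_sig = sig_metab + sig_cyto
    if len(serum_sig) < 3:
        report.steps["step2_modules"] = {
            "note": "fewer than 3 significant serum features; "
                    "module discovery skipped", "n_serum_significant":
            len(serum_sig)}
        report.completed.append("step2_modules")
        report.failed_step = None
        return
    serum = OmicsMatrix(
        pd.concat([metab_n.values.loc[[f for f in sig_metab]],
                   cyto.values.loc[[f for f in sig_cyto]]]),
        genes.groups, omic="serum")
    corr = mc.spearman_abs_corr(serum)
    dist = mc.corr_distance(corr)
    selection = mc.select_modules(
        dist, range(config.k_min, config.k_max + 1),
        methods=config.cluster_methods, seed=config.seed)
    best = selection.best
    profiles = mc.module_profiles(serum, best)
    members_df = pd.DataFrame({
        "feature": best.labels.index,
        "module": [f"M{c}" for c in best.labels.to_numpy()],
        "sign": [int(next(p.signs[f] for p in profiles if f in p.members))
                 for f in best.labels.index],
        "silhouette": best.silhouette.round(6).to_numpy()})
    members_df.to_csv(outdir / "modules.tsv", sep="\t", index=False)
    prof_df = pd.DataFrame({p.name: p.profile for p in profiles}).T
    prof_df.index.name = "module"
    prof_df.to_csv(outdir / "module_profiles.tsv", sep="\t",
                   float_format="%.6g")
    selection.candidates.to_csv(outdir / "clustering_candidates.tsv",
                                sep="\t", index=False, float_format="%.6g")
    with open(outdir / "clustering_report.json", "w") as fh:
        json.dump({"method": best.method, "k": int(best.k),
                   "mean_silhouette": best.mean_silhouette,
                   "low_signal": bool(selection.low_signal),
                   "medoids": list(map(str, best.medoids))}, fh, indent=1)
    report.steps["step2_modules"] = {
        "n_serum_significant": len(serum_sig), "method": best.method,
        "k": int(best.k), "mean_silhouette": round(best.mean_silhouette, 4),
        "seconds": round(time.time() - t0, 3)}
    report.completed.append("step2_modules")

    # ---- Step 3: per-module PLS ----------------------------------------
    report.failed_step = "step3_pls"
    t0 = _step("step3")
    module_members = {p.name: p.members for p in profiles}
    results, summary = pm.fit_all_modules(
        genes_n, module_members, metab_n, cyto, sig_genes,
        n_components=config.pls_components, scaling=config.pls_scaling)
    summary.to_csv(outdir / "pls_summary.tsv", sep="\t", index=False,
                   float_format="%.6g")
    for name, res in results.items():
        res.ranking.to_csv(outdir / f"loadings_{name}.tsv", sep="\t",
                           index=False, float_format="%.6g")
    report.steps["step3_pls"] = {
        "n_models": len(results),
        "min_R2": float(summary["R2_cum"].min()),
        "min_Q2": float(summary["Q2_cum"].min()),
        "seconds": round(time.time() - t0, 3)}
    report.completed.append("step3_pls")

    # ---- Step 4: enrichment and networks -------------------------------
    report.failed_step = "step4_enrichment"
    t0 = _step("step4")
    if config.gmt is not None:
        collection = en.read_gmt(config.gmt)
    elif truth is not None:
        sets = syn.make_gene_sets(truth, n_random=config.n_random_sets,
                                  seed=config.seed)
        syn.write_gmt(sets, outdir / "gene_sets_synthetic.gmt")
        collection = en.GeneSetCollection({k: set(v) for k, v in sets.items()})
    else:
        report.steps["step4_enrichment"] = {"note": "no GMT provided; skipped"}
        report.completed.append("step4_enrichment")
        report.failed_step = None
        return
    universe = list(genes.values.index)
    ora = en.fisher_ora(sig_genes, universe, collection, alpha=config.alpha,
                        relaxed=config.relaxed_alpha)
    ora.to_csv(outdir / "ora.tsv", sep="\t", float_format="%.6g")
    pw_net = en.pathway_network(ora, collection, config.jaccard_min)
    en.write_network(pw_net, outdir / "pathway_network.tsv",
                     outdir / "pathway_network.graphml")
    per_module = {}
    for name, res in results.items():
        per_module[name] = en.ranked_enrichment(res.ranking, collection,
                                                alpha=config.alpha)
        per_module[name].to_csv(outdir / f"ranked_enrichment_{name}.tsv",
                                sep="\t", float_format="%.6g")
    multi_net = en.multi_enrichment_network(per_module, alpha=config.alpha)
    en.write_network(multi_net, outdir / "multi_enrichment_network.tsv",
                     outdir / "multi_enrichment_network.graphml")
    report.steps["step4_enrichment"] = {
        "n_sets": len(collection.sets),
        "ora_significant": int(ora["significant"].sum()),
        "ora_relaxed_only": int((ora["relaxed"] & ~ora["significant"]).sum()),
        "multi_network_terms": sum(1 for _, d in multi_net.nodes(data=True)
                                   if d.get("kind") == "term"),
        "seconds": round(time.time() - t0, 3)}
    report.completed.append("step4_enrichment")
    report.failed_step = None

    _reconcile(report, outdir)


def _reconcile(report: RunReport, outdir: Path) -> None:
    """Check that report counts equal rows of the corresponding files."""
    checks = {
        "significant_genes": None,  # list-based, checked implicitly
        "modules.tsv": ("step2_modules", "n_serum_significant"),
        "pls_summary.tsv": ("step3_pls", "n_models"),
    }
    mismatches = []
    for fname, key in checks.items():
        if key is None or not (outdir / fname).exists():
            continue
        step, field_name = key
        n_rows = len(pd.read_csv(outdir / fname, sep="\t"))
        expect = report.steps.get(step, {}).get(field_name)
        if expect is not None and n_rows != expect:
            mismatches.append(f"{fname}: {n_rows} rows != reported {expect}")
    if mismatches:
        raise AssertionError("report/file reconciliation failed: "
                             + "; ".join(mismatches))
    report.steps["reconciled"] = True
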