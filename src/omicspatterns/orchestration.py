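"""End-to-end pipeline: prep -> factorization -> markers/labels -> gene sets
-> integration -> optional projection, with a manifest and per-stage seeds.

A single global seed fans out to per-stage seeds (stage name hashed into a
seed sequence) so every stage is individually reproducible from the
manifest. Every artifact is tab-separated text or JSON, so a run can be
restarted from any stage's outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import factorization as fz
from . import geneset_stat, integration, io_prep, pattern_analysis
from .containers import OmicsMatrix, UncertaintyMatrix
from .synthetic_data import SimConfig, generate_time_course, write_dataset

log = logging.getLogger("omicspatterns")


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for a pipeline run."""

    # inputs; leave None to simulate from `synthetic`
    expression: str | None = None
    methylation: str | None = None
    methylation_M: str | None = None
    methylation_U: str | None = None
    samples: str | None = None
    annotation: str | None = None
    gene_sets: str | None = None

    synthetic: dict = field(default_factory=dict)

    # factorization
    p_expr: int | None = 5
    p_meth: int | None = 3
    p_range_expr: tuple = (2, 10)
    p_range_meth: tuple = (2, 5)
    select_dimensions: bool = False
    n_restarts: int = 3
    n_sets: int = 1  # >1 switches methylation to parallel-set consensus
    sparsity: float = 0.0
    max_iter: int = 2000
    tol: float = 1.0e-6
    similarity_threshold: float = 0.85

    # pattern analysis / integration
    c_separation: float = 2.0
    cv_min: float = 0.1
    alpha: float = 0.05
    n_perm: int = 1000
    coverage: float = 100.0

    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("expression", "methylation", "samples", "annotation", "gene_sets",
                     "methylation_M", "methylation_U"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name}={p} does not exist")


def stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(stage.encode()).digest()
    tag = int.from_bytes(digest[:4], "big")
    return int(np.random.SeedSequence([int(seed) % 2**31, tag]).generate_state(1)[0] % 2**31)


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.expression is None:
        sim = SimConfig(**{"seed": stage_seed(config.seed, "simulate"), **config.synthetic})
        log.info("simulating inputs: %d genes, %d generations", sim.n_genes, sim.n_generations)
        expression, methylation, annotation, truth = generate_time_course(sim)
        write_dataset(outdir / "inputs", expression, methylation, annotation, truth)
        return expression, methylation, annotation
    config.validate_paths()
    meta = io_prep.read_metadata_tsv(config.samples)
    expr = OmicsMatrix(
        values=io_prep.read_matrix_tsv(config.expression), samples=meta, platform="expression"
    )
    beta = io_prep.read_matrix_tsv(config.methylation)
    M = U = None
    if config.methylation_M and config.methylation_U:
        M = io_prep.read_matrix_tsv(config.methylation_M)
        U = io_prep.read_matrix_tsv(config.methylation_U)
    meth = OmicsMatrix(values=beta, samples=meta, platform="methylation", M=M, U=U)
    annotation = io_prep.read_annotation_tsv(config.annotation)
    return expr, meth, annotation


def _factorize_platform(omics, sigma, p, p_range, config, stage):
    seed = stage_seed(config.seed, stage)
    if config.select_dimensions or p is None:
        sweep = fz.sweep_dimensions(
            omics, sigma, range(p_range[0], p_range[1] + 1),
            n_restarts=max(config.n_restarts, 2), seed=seed,
            sparsity=config.sparsity, max_iter=config.max_iter, tol=config.tol,
        )
        p, _ = fz.select_dimensionality(sweep, config.similarity_threshold)
        log.info("%s: selected %d patterns", stage, p)
    if config.n_sets > 1 and stage == "factorize_methylation":
        return fz.parallel_sets_consensus(
            omics, sigma, p, n_sets=config.n_sets, seed=seed,
            n_restarts=config.n_restarts, sparsity=config.sparsity,
            max_iter=config.max_iter, tol=config.tol,
        )
    return fz.fit(
        omics, sigma, p, n_restarts=config.n_restarts, seed=seed,
        sparsity=config.sparsity, max_iter=config.max_iter, tol=config.tol,
    )


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages, writing tables under ``outdir``; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict = {"config": asdict(config), "stages": {}, "outputs": {}}
    try:
        result = _run_stages(config, outdir, manifest)
    finally:
        log.removeHandler(handler)
        handler.close()
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return result


def _run_stages(config, outdir, manifest):
    def stage(name):
        manifest["stages"][name] = "started"
        log.info("stage %s", name)

    def done(name, **outputs):
        manifest["stages"][name] = "done"
        for key, path in outputs.items():
            manifest["outputs"][key] = str(path)

    try:
        stage("load")
        expression, methylation, annotation = _load_inputs(config, outdir)
        done("load")

        stage("prep")
        meth_gene = io_prep.select_promoter_probes(methylation, annotation)
        expr_set = io_prep.filter_expression_genes(expression)
        meth_set = io_prep.filter_methylation_genes(meth_gene)
        expr_keep, meth_keep = io_prep.union_filter(
            expr_set, meth_set, expression.feature_ids, meth_gene.feature_ids
        )
        expr_a = expression.subset_features(sorted(expr_keep))
        meth_a = meth_gene.subset_features(sorted(meth_keep))
        sigma_e = io_prep.uncertainty_for(expr_a)
        sigma_m = io_prep.uncertainty_for(meth_a, coverage=config.coverage)
        io_prep.write_matrix_tsv(expr_a.values, outdir / "expression_analysis.tsv")
        io_prep.write_matrix_tsv(meth_a.values, outdir / "methylation_analysis.tsv")
        manifest["prep_counts"] = {
            "expression_filter": len(expr_set),
            "methylation_filter": len(meth_set),
            "expression_analysis": expr_a.n_features,
            "methylation_analysis": meth_a.n_features,
        }
        done("prep", expression_analysis=outdir / "expression_analysis.tsv",
             methylation_analysis=outdir / "methylation_analysis.tsv")

        stage("factorize")
        F_e = _factorize_platform(expr_a, sigma_e, config.p_expr,
                                  config.p_range_expr, config, "factorize_expression")
        F_m = _factorize_platform(meth_a, sigma_m, config.p_meth,
                                  config.p_range_meth, config, "factorize_methylation")
        for tag, F in (("expression", F_e), ("methylation", F_m)):
            io_prep.write_matrix_tsv(F.A, outdir / f"A_{tag}.tsv")
            io_prep.write_matrix_tsv(F.P, outdir / f"P_{tag}.tsv")
        manifest["factorization"] = {
            "expression": {"p": F_e.p, "chi2": F_e.chi2},
            "methylation": {"p": F_m.p, "chi2": F_m.chi2},
        }
        done("factorize")

        stage("markers")
        labels_e = pattern_analysis.classify_patterns(
            F_e, expr_a.samples, c=config.c_separation, cv_min=config.cv_min)
        labels_m = pattern_analysis.classify_patterns(
            F_m, meth_a.samples, c=config.c_separation, cv_min=config.cv_min)
        exclude_e = [l.pattern for l in labels_e if l.label == "flat"]
        markers_e = pattern_analysis.pattern_markers(F_e.A, exclude=exclude_e)
        exclude_m = [l.pattern for l in labels_m if l.label == "flat"]
        markers_m = pattern_analysis.pattern_markers(F_m.A, exclude=exclude_m)
        markers_e.to_csv(outdir / "markers_expression.tsv", sep="\t")
        markers_m.to_csv(outdir / "markers_methylation.tsv", sep="\t")
        pattern_analysis.labels_table(labels_e).to_csv(outdir / "labels_expression.tsv", sep="\t")
        pattern_analysis.labels_table(labels_m).to_csv(outdir / "labels_methylation.tsv", sep="\t")
        done("markers")

        if config.gene_sets:
            stage("genesets")
            collection = io_prep.read_gmt(config.gene_sets)
            gs = geneset_stat.geneset_activity_table(
                F_e.A, collection, n_perm=config.n_perm,
                seed=stage_seed(config.seed, "genesets"),
            )
            gs.to_csv(outdir / "geneset_activity.tsv", sep="\t", index=False)
            done("genesets")

        stage("integrate")
        corr = integration.pattern_correlation(F_e.P, F_m.P)
        corr.to_csv(outdir / "pattern_correlation.tsv", sep="\t")
        delays = integration.timing_delay(labels_e, labels_m)
        delays.to_csv(outdir / "timing_delays.tsv", sep="\t", index=False)
        resistance_patterns = [
            l.pattern for l in labels_m if l.label in ("resistance", "repression")
        ]
        drivers = pd.DataFrame()
        if resistance_patterns:
            drivers = integration.call_epigenetic_drivers(
                expr_a, meth_a, markers_m, resistance_patterns, alpha=config.alpha
            )
            drivers.to_csv(outdir / "drivers.tsv", sep="\t")
        done("integrate")

        stage("report")
        report = {
            "n_expression_patterns": F_e.p,
            "n_methylation_patterns": F_m.p,
            "expression_labels": {l.pattern: l.label for l in labels_e},
            "methylation_labels": {l.pattern: l.label for l in labels_m},
            "median_delay": float(delays["delay_min"].median()) if len(delays) else None,
            "n_drivers_called": int(drivers["called"].sum()) if len(drivers) else 0,
        }
        (outdir / "report.json").write_text(json.dumps(report, indent=1))
        done("report", report=outdir / "report.json")
        return {
            "expression": F_e, "methylation": F_m,
            "labels_expression": labels_e, "labels_methylation": labels_m,
            "markers_expression": markers_e, "markers_methylation": markers_m,
            "delays": delays, "drivers": drivers, "report": report,
            "manifest": manifest,
        }
    except Exception:
        failing = [k for k, v in manifest["stages"].items() if v == "started"]
        log.exception("stage failed: %s", failing)
        manifest["failed_stage"] = failing[-1] if failing else None
        raise


def demo(seed: int = 0, outdir="demo_run") -> dict:
    """Small bundled run (400 genes) exercising every stage in well under a
    minute; the documented quickstart."""
    config = PipelineConfig(
        synthetic={"n_genes": 400, "n_drivers": 10},
        n_restarts=2,
        max_iter=600,
        seed=seed,
    )
    return run_pipeline(config, outdir)
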