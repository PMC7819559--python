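"""End-to-end orchestration: simulate -> unite -> annotate -> DMS -> DMR ->
enrichment -> expression link, with a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import obonet
import pandas as pd

from . import __version__
from .annotation import annotate_sites, build_catalog
from .config import RunConfig, _to_dict
from .coverage import MethylationMatrix, merge_strands, relaxed_background, unite
from .diffmeth import DifferentialMethylation, DifferentialMethylationResults, PermutationResult
from .dmr import call_dmrs, dms_in_dmr_mask
from .enrichment import (EnrichmentResult, expressed_gene_flag, expression_enrichment,
                         feature_enrichment, go_enrichment, propagate_annotations)
from .expression import MethylationExpressionModel, SlopeReport, build_observations, transform_counts
from .simulate import SimulatedDataset, simulate_dataset, write_dataset

log = logging.getLogger("urbmeth")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    config: RunConfig
    dataset: SimulatedDataset
    matrix: MethylationMatrix
    background_sites: pd.DataFrame
    dms_results: DifferentialMethylationResults
    dmrs: pd.DataFrame
    feature_enrichments: dict[str, EnrichmentResult]
    expression_enrichments: dict[str, EnrichmentResult]
    go_results: pd.DataFrame
    slope_report: SlopeReport | None
    permutation: PermutationResult | None
    manifest: dict


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def run_all(config: RunConfig, dataset: SimulatedDataset | None = None,
            run_permutation: bool = True, write: bool = True) -> PipelineResult:
    """Execute the full analysis; deterministic given (config, seed)."""
    config.validate()
    out = Path(config.outdir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": _to_dict(config),
        "config_hash": hashlib.sha256(
            json.dumps(_to_dict(config), sort_keys=True).encode()).hexdigest()[:16],
        "stages": {},
    }

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("simulate")
        if dataset is None:
            cfg = dataclasses.replace(config.simulation, rng_seed=config.seed)
            dataset = simulate_dataset(cfg)
            if write:
                write_dataset(dataset, out / "input")
        manifest["stages"]["simulate"] = {
            "n_samples": len(dataset.samples),
            "n_genes": len(dataset.genes),
            "n_true_dms": len(dataset.truth.true_dms),
        }
    except Exception as exc:
        raise PipelineError("simulate", exc) from exc

    try:
        stage("unite")
        merged = {sid: merge_strands(df, dataset.genome)
                  for sid, df in dataset.strand_counts.items()}
        matrix = unite(merged, dataset.samples, config.min_coverage, config.max_quantile)
        background_sites = relaxed_background(merged, config.relaxed_min_coverage,
                                              config.relaxed_min_samples)
        if write:
            matrix.to_tsv(out / "matrix.tsv")
        manifest["stages"]["unite"] = {"n_sites": matrix.n_sites,
                                       "n_background_sites": len(background_sites)}
    except Exception as exc:
        raise PipelineError("unite", exc) from exc

    try:
        stage("annotate")
        catalog = build_catalog(
            dataset.genome, dataset.genes, promoter_bp=config.promoter_bp,
            tss_upstream=config.tss_upstream, tss_downstream=config.tss_downstream,
            shore_bp=config.shore_bp, window=config.cgi_window,
            n_windows_avg=config.cgi_n_windows_avg, min_len=config.cgi_min_len,
            gc_min=config.cgi_gc_min, obs_exp_min=config.cgi_obs_exp_min)
        matrix_ann = annotate_sites(matrix.sites, catalog)
        background_ann = annotate_sites(background_sites, catalog)
        manifest["stages"]["annotate"] = {
            "n_cgi": int((catalog.intervals.feature == "cgi").sum()),
            "n_intervals": len(catalog.intervals)}
    except Exception as exc:
        raise PipelineError("annotate", exc) from exc

    try:
        stage("dms")
        model = DifferentialMethylation(matrix)
        dms_results = model.fit(config.diff_threshold, config.q_threshold)
        permutation = None
        if run_permutation:
            permutation = model.permutation_test(
                n_iter=config.perm_n_iter, seed=config.seed,
                diff_threshold=config.diff_threshold, q_threshold=config.q_threshold)
        if write:
            dms_results.dms.to_csv(out / "dms.tsv", sep="\t", index=False)
            if permutation is not None:
                (out / "permutation.json").write_text(json.dumps({
                    "statistic": permutation.statistic,
                    "observed": permutation.observed_statistic,
                    "p_value": permutation.p_value,
                    "n_iter": permutation.n_iter, "seed": permutation.seed}, indent=2))
        manifest["stages"]["dms"] = {"n_dms": dms_results.n_dms,
                                     "pi0": dms_results.pi0,
                                     "dms_hash": _hash_df(dms_results.dms)}
    except Exception as exc:
        raise PipelineError("dms", exc) from exc

    try:
        stage("dmr")
        dmrs = call_dmrs(dms_results.dms, config.dmr_window, config.dmr_min_sites)
        if write:
            bed = dmrs.assign(dmr_id=[f"dmr{i+1}" for i in range(len(dmrs))])
            bed[["chrom", "start", "end", "dmr_id", "n_sites", "direction_class"]].to_csv(
                out / "dmrs.bed", sep="\t", header=False, index=False)
        manifest["stages"]["dmr"] = {"n_dmrs": len(dmrs),
                                     "dmr_hash": _hash_df(dmrs.drop(columns="member_pos"))}
    except Exception as exc:
        raise PipelineError("dmr", exc) from exc

    try:
        stage("enrichment")
        dms_ann = annotate_sites(dms_results.dms[["chrom", "pos"]], catalog)
        feature_enr = {}
        for cls in ["regulatory", "promoter", "tss", "gene_body", "cgi",
                    "cgi_shore", "nonregulatory"]:
            try:
                feature_enr[cls] = feature_enrichment(dms_ann, background_ann, cls)
            except ValueError:
                continue
        expressed = expressed_gene_flag(dataset.expression, config.expressed_min_count,
                                        config.expressed_min_fraction)
        expr_enr = {}
        if dms_results.n_dms:
            expr_enr["all_dms"] = expression_enrichment(dms_ann, background_ann, expressed)
            in_dmr = dms_in_dmr_mask(dms_results.dms, dmrs)
            if in_dmr.any():
                expr_enr["dmr_restricted"] = expression_enrichment(
                    dms_ann, background_ann, expressed, dmr_restricted=True,
                    dms_in_dmr=in_dmr, window=config.dmr_window)

        ontology = obonet.read_obo(__import__("io").StringIO(dataset.ontology_obo))
        in_dmr = dms_in_dmr_mask(dms_results.dms, dmrs) if dms_results.n_dms else np.array([], bool)
        gene_linked = dms_ann.promoter | dms_ann.tss | dms_ann.gene_body
        focal_genes = sorted({g for genes, ok, linked
                              in zip(dms_ann.genes, in_dmr, gene_linked)
                              if ok and linked for g in genes})
        ann_map = propagate_annotations(dataset.gene_terms, ontology)
        background_genes = sorted(g for g in dataset.genes.gene_id if g in ann_map)
        go_results = go_enrichment(focal_genes, background_genes, dataset.gene_terms,
                                   ontology, config.go_fdr) if focal_genes else \
            pd.DataFrame(columns=["term", "name", "k", "K", "n", "N",
                                  "p_value", "fdr", "significant"])
        if write:
            rows = [dataclasses.asdict(r) for r in
                    list(feature_enr.values()) + list(expr_enr.values())]
            pd.DataFrame(rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
            go_results.to_csv(out / "go_enrichment.tsv", sep="\t", index=False)
        manifest["stages"]["enrichment"] = {
            "n_feature_tests": len(feature_enr),
            "n_go_terms_tested": len(go_results),
            "n_go_significant": int(go_results.significant.sum()) if len(go_results) else 0}
    except Exception as exc:
        raise PipelineError("enrichment", exc) from exc

    try:
        stage("expression_link")
        slope_report = None
        if dms_results.n_dms:
            expr = transform_counts(dataset.expression)
            obs = build_observations(dms_results.dms, dms_ann, matrix, expr)
            if not obs.empty:
                slope_report = MethylationExpressionModel(obs).fit()
                if write:
                    slope_report.slopes.to_csv(out / "slopes.tsv", sep="\t", index=False)
                    obs.to_csv(out / "observations.tsv", sep="\t", index=False)
        manifest["stages"]["expression_link"] = {
            "n_obs": 0 if slope_report is None else slope_report.n_obs}
    except Exception as exc:
        raise PipelineError("expression_link", exc) from exc

    if write:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return PipelineResult(config=config, dataset=dataset, matrix=matrix,
                          background_sites=background_sites, dms_results=dms_results,
                          dmrs=dmrs, feature_enrichments=feature_enr,
                          expression_enrichments=expr_enr, go_results=go_results,
                          slope_report=slope_report, permutation=permutation,
                          manifest=manifest)
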