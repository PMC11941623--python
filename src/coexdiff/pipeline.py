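"""End-to-end orchestration of the two-cohort network comparison.

Stages, in order: cohort assignment, low-expression filtering, TMM
normalization, NB exact-test differential expression with BH control,
gene-set enrichment on fold changes, per-cohort mutual-information network
at the configured percentile, per-cohort map-equation modules, per-cohort
hypergeometric module enrichment with a bipartite module-term network, and
cross-cohort degree-distribution comparison.  Every artifact is written in a
plain-text format and the run is fully deterministic given the master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as cio
from .coexnet import infer_network
from .gage import gage, gene_fold_changes
from .mapeq import optimize_partition
from .modfunc import build_bipartite, enrich_modules
from .netdesc import compare_degree_distributions, degree_distribution, summarize_network
from .normdge import (
    CountMatrix,
    compute_tmm_factors,
    cpm,
    estimate_common_dispersion,
    exact_test,
    filter_low_expression,
)
from .synthdata import SimParams, simulate_annotation, simulate_counts, simulate_design, simulate_truth

__all__ = ["PipelineConfig", "run_pipeline"]

__version__ = "0.1.0"

log = logging.getLogger("coexdiff.pipeline")


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of ``sim_params`` (synthetic mode) or the trio
    ``counts_path``/``design_path``/``annotation_path`` (real-data mode) must
    be provided.
    """

    output_dir: str | Path = "coexdiff_run"
    sim_params: SimParams | None = None
    counts_path: str | Path | None = None
    design_path: str | Path | None = None
    annotation_path: str | Path | None = None
    age_cutoff: float = 70.0
    min_cpm: float = 1.0
    mi_percentile: float = 99.0
    mi_expression: str = "log_cpm"  # "log_cpm" | "cpm" | "counts"
    n_trials: int = 1000
    q_threshold: float = 0.05
    min_module_size: int = 10
    seed: int = 0

    def validate(self) -> None:
        real = [self.counts_path, self.design_path, self.annotation_path]
        if self.sim_params is not None and any(p is not None for p in real):
            raise ValueError("provide either sim_params or real input paths, not both")
        if self.sim_params is None and not all(p is not None for p in real):
            raise ValueError("real-data mode needs counts, design and annotation paths")
        if not 0.0 < self.mi_percentile < 100.0:
            raise ValueError("mi_percentile must lie in (0, 100)")
        if not 0.0 < self.q_threshold < 1.0:
            raise ValueError("q_threshold must lie in (0, 1)")
        if self.mi_expression not in ("log_cpm", "cpm", "counts"):
            raise ValueError("mi_expression must be 'log_cpm', 'cpm' or 'counts'")


def _setup_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    return handler


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the run report (also written as JSON)."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir)
    try:
        return _run(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> dict:
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    report: dict = {"config": _echo_config(config), "version": __version__, "cohorts": {}}

    # --- inputs -----------------------------------------------------------
    if config.sim_params is not None:
        params = config.sim_params
        log.info("simulate: %d genes, %d+%d samples, seed %d",
                 params.n_genes, params.n_early, params.n_late, params.seed)
        truth = simulate_truth(params)
        design = simulate_design(params)
        counts = CountMatrix(simulate_counts(truth, design, params), design)
        annotation = simulate_annotation(truth)
        cio.write_counts(counts, outdir / "counts.tsv")
        cio.write_counts(counts, outdir / "counts.mtx")
        cio.write_design(design, outdir / "design.tsv")
        cio.write_gmt(annotation, outdir / "annotation.gmt")
        cio.write_json(
            {
                "module_of": truth.module_of,
                "de_genes": truth.de_genes,
                "perturbed_sets": truth.perturbed_sets,
                "library_sizes": truth.library_sizes,
            },
            outdir / "truth.json",
        )
    else:
        design = cio.read_design(config.design_path, cutoff=config.age_cutoff)
        counts = cio.read_counts(config.counts_path, design)
        annotation = cio.read_gmt(config.annotation_path)

    n_early = len(design.samples_in("early"))
    n_late = len(design.samples_in("late"))
    if n_early == 0 or n_late == 0:
        raise ValueError("both cohorts must be nonempty")
    log.info("cohorts: %d early / %d late (cutoff %.0f years)", n_early, n_late, design.cutoff)

    # --- filtering + normalization + DE ----------------------------------
    filtered = filter_low_expression(counts, min_cpm=config.min_cpm)
    log.info("filter: %d of %d genes kept (CPM >= %.2g)",
             len(filtered.genes), len(counts.genes), config.min_cpm)
    factors = compute_tmm_factors(filtered)
    log.info("TMM: reference sample %s", factors.reference_sample)
    dispersion = estimate_common_dispersion(filtered, factors)
    log.info("common dispersion: %.4f", dispersion)
    dge = exact_test(filtered, factors, dispersion)
    dge.to_csv(outdir / "dge.tsv", sep="\t", index_label="gene")
    n_sig = int((dge["FDR"] < config.q_threshold).sum())
    log.info("DE: %d genes at FDR < %.2g", n_sig, config.q_threshold)

    # --- gene-set enrichment on fold changes ------------------------------
    log_expr = cpm(filtered, factors, log=True)
    fc = gene_fold_changes(log_expr, design)
    gage_table = gage(fc, annotation)
    gage_table.to_csv(outdir / "gage.tsv", sep="\t", index_label="term")
    report["n_genes_input"] = len(counts.genes)
    report["n_genes_filtered"] = len(filtered.genes)
    report["n_de_genes"] = n_sig
    report["dispersion"] = dispersion
    if not gage_table.empty:
        report["gage_sets_q_up_sig"] = sorted(
            gage_table.index[gage_table["q_up"] < config.q_threshold]
        )

    # --- per-cohort networks, modules, enrichment -------------------------
    if config.mi_expression == "log_cpm":
        mi_input = log_expr
    elif config.mi_expression == "cpm":
        mi_input = cpm(filtered, factors, log=False)
    else:
        mi_input = filtered.counts.astype(float)
    histograms = {}
    for cohort, trial_seed in zip(("early", "late"), seeds[:2]):
        cols = [s for s, g in zip(design.sample_id, design.group) if g == cohort]
        expr = mi_input[cols]
        network = infer_network(expr, percentile=config.mi_percentile)
        log.info("%s network: %d nodes, %d edges, MI threshold %.4f bits",
                 cohort, len(network.nodes), network.n_edges, network.threshold_value)
        cio.write_edgelist(network, outdir / f"network_{cohort}.tsv")
        cio.write_graphml(network, outdir / f"network_{cohort}.graphml")

        partition = optimize_partition(
            network, n_trials=config.n_trials, seed=int(trial_seed.generate_state(1)[0] % 2**31)
        )
        log.info("%s modules: %d (description length %.3f bits)",
                 cohort, partition.n_modules, partition.description_length)
        cio.write_partition(partition, outdir / f"partition_{cohort}.tsv")

        universe = set(partition.module_of)
        enrichment = enrich_modules(
            partition, annotation, universe,
            min_module_size=config.min_module_size, q_threshold=config.q_threshold,
        )
        enrichment.to_csv(outdir / f"enrichment_{cohort}.tsv", sep="\t", index=False)
        bipartite = build_bipartite(enrichment, q_threshold=config.q_threshold)
        cio.write_graphml(bipartite, outdir / f"bipartite_{cohort}.graphml")

        graph = network.graph()
        graph.remove_nodes_from([v for v in graph if graph.degree(v) == 0])
        histograms[cohort] = degree_distribution(graph)
        summary = summarize_network(graph, partition)
        sig_rows = enrichment[enrichment["significant"]] if not enrichment.empty else enrichment
        summary.update(
            {
                "threshold_value": network.threshold_value,
                "mi_percentile": network.percentile,
                "n_enriched_modules": int(sig_rows["module_id"].nunique()) if len(sig_rows) else 0,
                "n_distinct_terms": int(sig_rows["term_id"].nunique()) if len(sig_rows) else 0,
            }
        )
        cio.write_json(summary, outdir / f"summary_{cohort}.json")
        report["cohorts"][cohort] = summary
        log.info("%s enrichment: %d modules enriched, %d distinct terms",
                 cohort, summary["n_enriched_modules"], summary["n_distinct_terms"])

    # --- cross-cohort comparison ------------------------------------------
    comparison = compare_degree_distributions(histograms["early"], histograms["late"])
    with open(outdir / "comparison.tsv", "w") as fh:
        fh.write("chi2\tdf\tp\tcramers_v\tn_total\n")
        fh.write(
            f"{comparison.chi2:.6g}\t{comparison.df}\t{comparison.p:.6g}\t"
            f"{comparison.cramers_v:.6g}\t{comparison.n_total}\n"
        )
    report["comparison"] = {
        "chi2": comparison.chi2,
        "df": comparison.df,
        "p": comparison.p,
        "cramers_v": comparison.cramers_v,
        "n_total": comparison.n_total,
    }
    log.info("degree comparison: chi2=%.3f df=%d p=%.3g V=%.3f",
             comparison.chi2, comparison.df, comparison.p, comparison.cramers_v)

    cio.write_json(report, outdir / "report.json")
    return report


def _echo_config(config: PipelineConfig) -> dict:
    echo = {
        "age_cutoff": config.age_cutoff,
        "min_cpm": config.min_cpm,
        "mi_percentile": config.mi_percentile,
        "mi_expression": config.mi_expression,
        "n_trials": config.n_trials,
        "q_threshold": config.q_threshold,
        "min_module_size": config.min_module_size,
        "seed": config.seed,
        "output_dir": str(config.output_dir),
    }
    if config.sim_params is not None:
        echo["sim_params"] = {k: v for k, v in vars(config.sim_params).items()}
    else:
        echo["inputs"] = {
            "counts": str(config.counts_path),
            "design": str(config.design_path),
            "annotation": str(config.annotation_path),
        }
    return echo
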