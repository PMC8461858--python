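"""End-to-end orchestration: load → score → DEGs → merge → rank → evaluate.

:class:`RunConfig` gathers every tunable of a run; :func:`run_pipeline`
executes the stages in order and writes ``ranking.tsv``, ``evaluation.tsv``
(when a benchmark is supplied), ``rare_drivers.tsv`` and a ``run.log``
echoing all parameter values and dropped-gene counts, so each of the
method's configurable readings is auditable after the fact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

from . import evaluation as ev
from . import io as mio
from .degs import call_degs, write_deg_set
from .errors import ComputationError, InputError, MencError
from .io import GeneSet
from .mutation import compute_mutation_scores, write_score_table
from .network import build_merged_graph, rank_drivers, write_ranking

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths and tunables for one pipeline run."""

    mutation_path: str
    ppi_path: str
    tumor_path: str | None = None
    normal_path: str | None = None
    benchmark_path: str | None = None
    outdir: str = "menc_out"
    mutation_format: str = "matrix"
    uppercase: bool = False
    deg_threshold: float = 1.0
    pseudocount: float = 1.0
    mif_mode: str = "gravity"
    c_variant: str = "literal"
    neighbor_count: str = "degree"
    recall_denominator: str = "in_dataset"
    top_k: int | None = None
    rare_threshold_pct: float = 2.0
    rare_top_n: int = 20


@dataclass
class PipelineResult:
    ranking: "object"
    curve: "object | None"
    rare: list
    outputs: dict[str, Path]


def _stage(name: str):
    """Decorate nothing — tag exceptions with the failing stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, MencError) and not getattr(exc, "stage", None):
                exc.stage = name
            return False
    return _Ctx()


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run every stage and write the output files.

    Raises :class:`InputError` or :class:`ComputationError` (annotated with a
    ``stage`` attribute naming the failing stage) on any problem.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("menc")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(logging.INFO)
    try:
        for f in fields(cfg):
            logger.info("config %s=%r", f.name, getattr(cfg, f.name))

        with _stage("load_mutation_matrix"):
            m = mio.load_mutation_matrix(cfg.mutation_path, format=cfg.mutation_format,
                                         uppercase=cfg.uppercase)
        with _stage("load_ppi"):
            ppi = mio.load_ppi(cfg.ppi_path, uppercase=cfg.uppercase)
        benchmark = None
        if cfg.benchmark_path:
            with _stage("load_gene_set"):
                benchmark = mio.load_gene_set(cfg.benchmark_path, name="benchmark",
                                              uppercase=cfg.uppercase)
        with _stage("compute_mutation_scores"):
            scores = compute_mutation_scores(m)
            write_score_table(scores, outdir / "mutation_scores.tsv")
        with _stage("call_degs"):
            if cfg.tumor_path is None or cfg.normal_path is None:
                raise InputError("paired tumor and normal expression paths are required")
            expr = mio.load_expression_pair(cfg.tumor_path, cfg.normal_path,
                                            uppercase=cfg.uppercase)
            degs = call_degs(expr, threshold=cfg.deg_threshold,
                             pseudocount=cfg.pseudocount)
            write_deg_set(degs, outdir / "degs.tsv")
            logger.info("cohort DEGs: %d genes", len(degs))
        with _stage("build_merged_graph"):
            mutated = GeneSet("mutated", m.mutated_genes())
            logger.info("mutated genes: %d", len(mutated))
            merged = build_merged_graph(ppi, mutated, degs)
            logger.info("merged graph: %d nodes, %d edges",
                        merged.graph.number_of_nodes(), merged.graph.number_of_edges())
        with _stage("rank_drivers"):
            ranking = rank_drivers(merged, scores, m, mif_mode=cfg.mif_mode,
                                   c_variant=cfg.c_variant,
                                   neighbor_count=cfg.neighbor_count)
            write_ranking(ranking, merged, scores, outdir / "ranking.tsv",
                          top=cfg.top_k)
        outputs = {"ranking": outdir / "ranking.tsv", "run_log": log_path,
                   "mutation_scores": outdir / "mutation_scores.tsv",
                   "degs": outdir / "degs.tsv"}
        curve = None
        rare: list = []
        if benchmark is not None:
            with _stage("evaluate_ranking"):
                max_k = min(cfg.top_k or len(ranking), len(ranking))
                curve = ev.evaluate_ranking(ranking, benchmark, mutated,
                                            max_k=max_k,
                                            recall_denominator=cfg.recall_denominator)
                ev.write_evaluation(curve, outdir / "evaluation.tsv")
                outputs["evaluation"] = outdir / "evaluation.tsv"
            with _stage("flag_rare_drivers"):
                top_n = min(cfg.rare_top_n, len(ranking))
                rare = ev.flag_rare_drivers(ranking, m, benchmark, top_n=top_n,
                                            threshold_pct=cfg.rare_threshold_pct)
                ev.write_rare_drivers(rare, outdir / "rare_drivers.tsv")
                outputs["rare_drivers"] = outdir / "rare_drivers.tsv"
        return PipelineResult(ranking=ranking, curve=curve, rare=rare,
                              outputs=outputs)
    finally:
        root.removeHandler(handler)
        handler.close()
        root.setLevel(old_level)
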