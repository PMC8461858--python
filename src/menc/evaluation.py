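"""Benchmarking a driver ranking against a known-driver catalog.

For each top-k cutoff, precision = hits/k and recall = hits/D with
hits = |top-k ∩ benchmark|. The recall denominator D is configurable: the
default ``"in_dataset"`` restricts the benchmark to genes actually mutated in
the cohort (recall against genes a cohort-restricted ranker can never return
is uninformative); ``"full_set"`` uses the whole catalog, the literal reading.
F1 is the harmonic mean, with 0/0 defined as 0.

Rare drivers are top-ranked genes mutated in fewer than 2% of patients.
Catalog membership is reported as an annotation on each record rather than
used as a filter, since curated catalogs routinely do contain low-frequency
drivers.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ComputationError
from .io import GeneSet, MutationMatrix
from .network import DriverRanking

__all__ = [
    "EvaluationCurve",
    "RareDriverRecord",
    "evaluate_ranking",
    "mutation_frequency",
    "flag_rare_drivers",
]


@dataclass
class EvaluationCurve:
    """Precision/recall/F1 at every cutoff k = 1..max_k."""

    k: list[int]
    precision: list[float]
    recall: list[float]
    f1: list[float]
    benchmark_size: int

    def at(self, k: int) -> tuple[float, float, float]:
        i = self.k.index(k)
        return self.precision[i], self.recall[i], self.f1[i]


@dataclass(frozen=True)
class RareDriverRecord:
    gene: str
    rank: int
    mut_count: int
    frequency_pct: float
    in_cgc: bool


def evaluate_ranking(r: DriverRanking, benchmark: GeneSet, mutated: GeneSet,
                     max_k: int | None = None,
                     recall_denominator: str = "in_dataset") -> EvaluationCurve:
    """Compute the precision/recall/F1 curve of a ranking against a benchmark."""
    if recall_denominator not in ("in_dataset", "full_set"):
        raise ValueError(f"unknown recall_denominator {recall_denominator!r}")
    if max_k is None:
        max_k = len(r)
    if max_k > len(r):
        raise ValueError(f"max_k={max_k} exceeds ranking length {len(r)}")
    if recall_denominator == "in_dataset":
        denom = len(benchmark.members & mutated.members)
    else:
        denom = len(benchmark.members)
    if denom == 0:
        raise ComputationError("empty recall denominator: benchmark does not "
                               "intersect the dataset")
    ks, precisions, recalls, f1s = [], [], [], []
    hits = 0
    for k, gene in enumerate(r.top(max_k), start=1):
        if gene in benchmark:
            hits += 1
        p = hits / k
        rec = hits / denom
        f1 = 0.0 if p + rec == 0 else 2 * p * rec / (p + rec)
        ks.append(k)
        precisions.append(p)
        recalls.append(rec)
        f1s.append(f1)
    return EvaluationCurve(k=ks, precision=precisions, recall=recalls, f1=f1s,
                           benchmark_size=denom)


def mutation_frequency(m: MutationMatrix, gene: str) -> tuple[int, float]:
    """(count, percent) of patients carrying a mutation in ``gene``.

    Percent is 100 * count / n_patients; exports round it to 6 decimals.
    """
    count = int(m.row(gene).sum())
    return count, 100.0 * count / m.n_patients


def flag_rare_drivers(r: DriverRanking, m: MutationMatrix, benchmark: GeneSet,
                      top_n: int, threshold_pct: float = 2.0) -> list[RareDriverRecord]:
    """Top-n genes mutated in strictly less than ``threshold_pct`` % of patients.

    Records are ordered by rank and annotated with benchmark membership.
    """
    if top_n > len(r):
        raise ValueError(f"top_n={top_n} exceeds ranking length {len(r)}")
    records = []
    for e in r.entries[:top_n]:
        if e.gene not in m:
            continue
        count, pct = mutation_frequency(m, e.gene)
        if pct < threshold_pct:
            records.append(RareDriverRecord(
                gene=e.gene, rank=e.rank, mut_count=count,
                frequency_pct=pct, in_cgc=e.gene in benchmark))
    return records


def write_evaluation(curve: EvaluationCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("k\tprecision\trecall\tf1\n")
        for k, p, r, f in zip(curve.k, curve.precision, curve.recall, curve.f1):
            fh.write(f"{k}\t{p:.6f}\t{r:.6f}\t{f:.6f}\n")


def write_rare_drivers(records: list[RareDriverRecord], path) -> None:
    """TSV with the catalog-style columns: Rank, Gene, Mut, frequency, CGC flag."""
    with open(path, "w") as fh:
        fh.write("Rank\tGene\tMut\tMutation frequency (%)\tCGC gene\n")
        for rec in records:
            fh.write(f"{rec.rank}\t{rec.gene}\t{rec.mut_count}\t"
                     f"{rec.frequency_pct:.6f}\t{'YES' if rec.in_cgc else 'NO'}\n")
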