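"""Per-gene mutation scores and the pairwise mutation-impact function (MIF).

The mutation score of gene *i* is

    M(i) = sum over patients k carrying a mutation in i of 1 / N_k

where N_k is the number of mutated genes in patient k — a mutation in a quiet
genome counts for more than one in a hypermutated sample. Genes never mutated
receive the background mutation score BMS = 1/N_max (N_max the largest
per-patient burden), which is no greater than the score of any mutated gene.

The MIF couples two genes' scores through the dissimilarity of their patient
incidence profiles, in the manner of a gravitational attraction:

    MIF(i, j) = M(i) * M(j) / d(i, j)^2

with d the Euclidean distance between the binary rows (so d^2 is the Hamming
distance). Identical profiles (d = 0) are floored at d = 1, the smallest
distance two distinct binary rows can achieve, keeping the MIF finite and
maximal. ``mode="literal"`` instead takes the text-book reciprocal reading
r = 1/d and computes M(i)*M(j)*d^2, which inverts the similarity relationship;
it exists for auditability, not for use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ComputationError
from .io import MutationMatrix

__all__ = [
    "MutationScoreTable",
    "compute_mutation_scores",
    "gene_distance",
    "compute_mif",
    "PairwiseMIF",
]


@dataclass
class MutationScoreTable:
    """Gene -> M(i), plus the background score for genes never mutated.

    ``background`` records which genes received the background score because
    they carry no mutation (a mutated gene can legitimately tie with the BMS
    value, so the flag cannot be recovered from the score alone).
    """

    scores: dict[str, float]
    bms: float
    background: frozenset[str] = frozenset()

    def get(self, gene: str) -> float:
        """M(i); unknown genes fall back to the background score."""
        return self.scores.get(gene, self.bms)

    def __getitem__(self, gene: str) -> float:
        return self.get(gene)


def compute_mutation_scores(m: MutationMatrix) -> MutationScoreTable:
    """Apply the 1/N_k scoring to every gene of a binary mutation matrix.

    Patients with zero mutated genes contribute to no score. Raises
    :class:`ComputationError` on an all-zero matrix, where the background
    score 1/N_max is undefined.
    """
    burdens = m.patient_burdens().astype(float)
    n_max = burdens.max() if burdens.size else 0
    if n_max == 0:
        raise ComputationError("all-zero mutation matrix: background score undefined")
    bms = 1.0 / n_max
    with np.errstate(divide="ignore"):
        inv = np.where(burdens > 0, 1.0 / np.where(burdens > 0, burdens, 1), 0.0)
    raw = m.values @ inv
    scores = {g: (float(s) if s > 0 else bms) for g, s in zip(m.genes, raw)}
    background = frozenset(g for g, s in zip(m.genes, raw) if s == 0)
    return MutationScoreTable(scores=scores, bms=bms, background=background)


def gene_distance(row_i: np.ndarray, row_j: np.ndarray) -> float:
    """Euclidean distance between two incidence rows.

    For binary rows this is sqrt(Hamming distance).
    """
    row_i = np.asarray(row_i)
    row_j = np.asarray(row_j)
    if row_i.shape != row_j.shape:
        raise ValueError(f"length mismatch: {row_i.shape} vs {row_j.shape}")
    diff = row_i.astype(float) - row_j.astype(float)
    return float(np.sqrt(np.dot(diff, diff)))


def compute_mif(scores: MutationScoreTable, m: MutationMatrix, i: str, j: str,
                mode: str = "gravity") -> float:
    """Mutation-impact function between two distinct genes of the matrix."""
    if i == j:
        raise ValueError(f"MIF is defined for distinct genes, got {i!r} twice")
    d = gene_distance(m.row(i), m.row(j))
    mi, mj = scores.get(i), scores.get(j)
    if mode == "gravity":
        d = max(d, 1.0)
        return mi * mj / (d * d)
    if mode == "literal":
        return mi * mj * d * d if d > 0 else mi * mj
    raise ValueError(f"unknown mif mode {mode!r}; expected 'gravity' or 'literal'")


class PairwiseMIF:
    """Memoizing MIF evaluator used by the network scorer.

    MIF values are computed lazily per requested pair rather than as a dense
    all-pairs table, keeping the cost proportional to the edges actually
    visited during semi-local scoring.
    """

    def __init__(self, scores: MutationScoreTable, m: MutationMatrix,
                 mode: str = "gravity"):
        if mode not in ("gravity", "literal"):
            raise ValueError(f"unknown mif mode {mode!r}")
        self.scores = scores
        self.matrix = m
        self.mode = mode
        self._cache: dict[frozenset[str], float] = {}

    def __call__(self, i: str, j: str) -> float:
        key = frozenset((i, j))
        val = self._cache.get(key)
        if val is None:
            val = compute_mif(self.scores, self.matrix, i, j, mode=self.mode)
            self._cache[key] = val
        return val


def write_score_table(scores: MutationScoreTable, path) -> None:
    """Export gene, score and an is_bms flag as TSV."""
    with open(path, "w") as fh:
        fh.write("gene\tscore\tis_bms\n")
        for gene in sorted(scores.scores):
            s = scores.scores[gene]
            fh.write(f"{gene}\t{s:.10g}\t{int(gene in scores.background)}\n")
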