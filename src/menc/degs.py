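"""Per-patient differential expression calling from paired tumor/normal profiles.

A gene is differentially expressed in a patient when the absolute log2 fold
change between that patient's tumor and normal measurement exceeds the
threshold *strictly* (|lfc| = threshold exactly is not a call). The cohort DEG
set is the union of the per-patient sets. A pseudocount (default 1) is added
to numerator and denominator so zero-expression cells stay well defined; no
variance model or multiple-testing correction is involved — the criterion is
a pure fold-change cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ComputationError
from .io import ExpressionPair

__all__ = ["DEGSet", "call_degs"]


@dataclass
class DEGSet:
    """Cohort-pooled and per-patient differentially expressed genes."""

    cohort: frozenset[str]
    per_patient: dict[str, frozenset[str]]
    threshold: float

    def __contains__(self, gene: str) -> bool:
        return gene in self.cohort

    def __len__(self) -> int:
        return len(self.cohort)


def call_degs(e: ExpressionPair, threshold: float = 1.0,
              pseudocount: float = 1.0) -> DEGSet:
    """Call DEGs per patient and pool them into the cohort set.

    Parameters
    ----------
    e
        Column-paired tumor/normal expression, linear scale, nonnegative.
    threshold
        log2 fold-change cutoff; calls require ``|lfc| > threshold`` strictly.
    pseudocount
        Added to both tumor and normal values before the ratio. With
        ``pseudocount=0`` any zero in either matrix makes the fold change
        undefined and raises :class:`ComputationError` naming the cell.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be nonnegative, got {pseudocount}")
    if pseudocount == 0:
        zero = np.argwhere((e.tumor == 0) | (e.normal == 0))
        if zero.size:
            i, j = zero[0]
            raise ComputationError(
                f"zero expression for gene {e.genes[i]!r}, patient "
                f"{e.patients[j]!r} with pseudocount=0: fold change undefined"
            )
    # log2 of the ratio (not a difference of logs): exact power-of-two fold
    # changes then hit the threshold exactly, which matters for the strict cut.
    lfc = np.log2((e.tumor + pseudocount) / (e.normal + pseudocount))
    called = np.abs(lfc) > threshold
    per_patient = {
        p: frozenset(g for g, hit in zip(e.genes, called[:, j]) if hit)
        for j, p in enumerate(e.patients)
    }
    cohort = frozenset().union(*per_patient.values()) if per_patient else frozenset()
    return DEGSet(cohort=cohort, per_patient=per_patient, threshold=threshold)


def write_deg_set(degs: DEGSet, path) -> None:
    """Export (patient, gene) calls as TSV."""
    with open(path, "w") as fh:
        fh.write("patient\tgene\n")
        for patient in degs.per_patient:
            for gene in sorted(degs.per_patient[patient]):
                fh.write(f"{patient}\t{gene}\n")
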