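"""Self-contained synthetic cohorts with the structure the method assumes.

The generator emulates the four external inputs — a binary mutation matrix
with heterogeneous per-gene frequencies, paired tumor/normal expression with
planted fold changes, a scale-free undirected interaction network, and a
planted driver list — so every pipeline stage can be exercised without
downloading cohort data.

The causal structure planted is the one the method is built to detect:
drivers sit on network hubs, and in each patient carrying a driver mutation
the expression of that driver's direct network neighbours is shifted by a
fixed log2 effect (sign drawn once per gene), on top of log-normal baseline
expression and Gaussian log-space noise. Passenger mutations are sprinkled
uniformly and move no expression. Driver per-gene frequencies are drawn from
a range whose lower bound may sit below 2%, so rare drivers occur.

Because the score is degree-anchored, recovery experiments must compare
planted drivers against *degree-matched* mutated passengers, not against the
passenger pool at large; :func:`degree_matched_controls` builds that control
set.

All randomness flows through one ``numpy.random.default_rng(seed)``; no
global RNG state is touched, and integer-valued artifacts (graph, mutation
matrix) are bit-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .io import (ExpressionPair, GeneSet, MutationMatrix, PPIGraph,
                 write_expression_pair, write_gene_set, write_mutation_matrix,
                 write_ppi)

__all__ = [
    "SyntheticCohort",
    "generate_ppi",
    "generate_cohort",
    "degree_matched_controls",
    "write_cohort",
]

#: Baseline mean log2 expression level; high enough that the +1 pseudocount
#: used downstream barely perturbs fold changes.
_BASE_LOG2_MEAN = 6.0
_BASE_LOG2_SD = 1.0


@dataclass
class SyntheticCohort:
    """All four inputs of one simulated study, reproducible from ``seed``."""

    mutation: MutationMatrix
    expression: ExpressionPair
    ppi: PPIGraph
    planted_drivers: GeneSet
    seed: int


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_ppi(n_genes: int, attach_m: int = 2, seed: int = 0) -> PPIGraph:
    """Connected scale-free-like graph via Barabási–Albert preferential attachment."""
    if not (n_genes > attach_m >= 1):
        raise ValueError(f"require n_genes > attach_m >= 1, got "
                         f"n_genes={n_genes}, attach_m={attach_m}")
    g = nx.barabasi_albert_graph(n_genes, attach_m, seed=int(seed))
    names = _gene_names(n_genes)
    return nx.relabel_nodes(g, dict(enumerate(names)))


def generate_cohort(n_genes: int = 300, n_patients: int = 60, n_drivers: int = 5,
                    driver_freq_range: tuple[float, float] = (1.0, 20.0),
                    passenger_freq: float = 1.0, fc_effect: float = 2.5,
                    noise_sd: float = 0.3, seed: int = 0,
                    attach_m: int = 2) -> SyntheticCohort:
    """Simulate one cohort.

    Parameters
    ----------
    n_genes, n_patients
        Sizes of the gene and sample axes (all genes are PPI nodes).
    n_drivers
        Number of planted drivers, placed on the highest-degree PPI nodes.
    driver_freq_range
        (lo, hi) percent; each driver's carrier frequency is drawn uniformly
        from this range. A lower bound below 2% admits rare drivers.
    passenger_freq
        Percent chance of a passenger mutation per gene per patient.
    fc_effect
        log2 shift applied to a driver's PPI neighbours in carrier patients;
        the sign is drawn once per (driver, neighbour) gene.
    noise_sd
        SD of Gaussian log2-space measurement noise on both matrices.
    seed
        Seeds the single RNG; every artifact is reproducible from it.

    Each planted driver is guaranteed at least one carrier patient (a driver
    nobody carries would be absent from the mutation data entirely).
    """
    if not n_drivers < n_genes:
        raise ValueError(f"n_drivers={n_drivers} must be < n_genes={n_genes}")
    lo, hi = driver_freq_range
    if not (0 < lo <= hi <= 100):
        raise ValueError(f"driver_freq_range must satisfy 0 < lo <= hi <= 100, "
                         f"got {driver_freq_range}")
    if not (0 <= passenger_freq <= 100):
        raise ValueError(f"passenger_freq must be a percent, got {passenger_freq}")
    if noise_sd < 0 or fc_effect < 0:
        raise ValueError("fc_effect and noise_sd must be nonnegative")
    rng = np.random.default_rng(int(seed))
    ppi = generate_ppi(n_genes, attach_m=attach_m, seed=int(seed))
    genes = _gene_names(n_genes)
    patients = [f"P{j:03d}" for j in range(1, n_patients + 1)]
    gidx = {g: i for i, g in enumerate(genes)}

    by_degree = sorted(genes, key=lambda g: (-ppi.degree(g), g))
    drivers = by_degree[:n_drivers]

    mut = rng.random((n_genes, n_patients)) < passenger_freq / 100.0
    for d in drivers:
        freq = rng.uniform(lo, hi) / 100.0
        carriers = rng.random(n_patients) < freq
        if not carriers.any():
            carriers[rng.integers(n_patients)] = True
        mut[gidx[d]] = carriers
    mutation = MutationMatrix(genes, patients, mut.astype(np.int8))

    base = rng.normal(_BASE_LOG2_MEAN, _BASE_LOG2_SD, size=n_genes)
    shift = np.zeros((n_genes, n_patients))
    for d in drivers:
        neighbors = list(ppi[d])
        signs = rng.choice((-1.0, 1.0), size=len(neighbors))
        carriers = mutation.row(d).astype(bool)
        for nb, sign in zip(neighbors, signs):
            shift[gidx[nb], carriers] += sign * fc_effect
    normal_log = base[:, None] + rng.normal(0, noise_sd, size=(n_genes, n_patients)) \
        if noise_sd > 0 else np.broadcast_to(base[:, None], (n_genes, n_patients)).copy()
    tumor_log = base[:, None] + shift
    if noise_sd > 0:
        tumor_log = tumor_log + rng.normal(0, noise_sd, size=(n_genes, n_patients))
    expression = ExpressionPair(genes, patients,
                                tumor=np.exp2(tumor_log), normal=np.exp2(normal_log))
    return SyntheticCohort(mutation=mutation, expression=expression, ppi=ppi,
                           planted_drivers=GeneSet("planted_drivers", drivers),
                           seed=int(seed))


def degree_matched_controls(cohort: SyntheticCohort,
                            candidates: list[str] | None = None) -> dict[str, str]:
    """Pair each planted driver with the mutated passenger closest in PPI degree.

    Matching is greedy from the highest-degree driver down, without
    replacement; ties resolve to the lexicographically smallest symbol so the
    mapping is deterministic. ``candidates`` defaults to all mutated
    non-driver genes.
    """
    drivers = sorted(cohort.planted_drivers.members,
                     key=lambda g: (-cohort.ppi.degree(g), g))
    if candidates is None:
        candidates = [g for g in cohort.mutation.mutated_genes()
                      if g not in cohort.planted_drivers and g in cohort.ppi]
    pool = set(candidates)
    matches: dict[str, str] = {}
    for d in drivers:
        if not pool:
            break
        best = min(pool, key=lambda g: (abs(cohort.ppi.degree(g) - cohort.ppi.degree(d)), g))
        matches[d] = best
        pool.discard(best)
    return matches


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the four inputs in the formats the loaders read; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mutation": outdir / "mutation_matrix.tsv",
        "expression_tumor": outdir / "expression_tumor.tsv",
        "expression_normal": outdir / "expression_normal.tsv",
        "ppi": outdir / "ppi_edges.tsv",
        "drivers": outdir / "planted_drivers.txt",
    }
    write_mutation_matrix(cohort.mutation, paths["mutation"])
    write_expression_pair(cohort.expression, paths["expression_tumor"],
                          paths["expression_normal"])
    write_ppi(cohort.ppi, paths["ppi"])
    write_gene_set(cohort.planted_drivers, paths["drivers"])
    return paths
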