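"""Semi-local network construction and the driver-gene objective function.

The merged graph is the PPI induced on (mutated genes ∪ cohort DEGs); each
node carries a role — MUTATED, DEG, or BOTH when it appears in both input
sets. For every mutated source gene v the semi-local network is the subgraph
induced on the nodes within two hops of v; restricting attention to the
nearest and next-nearest neighbours keeps the centrality cheap relative to
global measures while still seeing past direct interactors.

The score of a source v combines its local degree, a mutation branch weighted
by the mutation-impact function (MIF), and a DEG branch:

    score(v) = N(v) + Σ_{u∈Γ(v) mutated} c(u)·MIF(v,u) + Σ_{u∈Γ(v) DEG} b(u)
    c(u)     = Σ_{w∈Γ(u) mutated} N(u)·MIF(u,w)        + Σ_{w∈Γ(u) DEG} N(w)
    b(u)     = Σ_{w∈Γ(u) mutated} c(w)                 + Σ_{w∈Γ(u) DEG} N(w)

where Γ(x) is the neighbourhood and N(x) the scalar neighbourhood size of x
inside the semi-local network — by default the degree, optionally the number
of nodes within two hops (``neighbor_count="two_hop"``). A BOTH node
contributes to *both* branches of every sum, so its score can only increase
relative to a pure mutation or pure DEG role. The ``N(u)·MIF(u,w)`` factor in
c(u) is constant in w; it is implemented as printed, with
``c_variant="nw"`` available to use N(w) instead, symmetric with the DEG
branch.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import networkx as nx

from .degs import DEGSet
from .errors import ComputationError
from .io import GeneSet, MutationMatrix, PPIGraph
from .mutation import MutationScoreTable, PairwiseMIF

logger = logging.getLogger(__name__)

__all__ = [
    "Role",
    "MergedGraph",
    "SemiLocalNetwork",
    "DriverRanking",
    "RankedGene",
    "build_merged_graph",
    "extract_semilocal",
    "score_gene",
    "rank_drivers",
]


class Role(enum.Enum):
    """Whether a node entered the merged graph as a mutated gene, a DEG, or both."""

    MUTATED = "mutated"
    DEG = "deg"
    BOTH = "both"


@dataclass
class MergedGraph:
    """PPI induced on mutated genes and cohort DEGs, with node roles."""

    graph: nx.Graph
    role: dict[str, Role]

    def mutated_nodes(self) -> list[str]:
        return [g for g, r in self.role.items() if r in (Role.MUTATED, Role.BOTH)]


@dataclass
class SemiLocalNetwork:
    """Two-hop ego subgraph of the merged graph around one mutated source gene."""

    source: str
    graph: nx.Graph
    role: dict[str, Role]


@dataclass(frozen=True)
class RankedGene:
    gene: str
    score: float
    rank: int


@dataclass
class DriverRanking:
    """Mutated genes ordered by decreasing semi-local score."""

    entries: list[RankedGene]

    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def top(self, k: int) -> list[str]:
        return [e.gene for e in self.entries[:k]]


def build_merged_graph(ppi: PPIGraph, mutated: GeneSet, degs: DEGSet) -> MergedGraph:
    """Induce the PPI on mutated ∪ DEG genes and assign node roles.

    Genes absent from the PPI are dropped (with logged counts); the resulting
    node set must be non-empty.
    """
    mut = set(mutated.members)
    deg = set(degs.cohort)
    keep = (mut | deg) & set(ppi.nodes)
    dropped_mut = len(mut - set(ppi.nodes))
    dropped_deg = len(deg - set(ppi.nodes))
    if dropped_mut or dropped_deg:
        logger.info("build_merged_graph: dropped %d mutated gene(s) and %d DEG(s) "
                    "absent from the PPI", dropped_mut, dropped_deg)
    if not keep:
        raise ComputationError("no mutated gene or DEG maps onto the PPI network")
    graph = nx.Graph(ppi.subgraph(keep))
    role = {}
    for g in keep:
        if g in mut and g in deg:
            role[g] = Role.BOTH
        elif g in mut:
            role[g] = Role.MUTATED
        else:
            role[g] = Role.DEG
    return MergedGraph(graph=graph, role=role)


def extract_semilocal(g: MergedGraph, v: str) -> SemiLocalNetwork:
    """Subgraph induced on {v} ∪ Γ(v) ∪ Γ(Γ(v)), computed in the merged graph."""
    if v not in g.graph or g.role.get(v) not in (Role.MUTATED, Role.BOTH):
        raise ComputationError(
            f"source {v!r} is not a mutated gene of the merged graph; "
            "only mutated genes act as source nodes"
        )
    nodes = set(nx.ego_graph(g.graph, v, radius=2).nodes)
    sub = nx.Graph(g.graph.subgraph(nodes))
    return SemiLocalNetwork(source=v, graph=sub,
                            role={n: g.role[n] for n in nodes})


def _two_hop_counts(graph: nx.Graph) -> dict[str, int]:
    return {n: len(nx.ego_graph(graph, n, radius=2)) - 1 for n in graph.nodes}


def score_gene(net: SemiLocalNetwork, scores: MutationScoreTable,
               m: MutationMatrix, mif_mode: str = "gravity",
               c_variant: str = "literal", neighbor_count: str = "degree",
               _mif: PairwiseMIF | None = None) -> float:
    """Evaluate the semi-local objective for the network's source gene.

    Degrees and neighbourhoods are taken inside ``net``; neighbour walks may
    revisit the source. Returns a finite nonnegative real; an isolated source
    scores 0.
    """
    if c_variant not in ("literal", "nw"):
        raise ValueError(f"unknown c_variant {c_variant!r}")
    if neighbor_count not in ("degree", "two_hop"):
        raise ValueError(f"unknown neighbor_count {neighbor_count!r}")
    G = net.graph
    role = net.role
    if role.get(net.source) not in (Role.MUTATED, Role.BOTH):
        raise ComputationError(f"source {net.source!r} is not mutated")
    mif = _mif if _mif is not None else PairwiseMIF(scores, m, mode=mif_mode)
    if neighbor_count == "degree":
        nsize = dict(G.degree)
    else:
        nsize = _two_hop_counts(G)

    def is_mut(x: str) -> bool:
        return role[x] in (Role.MUTATED, Role.BOTH)

    def is_deg(x: str) -> bool:
        return role[x] in (Role.DEG, Role.BOTH)

    c_cache: dict[str, float] = {}

    def c(u: str) -> float:
        val = c_cache.get(u)
        if val is not None:
            return val
        total = 0.0
        for w in G[u]:
            if is_mut(w):
                factor = nsize[u] if c_variant == "literal" else nsize[w]
                total += factor * mif(u, w)
            if is_deg(w):
                total += nsize[w]
        c_cache[u] = total
        return total

    def b(u: str) -> float:
        total = 0.0
        for w in G[u]:
            if is_mut(w):
                total += c(w)
            if is_deg(w):
                total += nsize[w]
        return total

    v = net.source
    total = float(nsize[v])
    for u in G[v]:
        if is_mut(u):
            total += c(u) * mif(v, u)
        if is_deg(u):
            total += b(u)
    return total


def rank_drivers(g: MergedGraph, scores: MutationScoreTable, m: MutationMatrix,
                 mif_mode: str = "gravity", c_variant: str = "literal",
                 neighbor_count: str = "degree") -> DriverRanking:
    """Score every mutated node of the merged graph and sort deterministically.

    Ties are broken by higher mutation score M(i), then lexicographic symbol.
    """
    sources = g.mutated_nodes()
    if not sources:
        raise ComputationError("merged graph contains no mutated gene to rank")
    mif = PairwiseMIF(scores, m, mode=mif_mode)
    rows = []
    for v in sources:
        net = extract_semilocal(g, v)
        s = score_gene(net, scores, m, mif_mode=mif_mode, c_variant=c_variant,
                       neighbor_count=neighbor_count, _mif=mif)
        rows.append((v, s))
    rows.sort(key=lambda t: (-t[1], -scores.get(t[0]), t[0]))
    entries = [RankedGene(gene=v, score=s, rank=i + 1)
               for i, (v, s) in enumerate(rows)]
    return DriverRanking(entries=entries)


def write_ranking(r: DriverRanking, g: MergedGraph, scores: MutationScoreTable,
                  path, top: int | None = None) -> None:
    """Export the ranking as TSV: rank, gene, score, mutation_score, degree, role."""
    entries = r.entries if top is None else r.entries[:top]
    with open(path, "w") as fh:
        fh.write("rank\tgene\tscore\tmutation_score\tdegree\trole\n")
        for e in entries:
            fh.write(f"{e.rank}\t{e.gene}\t{e.score:.10g}\t"
                     f"{scores.get(e.gene):.10g}\t{g.graph.degree(e.gene)}\t"
                     f"{g.role[e.gene].value}\n")
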