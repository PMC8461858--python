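"""Readers, writers and canonical in-memory containers.

All external formats are plain TSV / line-oriented text:

* mutation matrix — genes as rows, patients as columns, 0/1 cells;
* minimal MAF — tab-separated with at least ``Hugo_Symbol`` and
  ``Tumor_Sample_Barcode`` columns, collapsed to a binary matrix;
* expression — two genes x samples TSVs (tumor, normal) with paired columns;
* PPI — two-column edge list, optional header;
* gene set — one symbol per line.

Gene symbols are matched by exact string equality after stripping whitespace.
Every loader accepts ``uppercase=True`` to normalize case; the flag must be
applied uniformly to all inputs of a run, since symbol-case mismatch between
sources silently empties every intersection downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

# Header tokens recognized (case-insensitively) on the first line of an edge list.
_PPI_HEADER_TOKENS = {
    "gene", "genea", "geneb", "gene_a", "gene_b", "gene1", "gene2",
    "protein", "proteina", "proteinb", "protein_a", "protein_b",
    "source", "target", "interactor_a", "interactor_b", "node1", "node2",
    "from", "to", "symbol_a", "symbol_b",
}


@dataclass
class MutationMatrix:
    """Binary gene x patient incidence of somatic alterations (SNV or CNV).

    ``values[i, j] == 1`` iff gene ``i`` carries an alteration in patient ``j``.
    """

    genes: list[str]
    patients: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.genes), len(self.patients)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.patients)} patients"
            )
        if len(self.patients) == 0:
            raise FormatError("mutation matrix must have at least one patient")
        if not np.isin(self.values, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.values, (0, 1)))[0]
            raise FormatError(
                f"non-binary cell at gene {self.genes[bad[0]]!r}, "
                f"patient {self.patients[bad[1]]!r}"
            )
        self.values = self.values.astype(np.int8)
        _check_unique(self.genes, "gene")
        _check_unique(self.patients, "patient")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def row(self, gene: str) -> np.ndarray:
        """Binary incidence vector of one gene across all patients."""
        try:
            return self.values[self._index[gene]]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in mutation matrix") from None

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def patient_burdens(self) -> np.ndarray:
        """N_k: number of mutated genes per patient (column sums)."""
        return self.values.sum(axis=0)

    def mutated_genes(self) -> list[str]:
        """Genes altered in at least one patient, in row order."""
        keep = self.values.sum(axis=1) > 0
        return [g for g, k in zip(self.genes, keep) if k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.patients)


@dataclass
class ExpressionPair:
    """Column-paired tumor and normal expression matrices (linear scale, >= 0)."""

    genes: list[str]
    patients: list[str]
    tumor: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.tumor = np.asarray(self.tumor, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        shape = (len(self.genes), len(self.patients))
        if self.tumor.shape != shape or self.normal.shape != shape:
            raise FormatError("tumor and normal matrices must share gene and patient axes")
        for name, m in (("tumor", self.tumor), ("normal", self.normal)):
            if not np.isfinite(m).all():
                raise FormatError(f"{name} expression contains non-finite values")
            if (m < 0).any():
                i, j = np.argwhere(m < 0)[0]
                raise FormatError(
                    f"negative {name} expression for gene {self.genes[i]!r}, "
                    f"patient {self.patients[j]!r}"
                )
        _check_unique(self.genes, "gene")
        _check_unique(self.patients, "patient")


@dataclass
class GeneSet:
    """A named set of gene symbols (e.g. a known-driver benchmark catalog)."""

    name: str
    members: frozenset[str]

    def __init__(self, name: str, members: Iterable[str]):
        self.name = name
        self.members = frozenset(members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __iter__(self):
        return iter(self.members)


#: The PPI network is an undirected :class:`networkx.Graph` with gene-symbol
#: nodes, no self-loops and no parallel edges.
PPIGraph = nx.Graph


def _check_unique(items: list[str], what: str) -> None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            raise FormatError(f"duplicate {what} {x!r}")
        seen.add(x)


def _norm(symbol: str, uppercase: bool) -> str:
    symbol = symbol.strip()
    return symbol.upper() if uppercase else symbol


def load_mutation_matrix(path: str | Path, format: str = "matrix",
                         uppercase: bool = False) -> MutationMatrix:
    """Load a binary mutation matrix from a TSV matrix or a minimal MAF table.

    ``format="matrix"``: header row of patient IDs, first column gene symbols,
    cells 0/1. ``format="maf"``: long-format records; any number of records
    (>= 1) for a (gene, sample) pair collapses to a single 1 — multiplicity and
    variant class are discarded, matching a strictly binary incidence model.
    All-zero gene rows are retained.
    """
    path = Path(path)
    if format == "matrix":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except OSError as exc:
            raise InputError(f"cannot read mutation matrix {path}: {exc}") from exc
        except (pd.errors.ParserError, ValueError) as exc:
            raise FormatError(f"malformed mutation matrix {path}: {exc}") from exc
        genes = [_norm(str(g), uppercase) for g in df.index]
        patients = [str(c).strip() for c in df.columns]
        values = df.to_numpy()
        if values.dtype == object or not np.issubdtype(values.dtype, np.number):
            raise FormatError(f"non-numeric cell in mutation matrix {path}")
        return MutationMatrix(genes, patients, values)
    if format == "maf":
        try:
            df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        except OSError as exc:
            raise InputError(f"cannot read MAF {path}: {exc}") from exc
        required = {"Hugo_Symbol", "Tumor_Sample_Barcode"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"MAF {path} lacks required column(s): {sorted(missing)}")
        genes_col = df["Hugo_Symbol"].map(lambda g: _norm(str(g), uppercase))
        samples_col = df["Tumor_Sample_Barcode"].map(lambda s: str(s).strip())
        genes = list(dict.fromkeys(genes_col))  # first-appearance order
        patients = list(dict.fromkeys(samples_col))
        gidx = {g: i for i, g in enumerate(genes)}
        pidx = {p: j for j, p in enumerate(patients)}
        values = np.zeros((len(genes), len(patients)), dtype=np.int8)
        for g, s in zip(genes_col, samples_col):
            values[gidx[g], pidx[s]] = 1
        return MutationMatrix(genes, patients, values)
    raise ValueError(f"unknown mutation format {format!r}; expected 'matrix' or 'maf'")


def write_mutation_matrix(m: MutationMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="gene")


def load_expression_pair(tumor_path: str | Path, normal_path: str | Path,
                         uppercase: bool = False) -> ExpressionPair:
    """Load paired tumor/normal expression TSVs (genes as rows, samples as columns)."""
    mats = []
    for p in (tumor_path, normal_path):
        try:
            df = pd.read_csv(p, sep="\t", index_col=0)
        except OSError as exc:
            raise InputError(f"cannot read expression {p}: {exc}") from exc
        df.index = [_norm(str(g), uppercase) for g in df.index]
        df.columns = [str(c).strip() for c in df.columns]
        mats.append(df)
    tumor, normal = mats
    if list(tumor.index) != list(normal.index) or list(tumor.columns) != list(normal.columns):
        raise FormatError("tumor and normal expression files must share identical gene and sample axes")
    return ExpressionPair(list(tumor.index), list(tumor.columns),
                          tumor.to_numpy(), normal.to_numpy())


def write_expression_pair(e: ExpressionPair, tumor_path: str | Path,
                          normal_path: str | Path) -> None:
    for mat, p in ((e.tumor, tumor_path), (e.normal, normal_path)):
        pd.DataFrame(mat, index=e.genes, columns=e.patients).to_csv(
            p, sep="\t", index_label="gene")


def load_ppi(path: str | Path, uppercase: bool = False) -> PPIGraph:
    """Load an undirected PPI network from a two-column TSV edge list.

    A first line whose tokens look like column names (``gene_a``, ``source``,
    ...) is treated as a header. Self-loops and duplicate edges are dropped,
    with counts logged.
    """
    path = Path(path)
    graph = nx.Graph()
    self_loops = duplicates = 0
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise InputError(f"cannot read PPI edge list {path}: {exc}") from exc
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected >= 2 tab-separated columns")
        a, b = _norm(parts[0], uppercase), _norm(parts[1], uppercase)
        if lineno == 1 and {a.lower(), b.lower()} <= _PPI_HEADER_TOKENS:
            continue
        if a == b:
            self_loops += 1
            graph.add_node(a)
            continue
        if graph.has_edge(a, b):
            duplicates += 1
            continue
        graph.add_edge(a, b)
    if self_loops or duplicates:
        logger.info("load_ppi(%s): dropped %d self-loop(s) and %d duplicate edge(s)",
                    path, self_loops, duplicates)
    return graph


def write_ppi(graph: PPIGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")


def load_gene_set(path: str | Path, name: str | None = None,
                  uppercase: bool = False) -> GeneSet:
    """Load a gene set from a plain-text file, one symbol per line."""
    path = Path(path)
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise InputError(f"cannot read gene list {path}: {exc}") from exc
    members = {_norm(x, uppercase) for x in lines if x.strip()}
    if not members:
        logger.warning("gene list %s is empty", path)
    return GeneSet(name or path.stem, members)


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(gs.members)) + ("\n" if gs.members else ""))
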