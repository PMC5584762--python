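"""File formats: GMT gene sets, TSV edge lists, label lists, score matrices.

All gene identity is the raw symbol string (case-sensitive, no whitespace);
no alias resolution is attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

NAMESPACES = ("GO-BP", "GO-CC", "GO-MF", "KEGG")
GO_NAMESPACES = ("GO-BP", "GO-CC", "GO-MF")

__all__ = [
    "AnnotationSet",
    "Network",
    "LabeledGenes",
    "read_gene_sets",
    "read_network",
    "read_labels",
    "write_matrix",
    "read_matrix",
]


def _check_symbol(symbol: str) -> str:
    if not symbol or any(ch.isspace() for ch in symbol):
        raise ValueError(f"invalid gene symbol: {symbol!r}")
    return symbol


@dataclass(frozen=True)
class AnnotationSet:
    """One named gene set (a GO term or KEGG pathway) with its namespace."""

    term_id: str
    term_name: str
    namespace: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace {self.namespace!r}; expected one of {NAMESPACES}")
        if not self.members:
            raise ValueError(f"annotation set {self.term_id} has no members")
        for g in self.members:
            _check_symbol(g)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class Network:
    """Undirected gene–gene interaction graph (no self-loops).

    Thin wrapper around a ``networkx.Graph``; edge confidence scores, when
    present, live in the ``score`` edge attribute (STRING convention,
    0–1000).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return self.graph.has_node(gene)

    def neighbors(self, gene: str) -> set[str]:
        if not self.graph.has_node(gene):
            return set()
        return set(self.graph.neighbors(gene))

    def edge_set(self) -> set[tuple[str, str, float | None]]:
        return {
            (*sorted((a, b)), data.get("score"))
            for a, b, data in self.graph.edges(data=True)
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.nodes == other.nodes and self.edge_set() == other.edge_set()

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str] | tuple[str, str, float]],
        extra_nodes: Iterable[str] = (),
    ) -> "Network":
        g = nx.Graph()
        for node in extra_nodes:
            g.add_node(_check_symbol(node))
        for edge in edges:
            a, b = _check_symbol(edge[0]), _check_symbol(edge[1])
            if a == b:
                logger.warning("dropping self-loop on %s", a)
                continue
            if len(edge) >= 3:
                score = float(edge[2])  # type: ignore[misc]
                if g.has_edge(a, b):
                    prev = g.edges[a, b].get("score")
                    if prev is not None:
                        score = max(score, prev)
                g.add_edge(a, b, score=score)
            else:
                g.add_edge(a, b)
        return cls(g)


@dataclass(frozen=True)
class LabeledGenes:
    """Ordered, disjoint positive (essential) and negative (non-essential)
    gene lists."""

    positives: tuple[str, ...]
    negatives: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.positives)) != len(self.positives):
            raise ValueError("duplicate genes in positive list")
        if len(set(self.negatives)) != len(self.negatives):
            raise ValueError("duplicate genes in negative list")
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise ValueError(f"genes labeled both positive and negative: {sorted(overlap)}")

    @property
    def n_pos(self) -> int:
        return len(self.positives)

    @property
    def n_neg(self) -> int:
        return len(self.negatives)

    @property
    def genes(self) -> tuple[str, ...]:
        """All labeled genes, positives first."""
        return self.positives + self.negatives

    def labels(self) -> np.ndarray:
        """0/1 label vector aligned with :attr:`genes` (1 = essential)."""
        return np.array([1] * self.n_pos + [0] * self.n_neg, dtype=np.int64)


def read_gene_sets(path: str | Path, namespace: str) -> list[AnnotationSet]:
    """Parse a GMT file (TAB-separated: term_id, description, genes...).

    Duplicate member symbols within a line are deduplicated with a warning;
    a duplicate term_id across lines is an error, as is a line with fewer
    than three columns.
    """
    path = Path(path)
    sets: list[AnnotationSet] = []
    seen_ids: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=3 columns, got {len(cols)}")
            term_id, term_name = cols[0], cols[1]
            if term_id in seen_ids:
                raise ValueError(f"{path}:{lineno}: duplicate term_id {term_id!r}")
            seen_ids.add(term_id)
            members: list[str] = []
            seen_members: set[str] = set()
            for sym in cols[2:]:
                if not sym:
                    continue
                if sym in seen_members:
                    logger.warning("%s:%d: duplicate member %s in %s deduplicated",
                                   path, lineno, sym, term_id)
                    continue
                seen_members.add(sym)
                members.append(sym)
            sets.append(AnnotationSet(term_id=term_id, term_name=term_name,
                                      namespace=namespace, members=frozenset(members)))
    return sets


def write_gene_sets(sets: Sequence[AnnotationSet], path: str | Path) -> None:
    """Write annotation sets in GMT format (members in sorted order)."""
    with Path(path).open("w") as fh:
        for s in sets:
            fh.write("\t".join([s.term_id, s.term_name, *sorted(s.members)]) + "\n")


def read_network(path: str | Path, min_score: float | None = None) -> Network:
    """Read a TSV edge list (geneA TAB geneB [TAB combined_score]).

    Lines starting with ``#`` are ignored.  Self-loop rows are dropped with
    a warning and duplicate edges collapsed (keeping the larger score).
    When ``min_score`` is given, edges scoring below it are dropped but
    their endpoints are kept as isolated nodes.
    """
    path = Path(path)
    edges: list[tuple[str, str, float] | tuple[str, str]] = []
    nodes: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#node:"):
                # isolated-node declaration emitted by write_network
                nodes.append(line[len("#node:"):].strip())
                continue
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: edge row needs >=2 columns")
            a, b = cols[0].strip(), cols[1].strip()
            if a == b:
                logger.warning("%s:%d: dropping self-loop on %s", path, lineno, a)
                continue
            if len(cols) >= 3 and cols[2].strip():
                try:
                    score = float(cols[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric score {cols[2]!r}") from exc
                if min_score is not None and score < min_score:
                    nodes.extend([a, b])
                    continue
                edges.append((a, b, score))
            else:
                edges.append((a, b))
    return Network.from_edges(edges, extra_nodes=nodes)


def write_network(net: Network, path: str | Path) -> None:
    """Write the edge list as TSV; isolated nodes are emitted as comment
    lines so a read round-trip preserves the node set."""
    g = net.graph
    with Path(path).open("w") as fh:
        for a, b, data in sorted(g.edges(data=True)):
            if "score" in data:
                fh.write(f"{a}\t{b}\t{data['score']:g}\n")
            else:
                fh.write(f"{a}\t{b}\n")
        for node in sorted(g.nodes):
            if g.degree(node) == 0:
                fh.write(f"#node:{node}\n")


def _read_gene_list(path: str | Path) -> list[str]:
    genes: list[str] = []
    seen: set[str] = set()
    with Path(path).open() as fh:
        for line in fh:
            sym = line.strip()
            if not sym or sym.startswith("#"):
                continue
            if sym in seen:
                logger.warning("%s: duplicate gene %s ignored", path, sym)
                continue
            seen.add(sym)
            genes.append(sym)
    return genes


def read_labels(pos_path: str | Path, neg_path: str | Path) -> LabeledGenes:
    """Read positive and negative gene lists (one symbol per line, ``#``
    comments allowed).  A gene present in both files is a hard error."""
    return LabeledGenes(
        positives=tuple(_read_gene_list(pos_path)),
        negatives=tuple(_read_gene_list(neg_path)),
    )


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in genes:
            fh.write(g + "\n")


# --- feature-matrix TSV ------------------------------------------------------
#
# Header cell encodes the feature as "term_id|namespace" so that a read
# round-trips the (term_id, namespace) pair; scores are written at 6
# significant digits.

def write_matrix(matrix, path: str | Path) -> None:
    from .enrichment import FeatureMatrix  # local import to avoid a cycle

    assert isinstance(matrix, FeatureMatrix)
    with Path(path).open("w") as fh:
        header = ["gene"] + [f"{tid}|{ns}" for tid, ns in matrix.features]
        fh.write("\t".join(header) + "\n")
        for gene, row in zip(matrix.genes, matrix.scores):
            fh.write(gene + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_matrix(path: str | Path):
    from .enrichment import FeatureMatrix

    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "gene":
            raise ValueError(f"{path}: matrix header must start with 'gene'")
        features: list[tuple[str, str]] = []
        for cell in header[1:]:
            tid, sep, ns = cell.rpartition("|")
            if not sep or ns not in NAMESPACES:
                raise ValueError(f"{path}: bad feature header cell {cell!r}")
            features.append((tid, ns))
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: row has {len(cols)} columns, header has {len(header)}"
                )
            genes.append(cols[0])
            row = [float(v) for v in cols[1:]]
            if any(not math.isfinite(v) for v in row):
                raise ValueError(f"{path}:{lineno}: non-finite score")
            rows.append(row)
    scores = np.array(rows, dtype=float) if rows else np.empty((0, len(features)))
    return FeatureMatrix(genes=tuple(genes), features=tuple(features), scores=scores)
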