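"""Synthetic benchmark generator with planted enrichment signal.

Emulates the pipeline's three inputs — a gene interaction network, GO/KEGG
annotation gene sets, and labeled essential/non-essential gene lists — with
a known ground truth.  The background network is Erdős–Rényi (a simple null;
degree-distribution realism is a non-goal).  A designated subset of
"informative" terms carries the signal: each positive gene is assigned one
to three informative terms and wired to each of their member genes with
probability ``p_signal`` well above the baseline ``p_background``, so the
positive gene's network neighborhood is genuinely hypergeometrically
enriched in those terms.  Positive genes are excluded from term-membership
draws, keeping the planted signal purely neighborhood-mediated — exactly the
mechanism the enrichment score measures.

The defaults mirror a compact version of a real essential-gene study: ~20%
positives (roughly the 1:4 essential/non-essential imbalance of curated
human gold standards), many more GO terms than KEGG pathways, and term sizes
of a few tens of genes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as eio
from .io import AnnotationSet, LabeledGenes, Network

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate",
    "export",
    "load_dataset",
]


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 1000
    n_pos: int = 200
    n_neg: int = 800
    n_go_terms: int = 500
    n_kegg_terms: int = 50
    term_size_range: tuple[int, int] = (6, 12)
    n_informative_terms: int = 20
    p_signal: float = 0.5
    p_background: float = 0.005
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_pos + self.n_neg > self.n_genes:
            raise ValueError("n_pos + n_neg exceeds n_genes")
        if self.n_informative_terms > self.n_go_terms + self.n_kegg_terms:
            raise ValueError("more informative terms than terms")
        lo, hi = self.term_size_range
        if not (1 <= lo <= hi):
            raise ValueError("term_size_range must satisfy 1 <= min <= max")
        if hi > self.n_genes - self.n_pos:
            raise ValueError(
                "term size can exceed the non-positive gene pool "
                f"({self.n_genes - self.n_pos}); shrink term_size_range or n_pos"
            )
        for p in (self.p_signal, self.p_background):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticConfig":
        data = json.loads(Path(path).read_text())
        if "term_size_range" in data:
            data["term_size_range"] = tuple(data["term_size_range"])
        return cls(**data)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for parameter-recovery tests."""

    informative_term_ids: tuple[str, ...]
    labels: dict[str, int]  # gene -> 1 (positive) / 0 (negative); unlabeled absent
    config: SyntheticConfig


@dataclass(frozen=True)
class SyntheticDataset:
    network: Network
    terms: tuple[AnnotationSet, ...]
    labeled: LabeledGenes
    truth: SyntheticTruth

    @property
    def go_terms(self) -> tuple[AnnotationSet, ...]:
        return tuple(t for t in self.terms if t.namespace != "KEGG")

    @property
    def kegg_terms(self) -> tuple[AnnotationSet, ...]:
        return tuple(t for t in self.terms if t.namespace == "KEGG")


def generate(config: SyntheticConfig = SyntheticConfig()) -> SyntheticDataset:
    """Draw one dataset; fully deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    genes = np.array([f"G{i:05d}" for i in range(1, config.n_genes + 1)])

    labeled_idx = rng.choice(config.n_genes, size=config.n_pos + config.n_neg, replace=False)
    pos_idx = np.sort(labeled_idx[: config.n_pos])
    neg_idx = np.sort(labeled_idx[config.n_pos:])
    pos_set = set(pos_idx.tolist())

    # Term membership is drawn from non-positive genes only, so the planted
    # signal is purely neighborhood-mediated.  Informative terms draw their
    # members first and those members are excluded from every other term's
    # draw: a gene set overlapping an informative term would inherit its
    # planted wiring and become a spurious ground-truth term, so disjoint
    # memberships are what make the planted terms identifiable.
    pool = np.array([i for i in range(config.n_genes) if i not in pos_set])
    n_terms = config.n_go_terms + config.n_kegg_terms
    lo, hi = config.term_size_range
    informative = np.sort(rng.choice(n_terms, size=config.n_informative_terms, replace=False))
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(n_terms)]
    if sum(sizes[t] for t in informative) + hi > len(pool):
        raise ValueError(
            "informative terms exhaust the non-positive gene pool; "
            "shrink term_size_range or n_informative_terms"
        )
    members_by_idx: dict[int, np.ndarray] = {}
    for t in informative:
        members_by_idx[int(t)] = pool[rng.choice(len(pool), size=sizes[t], replace=False)]
        pool = np.setdiff1d(pool, members_by_idx[int(t)])

    go_namespaces = ("GO-BP", "GO-CC", "GO-MF")
    terms: list[AnnotationSet] = []
    members_of: list[np.ndarray] = []
    for t in range(n_terms):
        if t in members_by_idx:
            members = members_by_idx[t]
        else:
            members = pool[rng.choice(len(pool), size=sizes[t], replace=False)]
        members_of.append(members)
        if t < config.n_go_terms:
            term_id = f"GO:{t + 1:07d}"
            namespace = go_namespaces[t % 3]
            name = f"synthetic GO term {t + 1}"
        else:
            term_id = f"hsa{t - config.n_go_terms + 1:05d}"
            namespace = "KEGG"
            name = f"synthetic KEGG pathway {t - config.n_go_terms + 1}"
        terms.append(
            AnnotationSet(
                term_id=term_id,
                term_name=name,
                namespace=namespace,
                members=frozenset(genes[members]),
            )
        )

    # Erdős–Rényi background over all gene pairs
    iu, ju = np.triu_indices(config.n_genes, k=1)
    keep = rng.random(len(iu)) < config.p_background
    edges = {(int(a), int(b)) for a, b in zip(iu[keep], ju[keep])}

    # planted wiring: positives link into their informative terms' members.
    # Each positive draws 1-3 informative terms; terms are dealt from a
    # shuffled cyclic queue so every informative term covers an equal share
    # of the positives (balanced coverage keeps the planted signal per term
    # comparable).
    queue: list[int] = []
    for g in pos_idx:
        k = min(int(rng.integers(1, 4)), len(informative))
        my_terms: list[int] = []
        while len(my_terms) < k:
            if not queue or set(queue) <= set(my_terms):
                queue.extend(int(t) for t in rng.permutation(informative))
            t = queue.pop(0)
            if t in my_terms:
                queue.append(t)  # re-queue duplicates for this positive
            else:
                my_terms.append(t)
        for t in my_terms:
            hits = rng.random(len(members_of[t])) < config.p_signal
            for member in members_of[t][hits]:
                a, b = (int(g), int(member)) if g < member else (int(member), int(g))
                if a != b:
                    edges.add((a, b))

    network = Network.from_edges(
        ((genes[a], genes[b]) for a, b in sorted(edges)), extra_nodes=genes.tolist()
    )
    labeled = LabeledGenes(
        positives=tuple(genes[pos_idx]), negatives=tuple(genes[neg_idx])
    )
    truth = SyntheticTruth(
        informative_term_ids=tuple(terms[t].term_id for t in informative),
        labels={**{g: 1 for g in labeled.positives}, **{g: 0 for g in labeled.negatives}},
        config=config,
    )
    return SyntheticDataset(network=network, terms=tuple(terms), labeled=labeled, truth=truth)


def export(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write net.tsv, go.gmt, kegg.gmt, pos.txt, neg.txt and truth.json in
    the formats of :mod:`essnet.io`; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": directory / "net.tsv",
        "go": directory / "go.gmt",
        "kegg": directory / "kegg.gmt",
        "pos": directory / "pos.txt",
        "neg": directory / "neg.txt",
        "truth": directory / "truth.json",
    }
    eio.write_network(dataset.network, paths["network"])
    eio.write_gene_sets(dataset.go_terms, paths["go"])
    eio.write_gene_sets(dataset.kegg_terms, paths["kegg"])
    eio.write_gene_list(dataset.labeled.positives, paths["pos"])
    eio.write_gene_list(dataset.labeled.negatives, paths["neg"])
    truth = {
        "informative_term_ids": list(dataset.truth.informative_term_ids),
        "labels": dataset.truth.labels,
        "config": asdict(dataset.truth.config),
        # GMT carries one namespace per file, so the GO-BP/CC/MF split is
        # recorded here for a lossless round-trip
        "term_namespaces": {t.term_id: t.namespace for t in dataset.terms},
    }
    paths["truth"].write_text(json.dumps(truth, indent=2) + "\n")
    return paths


def load_dataset(directory: str | Path) -> SyntheticDataset:
    """Read an exported dataset back; inverse of :func:`export`."""
    directory = Path(directory)
    truth_data = json.loads((directory / "truth.json").read_text())
    ns_of = truth_data["term_namespaces"]
    raw_go = eio.read_gene_sets(directory / "go.gmt", namespace="GO-BP")
    go = [
        AnnotationSet(t.term_id, t.term_name, ns_of[t.term_id], t.members) for t in raw_go
    ]
    kegg = eio.read_gene_sets(directory / "kegg.gmt", namespace="KEGG")
    network = eio.read_network(directory / "net.tsv")
    labeled = eio.read_labels(directory / "pos.txt", directory / "neg.txt")
    cfg = truth_data["config"]
    cfg["term_size_range"] = tuple(cfg["term_size_range"])
    truth = SyntheticTruth(
        informative_term_ids=tuple(truth_data["informative_term_ids"]),
        labels={g: int(v) for g, v in truth_data["labels"].items()},
        config=SyntheticConfig(**cfg),
    )
    return SyntheticDataset(network=network, terms=tuple(go + kegg), labeled=labeled, truth=truth)
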