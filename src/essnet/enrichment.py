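"""Network-neighborhood enrichment encoding of genes.

Each gene g is represented by the vector of enrichment scores of its
interaction neighborhood G(g) = {g} ∪ neighbors(g) against every annotation
gene set.  The score for one (gene, term) pair is the -log10 upper-tail
hypergeometric probability

    S(g, T) = -log10( sum_{k=m}^{n} C(M,k) C(N-M, n-k) / C(N,n) )

with N the background-universe size, M the term size, n = |G(g)| and
m = |G(g) ∩ T|.  Larger scores mean the neighborhood is more enriched in the
term's members; the scores are used as classifier features, not as
significance tests, so no multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .io import GO_NAMESPACES, AnnotationSet, LabeledGenes, Network

logger = logging.getLogger(__name__)

#: -log10 score assigned when the hypergeometric p-value underflows to 0;
#: 320 sits just past the smallest positive double (~1e-323).
DEFAULT_SCORE_CAP = 320.0

__all__ = [
    "Background",
    "Neighborhood",
    "FeatureMatrix",
    "make_background",
    "neighborhood",
    "enrichment_score",
    "encode_gene",
    "filter_unencodable",
    "build_feature_matrix",
]


@dataclass(frozen=True)
class Background:
    """The gene universe the hypergeometric test draws from.

    ``n_total`` (N) defaults to ``len(universe)`` but may be overridden with
    an explicit total-gene count (e.g. ~20,000 for the human genome) while
    keeping the membership universe for intersections.
    """

    universe: frozenset[str]
    n_total: int = 0

    def __post_init__(self) -> None:
        if self.n_total == 0:
            object.__setattr__(self, "n_total", len(self.universe))
        if self.n_total < 1:
            raise ValueError("background must contain at least one gene")
        if self.n_total < len(self.universe):
            raise ValueError("n_total override smaller than the membership universe")


@dataclass(frozen=True)
class Neighborhood:
    """A gene together with its direct network neighbors, intersected with
    the background universe."""

    center: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.center not in self.members:
            raise ValueError("neighborhood must contain its own center gene")

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class FeatureMatrix:
    """genes x terms grid of enrichment scores.

    Column order is fixed: all GO features (GO-BP/GO-CC/GO-MF) first, then
    all KEGG features.  Entries are finite and non-negative.
    """

    genes: tuple[str, ...]
    features: tuple[tuple[str, str], ...]  # (term_id, namespace)
    scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.genes), len(self.features)):
            raise ValueError(
                f"score grid {self.scores.shape} does not match "
                f"{len(self.genes)} genes x {len(self.features)} features"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in feature matrix")
        seen_kegg = False
        for _, ns in self.features:
            if ns == "KEGG":
                seen_kegg = True
            elif seen_kegg:
                raise ValueError("feature columns must be ordered GO block then KEGG block")
        if self.scores.size and (
            not np.all(np.isfinite(self.scores)) or self.scores.min() < 0
        ):
            raise ValueError("scores must be finite and non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def term_ids(self) -> tuple[str, ...]:
        return tuple(tid for tid, _ in self.features)

    def row(self, gene: str) -> np.ndarray:
        return self.scores[self.genes.index(gene)]

    def subset_genes(self, genes: Sequence[str]) -> "FeatureMatrix":
        idx = [self.genes.index(g) for g in genes]
        return FeatureMatrix(tuple(genes), self.features, self.scores[idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return (
            self.genes == other.genes
            and self.features == other.features
            and self.scores.shape == other.scores.shape
            and bool(np.allclose(self.scores, other.scores, rtol=1e-5, atol=1e-9))
        )


def order_terms(terms: Iterable[AnnotationSet]) -> list[AnnotationSet]:
    """Stable ordering with all GO terms before all KEGG pathways."""
    terms = list(terms)
    go = [t for t in terms if t.namespace in GO_NAMESPACES]
    kegg = [t for t in terms if t.namespace == "KEGG"]
    return go + kegg


def make_background(
    net: Network,
    terms: Iterable[AnnotationSet],
    extra_genes: Iterable[str] = (),
    n_total: int | None = None,
) -> Background:
    """Default universe: union of network nodes, all annotation members and
    any extra genes (e.g. the labeled lists); N may be overridden."""
    universe: set[str] = set(net.nodes) | set(extra_genes)
    for t in terms:
        universe |= t.members
    return Background(frozenset(universe), n_total=n_total or 0)


def neighborhood(net: Network, g: str, background: Background) -> Neighborhood:
    """G(g): the gene itself plus its direct interaction partners, restricted
    to the background universe."""
    if g not in background.universe:
        raise ValueError(f"gene {g!r} not in the background universe")
    members = ({g} | net.neighbors(g)) & background.universe
    members.add(g)  # g is always its own neighborhood member
    return Neighborhood(center=g, members=frozenset(members))


def _tail_scores(
    m: np.ndarray, n: np.ndarray, M: np.ndarray, N: int, cap: float
) -> np.ndarray:
    """Vectorized -log10 upper-tail hypergeometric probability.

    ``hypergeom.sf(m-1, N, M, n)`` is P[X >= m]; m == 0 gives p = 1 and
    score 0.  Underflow to p = 0 is clamped to ``cap``.
    """
    p = hypergeom.sf(m - 1, N, M, n)
    with np.errstate(divide="ignore"):
        score = -np.log10(p)
    score = np.where(np.isfinite(score), score, cap)
    return np.clip(score, 0.0, cap)


def enrichment_score(
    nbhd: Neighborhood,
    term: AnnotationSet,
    background: Background,
    cap: float = DEFAULT_SCORE_CAP,
) -> float:
    """Enrichment score of one neighborhood against one annotation set."""
    N = background.n_total
    members = nbhd.members & background.universe
    eff_term = term.members & background.universe
    n = len(members)
    M = len(eff_term)
    if n > N or M > N:
        raise ValueError(f"inconsistent background: n={n}, M={M} exceed N={N}")
    m = len(members & eff_term)
    return float(_tail_scores(np.array(m), np.array(n), np.array(M), N, cap))


def encode_gene(
    net: Network,
    g: str,
    terms: Sequence[AnnotationSet],
    background: Background,
    cap: float = DEFAULT_SCORE_CAP,
) -> np.ndarray:
    """Feature row for one gene: enrichment scores in term order (which must
    already be GO-first)."""
    nbhd = neighborhood(net, g, background)
    members = nbhd.members
    N = background.n_total
    n = len(members)
    if n > N:
        raise ValueError(f"inconsistent background: n={n} exceeds N={N}")
    eff = [t.members & background.universe for t in terms]
    M = np.array([len(e) for e in eff])
    if M.size and M.max() > N:
        raise ValueError("inconsistent background: term larger than N")
    m = np.array([len(members & e) for e in eff])
    return _tail_scores(m, np.full_like(M, n), M, N, cap)


def filter_unencodable(
    genes: LabeledGenes,
    net: Network,
    matrix: FeatureMatrix | None = None,
    drop_all_zero: bool = False,
) -> tuple[LabeledGenes, list[tuple[str, str]]]:
    """Discard labeled genes whose enrichment profile is unavailable.

    A gene is dropped iff it is absent from the interaction network (an
    isolated-but-present gene still has a well-defined, mostly-zero vector).
    With ``drop_all_zero=True`` and a prebuilt matrix, genes whose entire
    score row is zero are dropped as well.  Returns the kept lists (input
    order preserved) and the dropped (gene, reason) pairs.
    """
    dropped: list[tuple[str, str]] = []

    def keep(g: str) -> bool:
        if g not in net:
            dropped.append((g, "absent from network"))
            return False
        if drop_all_zero and matrix is not None and g in matrix.genes:
            if not matrix.row(g).any():
                dropped.append((g, "all-zero enrichment row"))
                return False
        return True

    kept = LabeledGenes(
        positives=tuple(g for g in genes.positives if keep(g)),
        negatives=tuple(g for g in genes.negatives if keep(g)),
    )
    for g, reason in dropped:
        logger.info("dropped %s: %s", g, reason)
    return kept, dropped


def build_feature_matrix(
    net: Network,
    genes: Sequence[str],
    terms: Sequence[AnnotationSet],
    background: Background,
    cap: float = DEFAULT_SCORE_CAP,
) -> FeatureMatrix:
    """Encode every gene against every term (GO columns first, then KEGG).

    Deterministic given its inputs; gene order in equals row order out.
    """
    ordered = order_terms(terms)
    N = background.n_total
    eff = [t.members & background.universe for t in ordered]
    M = np.array([len(e) for e in eff], dtype=np.int64)
    if M.size and M.max() > N:
        raise ValueError("inconsistent background: term larger than N")
    rows = np.empty((len(genes), len(ordered)), dtype=float)
    for i, g in enumerate(genes):
        members = neighborhood(net, g, background).members
        n = len(members)
        if n > N:
            raise ValueError(f"inconsistent background: n={n} exceeds N={N}")
        m = np.fromiter((len(members & e) for e in eff), dtype=np.int64, count=len(eff))
        rows[i] = _tail_scores(m, np.full_like(M, n), M, N, cap)
    return FeatureMatrix(
        genes=tuple(genes),
        features=tuple((t.term_id, t.namespace) for t in ordered),
        scores=rows,
    )
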