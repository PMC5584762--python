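"""Maximum-relevance minimum-redundancy (mRMR) feature ranking.

Features are discretized into three categories (below mean-sigma, middle,
above mean+sigma) and scored by discrete mutual information (MI, base-2
plug-in estimator).  The greedy mRMR loop repeatedly moves the feature
maximizing

    D - R = I(f, class) - mean_{s in selected} I(f, s)

from the candidate pool into the selected list (R is 0 for the first pick),
producing a full permutation of the features.  The MaxRel list is the same
features sorted by relevance D alone.  Both lists break ties by the lower
feature index, so rankings are fully deterministic.  Rankings are invariant
to the MI log base, which only rescales D and R by the same constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enrichment import FeatureMatrix

__all__ = [
    "DiscretizedFeature",
    "RankedFeatures",
    "discretize",
    "mutual_information",
    "mrmr_rank",
]


@dataclass(frozen=True)
class DiscretizedFeature:
    """Per-sample categorical codes in {0, 1, 2} plus the bin edges used."""

    codes: np.ndarray = field(repr=False)
    bin_edges: tuple[float, float]

    def __post_init__(self) -> None:
        low, high = self.bin_edges
        if low > high:
            raise ValueError("bin edges must satisfy low <= high")


@dataclass(frozen=True)
class RankedFeatures:
    """The mRMR list (selection order), the MaxRel list (relevance order),
    per-feature relevance D = I(f, c), and per-step (D, R, D-R) diagnostics
    for the picked feature."""

    mrmr_order: tuple[int, ...]
    maxrel_order: tuple[int, ...]
    relevance: np.ndarray = field(repr=False)
    step_scores: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.relevance)
        for name in ("mrmr_order", "maxrel_order"):
            order = getattr(self, name)
            if sorted(order) != list(range(n)):
                raise ValueError(f"{name} is not a permutation of 0..{n - 1}")

    @property
    def n_features(self) -> int:
        return len(self.relevance)


def discretize(values: np.ndarray) -> DiscretizedFeature:
    """Three bins with edges at mean +/- population sigma.

    Values at or below the low edge code 0, at or above the high edge code 2,
    strictly between the edges code 1.  A constant vector has zero variance
    and maps entirely to the middle bin.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty vector")
    mean = float(values.mean())
    sigma = float(values.std())  # population (ddof=0)
    codes = np.ones(values.shape, dtype=np.int8)
    if sigma > 0:
        low, high = mean - sigma, mean + sigma
        codes[values <= low] = 0
        codes[values >= high] = 2
    else:
        low = high = mean
    return DiscretizedFeature(codes=codes, bin_edges=(low, high))


def _as_codes(x) -> np.ndarray:
    if isinstance(x, DiscretizedFeature):
        return x.codes
    return np.asarray(x)


def _mi_from_counts(counts: np.ndarray) -> float:
    """Plug-in MI (bits) from a joint count table; 0*log(0) terms drop out."""
    n = counts.sum()
    if n == 0:
        raise ValueError("empty contingency table")
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / (px @ py)[mask])))


def mutual_information(a, b) -> float:
    """MI in bits between two categorical variables (DiscretizedFeature or
    raw integer codes, e.g. binary class labels)."""
    xa, xb = _as_codes(a), _as_codes(b)
    if xa.shape != xb.shape:
        raise ValueError(f"sample-count mismatch: {xa.shape} vs {xb.shape}")
    _, ia = np.unique(xa, return_inverse=True)
    _, ib = np.unique(xb, return_inverse=True)
    ka, kb = ia.max() + 1, ib.max() + 1
    counts = np.bincount(ia * kb + ib, minlength=ka * kb).reshape(ka, kb)
    return _mi_from_counts(counts)


def _pairwise_mi_to(codes: np.ndarray, s: int, candidates: np.ndarray) -> np.ndarray:
    """MI (bits) of column ``s`` against each candidate column, vectorized
    over the 3x3 joint tables."""
    n, _ = codes.shape
    cs = codes[:, s]
    sub = codes[:, candidates]
    counts = np.empty((3, 3, len(candidates)), dtype=np.int64)
    for a in range(3):
        rows = sub[cs == a]
        for b in range(3):
            counts[a, b] = (rows == b).sum(axis=0)
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return np.nansum(terms, axis=(0, 1))


def mrmr_rank(matrix: FeatureMatrix, labels: np.ndarray) -> RankedFeatures:
    """Rank all features of ``matrix`` by the greedy mRMR criterion.

    ``labels`` is the binary class vector aligned with the matrix rows (used
    raw, not discretized).  Requires at least two samples, one feature and
    both classes present.
    """
    labels = np.asarray(labels)
    n_samples, n_features = matrix.scores.shape
    if n_samples < 2:
        raise ValueError("need at least two samples")
    if n_features < 1:
        raise ValueError("need at least one feature")
    if len(labels) != n_samples:
        raise ValueError("label vector length does not match the matrix")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")

    codes = np.empty((n_samples, n_features), dtype=np.int8)
    for j in range(n_features):
        codes[:, j] = discretize(matrix.scores[:, j]).codes

    relevance = np.array(
        [mutual_information(codes[:, j], labels) for j in range(n_features)]
    )
    # stable argsort on -D: ties resolve to the lower feature index
    maxrel_order = tuple(int(j) for j in np.argsort(-relevance, kind="stable"))

    selected: list[int] = []
    step_scores: list[tuple[float, float, float]] = []
    remaining = np.ones(n_features, dtype=bool)
    redundancy_sum = np.zeros(n_features)
    for _ in range(n_features):
        cand = np.flatnonzero(remaining)
        r = redundancy_sum[cand] / len(selected) if selected else np.zeros(len(cand))
        crit = relevance[cand] - r
        best = int(cand[np.argmax(crit)])  # argmax returns the first (lowest-index) max
        i = int(np.where(cand == best)[0][0])
        step_scores.append((float(relevance[best]), float(r[i]), float(crit[i])))
        remaining[best] = False
        selected.append(best)
        rest = np.flatnonzero(remaining)
        if rest.size:
            redundancy_sum[rest] += _pairwise_mi_to(codes, best, rest)

    return RankedFeatures(
        mrmr_order=tuple(selected),
        maxrel_order=maxrel_order,
        relevance=relevance,
        step_scores=tuple(step_scores),
    )
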