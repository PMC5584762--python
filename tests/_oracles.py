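"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately written from first principles (explicit
enumeration, dict counting, full recomputation each step) and shares no code
with the package, so agreement is a meaningful check.
"""

from __future__ import annotations

import math
from collections import Counter


def hypergeom_tail_p(N: int, M: int, n: int, m: int) -> float:
    """P[X >= m] for X ~ Hypergeom(N, M, n) by explicit enumeration of k."""
    total = math.comb(N, n)
    acc = 0
    for k in range(m, n + 1):
        if k > M or n - k > N - M:
            continue
        acc += math.comb(M, k) * math.comb(N - M, n - k)
    return acc / total


def discretize_ref(values) -> list[int]:
    """Three-bin codes with edges mean +/- population sigma; boundary values
    go to the outer bins; constant vectors are all middle-bin."""
    n = len(values)
    mean = sum(values) / n
    sigma = math.sqrt(sum((v - mean) ** 2 for v in values) / n)
    if sigma == 0:
        return [1] * n
    out = []
    for v in values:
        if v <= mean - sigma:
            out.append(0)
        elif v >= mean + sigma:
            out.append(2)
        else:
            out.append(1)
    return out


def mi_ref(x, y, base: float = 2.0) -> float:
    """Plug-in mutual information via dict counting."""
    n = len(x)
    assert len(y) == n
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    mi = 0.0
    for (a, b), c in joint.items():
        p_ab = c / n
        mi += p_ab * math.log(p_ab / ((px[a] / n) * (py[b] / n)), base)
    return mi


def mrmr_ref(columns, labels, base: float = 2.0):
    """Greedy mRMR re-derived from scratch at every step.

    ``columns`` is a list of per-feature value sequences.  Returns
    (mrmr_order, maxrel_order, relevance).  D and R are recomputed in full
    for every candidate at every step; ties break to the lower index.
    """
    codes = [discretize_ref(col) for col in columns]
    labels = list(labels)
    relevance = [mi_ref(c, labels, base) for c in codes]

    maxrel = sorted(range(len(codes)), key=lambda j: (-relevance[j], j))

    selected: list[int] = []
    remaining = list(range(len(codes)))
    while remaining:
        best_j, best_score = None, None
        for j in remaining:
            if selected:
                red = sum(mi_ref(codes[j], codes[s], base) for s in selected) / len(selected)
            else:
                red = 0.0
            score = relevance[j] - red
            if best_score is None or score > best_score + 1e-12:
                best_j, best_score = j, score
        selected.append(best_j)
        remaining.remove(best_j)
    return selected, maxrel, relevance
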