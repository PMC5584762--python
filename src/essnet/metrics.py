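"""Binary-classification performance measures for imbalanced gene classes.

Sensitivity (SN), specificity (SP) and overall accuracy (ACC) summarise the
per-class hit rates, but with roughly four non-essential genes per essential
gene they can look flattering for trivial classifiers.  The Matthews
correlation coefficient (MCC) — the Pearson correlation between predicted and
true binary labels — is the headline measure throughout the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ConfusionCounts", "MetricSet", "compute_metrics"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pooled confusion-matrix counts: TP/FN split the positive (essential)
    class, TN/FP split the negative class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricSet:
    """SN, SP, ACC in [0, 1]; MCC in [-1, 1].

    ``sn``/``sp`` are NaN when the corresponding class is empty.  When any
    factor of the MCC denominator is zero the coefficient is undefined; it is
    reported as 0.0 with ``mcc_defined=False``.
    """

    sn: float
    sp: float
    acc: float
    mcc: float
    mcc_defined: bool = True

    def rounded(self, ndigits: int = 3) -> dict[str, float]:
        """Metrics rounded for reporting (3 decimals by default)."""
        return {
            "SN": round(self.sn, ndigits),
            "SP": round(self.sp, ndigits),
            "ACC": round(self.acc, ndigits),
            "MCC": round(self.mcc, ndigits),
        }


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Compute SN = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/total and

        MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

    Raises ``ValueError`` on an all-zero table.
    """
    if c.total == 0:
        raise ValueError("confusion counts are all zero")

    sn = c.tp / c.positives if c.positives > 0 else math.nan
    sp = c.tn / c.negatives if c.negatives > 0 else math.nan
    acc = (c.tp + c.tn) / c.total

    denom2 = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom2 == 0:
        return MetricSet(sn=sn, sp=sp, acc=acc, mcc=0.0, mcc_defined=False)
    mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom2)
    return MetricSet(sn=sn, sp=sp, acc=acc, mcc=mcc, mcc_defined=True)


def reconstruct_counts(n_pos: int, n_neg: int, sn: float, sp: float) -> ConfusionCounts:
    """Rebuild integer confusion counts from class sizes and per-class
    accuracies: TP = round(SN*P), TN = round(SP*N).

    Useful for recovering a full metric set from published per-class rates.
    """
    tp = round(sn * n_pos)
    tn = round(sp * n_neg)
    return ConfusionCounts(tp=tp, tn=tn, fp=n_neg - tn, fn=n_pos - tp)
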