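"""Confusion-matrix evaluation and cascade false-positive projection.

The positive class is DIC throughout.  The five standard proportions are
ACC = (TP+TN)/(TP+FP+TN+FN), TPR = TP/(TP+FN), TNR = TN/(TN+FP),
PPV = TP/(TP+FP) and NPV = TN/(TN+FN); any metric whose denominator is
zero is reported as an explicit undefined marker (None), never as 0.

``project_cascade_fpr`` composes per-stage per-class accuracies into the
expected DIC false-positive rate at a given non-DIC : DIC population
ratio: after k stages the surviving false-positive mass is
ratio * prod(1 - nonDIC_accuracy_i) and the surviving true-positive mass
is prod(DIC_accuracy_i); the projection is FP / (FP + TP).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("counts must be non-negative")
        if self.TP + self.FP + self.FN + self.TN < 1:
            raise ValueError("at least one observation required")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class MetricsReport:
    ACC: Optional[float]
    TPR: Optional[float]
    TNR: Optional[float]
    PPV: Optional[float]
    NPV: Optional[float]

    def as_dict(self) -> dict:
        return {"ACC": self.ACC, "TPR": self.TPR, "TNR": self.TNR,
                "PPV": self.PPV, "NPV": self.NPV}


@dataclass(frozen=True)
class StageRates:
    """Per-class test accuracies of one CNN stage."""
    nonDIC_accuracy: float
    DIC_accuracy: float

    def __post_init__(self):
        for v in (self.nonDIC_accuracy, self.DIC_accuracy):
            if not 0.0 <= v <= 1.0:
                raise ValueError("accuracies must lie in [0, 1]")


def confusion(predicted: Sequence[str], truth: Sequence[str]) -> ConfusionCounts:
    """Tally TP/FP/FN/TN with DIC as the positive class."""
    if len(predicted) != len(truth):
        raise ValueError("label vectors differ in length")
    if len(predicted) == 0:
        raise ValueError("empty label vectors")
    tp = fp = fn = tn = 0
    for p, t in zip(predicted, truth):
        if p == "DIC" and t == "DIC":
            tp += 1
        elif p == "DIC":
            fp += 1
        elif t == "DIC":
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def metrics(c: ConfusionCounts) -> MetricsReport:
    return MetricsReport(
        ACC=_ratio(c.TP + c.TN, c.total),
        TPR=_ratio(c.TP, c.TP + c.FN),
        TNR=_ratio(c.TN, c.TN + c.FP),
        PPV=_ratio(c.TP, c.TP + c.FP),
        NPV=_ratio(c.TN, c.TN + c.FN),
    )


def project_cascade_fpr(ratio_nonDIC_per_DIC: float,
                        stages: Sequence[StageRates]) -> Optional[float]:
    """Expected DIC false-positive rate after the cascade stages."""
    if ratio_nonDIC_per_DIC <= 0:
        raise ValueError("ratio must be positive")
    if not 1 <= len(stages) <= 2:
        raise ValueError("one or two stages expected")
    fp = ratio_nonDIC_per_DIC
    tp = 1.0
    for st in stages:
        fp *= 1.0 - st.nonDIC_accuracy
        tp *= st.DIC_accuracy
    if fp + tp == 0:
        return None
    return fp / (fp + tp)


def subgroup_accuracy(subgroup_size: int, misidentified: int) -> float:
    """Accuracy on a labeled subgroup (e.g. long-arm-entangled bodies):
    (size - misidentified) / size."""
    if subgroup_size <= 0:
        raise ValueError("subgroup must be non-empty")
    return (subgroup_size - misidentified) / subgroup_size


def percent(value: Optional[float], decimals: int = 1) -> Optional[float]:
    """Half-up rounding of a proportion to a printed percentage."""
    if value is None:
        return None
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value * 100)).quantize(q, rounding=ROUND_HALF_UP))


def format_table(first_stage: ConfusionCounts,
                 two_stage: ConfusionCounts) -> str:
    """Text table comparing the two identification modes (counts plus the
    five percentages, one decimal, half-up)."""
    m1, m2 = metrics(first_stage), metrics(two_stage)

    def fmt(v):
        return "undefined" if v is None else f"{percent(v):.1f}%"

    lines = [
        "Parameter      First-stage CNN only    Two-stage CNN",
        f"TP             {first_stage.TP:<23d} {two_stage.TP}",
        f"FN             {first_stage.FN:<23d} {two_stage.FN}",
        f"FP             {first_stage.FP:<23d} {two_stage.FP}",
        f"TN             {first_stage.TN:<23d} {two_stage.TN}",
    ]
    for name in ("ACC", "TPR", "TNR", "PPV", "NPV"):
        v1, v2 = getattr(m1, name), getattr(m2, name)
        lines.append(f"{name}            {fmt(v1):<23s} {fmt(v2)}")
    return "\n".join(lines)
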