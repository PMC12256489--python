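"""Incremental cost-effectiveness: ICER, dominance, thresholds, net benefit."""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

from .core import WTP_HIGH, WTP_INTERMEDIATE

__all__ = ["CEClass", "CEResult", "icer", "classify_cost_effectiveness",
           "net_monetary_benefit", "format_money"]


class CEClass(str, enum.Enum):
    DOMINANT = "dominant"
    HIGHLY_CE = "highly_cost_effective"
    INTERMEDIATELY_CE = "intermediately_cost_effective"
    NOT_CE = "not_cost_effective"
    DOMINATED = "dominated"


@dataclass
class CEResult:
    cost_new: float
    qaly_new: float
    cost_ref: float
    qaly_ref: float
    incremental_cost: float
    incremental_qaly: float
    icer: Optional[float]          # None when ΔE = 0 (undefined)
    classification: Optional[CEClass]

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["classification"] = self.classification.value if self.classification else None
        return d


def icer(cost_new: float, qaly_new: float, cost_ref: float, qaly_ref: float,
         thresholds: tuple[float, float] = (WTP_HIGH, WTP_INTERMEDIATE)) -> CEResult:
    """Incremental cost-effectiveness of a strategy against a reference.

    Dominance short-circuits the ratio: lower cost with higher effect is
    DOMINANT, higher cost with lower effect DOMINATED. A zero effect
    difference leaves the ICER undefined (flagged ``None``) rather than
    infinite.
    """
    vals = (cost_new, qaly_new, cost_ref, qaly_ref)
    if any(v is None or math.isnan(v) or math.isinf(v) for v in vals):
        raise ValueError("inputs must be finite")
    dc = cost_new - cost_ref
    de = qaly_new - qaly_ref
    ratio = dc / de if de != 0 else None
    result = CEResult(cost_new, qaly_new, cost_ref, qaly_ref, dc, de, ratio, None)
    if dc < 0 and de > 0:
        result.classification = CEClass.DOMINANT
    elif dc > 0 and de < 0:
        result.classification = CEClass.DOMINATED
    elif ratio is not None:
        result.classification = classify_cost_effectiveness(result, thresholds)
    return result


def classify_cost_effectiveness(result: CEResult,
                                thresholds: tuple[float, float] = (WTP_HIGH, WTP_INTERMEDIATE)
                                ) -> CEClass:
    """Map an ICER onto the GDP-per-capita threshold bands (strict '<')."""
    low, high = thresholds
    if not low < high:
        raise ValueError("thresholds must satisfy low < high")
    if result.classification in (CEClass.DOMINANT, CEClass.DOMINATED):
        return result.classification
    if result.icer is None:
        raise ValueError("ICER undefined (zero incremental effect); classification withheld")
    if result.incremental_qaly < 0:
        # more effect lost per dollar saved than the threshold tolerates
        return CEClass.NOT_CE if result.icer < high else CEClass.HIGHLY_CE
    if result.icer < low:
        return CEClass.HIGHLY_CE
    if result.icer < high:
        return CEClass.INTERMEDIATELY_CE
    return CEClass.NOT_CE


def net_monetary_benefit(incremental_cost: float, incremental_qaly: float,
                         wtp: float) -> float:
    """NMB = wtp * ΔE − ΔC; positive iff the ICER beats ``wtp`` when ΔE > 0."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * incremental_qaly - incremental_cost


def format_money(x: float, decimals: int = 2) -> str:
    """Table-style money formatting; negatives rendered in parentheses."""
    s = f"{abs(x):,.{decimals}f}"
    return f"({s})" if x < 0 else s
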