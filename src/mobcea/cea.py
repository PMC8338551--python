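"""Incremental cost-effectiveness arithmetic.

ICER with dominance classification, net monetary benefit, and
cost-effectiveness-plane quadrants.  Increments are treatment minus
comparator throughout.  A dominant (or dominated) result still carries the
raw ratio delta_cost/delta_effect, which is conventionally reported even
when the classification, not the number, is the verdict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

from .errors import DomainError

#: |delta_effect| below this counts as zero for classification purposes.
ZERO_EFFECT_TOL = 1e-12

DOMINANCE_LABELS = (
    "strongly_dominant",
    "strongly_dominated",
    "weakly_dominant",
    "weakly_dominated",
    "indeterminate",
)


@dataclass(frozen=True)
class NMBValue:
    """Net monetary benefit lambda*E - C at willingness-to-pay lambda."""

    lam: float
    value: float


def nmb(cost: float, effectiveness: float, lam: float) -> NMBValue:
    if lam < 0:
        raise DomainError(f"willingness-to-pay lambda must be >= 0, got {lam}")
    if not (math.isfinite(cost) and math.isfinite(effectiveness)):
        raise DomainError("cost and effectiveness must be finite")
    return NMBValue(lam, lam * effectiveness - cost)


def classify_quadrant(delta_cost: float, delta_effect: float) -> str:
    """Cost-effectiveness-plane sector of an increment pair.

    NE: more costly, more effective; NW: more costly, less effective;
    SE: less costly, more effective; SW: less costly, less effective.
    Boundary zeros in delta_effect go to SE when delta_cost < 0 and NW
    otherwise, preserving "cost-effective at lambda = 0 iff delta_cost < 0".
    """
    if not (math.isfinite(delta_cost) and math.isfinite(delta_effect)):
        raise DomainError("delta_cost and delta_effect must be finite")
    # southern half iff delta_cost strictly negative, so SE+SW is exactly the
    # set of draws that are cost-effective at lambda = 0
    if delta_effect > 0:
        return "SE" if delta_cost < 0 else "NE"
    if delta_effect < 0:
        return "SW" if delta_cost < 0 else "NW"
    return "SE" if delta_cost < 0 else "NW"


@dataclass(frozen=True)
class CEAResult:
    """Paired-arm comparison: arm costs/effects, increments, ICER.

    ``icer`` is the numeric ratio in the trade-off quadrants and a
    dominance label otherwise; ``icer_ratio`` is always the raw quotient
    delta_cost/delta_effect when delta_effect is nonzero.
    """

    cost_comparator: float
    cost_treatment: float
    effect_comparator: float
    effect_treatment: float
    delta_cost: float
    delta_effect: float
    icer: Union[float, str]
    icer_ratio: Optional[float]

    @property
    def is_dominance(self) -> bool:
        return isinstance(self.icer, str)

    def to_dict(self) -> dict:
        return {
            "cost_comparator": self.cost_comparator,
            "cost_treatment": self.cost_treatment,
            "effect_comparator": self.effect_comparator,
            "effect_treatment": self.effect_treatment,
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
            "icer": self.icer,
            "icer_ratio": self.icer_ratio,
        }


def icer(delta_cost: float, delta_effect: float) -> tuple[Union[float, str], Optional[float]]:
    """Classify an increment pair: (icer value or dominance label, raw ratio).

    delta_cost < 0 with delta_effect > 0 is strong dominance of the
    treatment (cheaper and better); the mirror image is strong dominatedness;
    zero delta_effect gives weak dominance/dominatedness by the sign of
    delta_cost; both zero is indeterminate; otherwise the numeric ratio.
    """
    if not (math.isfinite(delta_cost) and math.isfinite(delta_effect)):
        raise DomainError("delta_cost and delta_effect must be finite")
    effect_is_zero = abs(delta_effect) <= ZERO_EFFECT_TOL
    ratio = None if effect_is_zero else delta_cost / delta_effect
    if effect_is_zero:
        if delta_cost < 0:
            return "weakly_dominant", ratio
        if delta_cost > 0:
            return "weakly_dominated", ratio
        return "indeterminate", ratio
    if delta_cost < 0 and delta_effect > 0:
        return "strongly_dominant", ratio
    if delta_cost > 0 and delta_effect < 0:
        return "strongly_dominated", ratio
    return ratio, ratio


def compare_strategies(
    cost_comparator: float,
    effect_comparator: float,
    cost_treatment: float,
    effect_treatment: float,
    rounding: str = "unrounded",
) -> CEAResult:
    """Full incremental comparison of treatment versus comparator.

    ``rounding="printed"`` reproduces published-table arithmetic by
    rounding delta_cost to cents and delta_effect to three decimals before
    forming the ratio; the default divides unrounded increments.
    """
    if rounding not in ("unrounded", "printed"):
        raise DomainError(f"unknown rounding mode '{rounding}'")
    delta_cost = cost_treatment - cost_comparator
    delta_effect = effect_treatment - effect_comparator
    if rounding == "printed":
        delta_cost = round(delta_cost, 2)
        delta_effect = round(delta_effect, 3)
    icer_value, ratio = icer(delta_cost, delta_effect)
    return CEAResult(
        cost_comparator=cost_comparator,
        cost_treatment=cost_treatment,
        effect_comparator=effect_comparator,
        effect_treatment=effect_treatment,
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        icer=icer_value,
        icer_ratio=ratio,
    )
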