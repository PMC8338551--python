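"""Valuation rules and payer-partitioned cost breakdowns.

Implements the societal-perspective costing conventions: hospital per-diems
obtained by dividing the tariff by the mean length of stay, tariff halving
when a procedure costed separately would otherwise be double-counted
(leaving the hotel component only), gross-wage valuation of lost work time
versus net-wage valuation of leisure and caregiver time (with leisure
substituting for work from the retirement age onward), and an opportunity
cost for apheresis sessions missed through poor mobilization.

Costs are computed in floats (summed with ``math.fsum``) and rounded
half-away-from-zero to cents only at report time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .config import StrategyDefinition
from .errors import DomainError
from .tree import ArmOutcome

PAYERS = ("INHS", "out_of_pocket", "patient_time")


def round_cents(amount: float) -> float:
    """Round to cents, half away from zero (printed-table style)."""
    return float(Decimal(repr(amount)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def daily_hospital_cost(tariff: float, mean_los: float) -> float:
    """Per-diem cost: the admission tariff spread over the mean stay."""
    if tariff < 0:
        raise DomainError(f"tariff must be >= 0, got {tariff}")
    if mean_los <= 0:
        raise DomainError(f"mean length of stay must be positive, got {mean_los}")
    return tariff / mean_los


def hotel_cost(tariff: float, itemized_separately: bool) -> float:
    """Halve the tariff when the procedure itself is costed separately,
    leaving only the hotel (bed and board) component."""
    if tariff < 0:
        raise DomainError(f"tariff must be >= 0, got {tariff}")
    return tariff / 2.0 if itemized_separately else tariff


def time_cost(hours: float, rate: float, kind: str) -> float:
    """Value time at the wage rate appropriate to its kind.

    ``productivity`` hours are lost work time (gross wage rate);
    ``informal_or_leisure`` hours are caregiver or substituted leisure time
    (net, take-home rate).  The caller selects the rate; the ``kind``
    argument documents and checks the intent.
    """
    if kind not in ("productivity", "informal_or_leisure"):
        raise DomainError(f"unknown time kind '{kind}'")
    if hours < 0 or rate < 0:
        raise DomainError(f"hours and rate must be >= 0, got {hours}, {rate}")
    return hours * rate


def working_time_kind(age: float, employed: bool, retirement_age: float = 70.0) -> str:
    """Lost time is productivity only for employed patients below the
    retirement age; otherwise leisure substitutes for work."""
    return "productivity" if employed and age < retirement_age else "informal_or_leisure"


@dataclass(frozen=True)
class CostRow:
    label: str
    category: str
    payer: str
    quantity: float
    unit_cost: float
    cost: float


@dataclass(frozen=True)
class CostBreakdown:
    """Per-item costs for one arm with payer and category subtotals."""

    arm: str
    rows: tuple[CostRow, ...]

    @property
    def by_payer(self) -> dict[str, float]:
        out = {payer: 0.0 for payer in PAYERS}
        for payer in PAYERS:
            out[payer] = math.fsum(r.cost for r in self.rows if r.payer == payer)
        return out

    @property
    def by_category(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for row in self.rows:
            out[row.category] = out.get(row.category, 0.0) + row.cost
        return out

    @property
    def total(self) -> float:
        return math.fsum(r.cost for r in self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.arm, r.category, r.label, r.payer, r.quantity, r.unit_cost, r.cost) for r in self.rows],
            columns=["arm", "category", "item", "payer", "quantity", "unit_cost", "cost"],
        )


def arm_cost_breakdown(
    outcome: ArmOutcome, strategy: StrategyDefinition, values: dict[str, float]
) -> CostBreakdown:
    """One row per cost item: expected cost = expected quantity x unit cost."""
    rows = []
    for item in strategy.cost_items:
        if item.unit_cost not in values:
            raise DomainError(f"unresolved parameter reference '{item.unit_cost}' in item '{item.label}'")
        quantity = outcome.expected_quantities[item.label]
        unit = values[item.unit_cost]
        cost = quantity * unit
        if cost < 0:
            raise DomainError(f"negative expected cost {cost} for item '{item.label}'")
        rows.append(CostRow(item.label, item.category, item.payer, quantity, unit, cost))
    return CostBreakdown(outcome.strategy, tuple(rows))


def total_cost(breakdown: CostBreakdown, perspective: str = "societal") -> float:
    """Societal = all payers; INHS-only = the third-party payer subtotal."""
    if perspective == "societal":
        return breakdown.total
    if perspective in ("inhs", "INHS_only"):
        return breakdown.by_payer["INHS"]
    raise DomainError(f"unknown perspective '{perspective}' (expected 'societal' or 'inhs')")
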