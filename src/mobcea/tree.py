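"""Decision-tree evaluation of one mobilization arm.

The tree is flat: intermediate chance nodes (febrile neutropenia,
transfusions) only matter through their expected resource quantities, so
each arm reduces to (i) an effectiveness probability -- the
plerixafor-weighted mixture of success with and without the rescue agent --
and (ii) one expected quantity per cost item, the product of its factor
means (a Bernoulli gate times a conditional amount is just such a product).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .config import StrategyDefinition
from .errors import DomainError


def _check_probability(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise DomainError(f"{name} must be a probability in [0, 1], got {value}")


def mixture_effectiveness(p_plx: float, e_with: float, e_without: float) -> float:
    """Probability of a successful 4x10^6 CD34+/kg apheresis for one arm.

    With probability ``p_plx`` the patient receives on-demand plerixafor
    and succeeds with probability ``e_with``; otherwise success has
    probability ``e_without``.  Returned unrounded.
    """
    _check_probability(p_plx, "p_plx")
    _check_probability(e_with, "e_with")
    _check_probability(e_without, "e_without")
    return p_plx * e_with + (1.0 - p_plx) * e_without


def expected_quantity(p_event: float, amount_if_event: float) -> float:
    """Expectation of a Bernoulli-gated amount (e.g. plerixafor vials)."""
    _check_probability(p_event, "p_event")
    if amount_if_event < 0:
        raise DomainError(f"amount_if_event must be >= 0, got {amount_if_event}")
    return p_event * amount_if_event


@dataclass(frozen=True)
class ArmOutcome:
    """Deterministic evaluation of one arm: effectiveness plus the expected
    quantity of every cost item (keyed by item label)."""

    strategy: str
    effectiveness: float
    expected_quantities: dict[str, float]


def evaluate_arm(strategy: StrategyDefinition, values: Mapping[str, float]) -> ArmOutcome:
    """Evaluate one arm at a resolved parameter assignment.

    ``values`` maps parameter names to numbers (base-case means, one-way
    bounds, or a single Monte Carlo draw).  Linear in every quantity
    factor; deterministic for fixed inputs.
    """
    for ref in (strategy.p_plx, strategy.e_with_plx, strategy.e_without_plx):
        if ref not in values:
            raise DomainError(f"unresolved parameter reference '{ref}' in strategy '{strategy.name}'")
    effectiveness = mixture_effectiveness(
        values[strategy.p_plx], values[strategy.e_with_plx], values[strategy.e_without_plx]
    )
    quantities: dict[str, float] = {}
    for item in strategy.cost_items:
        q = 1.0
        for factor in item.quantity_factors:
            if factor not in values:
                raise DomainError(f"unresolved parameter reference '{factor}' in item '{item.label}'")
            q *= values[factor]
        if q < 0:
            raise DomainError(f"negative expected quantity {q} for item '{item.label}'")
        quantities[item.label] = q
    return ArmOutcome(strategy.name, effectiveness, quantities)
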