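"""Random, valid model configurations with the structure the analysis assumes.

The generator emulates the shape of the real elicitation: two strategies
sharing one effectiveness pair, gamma-distributed resource quantities whose
declared CIs are *derived from their own fitted distribution* (so the
distribution fitter is exactly invertible on synthetic data), beta
probabilities, optional Bernoulli-gated composite items, fixed unit costs,
and cost items spread across all three payers.

Degenerate draws are injected deliberately: with configurable probability
the two arms are exactly equally effective, and with another the two arms
share an identical item list (incremental cost exactly zero), so that all
five dominance labels occur across seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import (
    CostItem,
    Demographics,
    ModelConfig,
    StrategyDefinition,
    UncertainQuantity,
    Wages,
)
from .distributions import beta_default_sd, beta_from_mean_sd, gamma_from_mean_cv
from .errors import DomainError

_CATEGORIES_BY_PAYER = {
    "INHS": (
        "mobilization_drugs", "mobilization_admin", "full_blood_count",
        "central_venous_catheter", "febrile_neutropenia", "transfusions",
        "apheresis_procedures", "missed_apheresis", "stem_cell_handling",
    ),
    "out_of_pocket": ("transportation", "parking"),
    "patient_time": ("productivity_loss", "informal_care"),
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Knobs of the random-configuration generator.

    Ranges are inclusive; the CV governs every generated gamma quantity
    (0.4 matches the empirical regularity of the real elicitation).
    """

    seed: int = 0
    n_cost_items: tuple[int, int] = (3, 8)
    cv: float = 0.4
    prob_range: tuple[float, float] = (0.05, 0.95)
    eff_gap_range: tuple[float, float] = (-0.15, 0.25)
    wage_range: tuple[float, float] = (10.0, 40.0)
    unit_cost_range: tuple[float, float] = (20.0, 5000.0)
    quantity_mean_range: tuple[float, float] = (0.1, 10.0)
    composite_items: bool = True
    p_equal_effectiveness: float = 0.12
    p_identical_costs: float = 0.12

    def check(self) -> None:
        for name in ("n_cost_items", "prob_range", "eff_gap_range", "wage_range",
                     "unit_cost_range", "quantity_mean_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise DomainError(f"{name} range is not well-ordered: ({lo}, {hi})")
        if self.cv <= 0:
            raise DomainError(f"cv must be positive, got {self.cv}")
        if not (0.0 <= self.prob_range[0] and self.prob_range[1] <= 1.0):
            raise DomainError(f"prob_range outside [0, 1]: {self.prob_range}")
        if not (0.0 <= self.p_equal_effectiveness <= 1.0 and 0.0 <= self.p_identical_costs <= 1.0):
            raise DomainError("degenerate-draw probabilities must be in [0, 1]")


def _gamma_quantity(name: str, mean: float, cv: float) -> UncertainQuantity:
    ci = gamma_from_mean_cv(mean, cv).ci95()
    return UncertainQuantity(name=name, mean=mean, ci_low=ci[0], ci_high=ci[1],
                             dist="gamma", units="units")


def _beta_probability(name: str, mean: float) -> UncertainQuantity:
    ci = beta_from_mean_sd(mean, beta_default_sd(mean)).ci95()
    return UncertainQuantity(name=name, mean=mean, ci_low=ci[0], ci_high=ci[1],
                             dist="beta", units="probability")


def random_model_config(spec: GeneratorSpec) -> ModelConfig:
    """Generate a configuration that passes :func:`mobcea.config.validate`.

    Same seed, same configuration (the generator is a pure function of the
    seed).
    """
    spec.check()
    rng = np.random.default_rng(spec.seed)
    params: dict[str, UncertainQuantity] = {}

    def add(p: UncertainQuantity) -> str:
        params[p.name] = p
        return p.name

    e_without = float(rng.uniform(0.3, 0.75))
    if rng.uniform() < spec.p_equal_effectiveness:
        gap = 0.0
    else:
        gap = float(rng.uniform(*spec.eff_gap_range))
    e_with = float(np.clip(e_without + gap, 0.02, 0.98))
    add(_beta_probability("e_without_plx", e_without))
    if e_with == e_without:
        # exact equality: reuse the same parameter object under both names
        params["e_with_plx"] = UncertainQuantity(
            name="e_with_plx", mean=e_without,
            ci_low=params["e_without_plx"].ci_low, ci_high=params["e_without_plx"].ci_high,
            dist="beta", units="probability",
        )
    else:
        add(_beta_probability("e_with_plx", e_with))

    identical_costs = bool(rng.uniform() < spec.p_identical_costs)
    p1 = float(rng.uniform(*spec.prob_range))
    p2 = p1 if identical_costs else float(rng.uniform(*spec.prob_range))
    add(_beta_probability("p_plx_arm_a", p1))
    add(_beta_probability("p_plx_arm_b", p2))

    def make_items(arm: str) -> list[CostItem]:
        n_items = int(rng.integers(spec.n_cost_items[0], spec.n_cost_items[1] + 1))
        items = []
        for i in range(n_items):
            payer = str(rng.choice(list(_CATEGORIES_BY_PAYER)))
            category = str(rng.choice(_CATEGORIES_BY_PAYER[payer]))
            qty_name = add(_gamma_quantity(
                f"qty_{arm}_{i}", float(rng.uniform(*spec.quantity_mean_range)), spec.cv))
            factors = [qty_name]
            if spec.composite_items and rng.uniform() < 0.3:
                gate = add(UncertainQuantity(
                    name=f"gate_{arm}_{i}", mean=float(rng.uniform(0.2, 0.8)),
                    dist="bernoulli", units="probability"))
                factors.insert(0, gate)
            unit = add(UncertainQuantity(
                name=f"uc_{arm}_{i}", mean=float(rng.uniform(*spec.unit_cost_range)),
                dist="fixed", units="€"))
            items.append(CostItem(
                label=f"item {arm} {i}", category=category, payer=payer,
                quantity_factors=tuple(factors), unit_cost=unit))
        return items

    items_a = make_items("a")
    items_b = items_a if identical_costs else make_items("b")

    comparator = StrategyDefinition(
        name="arm A (comparator)", cost_items=tuple(items_a),
        p_plx="p_plx_arm_a", e_with_plx="e_with_plx", e_without_plx="e_without_plx")
    treatment = StrategyDefinition(
        name="arm B (treatment)", cost_items=tuple(items_b),
        p_plx="p_plx_arm_a" if identical_costs else "p_plx_arm_b",
        e_with_plx="e_with_plx", e_without_plx="e_without_plx")

    wage_gross = float(rng.uniform(*spec.wage_range))
    return ModelConfig(
        demographics=Demographics(
            age_mean=float(rng.uniform(45, 68)), age_low=40.0, age_high=70.0,
            employed_fraction=0.5, retirement_age=70.0),
        wages=Wages(gross_hourly=wage_gross, net_hourly=0.75 * wage_gross),
        parameters=params,
        strategies=(comparator, treatment),
    )


def perturb(
    config: ModelConfig,
    rule: str,
    amount: float,
    rng: Optional[np.random.Generator] = None,
) -> ModelConfig:
    """Metamorphic transformations of a configuration.

    ``scale_costs``: multiply every unit-cost parameter by ``amount`` (> 0);
    incremental cost and the raw ICER scale by ``amount``, effectiveness is
    untouched.  ``add_common_item``: append a fixed item of cost ``amount``
    (>= 0) to both arms; incremental cost is invariant.  ``widen_cis``:
    scale every declared CI half-width by ``amount`` (>= 1) around the
    mean; 1 is the identity.
    """
    unit_refs = {item.unit_cost for strat in config.strategies for item in strat.cost_items}

    if rule == "scale_costs":
        if amount <= 0:
            raise DomainError(f"scale_costs requires a positive factor, got {amount}")
        new_params = {}
        for name, p in config.parameters.items():
            if name in unit_refs:
                new_params[name] = p.model_copy(update={
                    "mean": p.mean * amount,
                    "ci_low": None if p.ci_low is None else p.ci_low * amount,
                    "ci_high": None if p.ci_high is None else p.ci_high * amount,
                })
            else:
                new_params[name] = p
        return config.model_copy(update={"parameters": new_params})

    if rule == "add_common_item":
        if amount < 0:
            raise DomainError(f"add_common_item requires a cost >= 0, got {amount}")
        name = "uc_common_perturbation"
        if name in config.parameters:
            raise DomainError(f"parameter '{name}' already present")
        new_params = dict(config.parameters)
        new_params[name] = UncertainQuantity(name=name, mean=amount, dist="fixed", units="€")
        extra = CostItem(label="common perturbation item", category="stem_cell_handling",
                         payer="INHS", quantity_factors=(), unit_cost=name)
        new_strategies = tuple(
            s.model_copy(update={"cost_items": s.cost_items + (extra,)})
            for s in config.strategies
        )
        return config.model_copy(update={"parameters": new_params, "strategies": new_strategies})

    if rule == "widen_cis":
        if amount < 1:
            raise DomainError(f"widen_cis requires a factor >= 1, got {amount}")
        if amount == 1:
            return config  # exact identity, no float round-trip
        new_params = {}
        for name, p in config.parameters.items():
            if p.has_ci and p.dist == "gamma":
                lo = max(0.0, p.mean - (p.mean - p.ci_low) * amount)
                hi = p.mean + (p.ci_high - p.mean) * amount
                new_params[name] = p.model_copy(update={"ci_low": lo, "ci_high": hi})
            else:
                new_params[name] = p
        return config.model_copy(update={"parameters": new_params})

    raise DomainError(f"unknown perturbation rule '{rule}'")
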