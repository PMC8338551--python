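"""One-way (tornado), scenario, and probabilistic sensitivity analyses.

The probabilistic analysis is a Monte Carlo simulation (10,000 iterations
by default): each iteration draws every uncertain parameter from its
fitted distribution -- the effectiveness pair is drawn once and shared
across arms, and each parameter uses its own name-keyed substream -- and
records the incremental cost and effectiveness of the treatment.  The
cost-effectiveness acceptability curve (CEAC) reports, per
willingness-to-pay lambda, the fraction of iterations in which each
strategy has the higher net monetary benefit; the frontier (CEAF) follows
the strategy with the higher *expected* net benefit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .cea import CEAResult, compare_strategies
from .config import ModelConfig, StrategyDefinition, resolve_means
from .costing import CostBreakdown, arm_cost_breakdown, total_cost
from .distributions import fit_parameter, parameter_rng, sample
from .errors import DomainError
from .tree import evaluate_arm, mixture_effectiveness

QUADRANTS = ("NE", "NW", "SE", "SW")

DEFAULT_PSA_ITERATIONS = 10_000


# --------------------------------------------------------------------------
# Deterministic evaluation
# --------------------------------------------------------------------------

def evaluate_config(
    config: ModelConfig,
    overrides: Optional[Mapping[str, float]] = None,
    effect_override: Optional[Mapping[str, float]] = None,
    cost_override: Optional[Mapping[str, float]] = None,
    rounding: str = "unrounded",
) -> tuple[CEAResult, dict[str, CostBreakdown]]:
    """Evaluate both arms at point values and compare them.

    ``overrides`` replaces parameter values (base-case means otherwise);
    ``effect_override``/``cost_override`` map strategy names to replacement
    arm-level effectiveness or total cost (used by scenario presets whose
    underlying tariffs are not decomposable).
    """
    values = resolve_means(config)
    if overrides:
        for name, value in overrides.items():
            if name not in values:
                raise DomainError(f"override references unknown parameter '{name}'")
            values[name] = value

    costs: dict[str, float] = {}
    effects: dict[str, float] = {}
    breakdowns: dict[str, CostBreakdown] = {}
    for strat in config.strategies:
        outcome = evaluate_arm(strat, values)
        breakdown = arm_cost_breakdown(outcome, strat, values)
        breakdowns[strat.name] = breakdown
        costs[strat.name] = total_cost(breakdown, "societal")
        effects[strat.name] = outcome.effectiveness

    comp, treat = config.comparator.name, config.treatment.name
    if effect_override:
        effects.update({k: v for k, v in effect_override.items()})
    if cost_override:
        costs.update({k: v for k, v in cost_override.items()})
    result = compare_strategies(costs[comp], effects[comp], costs[treat], effects[treat], rounding)
    return result, breakdowns


# --------------------------------------------------------------------------
# One-way / tornado
# --------------------------------------------------------------------------

def one_way(config: ModelConfig, parameter: str, bound: str) -> CEAResult:
    """Re-evaluate with one parameter at its CI (or range) bound.

    Parameters shared by both arms move in both arms simultaneously; all
    other parameters stay at base case.
    """
    if parameter not in config.parameters:
        raise DomainError(f"unknown parameter '{parameter}'")
    param = config.parameters[parameter]
    if not param.has_ci:
        raise DomainError(f"parameter '{parameter}' has no declared CI or range")
    if bound not in ("low", "high"):
        raise DomainError(f"bound must be 'low' or 'high', got '{bound}'")
    value = param.ci_low if bound == "low" else param.ci_high
    result, _ = evaluate_config(config, overrides={parameter: value})
    return result


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    bound: str
    icer: Union[float, str]
    icer_ratio: Optional[float]
    pct_deviation: Optional[float]


def tornado(config: ModelConfig) -> list[TornadoEntry]:
    """One-way results at both bounds for every parameter with a CI,
    sorted widest bar (max |percent deviation| of the raw ratio) first."""
    base, _ = evaluate_config(config)
    base_ratio = base.icer_ratio

    per_param: list[tuple[float, list[TornadoEntry]]] = []
    for name, param in config.parameters.items():
        if not param.has_ci or param.ci_low == param.ci_high:
            continue
        entries = []
        for bound in ("low", "high"):
            result = one_way(config, name, bound)
            if base_ratio not in (None, 0.0) and result.icer_ratio is not None:
                pct = 100.0 * (result.icer_ratio - base_ratio) / abs(base_ratio)
            else:
                pct = None
            entries.append(TornadoEntry(name, bound, result.icer, result.icer_ratio, pct))
        width = max(abs(e.pct_deviation) for e in entries if e.pct_deviation is not None) \
            if any(e.pct_deviation is not None for e in entries) else float("inf")
        per_param.append((width, entries))

    per_param.sort(key=lambda pair: (-pair[0], pair[1][0].parameter))
    return [entry for _, entries in per_param for entry in entries]


# --------------------------------------------------------------------------
# Scenarios
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """A named structural variation of the base case.

    Arm-total cost overrides carry published totals for scenarios whose
    underlying tariff recombination is not decomposable from the available
    tables; effectiveness rules swap or equalize the arm mixtures.
    """

    name: str
    description: str
    effect_rule: Optional[str] = None           # None | "equal" | "swap"
    cost_override: Optional[dict[str, float]] = None  # arm role -> €
    rounding: str = "unrounded"


_COMP = "comparator"
_TREAT = "treatment"

SCENARIO_PRESETS: dict[str, Scenario] = {
    "same_effectiveness": Scenario(
        "same_effectiveness",
        "Both regimens assumed equally effective (comparator raised to the treatment's mixture).",
        effect_rule="equal",
    ),
    "reversed_effectiveness": Scenario(
        "reversed_effectiveness",
        "Arm effectiveness values swapped; published-table (rounded-increment) ICER arithmetic.",
        effect_rule="swap",
        rounding="printed",
    ),
    "ctx_day_hospital": Scenario(
        "ctx_day_hospital",
        "Cyclophosphamide administration costed at the day-hospital tariff for all patients.",
        cost_override={_COMP: 8438.32, _TREAT: 8708.42},
    ),
    "reversed_neutropenia_setting": Scenario(
        "reversed_neutropenia_setting",
        "Inpatient/outpatient shares for febrile neutropenia management reversed.",
        cost_override={_COMP: 9114.88},
    ),
    "cvc_for_chemo_free": Scenario(
        "cvc_for_chemo_free",
        "Central venous catheter extended to all chemotherapy-free patients undergoing apheresis.",
        cost_override={_TREAT: 8110.62},
    ),
    "outpatient_apheresis_chemo": Scenario(
        "outpatient_apheresis_chemo",
        "Outpatient apheresis for all patients on the chemotherapy-based regimen.",
        cost_override={_COMP: 9142.26},
    ),
}


def run_scenario(config: ModelConfig, scenario: Union[str, Scenario]) -> CEAResult:
    """Evaluate a named preset (or ad-hoc :class:`Scenario`) on a config."""
    if isinstance(scenario, str):
        if scenario not in SCENARIO_PRESETS:
            raise DomainError(
                f"unknown scenario preset '{scenario}'; available: {sorted(SCENARIO_PRESETS)}"
            )
        scenario = SCENARIO_PRESETS[scenario]

    base, _ = evaluate_config(config)
    comp, treat = config.comparator.name, config.treatment.name

    effect_override = None
    if scenario.effect_rule == "equal":
        effect_override = {comp: base.effect_treatment, treat: base.effect_treatment}
    elif scenario.effect_rule == "swap":
        effect_override = {comp: base.effect_treatment, treat: base.effect_comparator}
    elif scenario.effect_rule is not None:
        raise DomainError(f"unknown effect rule '{scenario.effect_rule}'")

    cost_override = None
    if scenario.cost_override:
        role_to_name = {_COMP: comp, _TREAT: treat}
        cost_override = {role_to_name[role]: v for role, v in scenario.cost_override.items()}

    result, _ = evaluate_config(
        config, effect_override=effect_override, cost_override=cost_override,
        rounding=scenario.rounding,
    )
    return result


# --------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# --------------------------------------------------------------------------

def _arm_cost_draws(strategy: StrategyDefinition, draws: Mapping[str, np.ndarray], n: int) -> np.ndarray:
    total = np.zeros(n)
    for item in strategy.cost_items:
        value = np.broadcast_to(np.asarray(draws[item.unit_cost], dtype=float), (n,)).copy()
        for factor in item.quantity_factors:
            value *= draws[factor]
        total += value
    return total


@dataclass(frozen=True)
class PSAResult:
    """Monte Carlo draws of (delta_cost, delta_effect) with quadrant labels."""

    n: int
    seed: int
    delta_cost: np.ndarray
    delta_effect: np.ndarray
    quadrant: np.ndarray  # array of "NE"/"NW"/"SE"/"SW"
    parameter_draws: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def quadrant_shares(self) -> dict[str, float]:
        return {q: float(np.count_nonzero(self.quadrant == q)) / self.n for q in QUADRANTS}

    @property
    def mean_delta_cost(self) -> float:
        return float(self.delta_cost.mean())

    @property
    def mean_delta_effect(self) -> float:
        return float(self.delta_effect.mean())


def _classify_quadrants(delta_cost: np.ndarray, delta_effect: np.ndarray) -> np.ndarray:
    # Vectorized version of cea.classify_quadrant, same boundary convention.
    south = delta_cost < 0
    out = np.where(
        delta_effect > 0,
        np.where(south, "SE", "NE"),
        np.where(delta_effect < 0, np.where(south, "SW", "NW"),
                 np.where(south, "SE", "NW")),
    )
    return out.astype("<U2")


def run_psa(config: ModelConfig, n: int = DEFAULT_PSA_ITERATIONS, seed: int = 0) -> PSAResult:
    """Monte Carlo propagation of parameter uncertainty.

    Each uncertain parameter is sampled from its fitted distribution with
    a substream derived from ``seed`` and the parameter name; ``fixed``
    parameters (unit costs, notably drug prices) stay at their means.
    Deterministic given (n, seed).
    """
    if n < 1:
        raise DomainError(f"iteration count must be >= 1, got {n}")
    draws: dict[str, np.ndarray] = {}
    for name, param in config.parameters.items():
        dist = fit_parameter(param)
        if dist.family == "fixed":
            draws[name] = np.full(n, dist.params[0])
        else:
            draws[name] = sample(dist, n, parameter_rng(seed, name))

    comp, treat = config.comparator, config.treatment
    cost_comp = _arm_cost_draws(comp, draws, n)
    cost_treat = _arm_cost_draws(treat, draws, n)
    # Effectiveness pair shared across arms: same named draws enter both mixtures.
    eff_comp = draws[comp.p_plx] * draws[comp.e_with_plx] + (1 - draws[comp.p_plx]) * draws[comp.e_without_plx]
    eff_treat = draws[treat.p_plx] * draws[treat.e_with_plx] + (1 - draws[treat.p_plx]) * draws[treat.e_without_plx]

    delta_cost = cost_treat - cost_comp
    delta_effect = eff_treat - eff_comp
    return PSAResult(
        n=n, seed=seed, delta_cost=delta_cost, delta_effect=delta_effect,
        quadrant=_classify_quadrants(delta_cost, delta_effect),
        parameter_draws=draws,
    )


# --------------------------------------------------------------------------
# CEAC / CEAF
# --------------------------------------------------------------------------

def default_lambda_grid(lambda_max: float = 100_000.0, step: float = 1_000.0) -> np.ndarray:
    """0 to lambda_max in the given step; always contains the quoted
    willingness-to-pay anchors 0, 25,000 and 40,000 €."""
    grid = np.arange(0.0, lambda_max + step / 2, step)
    return np.unique(np.concatenate([grid, [0.0, 25_000.0, 40_000.0]]))


@dataclass(frozen=True)
class AcceptabilityCurve:
    """Per-lambda acceptability probabilities and the expected-NMB frontier."""

    lambdas: np.ndarray
    p_treatment: np.ndarray
    p_comparator: np.ndarray
    frontier_strategy: tuple[str, ...]   # "treatment" or "comparator" per lambda
    frontier_probability: np.ndarray
    psa_key: tuple[int, int]             # (n, seed) of the generating run


def ceac(psa: PSAResult, lambdas: Sequence[float]) -> AcceptabilityCurve:
    """Acceptability: fraction of draws with positive incremental NMB.

    The treatment is credited when lambda*dE - dC > 0 strictly; exact ties
    go to the comparator.  The frontier picks the strategy with the higher
    mean NMB (comparator on ties) and reports that strategy's
    acceptability probability.
    """
    lambdas = np.asarray(list(lambdas), dtype=float)
    if lambdas.size == 0:
        raise DomainError("lambda grid must be non-empty")
    if np.any(lambdas < 0):
        raise DomainError("willingness-to-pay values must be >= 0")

    inmb = lambdas[:, None] * psa.delta_effect[None, :] - psa.delta_cost[None, :]
    p_treat = (inmb > 0).mean(axis=1)
    mean_inmb = lambdas * psa.mean_delta_effect - psa.mean_delta_cost
    frontier = tuple("treatment" if v > 0 else "comparator" for v in mean_inmb)
    frontier_prob = np.where(np.asarray(frontier) == "treatment", p_treat, 1.0 - p_treat)
    return AcceptabilityCurve(
        lambdas=lambdas, p_treatment=p_treat, p_comparator=1.0 - p_treat,
        frontier_strategy=frontier, frontier_probability=frontier_prob,
        psa_key=(psa.n, psa.seed),
    )


@dataclass(frozen=True)
class FrontierAnnotation:
    lambdas: np.ndarray
    strategy: tuple[str, ...]
    probability: np.ndarray
    #: Smallest grid lambda from which the treatment is optimal at every
    #: larger grid value; None when the treatment never takes the frontier.
    treatment_optimal_from: Optional[float]


def ceaf(curve: AcceptabilityCurve, psa: PSAResult) -> FrontierAnnotation:
    """Frontier annotation; the curve and run must belong together."""
    if curve.psa_key != (psa.n, psa.seed):
        raise DomainError(
            f"curve was built from PSA run {curve.psa_key}, got run {(psa.n, psa.seed)}"
        )
    is_treat = np.asarray([s == "treatment" for s in curve.frontier_strategy])
    threshold: Optional[float] = None
    if is_treat.any():
        # last index where the comparator is optimal, if any
        if is_treat.all():
            threshold = float(curve.lambdas[0])
        else:
            last_comp = np.max(np.nonzero(~is_treat))
            if last_comp + 1 < is_treat.size:
                threshold = float(curve.lambdas[last_comp + 1])
    return FrontierAnnotation(
        lambdas=curve.lambdas, strategy=curve.frontier_strategy,
        probability=curve.frontier_probability, treatment_optimal_from=threshold,
    )
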