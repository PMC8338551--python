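"""Declarative model configuration for the two-arm mobilization decision model.

A :class:`ModelConfig` describes exactly two mobilization strategies (the
comparator first, the treatment second), a flat mapping of named uncertain
parameters, demographics, and wage rates.  Every cost item is expressed as a
product of quantity factors (references into the parameter mapping) times a
unit cost (also a parameter reference), tagged with the payer who bears it:
the national health service (INHS), the patient's out-of-pocket budget, or
patient/caregiver time.

Configurations round-trip losslessly through YAML (JSON is a YAML subset, so
JSON documents load too).  Structural problems -- unknown distribution
family, missing fields, dangling parameter references -- raise
:class:`~mobcea.errors.ConfigError` at load time; semantic rule violations
(CI ordering, probability bounds, shared-effectiveness wiring) are collected
by :func:`validate` and returned as a list rather than raised.
"""

from __future__ import annotations

import hashlib
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigError

SCHEMA_VERSION = "1.0"

DistFamily = Literal["gamma", "beta", "bernoulli", "uniform", "fixed"]

Category = Literal[
    "mobilization_drugs",
    "mobilization_admin",
    "full_blood_count",
    "central_venous_catheter",
    "febrile_neutropenia",
    "transfusions",
    "apheresis_procedures",
    "missed_apheresis",
    "stem_cell_handling",
    "transportation",
    "parking",
    "productivity_loss",
    "informal_care",
]

Payer = Literal["INHS", "out_of_pocket", "patient_time"]


class UncertainQuantity(BaseModel):
    """A named model parameter: mean, optional 95% CI, distribution family.

    ``dist="fixed"`` parameters sample to their mean always; ``bernoulli``
    and ``beta`` parameters are probabilities and must live in [0, 1] (a
    rule enforced by :func:`validate`, not at construction, so that invalid
    documents can be diagnosed rather than rejected wholesale).
    """

    model_config = ConfigDict(frozen=True)

    name: str
    mean: float = Field(ge=0)
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    dist: DistFamily = "fixed"
    units: str = ""

    @property
    def has_ci(self) -> bool:
        return self.ci_low is not None and self.ci_high is not None


class CostItem(BaseModel):
    """One costed resource: (product of quantity factors) x unit cost.

    ``quantity_factors`` is an ordered list of parameter names; an empty
    list means a per-patient quantity of exactly 1.  The expected item cost
    is the product of the factor means times the unit-cost mean; in the
    probabilistic analysis each factor is sampled independently.
    """

    model_config = ConfigDict(frozen=True)

    label: str
    category: Category
    payer: Payer
    quantity_factors: tuple[str, ...] = ()
    unit_cost: str


class StrategyDefinition(BaseModel):
    """One mobilization arm: its cost items and effectiveness wiring.

    Effectiveness is a plerixafor-weighted mixture: with probability
    ``p_plx`` the patient receives on-demand plerixafor and succeeds with
    probability ``e_with_plx``, otherwise with ``e_without_plx``.  The two
    success probabilities are shared between arms by construction (same
    parameter names in one configuration).
    """

    model_config = ConfigDict(frozen=True)

    name: str
    cost_items: tuple[CostItem, ...] = ()
    p_plx: str
    e_with_plx: str
    e_without_plx: str


class Demographics(BaseModel):
    model_config = ConfigDict(frozen=True)

    age_mean: float
    age_low: float
    age_high: float
    employed_fraction: float
    retirement_age: float = 70.0


class Wages(BaseModel):
    """Hourly wage rates in euros: gross values lost work time, net values
    leisure and caregiver time."""

    model_config = ConfigDict(frozen=True)

    gross_hourly: float
    net_hourly: float


class ModelConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    schema_version: str = SCHEMA_VERSION
    currency_year: str = "€2019"
    demographics: Demographics
    wages: Wages
    parameters: dict[str, UncertainQuantity]
    strategies: tuple[StrategyDefinition, ...]

    @model_validator(mode="before")
    @classmethod
    def _fill_parameter_names(cls, data):
        # Allow terse documents where the mapping key doubles as the name.
        if isinstance(data, dict) and isinstance(data.get("parameters"), dict):
            params = {}
            for key, val in data["parameters"].items():
                if isinstance(val, dict) and "name" not in val:
                    val = {**val, "name": key}
                params[key] = val
            data = {**data, "parameters": params}
        return data

    @property
    def comparator(self) -> StrategyDefinition:
        return self.strategies[0]

    @property
    def treatment(self) -> StrategyDefinition:
        return self.strategies[1]

    def referenced_names(self) -> list[tuple[str, str]]:
        """(context, parameter-name) pairs for every reference in the config."""
        refs: list[tuple[str, str]] = []
        for strat in self.strategies:
            for attr in ("p_plx", "e_with_plx", "e_without_plx"):
                refs.append((f"strategy '{strat.name}'.{attr}", getattr(strat, attr)))
            for item in strat.cost_items:
                for factor in item.quantity_factors:
                    refs.append((f"item '{item.label}' quantity factor", factor))
                refs.append((f"item '{item.label}' unit cost", item.unit_cost))
        return refs


def resolve_means(config: ModelConfig) -> dict[str, float]:
    """Parameter name -> base-case (mean) value."""
    return {name: p.mean for name, p in config.parameters.items()}


def validate(config: ModelConfig) -> list[str]:
    """Check every semantic invariant; return violations (empty iff valid).

    Violations name the offending parameter or strategy and the rule, and
    are returned rather than raised so a configuration can be diagnosed in
    full.
    """
    violations: list[str] = []
    for name, p in config.parameters.items():
        if p.name != name:
            violations.append(f"parameter '{name}': mapping key differs from name '{p.name}'")
        if p.has_ci:
            if not (p.ci_low <= p.mean <= p.ci_high):
                violations.append(
                    f"parameter '{name}': CI ordering violated "
                    f"(requires ci_low <= mean <= ci_high, got {p.ci_low}, {p.mean}, {p.ci_high})"
                )
        elif p.ci_low is not None or p.ci_high is not None:
            violations.append(f"parameter '{name}': only one CI bound declared")
        if p.dist in ("beta", "bernoulli"):
            if not 0.0 <= p.mean <= 1.0:
                violations.append(f"parameter '{name}': {p.dist} mean {p.mean} outside [0, 1]")
            if p.has_ci and not (0.0 <= p.ci_low and p.ci_high <= 1.0):
                violations.append(f"parameter '{name}': {p.dist} CI bounds outside [0, 1]")
        if p.dist == "uniform" and not p.has_ci:
            violations.append(f"parameter '{name}': uniform distribution requires CI bounds")

    for context, ref in config.referenced_names():
        if ref not in config.parameters:
            violations.append(f"{context}: unresolved parameter reference '{ref}'")

    if len(config.strategies) != 2:
        violations.append(f"configuration must define exactly two strategies, got {len(config.strategies)}")
    else:
        comp, treat = config.strategies
        if comp.e_with_plx != treat.e_with_plx or comp.e_without_plx != treat.e_without_plx:
            violations.append(
                "strategies must share the effectiveness parameters "
                f"(got {comp.e_with_plx}/{comp.e_without_plx} vs {treat.e_with_plx}/{treat.e_without_plx})"
            )

    if not 0.0 <= config.demographics.employed_fraction <= 1.0:
        violations.append(
            f"demographics.employed_fraction {config.demographics.employed_fraction} outside [0, 1]"
        )
    return violations


def save_config(config: ModelConfig) -> str:
    """Serialize to canonical YAML (sorted keys, stable formatting)."""
    data = config.model_dump(mode="json")
    return yaml.safe_dump(data, sort_keys=True, default_flow_style=False, allow_unicode=True)


def load_config(text: str) -> ModelConfig:
    """Parse and structurally validate a YAML/JSON configuration document.

    Raises :class:`ConfigError` for malformed documents, unknown
    distribution families, missing required fields, and parameter
    references that do not resolve (the error names the reference).
    """
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - depends on yaml internals
        raise ConfigError(f"document is not valid YAML/JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError("document must be a mapping at the top level")
    try:
        config = ModelConfig.model_validate(data)
    except Exception as exc:
        raise ConfigError(f"schema error: {exc}") from exc
    for context, ref in config.referenced_names():
        if ref not in config.parameters:
            raise ConfigError(f"{context}: unresolved parameter reference '{ref}'")
    return config


def config_digest(config: ModelConfig) -> str:
    """SHA-256 digest of the canonicalized document (stable across
    field-order permutations of the source text)."""
    return hashlib.sha256(save_config(config).encode("utf-8")).hexdigest()
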