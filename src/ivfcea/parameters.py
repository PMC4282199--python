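"""Model parameters: strategy probabilities, unit costs, and config I/O.

All monetary values are euros indexed to 2013; probabilities are unitless
in [0, 1]. A :class:`ModelConfig` bundles one cost table with one or more
named transfer strategies and is the single input object every other
module consumes. Configs live in YAML (JSON is a YAML subset and is
accepted transparently); unknown keys are rejected so typos fail loudly.

Parameters are addressed by dotted paths, e.g. ``costs.diagnostic_test``
or ``strategies.eSET.p_ongoing_fresh``; the strategy segment accepts the
wildcard ``*`` to touch a field in every strategy at once (used for
quantities the underlying trial reports only once, such as the frozen
ongoing-pregnancy rate).
"""

from __future__ import annotations

import copy
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "TwinCounting",
    "StrategyParams",
    "CostTable",
    "ModelConfig",
    "ParameterLookupError",
    "load_config",
    "save_config",
    "perturb",
    "set_parameter",
    "get_parameter",
    "resolve_parameter",
    "base_case_path",
    "load_base_case",
]


class TwinCounting(str, Enum):
    """How a live twin delivery contributes to the live-birth tally."""

    DELIVERY_EVENT = "delivery_event"  # one delivery == one birth event
    CHILDREN = "children"  # a twin delivery counts two children


class ParameterLookupError(KeyError):
    """Raised when a dotted parameter path names no existing field."""


_PROB_FIELDS = frozenset(
    {
        "p_ongoing_fresh",
        "p_ongoing_frozen",
        "p_frozen_available",
        "p_twin_given_ongoing",
        "p_twin_frozen",
        "p_live_given_ongoing",
        "p_complication",
        "tested_fraction",
    }
)

#: Fresh-cycle cost components, charged to every couple entering treatment.
FRESH_CYCLE_FIELDS = (
    "medication",
    "hospital_care",
    "opu",
    "laboratory",
    "embryo_transfer",
    "admission_other",
)


class StrategyParams(BaseModel):
    """Branch probabilities and diagnostic-test uptake for one strategy.

    ``p_twin_frozen`` covers the frozen-transfer branch: frozen transfers
    are single-embryo in every strategy (no frozen double transfer is
    costed), so a double-transfer strategy needs a lower twin probability
    there; ``None`` falls back to ``p_twin_given_ongoing``.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    name: str
    p_ongoing_fresh: float
    p_ongoing_frozen: float
    p_frozen_available: float
    p_twin_given_ongoing: float
    p_twin_frozen: Optional[float] = None
    p_live_given_ongoing: float
    p_complication: float
    tested_fraction: float = 0.0
    count_twins_as: TwinCounting = TwinCounting.CHILDREN

    @field_validator(*sorted(_PROB_FIELDS))
    @classmethod
    def _in_unit_interval(cls, v, info):
        if v is None:
            return v
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{info.field_name} = {v} is outside [0, 1]")
        return v

    @property
    def twin_prob_frozen(self) -> float:
        return (
            self.p_twin_given_ongoing
            if self.p_twin_frozen is None
            else self.p_twin_frozen
        )


class CostTable(BaseModel):
    """Unit costs in euros (index year 2013).

    The six fresh-cycle components are charged once per couple; pregnancy
    strata run from week 5 to 40; delivery costs run to six weeks post
    delivery. ``frozen_cycle`` is the all-in cost of one cryo transfer
    cycle and ``diagnostic_test`` the fixed per-couple price of the
    embryo-viability test.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    medication: float
    hospital_care: float
    opu: float
    laboratory: float
    embryo_transfer: float
    admission_other: float
    frozen_cycle: float
    pregnancy_singleton_complicated: float
    pregnancy_singleton_uncomplicated: float
    pregnancy_twin_complicated: float
    pregnancy_twin_uncomplicated: float
    delivery_singleton: float
    delivery_twin: float
    diagnostic_test: float

    @model_validator(mode="after")
    def _non_negative(self) -> "CostTable":
        for name, value in self:
            if value < 0:
                raise ValueError(f"cost {name} = {value} is negative")
        return self

    @property
    def fresh_cycle_total(self) -> float:
        return sum(getattr(self, f) for f in FRESH_CYCLE_FIELDS)


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    strategies: list[StrategyParams]
    costs: CostTable
    max_cycles: int = 2
    currency_year: int = 2013
    metadata: dict = Field(default_factory=dict)

    @model_validator(mode="after")
    def _unique_names(self) -> "ModelConfig":
        names = [s.name for s in self.strategies]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate strategy names in {names}")
        if self.max_cycles not in (1, 2):
            raise ValueError(f"max_cycles must be 1 or 2, got {self.max_cycles}")
        return self

    def strategy(self, name: str) -> StrategyParams:
        for s in self.strategies:
            if s.name == name:
                return s
        raise ParameterLookupError(f"no strategy named {name!r}")

    @property
    def strategy_names(self) -> list[str]:
        return [s.name for s in self.strategies]


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a model configuration from YAML (or JSON)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return ModelConfig.model_validate(raw)


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Write a config to YAML such that :func:`load_config` round-trips."""
    payload = config.model_dump(mode="json")
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# dotted parameter paths


def _split(parameter: str) -> tuple[str, ...]:
    parts = tuple(parameter.split("."))
    if len(parts) == 2 and parts[0] == "costs":
        if parts[1] not in CostTable.model_fields:
            raise ParameterLookupError(f"unknown cost field {parts[1]!r}")
        return parts
    if len(parts) == 3 and parts[0] == "strategies":
        field = parts[2]
        if field not in StrategyParams.model_fields or field in ("name", "count_twins_as"):
            raise ParameterLookupError(f"unknown strategy field {field!r}")
        return parts
    raise ParameterLookupError(
        f"cannot parse parameter path {parameter!r}; expected "
        "'costs.<field>' or 'strategies.<name|*>.<field>'"
    )


def resolve_parameter(
    config: ModelConfig, parameter: str
) -> Iterator[tuple[BaseModel, str]]:
    """Yield (owner object, field name) pairs addressed by a dotted path."""
    parts = _split(parameter)
    if parts[0] == "costs":
        yield config.costs, parts[1]
        return
    _, which, field = parts
    matched = False
    for s in config.strategies:
        if which in ("*", s.name):
            matched = True
            yield s, field
    if not matched:
        raise ParameterLookupError(f"no strategy named {which!r}")


def get_parameter(config: ModelConfig, parameter: str) -> float:
    """Current value of a parameter (first match for wildcard paths)."""
    owner, field = next(resolve_parameter(config, parameter))
    value = getattr(owner, field)
    if field == "p_twin_frozen" and value is None:
        return owner.twin_prob_frozen
    return value


def set_parameter(config: ModelConfig, parameter: str, value: float) -> ModelConfig:
    """Return a new config with the addressed field set to ``value``."""
    new = copy.deepcopy(config)
    for owner, field in resolve_parameter(new, parameter):
        setattr(owner, field, value)
    return new


def perturb(config: ModelConfig, parameter: str, factor: float) -> ModelConfig:
    """Return a copy with the parameter multiplied by ``factor``.

    Probability fields are clipped back into [0, 1] after scaling; costs
    are left unclipped (they are validated non-negative). The input
    config is never mutated.
    """
    new = copy.deepcopy(config)
    for owner, field in resolve_parameter(new, parameter):
        current = getattr(owner, field)
        if field == "p_twin_frozen" and current is None:
            current = owner.twin_prob_frozen
        scaled = current * factor
        if field in _PROB_FIELDS:
            scaled = min(1.0, max(0.0, scaled))
        setattr(owner, field, scaled)
    return new


def base_case_path() -> Path:
    """Path of the base-case configuration shipped with the package."""
    return Path(__file__).parent / "data" / "base_case.yaml"


def load_base_case() -> ModelConfig:
    """The shipped base-case configuration (calibrated fields included)."""
    return load_config(base_case_path())
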