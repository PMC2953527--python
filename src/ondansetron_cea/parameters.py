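"""Model inputs: efficacy probabilities, unit costs, population constants, utilities.

Every quantity the model consumes is an uncertain scalar described by a
:class:`ParameterDistribution` (a point estimate plus a sensitivity range and a
sampling family).  A :class:`Scenario` bundles the full input set for one
country and is round-trippable through a YAML/JSON config document; the two
reference scenarios (US and Canada, 2006 dollars) ship as package data and are
loaded through :func:`ondansetron_cea.synthetic_scenarios.builtin_scenario`.

Probabilities are expressed as fractions in [0, 1]; costs are per-unit amounts
in the scenario's currency at the stated base year.  Internal arithmetic is
kept at full floating precision — rounding to cents happens only in reports.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import yaml

__all__ = [
    "SchemaError",
    "ValidationError",
    "DistributionKind",
    "Currency",
    "Country",
    "ParameterDistribution",
    "ArmEfficacy",
    "EfficacyTable",
    "CostTable",
    "PopulationProfile",
    "UtilitySet",
    "ExchangeRate",
    "Scenario",
    "load_scenario",
    "save_scenario",
    "adjusted_ed_cost",
    "convert_currency",
]


class SchemaError(ValueError):
    """A config document is missing a required field or has the wrong shape."""


class ValidationError(ValueError):
    """A loaded value violates a model invariant; the message names the field."""


class DistributionKind(str, enum.Enum):
    POINT = "point"
    NORMAL = "normal"
    GAMMA = "gamma"


class Currency(str, enum.Enum):
    USD = "USD"
    CAD = "CAD"


class Country(str, enum.Enum):
    US = "US"
    CANADA = "Canada"


@dataclass(frozen=True)
class ParameterDistribution:
    """Point estimate with its sensitivity range and sampling family.

    ``low``/``high`` are the bounds used in one-way sensitivity analysis
    (95% CI where the source meta-analysis provided one, otherwise +/-25%
    of the point estimate).  ``kind`` selects the microsimulation sampling
    family; ``point`` parameters never vary.
    """

    mean: float
    low: float | None = None
    high: float | None = None
    kind: DistributionKind = DistributionKind.POINT

    def __post_init__(self) -> None:
        object.__setattr__(self, "low", self.mean if self.low is None else float(self.low))
        object.__setattr__(self, "high", self.mean if self.high is None else float(self.high))
        object.__setattr__(self, "mean", float(self.mean))
        object.__setattr__(self, "kind", DistributionKind(self.kind))

    def validate(self, name: str, *, probability: bool = False) -> None:
        if not (self.low <= self.mean <= self.high):
            raise ValidationError(
                f"{name}: range ({self.low}, {self.high}) must bracket the mean {self.mean}"
            )
        if probability:
            for label, v in (("low", self.low), ("mean", self.mean), ("high", self.high)):
                if not 0.0 <= v <= 1.0:
                    raise ValidationError(f"{name}.{label}: probability {v} outside [0, 1]")
        else:
            for label, v in (("low", self.low), ("mean", self.mean), ("high", self.high)):
                if v < 0.0:
                    raise ValidationError(f"{name}.{label}: cost {v} must be >= 0")

    @property
    def sd(self) -> float:
        """Standard deviation implied by reading (low, high) as a 95% interval."""
        return max(self.high - self.low, 0.0) / (2.0 * 1.959963984540054)

    def to_dict(self) -> dict:
        return {"mean": self.mean, "low": self.low, "high": self.high, "dist": self.kind.value}

    @classmethod
    def from_dict(cls, obj: dict, name: str) -> "ParameterDistribution":
        if not isinstance(obj, dict) or "mean" not in obj:
            raise SchemaError(f"{name}: expected an object with a 'mean' key, got {obj!r}")
        try:
            return cls(
                mean=obj["mean"],
                low=obj.get("low"),
                high=obj.get("high"),
                kind=obj.get("dist", "point"),
            )
        except ValueError as exc:  # bad enum value
            raise SchemaError(f"{name}: {exc}") from exc


# Chance-node probabilities for one treatment arm, in tree order.
_ARM_FIELDS = (
    "p_vomit",
    "p_iv_given_vomit",
    "p_iv_given_no_vomit",
    "p_admit_given_iv",
    "p_revisit",
    "p_admit_at_revisit",
    "p_redose",
)


@dataclass(frozen=True)
class ArmEfficacy:
    """Per-arm event probabilities at the tree's chance nodes."""

    p_vomit: ParameterDistribution
    p_iv_given_vomit: ParameterDistribution
    p_iv_given_no_vomit: ParameterDistribution
    p_admit_given_iv: ParameterDistribution
    p_revisit: ParameterDistribution
    p_admit_at_revisit: ParameterDistribution
    p_redose: ParameterDistribution = field(
        default_factory=lambda: ParameterDistribution(0.0)
    )

    def validate(self, name: str) -> None:
        for f in _ARM_FIELDS:
            getattr(self, f).validate(f"{name}.{f}", probability=True)

    def to_dict(self) -> dict:
        return {f: getattr(self, f).to_dict() for f in _ARM_FIELDS}

    @classmethod
    def from_dict(cls, obj: dict, name: str) -> "ArmEfficacy":
        kwargs = {}
        for f in _ARM_FIELDS:
            if f == "p_redose" and f not in obj:
                continue
            if f not in obj:
                raise SchemaError(f"{name}.{f}: missing required field")
            kwargs[f] = ParameterDistribution.from_dict(obj[f], f"{name}.{f}")
        return cls(**kwargs)


@dataclass(frozen=True)
class EfficacyTable:
    """Event probabilities for both strategies (treat-all vs standard care)."""

    ondansetron: ArmEfficacy
    control: ArmEfficacy

    def validate(self) -> None:
        self.ondansetron.validate("efficacy.ondansetron")
        self.control.validate("efficacy.control")
        if self.control.p_redose.mean != 0.0:
            raise ValidationError(
                "efficacy.control.p_redose: must be identically 0 (no drug in the control arm)"
            )

    def arm(self, name: str) -> ArmEfficacy:
        return getattr(self, name)

    def to_dict(self) -> dict:
        return {"ondansetron": self.ondansetron.to_dict(), "control": self.control.to_dict()}

    @classmethod
    def from_dict(cls, obj: dict) -> "EfficacyTable":
        for arm in ("ondansetron", "control"):
            if arm not in obj:
                raise SchemaError(f"efficacy.{arm}: missing required field")
        return cls(
            ondansetron=ArmEfficacy.from_dict(obj["ondansetron"], "efficacy.ondansetron"),
            control=ArmEfficacy.from_dict(obj["control"], "efficacy.control"),
        )


_COST_FIELDS = (
    "hospitalization",
    "ed_visit_mean",
    "physician_inpatient",
    "physician_ed",
    "iv_insertion",
    "ondansetron_dose",
    "wage_per_hour",
    "special_food_ors",
    "extra_diapers",
    "travel",
)


@dataclass(frozen=True)
class CostTable:
    """Per-country unit costs (medical and nonmedical), base-year currency.

    ``ed_embedded_iv_fraction`` is the fraction of ED visits in the source
    cost data that included intravenous rehydration; the per-visit ED cost
    used at every ED encounter in the tree is the raw mean minus that
    fraction times the IV-insertion fee (see :func:`adjusted_ed_cost`),
    which avoids double-counting IV costs that the tree bills explicitly.
    """

    currency: Currency
    hospitalization: ParameterDistribution
    ed_visit_mean: ParameterDistribution
    physician_inpatient: ParameterDistribution
    physician_ed: ParameterDistribution
    iv_insertion: ParameterDistribution
    ondansetron_dose: ParameterDistribution
    wage_per_hour: ParameterDistribution
    special_food_ors: ParameterDistribution
    extra_diapers: ParameterDistribution
    travel: ParameterDistribution
    base_year: int = 2006
    ed_embedded_iv_fraction: float = 0.0

    def validate(self) -> None:
        for f in _COST_FIELDS:
            dist = getattr(self, f)
            dist.validate(f"costs.{f}")
            if dist.mean <= 0.0:
                raise ValidationError(f"costs.{f}.mean: must be strictly positive, got {dist.mean}")
        if not 0.0 <= self.ed_embedded_iv_fraction <= 1.0:
            raise ValidationError(
                f"costs.ed_embedded_iv_fraction: {self.ed_embedded_iv_fraction} outside [0, 1]"
            )

    @property
    def ed_visit_adjusted(self) -> float:
        """Per-visit ED cost with the embedded IV component removed."""
        return adjusted_ed_cost(
            self.ed_visit_mean.mean, self.iv_insertion.mean, self.ed_embedded_iv_fraction
        )

    def to_dict(self) -> dict:
        out = {
            "currency": self.currency.value,
            "base_year": self.base_year,
            "ed_embedded_iv_fraction": self.ed_embedded_iv_fraction,
        }
        out.update({f: getattr(self, f).to_dict() for f in _COST_FIELDS})
        return out

    @classmethod
    def from_dict(cls, obj: dict) -> "CostTable":
        if "currency" not in obj:
            raise SchemaError("costs.currency: missing required field")
        try:
            currency = Currency(obj["currency"])
        except ValueError as exc:
            raise ValidationError(f"costs.currency: unknown currency {obj['currency']!r}") from exc
        kwargs = {}
        for f in _COST_FIELDS:
            if f not in obj:
                raise SchemaError(f"costs.{f}: missing required field")
            kwargs[f] = ParameterDistribution.from_dict(obj[f], f"costs.{f}")
        return cls(
            currency=currency,
            base_year=int(obj.get("base_year", 2006)),
            ed_embedded_iv_fraction=float(obj.get("ed_embedded_iv_fraction", 0.0)),
            **kwargs,
        )


@dataclass(frozen=True)
class PopulationProfile:
    """Annual eligible-population constants for one country."""

    country: Country
    annual_ed_visits: int
    eligibility_fraction: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "country", Country(self.country))

    def validate(self) -> None:
        if self.annual_ed_visits < 0:
            raise ValidationError("population.annual_ed_visits: must be >= 0")
        if not 0.0 < self.eligibility_fraction <= 1.0:
            raise ValidationError(
                f"population.eligibility_fraction: {self.eligibility_fraction} outside (0, 1]"
            )

    @property
    def eligible_count(self) -> int:
        return math.floor(self.annual_ed_visits * self.eligibility_fraction)

    def to_dict(self) -> dict:
        return {
            "country": self.country.value,
            "annual_ed_visits": self.annual_ed_visits,
            "eligibility_fraction": self.eligibility_fraction,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "PopulationProfile":
        for f in ("country", "annual_ed_visits", "eligibility_fraction"):
            if f not in obj:
                raise SchemaError(f"population.{f}: missing required field")
        try:
            country = Country(obj["country"])
        except ValueError as exc:
            raise ValidationError(f"population.country: unknown country {obj['country']!r}") from exc
        return cls(
            country=country,
            annual_ed_visits=int(obj["annual_ed_visits"]),
            eligibility_fraction=float(obj["eligibility_fraction"]),
        )


@dataclass(frozen=True)
class UtilitySet:
    """Annual health-state utility weights (QALYs per patient-year).

    Moderate gastroenteritis (outpatient course, with or without IV
    rehydration) carries 0.93; severe gastroenteritis (hospitalized) 0.90.
    """

    u_moderate: float = 0.93
    u_severe: float = 0.90

    def validate(self) -> None:
        if not 0.0 <= self.u_severe <= self.u_moderate <= 1.0:
            raise ValidationError(
                f"utilities: need 0 <= severe ({self.u_severe}) <= moderate "
                f"({self.u_moderate}) <= 1"
            )

    def to_dict(self) -> dict:
        return {"moderate": self.u_moderate, "severe": self.u_severe}

    @classmethod
    def from_dict(cls, obj: dict) -> "UtilitySet":
        for f in ("moderate", "severe"):
            if f not in obj:
                raise SchemaError(f"utilities.{f}: missing required field")
        return cls(u_moderate=float(obj["moderate"]), u_severe=float(obj["severe"]))


@dataclass(frozen=True)
class ExchangeRate:
    """US dollars per Canadian dollar (2006), with its sensitivity range."""

    usd_per_cad: float = 0.88
    low: float = 0.80
    high: float = 1.00

    def validate(self) -> None:
        if self.usd_per_cad <= 0:
            raise ValidationError("exchange_rate.usd_per_cad: must be > 0")
        if not self.low <= self.usd_per_cad <= self.high:
            raise ValidationError(
                f"exchange_rate: range ({self.low}, {self.high}) must bracket "
                f"{self.usd_per_cad}"
            )

    def to_dict(self) -> dict:
        return {"usd_per_cad": self.usd_per_cad, "low": self.low, "high": self.high}

    @classmethod
    def from_dict(cls, obj: dict) -> "ExchangeRate":
        if "usd_per_cad" not in obj:
            raise SchemaError("exchange_rate.usd_per_cad: missing required field")
        return cls(
            usd_per_cad=float(obj["usd_per_cad"]),
            low=float(obj.get("low", obj["usd_per_cad"])),
            high=float(obj.get("high", obj["usd_per_cad"])),
        )


@dataclass(frozen=True)
class Scenario:
    """Complete input set for one country: efficacy, costs, population, utilities."""

    name: str
    efficacy: EfficacyTable
    costs: CostTable
    population: PopulationProfile
    utilities: UtilitySet = field(default_factory=UtilitySet)
    exchange_rate: ExchangeRate = field(default_factory=ExchangeRate)

    def validate(self) -> None:
        self.efficacy.validate()
        self.costs.validate()
        self.population.validate()
        self.utilities.validate()
        self.exchange_rate.validate()

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "efficacy": self.efficacy.to_dict(),
            "costs": self.costs.to_dict(),
            "population": self.population.to_dict(),
            "utilities": self.utilities.to_dict(),
            "exchange_rate": self.exchange_rate.to_dict(),
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "Scenario":
        for f in ("efficacy", "costs", "population"):
            if f not in obj:
                raise SchemaError(f"{f}: missing required section")
        scenario = cls(
            name=str(obj.get("name", "unnamed")),
            efficacy=EfficacyTable.from_dict(obj["efficacy"]),
            costs=CostTable.from_dict(obj["costs"]),
            population=PopulationProfile.from_dict(obj["population"]),
            utilities=(
                UtilitySet.from_dict(obj["utilities"]) if "utilities" in obj else UtilitySet()
            ),
            exchange_rate=(
                ExchangeRate.from_dict(obj["exchange_rate"])
                if "exchange_rate" in obj
                else ExchangeRate()
            ),
        )
        scenario.validate()
        return scenario


def load_scenario(config_path: Union[str, Path]) -> Scenario:
    """Load and validate a scenario from a YAML or JSON config document.

    Raises :class:`SchemaError` for missing/ill-shaped fields and
    :class:`ValidationError` (naming the offending field) for out-of-range
    values.
    """
    path = Path(config_path)
    text = path.read_text()
    obj = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(obj, dict):
        raise SchemaError(f"{path}: top level must be a mapping")
    return Scenario.from_dict(obj)


def save_scenario(scenario: Scenario, config_path: Union[str, Path]) -> None:
    """Serialize a scenario to YAML (or JSON if the path ends in .json)."""
    path = Path(config_path)
    obj = scenario.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(obj, indent=2))
    else:
        path.write_text(yaml.safe_dump(obj, sort_keys=False))


def adjusted_ed_cost(
    ed_visit_mean: float, iv_insertion: float, embedded_iv_fraction: float
) -> float:
    """ED-visit cost with the average embedded IV-insertion cost removed.

    Administrative ED cost means can already include IV rehydration for a
    fraction of visits; since the tree bills IV insertion explicitly on the
    IV branches, that embedded share is subtracted once here (floored at 0).
    """
    if ed_visit_mean < 0 or iv_insertion < 0:
        raise ValueError("adjusted_ed_cost: costs must be >= 0")
    if not 0.0 <= embedded_iv_fraction <= 1.0:
        raise ValueError(
            f"adjusted_ed_cost: embedded_iv_fraction {embedded_iv_fraction} outside [0, 1]"
        )
    return max(ed_visit_mean - embedded_iv_fraction * iv_insertion, 0.0)


def convert_currency(
    amount: float,
    from_currency: Union[Currency, str],
    to_currency: Union[Currency, str],
    rate: ExchangeRate | None = None,
) -> float:
    """Convert between 2006 CAD and USD at the scenario exchange rate."""
    if amount < 0:
        raise ValueError("convert_currency: amount must be >= 0")
    src, dst = Currency(from_currency), Currency(to_currency)
    rate = rate or ExchangeRate()
    if src == dst:
        return amount
    if src == Currency.CAD:  # CAD -> USD
        return amount * rate.usd_per_cad
    return amount / rate.usd_per_cad  # USD -> CAD
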