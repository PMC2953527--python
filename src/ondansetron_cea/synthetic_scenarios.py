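"""Reference scenarios and randomized synthetic scenario generation.

``builtin_scenario`` loads the shipped country scenarios (verbatim 2006
input tables).  ``generate_scenario`` produces structurally valid random
scenarios — control probabilities drawn uniformly, treated-arm
probabilities derived through a multiplicative effect, costs drawn
log-uniformly — so every pipeline stage can be property-tested without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import List

import numpy as np
import yaml

from .parameters import (
    ArmEfficacy,
    CostTable,
    Country,
    Currency,
    EfficacyTable,
    ExchangeRate,
    ParameterDistribution,
    PopulationProfile,
    Scenario,
    UtilitySet,
)

__all__ = ["ScenarioSpec", "generate_scenario", "builtin_scenario", "builtin_names"]

_BUILTIN = {
    "us_2006": "us_2006.yaml",
    "canada_2006": "canada_2006.yaml",
    "canada_2006_provincial_price": "canada_2006_provincial_price.yaml",
}
_BY_COUNTRY = {"US": "us_2006", "Canada": "canada_2006"}


def builtin_names() -> List[str]:
    return sorted(_BUILTIN)


def builtin_scenario(name: str = "us_2006") -> Scenario:
    """Load a shipped scenario by name ("us_2006", "canada_2006", ...) or country."""
    key = _BY_COUNTRY.get(name, name)
    if key not in _BUILTIN:
        raise KeyError(f"unknown builtin scenario {name!r}; available: {builtin_names()}")
    text = resources.files("ondansetron_cea").joinpath("data", _BUILTIN[key]).read_text()
    scenario = Scenario.from_dict(yaml.safe_load(text))
    return scenario


@dataclass(frozen=True)
class ScenarioSpec:
    """Recipe for one random scenario.

    ``arm_effect`` multiplies every control-arm probability to produce the
    treated arm (values < 1 emulate a beneficial drug); ``cost_scale`` sets
    the log-uniform magnitude of unit costs (drawn over one decade around
    it, each with a +/-25% sensitivity range).
    """

    seed: int
    probability_bounds: tuple[float, float] = (0.02, 0.6)
    cost_scale: float = 500.0
    arm_effect: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.probability_bounds
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"probability_bounds {self.probability_bounds} invalid")
        if self.cost_scale <= 0:
            raise ValueError("cost_scale must be > 0")
        if self.arm_effect < 0:
            raise ValueError("arm_effect must be >= 0")


def _prob_dist(mean: float) -> ParameterDistribution:
    lo = max(0.0, 0.75 * mean)
    hi = min(1.0, 1.25 * mean) if mean > 0 else 0.0
    kind = "normal" if mean > 0 else "point"
    return ParameterDistribution(mean=mean, low=lo, high=hi, kind=kind)


def _cost_dist(rng: np.random.Generator, scale: float) -> ParameterDistribution:
    mean = float(scale * 10 ** rng.uniform(-0.5, 0.5))
    return ParameterDistribution(mean=mean, low=0.75 * mean, high=1.25 * mean, kind="normal")


def generate_scenario(spec: ScenarioSpec) -> Scenario:
    """Seeded, reproducible random scenario satisfying all model invariants."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.probability_bounds

    control_p = {
        name: float(rng.uniform(lo, hi))
        for name in (
            "p_vomit",
            "p_iv_given_vomit",
            "p_iv_given_no_vomit",
            "p_admit_given_iv",
            "p_revisit",
            "p_admit_at_revisit",
        )
    }
    treated_p = {k: min(1.0, v * spec.arm_effect) for k, v in control_p.items()}
    treated_p["p_redose"] = float(rng.uniform(0.0, min(0.2, hi)))

    control = ArmEfficacy(
        **{k: _prob_dist(v) for k, v in control_p.items()},
        p_redose=ParameterDistribution(0.0),
    )
    treated = ArmEfficacy(**{k: _prob_dist(v) for k, v in treated_p.items()})
    efficacy = EfficacyTable(ondansetron=treated, control=control)

    costs = CostTable(
        currency=Currency.USD,
        hospitalization=_cost_dist(rng, spec.cost_scale * 10),
        ed_visit_mean=_cost_dist(rng, spec.cost_scale),
        physician_inpatient=_cost_dist(rng, spec.cost_scale),
        physician_ed=_cost_dist(rng, spec.cost_scale / 10),
        iv_insertion=_cost_dist(rng, spec.cost_scale / 2),
        ondansetron_dose=_cost_dist(rng, spec.cost_scale / 20),
        wage_per_hour=_cost_dist(rng, spec.cost_scale / 25),
        special_food_ors=_cost_dist(rng, spec.cost_scale / 20),
        extra_diapers=_cost_dist(rng, spec.cost_scale / 50),
        travel=_cost_dist(rng, spec.cost_scale / 25),
        ed_embedded_iv_fraction=float(rng.uniform(0.0, 0.3)),
    )

    u_moderate = float(rng.uniform(0.9, 1.0))
    utilities = UtilitySet(
        u_moderate=u_moderate, u_severe=max(0.0, u_moderate - float(rng.uniform(0.0, 0.1)))
    )
    population = PopulationProfile(
        country=Country.US,
        annual_ed_visits=int(rng.integers(10_000, 2_000_000)),
        eligibility_fraction=float(rng.uniform(0.05, 0.2)),
    )
    scenario = Scenario(
        name=f"synthetic_{spec.seed}",
        efficacy=efficacy,
        costs=costs,
        population=population,
        utilities=utilities,
        exchange_rate=ExchangeRate(),
    )
    scenario.validate()
    return scenario
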