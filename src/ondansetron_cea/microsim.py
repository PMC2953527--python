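"""Monte Carlo microsimulation of individual patients through the tree.

Each trial simulates one eligible child per strategy: a parameter set is
drawn from the stated uncertainty distributions (normal or moment-matched
gamma, truncated to valid support by rejection), then the child is walked
through the tree with a Bernoulli draw at each chance node.  Means over
trials estimate per-patient expected cost and QALY; the number of trials
defaults to the eligible population count of the scenario's country.

Randomness comes from numpy ``SeedSequence`` substreams, one per
(arm, parameter-or-node) pair in a fixed documented order, so a fixed seed
and configuration reproduce results bit-for-bit; the two arms use disjoint
substreams and are simulated independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .decision_model import DIAPER_UPLIFT, Arm, Perspective
from .parameters import (
    CostTable,
    DistributionKind,
    EfficacyTable,
    ParameterDistribution,
    Scenario,
    UtilitySet,
)

__all__ = ["SimulationConfig", "ArmSample", "SimulationResult", "sample_parameter", "simulate"]

# fixed substream order: efficacy parameters, cost parameters, chance nodes
_EFF_STREAMS = (
    "p_vomit",
    "p_iv_given_vomit",
    "p_iv_given_no_vomit",
    "p_admit_given_iv",
    "p_revisit",
    "p_admit_at_revisit",
    "p_redose",
)
_COST_STREAMS = (
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
_NODE_STREAMS = ("u_vomit", "u_iv", "u_admit", "u_revisit", "u_admit_revisit", "u_redose")


@dataclass(frozen=True)
class SimulationConfig:
    """Trial count, seed and parameter-uncertainty mode for one run."""

    n_trials: int
    seed: int = 0
    #: "sampled" redraws the parameter set each trial (parameter uncertainty
    #: plus patient-level chance); "point" keeps parameters at their means
    #: (pure first-order uncertainty).
    parameter_sampling: str = "sampled"

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")
        if self.parameter_sampling not in ("sampled", "point"):
            raise ValueError(
                f"parameter_sampling must be 'sampled' or 'point', got "
                f"{self.parameter_sampling!r}"
            )

    @classmethod
    def for_scenario(cls, scenario: Scenario, seed: int = 0, **kwargs) -> "SimulationConfig":
        """Default configuration: one trial per eligible child."""
        return cls(n_trials=scenario.population.eligible_count, seed=seed, **kwargs)


@dataclass(frozen=True)
class ArmSample:
    """Per-arm trial summaries."""

    arm: Arm
    mean_cost: float
    se_cost: float
    cost_interval: tuple[float, float]  # 2.5-97.5 percentile of trial costs
    mean_qaly: float


@dataclass(frozen=True)
class SimulationResult:
    """Summaries of one seeded microsimulation run."""

    control: ArmSample
    ondansetron: ArmSample
    net_savings: float
    net_savings_interval: tuple[float, float]  # normal-approximation 95% CI of the mean
    n_trials: int
    seed: int
    parameter_sampling: str
    perspective: Perspective


def _truncated_draw(
    rng: np.random.Generator,
    dist: ParameterDistribution,
    n: int,
    lower: float,
    upper: float,
) -> np.ndarray:
    """Rejection-sample ``n`` values from ``dist`` truncated to [lower, upper].

    Rejection (rather than clipping) preserves the distribution's shape on
    its valid support; a degenerate spread returns the mean.
    """
    sd = dist.sd
    if dist.kind is DistributionKind.POINT or sd <= 0.0:
        return np.full(n, dist.mean)
    if dist.kind is DistributionKind.NORMAL:
        def draw(k: int) -> np.ndarray:
            return rng.normal(dist.mean, sd, size=k)
    elif dist.kind is DistributionKind.GAMMA:
        # method-of-moments: shape*scale = mean, shape*scale^2 = sd^2
        shape = (dist.mean / sd) ** 2
        scale = sd**2 / dist.mean
        def draw(k: int) -> np.ndarray:
            return rng.gamma(shape, scale, size=k)
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown distribution kind {dist.kind}")
    values = draw(n)
    bad = (values < lower) | (values > upper)
    while bad.any():
        values[bad] = draw(int(bad.sum()))
        bad = (values < lower) | (values > upper)
    return values


def sample_parameter(
    dist: ParameterDistribution,
    rng: np.random.Generator,
    *,
    probability: bool = False,
    size: Optional[int] = None,
) -> float | np.ndarray:
    """Draw from a parameter's uncertainty distribution on its valid support.

    Probabilities are truncated to [0, 1], costs to [0, inf); ``point``
    parameters (or a zero spread) return the mean unchanged.
    """
    n = 1 if size is None else size
    upper = 1.0 if probability else np.inf
    values = _truncated_draw(rng, dist, n, 0.0, upper)
    return float(values[0]) if size is None else values


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Named, disjoint substreams in a fixed order."""
    names = [
        f"{arm}:{name}"
        for arm in ("control", "ondansetron")
        for name in (*_EFF_STREAMS, *_COST_STREAMS, *_NODE_STREAMS)
    ]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _simulate_arm(
    arm: Arm,
    streams: dict[str, np.random.Generator],
    config: SimulationConfig,
    efficacy: EfficacyTable,
    costs: CostTable,
    utilities: UtilitySet,
    perspective: Perspective,
    revisit_rate: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial (cost, qaly) arrays for one arm."""
    n = config.n_trials
    eff = efficacy.arm(arm.value)
    pfx = arm.value

    def eff_param(name: str, dist: ParameterDistribution) -> np.ndarray:
        if config.parameter_sampling == "point":
            return np.full(n, dist.mean)
        return sample_parameter(dist, streams[f"{pfx}:{name}"], probability=True, size=n)

    def cost_param(name: str) -> np.ndarray:
        dist = getattr(costs, name)
        if config.parameter_sampling == "point":
            return np.full(n, dist.mean)
        return sample_parameter(dist, streams[f"{pfx}:{name}"], size=n)

    p_vomit = eff_param("p_vomit", eff.p_vomit)
    p_iv_v = eff_param("p_iv_given_vomit", eff.p_iv_given_vomit)
    p_iv_nv = eff_param("p_iv_given_no_vomit", eff.p_iv_given_no_vomit)
    p_admit = eff_param("p_admit_given_iv", eff.p_admit_given_iv)
    revisit_dist = (
        efficacy.control.p_revisit if revisit_rate == "standard_care" else eff.p_revisit
    )
    p_revisit = eff_param("p_revisit", revisit_dist)
    p_adr = eff_param("p_admit_at_revisit", eff.p_admit_at_revisit)
    p_redose = (
        eff_param("p_redose", eff.p_redose)
        if arm is Arm.ONDANSETRON
        else np.zeros(n)
    )

    hosp = cost_param("hospitalization")
    ed_mean = cost_param("ed_visit_mean")
    phys_in = cost_param("physician_inpatient")
    phys_ed = cost_param("physician_ed")
    iv_fee = cost_param("iv_insertion")
    dose = cost_param("ondansetron_dose")
    wage = cost_param("wage_per_hour")
    food = cost_param("special_food_ors")
    diapers = cost_param("extra_diapers")
    travel = cost_param("travel")

    def uniforms(name: str) -> np.ndarray:
        return streams[f"{pfx}:{name}"].random(n)

    vomited = uniforms("u_vomit") < p_vomit
    iv = uniforms("u_iv") < np.where(vomited, p_iv_v, p_iv_nv)
    admitted = iv & (uniforms("u_admit") < p_admit)
    revisited = ~admitted & (uniforms("u_revisit") < p_revisit)
    adr = revisited & (uniforms("u_admit_revisit") < p_adr)
    redosed = (
        uniforms("u_redose") < p_redose if arm is Arm.ONDANSETRON else np.zeros(n, dtype=bool)
    )

    ed_visit = np.maximum(ed_mean - costs.ed_embedded_iv_fraction * iv_fee, 0.0)
    ed_encounter = ed_visit + phys_ed
    admission = hosp + phys_in
    cost = (
        ed_encounter
        + iv * iv_fee
        + admitted * admission
        + revisited * ed_encounter
        + adr * admission
    )
    if arm is Arm.ONDANSETRON:
        cost = cost + dose * (1.0 + redosed)

    if perspective is Perspective.SOCIETAL:
        hours = np.where(admitted, 24.0, np.where(iv, 16.0, 8.0))
        hours = hours + revisited * np.where(adr, 24.0, 8.0)
        uplift = DIAPER_UPLIFT if arm is Arm.ONDANSETRON else 1.0
        cost = cost + food + travel + diapers * uplift + wage * hours

    qaly = np.where(admitted | adr, utilities.u_severe, utilities.u_moderate)
    return cost, qaly


def _summarize(arm: Arm, cost: np.ndarray, qaly: np.ndarray) -> ArmSample:
    n = cost.size
    se = float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    lo, hi = np.percentile(cost, [2.5, 97.5])
    return ArmSample(
        arm=arm,
        mean_cost=float(cost.mean()),
        se_cost=se,
        cost_interval=(float(lo), float(hi)),
        mean_qaly=float(qaly.mean()),
    )


def simulate(
    config: SimulationConfig,
    efficacy: EfficacyTable,
    costs: CostTable,
    utilities: UtilitySet,
    perspective: Perspective = Perspective.HEALTH_CARE,
    *,
    revisit_rate: str = "standard_care",
    return_trials: bool = False,
) -> SimulationResult | tuple[SimulationResult, pd.DataFrame]:
    """Run the seeded microsimulation for both arms.

    Returns per-arm mean cost with standard error and a 2.5-97.5 percentile
    interval of trial costs, mean QALY weights, and the net savings
    (control minus ondansetron) with a normal-approximation 95% CI of the
    mean.  With ``return_trials=True`` the per-trial cost table is returned
    as a second value.
    """
    perspective = Perspective(perspective)
    streams = _streams(config.seed)
    cost_c, qaly_c = _simulate_arm(
        Arm.CONTROL, streams, config, efficacy, costs, utilities, perspective, revisit_rate
    )
    cost_o, qaly_o = _simulate_arm(
        Arm.ONDANSETRON, streams, config, efficacy, costs, utilities, perspective, revisit_rate
    )
    control = _summarize(Arm.CONTROL, cost_c, qaly_c)
    treated = _summarize(Arm.ONDANSETRON, cost_o, qaly_o)
    net = control.mean_cost - treated.mean_cost
    se_net = float(np.hypot(control.se_cost, treated.se_cost))
    result = SimulationResult(
        control=control,
        ondansetron=treated,
        net_savings=net,
        net_savings_interval=(net - 1.96 * se_net, net + 1.96 * se_net),
        n_trials=config.n_trials,
        seed=config.seed,
        parameter_sampling=config.parameter_sampling,
        perspective=perspective,
    )
    if return_trials:
        trials = pd.DataFrame(
            {
                "trial": np.arange(config.n_trials),
                "cost_control": cost_c,
                "cost_ondansetron": cost_o,
                "qaly_control": qaly_c,
                "qaly_ondansetron": qaly_o,
            }
        )
        return result, trials
    return result
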