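"""The two-strategy decision tree: path enumeration, payoffs, expected values.

The model compares routine single-dose oral ondansetron (on top of oral
rehydration therapy) against standard care for a child presenting to the ED
with gastroenteritis, vomiting and dehydration.  Chance nodes fire in tree
order:

    vomit -> IV rehydration (conditional on vomiting status)
          -> hospital admission (conditional on IV; admission without IV
             does not occur at the index visit)
          -> ED revisit (discharged patients only)
          -> admission at the revisit (conditional on revisiting)

plus, in the ondansetron arm only, an independent "vomited the initial dose"
branch that dispenses a second dose without altering efficacy.

Revisit-rate convention
-----------------------
By default the probability of a repeat ED visit is treated as a property of
post-discharge care, not of the single ED dose of antiemetic, and both arms
use the standard-care estimate (``revisit_rate="standard_care"``); what
happens *at* the revisit (admission) stays arm-specific.  Pass
``revisit_rate="arm"`` to use each arm's own revisit estimate instead.  The
rationale and its consequences for reproducing published totals are laid out
in the methods note.

Payoffs per terminal path (health-care perspective): an adjusted ED-visit
cost plus ED physician fee at every ED encounter; IV insertion on IV
branches; hospitalization plus inpatient physician fee per admission (index
or revisit); the dose price (doubled on the redose branch) in the treated
arm.  The societal perspective adds caregiver lost wages under the
8/16/24-hour rule per episode, special food/ORS, travel, and diapers (33%
higher with ondansetron, reflecting its transient increase in diarrhea).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, replace
from itertools import product
from pathlib import Path
from typing import Iterable, List, Union

import pandas as pd

from .parameters import (
    ArmEfficacy,
    CostTable,
    Country,
    Currency,
    EfficacyTable,
    UtilitySet,
)

__all__ = [
    "Arm",
    "Perspective",
    "TerminalPath",
    "EvaluationResult",
    "enumerate_paths",
    "work_hours",
    "path_cost",
    "path_qaly",
    "evaluate_tree",
    "expected_values",
    "net_savings",
    "oracle_expected_values",
    "paths_to_dataframe",
    "write_paths",
]

#: ondansetron's transient diarrhea increase, applied to diaper costs
DIAPER_UPLIFT = 1.33


class Arm(str, enum.Enum):
    ONDANSETRON = "ondansetron"
    CONTROL = "control"


class Perspective(str, enum.Enum):
    HEALTH_CARE = "health_care"
    SOCIETAL = "societal"


@dataclass(frozen=True)
class TerminalPath:
    """One root-to-leaf outcome combination with its probability and payoffs."""

    vomited: bool
    iv_in_ed: bool
    admitted: bool
    revisited: bool
    admitted_at_revisit: bool
    redosed: bool
    probability: float
    cost_medical: float = 0.0
    cost_nonmedical: float = 0.0
    qaly: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"path probability {self.probability} outside [0, 1]")
        if self.admitted and not self.iv_in_ed:
            raise ValueError("admission at the index visit implies IV rehydration in the ED")
        if self.admitted_at_revisit and not self.revisited:
            raise ValueError("admission at revisit implies a revisit")
        if self.admitted and self.revisited:
            raise ValueError("patients admitted at the index visit do not revisit")


@dataclass(frozen=True)
class EvaluationResult:
    """Per-arm expected payoffs for one perspective and country."""

    arm: Arm
    perspective: Perspective
    expected_cost_per_patient: float
    expected_qaly_per_patient: float
    country: Country


def _resolve_revisit(arm_eff: ArmEfficacy, efficacy: EfficacyTable, revisit_rate: str) -> float:
    if revisit_rate == "standard_care":
        return efficacy.control.p_revisit.mean
    if revisit_rate == "arm":
        return arm_eff.p_revisit.mean
    raise ValueError(f"revisit_rate must be 'standard_care' or 'arm', got {revisit_rate!r}")


def enumerate_paths(
    arm: Arm,
    efficacy: EfficacyTable,
    *,
    revisit_rate: str = "standard_care",
) -> List[TerminalPath]:
    """All terminal paths for one strategy at point estimates (probabilities only).

    Paths are mutually exclusive and exhaustive; zero-probability branches
    are pruned, so their probabilities sum to exactly 1.
    """
    arm = Arm(arm)
    eff = efficacy.arm(arm.value)
    p_rv = _resolve_revisit(eff, efficacy, revisit_rate)
    p_rd = eff.p_redose.mean if arm is Arm.ONDANSETRON else 0.0

    for name in ("p_vomit", "p_iv_given_vomit", "p_iv_given_no_vomit", "p_admit_given_iv",
                 "p_admit_at_revisit"):
        p = getattr(eff, name).mean
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{arm.value}.{name}: probability {p} outside [0, 1]")
    if not 0.0 <= p_rv <= 1.0 or not 0.0 <= p_rd <= 1.0:
        raise ValueError("revisit/redose probability outside [0, 1]")

    def branch(p: float) -> list[tuple[bool, float]]:
        # prune zero-probability sides so degenerate trees collapse cleanly
        out = []
        if p > 0.0:
            out.append((True, p))
        if p < 1.0:
            out.append((False, 1.0 - p))
        return out

    paths: List[TerminalPath] = []
    for vomited, p_v in branch(eff.p_vomit.mean):
        p_iv = eff.p_iv_given_vomit.mean if vomited else eff.p_iv_given_no_vomit.mean
        for iv, p_i in branch(p_iv):
            admit_opts = branch(eff.p_admit_given_iv.mean) if iv else [(False, 1.0)]
            for admitted, p_a in admit_opts:
                if admitted:
                    tail_opts: list[tuple[bool, bool, float]] = [(False, False, 1.0)]
                else:
                    tail_opts = []
                    for revisited, p_r in branch(p_rv):
                        if revisited:
                            for adr, p_ar in branch(eff.p_admit_at_revisit.mean):
                                tail_opts.append((True, adr, p_r * p_ar))
                        else:
                            tail_opts.append((False, False, p_r))
                for revisited, adr, p_tail in tail_opts:
                    for redosed, p_rd_b in branch(p_rd) if arm is Arm.ONDANSETRON else [(False, 1.0)]:
                        paths.append(
                            TerminalPath(
                                vomited=vomited,
                                iv_in_ed=iv,
                                admitted=admitted,
                                revisited=revisited,
                                admitted_at_revisit=adr,
                                redosed=redosed,
                                probability=p_v * p_i * p_a * p_tail * p_rd_b,
                            )
                        )
    return paths


def work_hours(path: TerminalPath) -> float:
    """Caregiver work hours lost, by episode.

    Index visit: 8 h for an outpatient course without IV, 16 h with IV but
    no admission, 24 h if admitted.  A revisit adds a second episode's hours
    under the same rule (8 h if discharged again, 24 h if admitted then).
    """
    if path.admitted:
        hours = 24.0
    elif path.iv_in_ed:
        hours = 16.0
    else:
        hours = 8.0
    if path.revisited:
        hours += 24.0 if path.admitted_at_revisit else 8.0
    return hours


def path_cost(
    path: TerminalPath,
    costs: CostTable,
    arm: Arm,
    perspective: Perspective = Perspective.HEALTH_CARE,
) -> float:
    """Accrued cost of one terminal path under the given perspective."""
    medical, nonmedical = path_cost_components(path, costs, arm)
    if Perspective(perspective) is Perspective.HEALTH_CARE:
        return medical
    return medical + nonmedical


def path_cost_components(
    path: TerminalPath, costs: CostTable, arm: Arm
) -> tuple[float, float]:
    """(medical, nonmedical) cost components of one terminal path."""
    arm = Arm(arm)
    ed_encounter = costs.ed_visit_adjusted + costs.physician_ed.mean
    admission = costs.hospitalization.mean + costs.physician_inpatient.mean

    medical = ed_encounter
    if path.iv_in_ed:
        medical += costs.iv_insertion.mean
    if path.admitted:
        medical += admission
    if path.revisited:
        medical += ed_encounter
        if path.admitted_at_revisit:
            medical += admission
    if arm is Arm.ONDANSETRON:
        medical += costs.ondansetron_dose.mean * (2.0 if path.redosed else 1.0)

    diaper = costs.extra_diapers.mean * (DIAPER_UPLIFT if arm is Arm.ONDANSETRON else 1.0)
    nonmedical = (
        costs.special_food_ors.mean
        + costs.travel.mean
        + diaper
        + costs.wage_per_hour.mean * work_hours(path)
    )
    return medical, nonmedical


def path_qaly(path: TerminalPath, utilities: UtilitySet) -> float:
    """Annual QALY weight: severe if hospitalized at either visit, else moderate."""
    if path.admitted or path.admitted_at_revisit:
        return utilities.u_severe
    return utilities.u_moderate


def evaluate_tree(
    arm: Arm,
    efficacy: EfficacyTable,
    costs: CostTable,
    utilities: UtilitySet,
    *,
    revisit_rate: str = "standard_care",
) -> List[TerminalPath]:
    """Enumerate one arm's paths and attach cost and QALY payoffs."""
    arm = Arm(arm)
    out = []
    for path in enumerate_paths(arm, efficacy, revisit_rate=revisit_rate):
        medical, nonmedical = path_cost_components(path, costs, arm)
        out.append(
            replace(
                path,
                cost_medical=medical,
                cost_nonmedical=nonmedical,
                qaly=path_qaly(path, utilities),
            )
        )
    return out


def _country_of(costs: CostTable) -> Country:
    return Country.US if costs.currency is Currency.USD else Country.CANADA


def expected_values(
    arm: Arm,
    efficacy: EfficacyTable,
    costs: CostTable,
    utilities: UtilitySet,
    perspective: Perspective = Perspective.HEALTH_CARE,
    *,
    revisit_rate: str = "standard_care",
) -> EvaluationResult:
    """Probability-weighted expected cost and QALY per patient for one arm."""
    perspective = Perspective(perspective)
    paths = evaluate_tree(arm, efficacy, costs, utilities, revisit_rate=revisit_rate)
    total_p = sum(p.probability for p in paths)
    if abs(total_p - 1.0) > 1e-9:
        raise AssertionError(f"path probabilities sum to {total_p}, not 1")
    cost = sum(
        p.probability
        * (p.cost_medical + (p.cost_nonmedical if perspective is Perspective.SOCIETAL else 0.0))
        for p in paths
    )
    qaly = sum(p.probability * p.qaly for p in paths)
    return EvaluationResult(
        arm=Arm(arm),
        perspective=perspective,
        expected_cost_per_patient=cost,
        expected_qaly_per_patient=qaly,
        country=_country_of(costs),
    )


def net_savings(
    efficacy: EfficacyTable,
    costs: CostTable,
    utilities: UtilitySet,
    perspective: Perspective = Perspective.HEALTH_CARE,
    *,
    revisit_rate: str = "standard_care",
) -> float:
    """Expected cost(control) - expected cost(ondansetron); negative means net cost."""
    kwargs = dict(revisit_rate=revisit_rate)
    control = expected_values(Arm.CONTROL, efficacy, costs, utilities, perspective, **kwargs)
    treated = expected_values(Arm.ONDANSETRON, efficacy, costs, utilities, perspective, **kwargs)
    return control.expected_cost_per_patient - treated.expected_cost_per_patient


# ---------------------------------------------------------------------------
# Independent brute-force oracle (used only by the test suite).
# ---------------------------------------------------------------------------

def oracle_expected_values(
    arm: Arm,
    efficacy: EfficacyTable,
    costs: CostTable,
    utilities: UtilitySet,
    perspective: Perspective = Perspective.HEALTH_CARE,
    *,
    revisit_rate: str = "standard_care",
) -> EvaluationResult:
    """Expected values by exhaustive if-chain enumeration of every flag combo.

    Deliberately shares no code with :func:`enumerate_paths` /
    :func:`path_cost`; impossible flag combinations receive probability 0.
    """
    arm = Arm(arm)
    e = efficacy.ondansetron if arm is Arm.ONDANSETRON else efficacy.control
    pv = e.p_vomit.mean
    piv_v = e.p_iv_given_vomit.mean
    piv_nv = e.p_iv_given_no_vomit.mean
    pad = e.p_admit_given_iv.mean
    if revisit_rate == "standard_care":
        prv = efficacy.control.p_revisit.mean
    else:
        prv = e.p_revisit.mean
    padr = e.p_admit_at_revisit.mean
    prd = e.p_redose.mean if arm is Arm.ONDANSETRON else 0.0

    ed_visit = costs.ed_visit_mean.mean - costs.ed_embedded_iv_fraction * costs.iv_insertion.mean
    if ed_visit < 0.0:
        ed_visit = 0.0

    total_cost = 0.0
    total_qaly = 0.0
    total_prob = 0.0
    for vomited, iv, admitted, revisited, adr, redosed in product([True, False], repeat=6):
        # --- probability ---
        if admitted and not iv:
            continue
        if adr and not revisited:
            continue
        if revisited and admitted:
            continue
        if redosed and arm is not Arm.ONDANSETRON:
            continue
        prob = pv if vomited else (1.0 - pv)
        if vomited:
            prob *= piv_v if iv else (1.0 - piv_v)
        else:
            prob *= piv_nv if iv else (1.0 - piv_nv)
        if iv:
            prob *= pad if admitted else (1.0 - pad)
        if not admitted:
            prob *= prv if revisited else (1.0 - prv)
        if revisited:
            prob *= padr if adr else (1.0 - padr)
        if arm is Arm.ONDANSETRON:
            prob *= prd if redosed else (1.0 - prd)
        if prob == 0.0:
            continue

        # --- medical cost ---
        cost = ed_visit + costs.physician_ed.mean
        if iv:
            cost += costs.iv_insertion.mean
        if admitted:
            cost += costs.hospitalization.mean + costs.physician_inpatient.mean
        if revisited:
            cost += ed_visit + costs.physician_ed.mean
        if adr:
            cost += costs.hospitalization.mean + costs.physician_inpatient.mean
        if arm is Arm.ONDANSETRON:
            if redosed:
                cost += 2.0 * costs.ondansetron_dose.mean
            else:
                cost += costs.ondansetron_dose.mean

        # --- nonmedical cost ---
        if Perspective(perspective) is Perspective.SOCIETAL:
            if admitted:
                hours = 24.0
            elif iv:
                hours = 16.0
            else:
                hours = 8.0
            if revisited:
                if adr:
                    hours += 24.0
                else:
                    hours += 8.0
            cost += costs.wage_per_hour.mean * hours
            cost += costs.special_food_ors.mean + costs.travel.mean
            if arm is Arm.ONDANSETRON:
                cost += costs.extra_diapers.mean * 1.33
            else:
                cost += costs.extra_diapers.mean

        if admitted or adr:
            weight = utilities.u_severe
        else:
            weight = utilities.u_moderate

        total_prob += prob
        total_cost += prob * cost
        total_qaly += prob * weight

    assert abs(total_prob - 1.0) < 1e-9
    return EvaluationResult(
        arm=arm,
        perspective=Perspective(perspective),
        expected_cost_per_patient=total_cost,
        expected_qaly_per_patient=total_qaly,
        country=_country_of(costs),
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def paths_to_dataframe(paths: Iterable[TerminalPath]) -> pd.DataFrame:
    """One row per terminal path: flags, probability, payoff components."""
    return pd.DataFrame(
        {
            "vomited": p.vomited,
            "iv_in_ed": p.iv_in_ed,
            "admitted": p.admitted,
            "revisited": p.revisited,
            "admitted_at_revisit": p.admitted_at_revisit,
            "redosed": p.redosed,
            "probability": p.probability,
            "cost_medical": p.cost_medical,
            "cost_nonmedical": p.cost_nonmedical,
            "qaly": p.qaly,
        }
        for p in paths
    )


def write_paths(
    paths: Iterable[TerminalPath], out_path: Union[str, Path], fmt: str = "csv"
) -> None:
    """Write a per-path table as CSV or JSON records."""
    frame = paths_to_dataframe(paths)
    out_path = Path(out_path)
    if fmt == "csv":
        frame.to_csv(out_path, index=False)
    elif fmt == "json":
        out_path.write_text(json.dumps(frame.to_dict(orient="records"), indent=2))
    else:
        raise ValueError(f"unknown format {fmt!r}")
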