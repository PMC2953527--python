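"""Tree enumeration, payoff accrual and expected-value rollback."""

from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ondansetron_cea import (
    Arm,
    ArmEfficacy,
    EfficacyTable,
    ParameterDistribution,
    Perspective,
    TerminalPath,
    UtilitySet,
    enumerate_paths,
    expected_values,
    net_savings,
    path_cost,
    path_qaly,
    work_hours,
)
from ondansetron_cea.decision_model import oracle_expected_values, paths_to_dataframe
from ondansetron_cea.synthetic_scenarios import ScenarioSpec, generate_scenario


def _arm(probs: dict) -> ArmEfficacy:
    defaults = dict(
        p_vomit=0.0, p_iv_given_vomit=0.0, p_iv_given_no_vomit=0.0,
        p_admit_given_iv=0.0, p_revisit=0.0, p_admit_at_revisit=0.0, p_redose=0.0,
    )
    defaults.update(probs)
    return ArmEfficacy(**{k: ParameterDistribution(v) for k, v in defaults.items()})


def _table(ond: dict, ctl: dict) -> EfficacyTable:
    return EfficacyTable(ondansetron=_arm(ond), control=_arm(ctl))


def _path(**flags) -> TerminalPath:
    base = dict(vomited=False, iv_in_ed=False, admitted=False, revisited=False,
                admitted_at_revisit=False, redosed=False, probability=1.0)
    base.update(flags)
    return TerminalPath(**base)


class TestEnumeratePaths:
    def test_total_iv_probability_both_arms(self, us):
        # law of total probability over vomiting status at the index visit
        for arm, expected in ((Arm.CONTROL, 0.36 * 0.47 + 0.64 * 0.15),
                              (Arm.ONDANSETRON, 0.15 * 0.41 + 0.85 * 0.04)):
            paths = enumerate_paths(arm, us.efficacy)
            p_iv = sum(p.probability for p in paths if p.iv_in_ed)
            assert p_iv == pytest.approx(expected, abs=1e-12)

    def test_probabilities_sum_to_one(self, us, canada):
        for scenario in (us, canada):
            for arm in Arm:
                for convention in ("standard_care", "arm"):
                    total = sum(
                        p.probability
                        for p in enumerate_paths(arm, scenario.efficacy,
                                                 revisit_rate=convention)
                    )
                    assert total == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_tree_collapses_to_single_path(self):
        table = _table({}, {})
        for arm in Arm:
            paths = enumerate_paths(arm, table)
            assert len(paths) == 1
            p = paths[0]
            assert p.probability == 1.0
            assert not (p.vomited or p.iv_in_ed or p.admitted or p.revisited)

    def test_structural_invariants(self, us):
        for arm in Arm:
            for p in enumerate_paths(arm, us.efficacy):
                if p.admitted:
                    assert p.iv_in_ed and not p.revisited
                if p.admitted_at_revisit:
                    assert p.revisited
                if p.redosed:
                    assert arm is Arm.ONDANSETRON

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            enumerate_paths(Arm.CONTROL, _table({}, {"p_vomit": 1.3}))

    @settings(derandomize=True, max_examples=60)
    @given(probs=st.lists(st.floats(0, 1), min_size=7, max_size=7))
    def test_normalization_property(self, probs):
        names = ("p_vomit", "p_iv_given_vomit", "p_iv_given_no_vomit",
                 "p_admit_given_iv", "p_revisit", "p_admit_at_revisit", "p_redose")
        ond = dict(zip(names, probs))
        ctl = {k: v for k, v in ond.items() if k != "p_redose"}
        table = _table(ond, ctl)
        for arm in Arm:
            total = sum(p.probability for p in enumerate_paths(arm, table))
            assert total == pytest.approx(1.0, abs=1e-12)


class TestWorkHours:
    @pytest.mark.parametrize(
        "flags, hours",
        [
            (dict(), 8),
            (dict(iv_in_ed=True), 16),
            (dict(iv_in_ed=True, admitted=True), 24),
            (dict(revisited=True), 16),  # 8 + 8 for the second discharge
            (dict(iv_in_ed=True, revisited=True, admitted_at_revisit=True), 16 + 24),
        ],
    )
    def test_episode_rule(self, flags, hours):
        assert work_hours(_path(**flags)) == hours


class TestPathPayoffs:
    def test_no_event_control_health_care(self, us):
        # adjusted ED visit (704 - 0.25*194 = 655.50) plus the ED physician fee
        cost = path_cost(_path(), us.costs, Arm.CONTROL)
        assert cost == pytest.approx(655.50 + 61.31)

    def test_redose_adds_two_dose_prices(self, us):
        cost = path_cost(_path(redosed=True), us.costs, Arm.ONDANSETRON)
        assert cost == pytest.approx(716.81 + 2 * 26.57)

    def test_diaper_uplift_ratio(self, us):
        from ondansetron_cea.decision_model import path_cost_components

        _, ond = path_cost_components(_path(), us.costs, Arm.ONDANSETRON)
        _, ctl = path_cost_components(_path(), us.costs, Arm.CONTROL)
        diaper_ond = ond - us.costs.special_food_ors.mean - us.costs.travel.mean \
            - us.costs.wage_per_hour.mean * 8
        diaper_ctl = ctl - us.costs.special_food_ors.mean - us.costs.travel.mean \
            - us.costs.wage_per_hour.mean * 8
        assert diaper_ond / diaper_ctl == pytest.approx(1.33)

    def test_societal_adds_nonmedical(self, us):
        p = _path(iv_in_ed=True)
        hc = path_cost(p, us.costs, Arm.CONTROL, Perspective.HEALTH_CARE)
        soc = path_cost(p, us.costs, Arm.CONTROL, Perspective.SOCIETAL)
        assert soc == pytest.approx(
            hc + 24 + 19 + 9 + 19.29 * 16
        )

    @pytest.mark.parametrize(
        "flags, utility",
        [
            (dict(), 0.93),
            (dict(iv_in_ed=True), 0.93),  # IV without admission stays moderate
            (dict(iv_in_ed=True, admitted=True), 0.90),
            (dict(revisited=True, admitted_at_revisit=True), 0.90),
        ],
    )
    def test_qaly_weights(self, flags, utility):
        assert path_qaly(_path(**flags), UtilitySet()) == utility


class TestExpectedValues:
    def test_us_control_cost_magnitude(self, us):
        ev = expected_values(Arm.CONTROL, us.efficacy, us.costs, us.utilities)
        assert 1400 < ev.expected_cost_per_patient < 1800

    def test_single_path_tree_cost_is_no_event_cost(self, us):
        table = _table({}, {})
        ev = expected_values(Arm.CONTROL, table, us.costs, us.utilities)
        assert ev.expected_cost_per_patient == pytest.approx(716.81)

    def test_societal_at_least_health_care(self, us, canada):
        for scenario in (us, canada):
            for arm in Arm:
                hc = expected_values(arm, scenario.efficacy, scenario.costs,
                                     scenario.utilities, Perspective.HEALTH_CARE)
                soc = expected_values(arm, scenario.efficacy, scenario.costs,
                                      scenario.utilities, Perspective.SOCIETAL)
                assert soc.expected_cost_per_patient >= hc.expected_cost_per_patient

    def test_identical_arms_and_free_drug_yield_zero_savings(self, us):
        efficacy = EfficacyTable(
            ondansetron=replace(us.efficacy.control,
                                p_redose=ParameterDistribution(0.0)),
            control=us.efficacy.control,
        )
        costs = replace(us.costs, ondansetron_dose=ParameterDistribution(1e-12, 1e-12, 1e-12))
        savings = net_savings(efficacy, costs, us.utilities)
        assert savings == pytest.approx(0.0, abs=1e-9)

    def test_increasing_unit_cost_raises_both_arms(self, us):
        bigger = replace(
            us.costs, hospitalization=ParameterDistribution(9000, 9000, 9000)
        )
        for arm in Arm:
            low = expected_values(arm, us.efficacy, us.costs, us.utilities)
            high = expected_values(arm, us.efficacy, bigger, us.utilities)
            assert high.expected_cost_per_patient > low.expected_cost_per_patient

    def test_hospital_cost_increase_raises_savings_when_control_admits_more(self, us):
        bigger = replace(
            us.costs, hospitalization=ParameterDistribution(9000, 9000, 9000)
        )
        assert net_savings(us.efficacy, bigger, us.utilities) > net_savings(
            us.efficacy, us.costs, us.utilities
        )


class TestOracleEquivalence:
    def test_matches_tree_walker_on_randomized_scenarios(self):
        worst = 0.0
        for seed in range(100):
            sc = generate_scenario(ScenarioSpec(seed=seed, arm_effect=0.3 + (seed % 7) / 10))
            for arm in Arm:
                for persp in Perspective:
                    ev = expected_values(arm, sc.efficacy, sc.costs, sc.utilities, persp)
                    ov = oracle_expected_values(arm, sc.efficacy, sc.costs,
                                                sc.utilities, persp)
                    worst = max(worst, abs(ev.expected_cost_per_patient
                                           - ov.expected_cost_per_patient))
                    worst = max(worst, abs(ev.expected_qaly_per_patient
                                           - ov.expected_qaly_per_patient))
        assert worst < 1e-9

    def test_degenerate_scenario_equals_no_event_cost(self, us):
        table = _table({}, {})
        ov = oracle_expected_values(Arm.CONTROL, table, us.costs, us.utilities)
        assert ov.expected_cost_per_patient == pytest.approx(716.81)


class TestExport:
    def test_path_frame_columns_and_mass(self, us):
        from ondansetron_cea.decision_model import evaluate_tree

        frame = paths_to_dataframe(
            evaluate_tree(Arm.ONDANSETRON, us.efficacy, us.costs, us.utilities)
        )
        assert frame["probability"].sum() == pytest.approx(1.0, abs=1e-12)
        assert {"vomited", "probability", "cost_medical", "cost_nonmedical",
                "qaly"} <= set(frame.columns)
        assert (frame["cost_medical"] >= 0).all()
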