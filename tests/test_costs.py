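"""Vial arithmetic and per-state quarterly cost construction."""

import dataclasses

import pytest
from hypothesis import given, strategies as st

from mcrc_cea import (
    AdverseEvent,
    AdverseEventProfile,
    DoseSchedule,
    ValidationError,
    cost_per_administration,
    expected_ae_cost,
    moab_cycle_cost,
    state_cycle_costs,
    total_dose,
    vials_per_administration,
)


class TestDoseArithmetic:
    def test_cetuximab_total_dose(self, base_case):
        assert total_dose(base_case.costs["cetuximab"].dose_schedule) == pytest.approx(875.0)

    def test_panitumumab_total_dose(self, base_case):
        assert total_dose(base_case.costs["panitumumab"].dose_schedule) == pytest.approx(420.0)

    def test_zero_dose_rejected(self):
        with pytest.raises(ValidationError):
            DoseSchedule(dose_basis="per_weight", dose=0.0, vial_unit_price=1.0)


class TestVialCeiling:
    @pytest.mark.parametrize(
        "dose,vial,expected", [(875, 100, 9), (420, 100, 5), (400, 100, 4), (1, 100, 1)]
    )
    def test_examples(self, dose, vial, expected):
        assert vials_per_administration(dose, vial) == expected

    @given(
        dose=st.decimals(min_value="0.1", max_value="100000", places=2).map(float),
        vial=st.decimals(min_value="0.5", max_value="1000", places=2).map(float),
    )
    def test_ceiling_property(self, dose, vial):
        count = vials_per_administration(dose, vial)
        assert count * vial >= dose
        assert (count - 1) * vial < dose


class TestDrugCosts:
    def test_cetuximab_cost_per_application(self, base_case):
        # 9 vials x $166.70
        cost = cost_per_administration(base_case.costs["cetuximab"].dose_schedule)
        assert cost == pytest.approx(1500.30, abs=1e-9)

    def test_panitumumab_cost_per_application(self, base_case):
        # 5 vials x $270.43 = 1352.15 (the published table prints 1352.11)
        cost = cost_per_administration(base_case.costs["panitumumab"].dose_schedule)
        assert cost == pytest.approx(1352.15, abs=1e-9)

    def test_cetuximab_quarterly_drug_cost(self, base_case):
        cost = moab_cycle_cost(base_case.costs["cetuximab"].dose_schedule)
        assert cost == pytest.approx(9001.80, abs=1e-9)

    def test_free_vials_cost_nothing(self, base_case):
        schedule = dataclasses.replace(
            base_case.costs["cetuximab"].dose_schedule, vial_unit_price=0.0
        )
        assert moab_cycle_cost(schedule) == 0.0

    def test_cycle_cost_linear_in_vial_price(self, base_case):
        # linearity makes the ICER monotone in price, so the threshold
        # search is well-posed
        schedule = base_case.costs["cetuximab"].dose_schedule
        base = moab_cycle_cost(schedule)
        for factor in (0.25, 0.5, 2.0):
            scaled = dataclasses.replace(schedule, vial_unit_price=schedule.vial_unit_price * factor)
            assert moab_cycle_cost(scaled) == pytest.approx(base * factor, rel=1e-12)


class TestAdverseEvents:
    def test_printed_aggregates_pass_through(self, base_case):
        assert expected_ae_cost(base_case.costs["cetuximab"].adverse_events) == 66.84
        assert expected_ae_cost(base_case.costs["panitumumab"].adverse_events) == 63.34

    def test_expectation_when_unit_costs_supplied(self):
        profile = AdverseEventProfile(
            events=(AdverseEvent("eventA", 0.5, unit_cost=100.0),)
        )
        assert expected_ae_cost(profile) == pytest.approx(50.0)

    def test_no_cost_information_rejected(self):
        with pytest.raises(ValidationError):
            expected_ae_cost(AdverseEventProfile(events=(AdverseEvent("a", 0.1),)))


class TestStateCycleCosts:
    def test_bsc_quarterly_total(self, base_case):
        costs = state_cycle_costs(base_case.costs["BSC"])
        assert costs.total == pytest.approx(147.18, abs=1e-9)
        assert costs.moab == 0.0

    def test_cetuximab_on_treatment_total(self, base_case):
        # published quarterly column total 9,335.43 plus the AE aggregate 66.84
        costs = state_cycle_costs(base_case.costs["cetuximab"])
        assert costs.total - costs.adverse_event == pytest.approx(9335.43, abs=1e-9)
        assert costs.total == pytest.approx(9335.43 + 66.84, abs=1e-9)

    def test_panitumumab_matches_printed_total_to_20_cents(self, base_case):
        # recomputed vial arithmetic differs from the printed column at the
        # cent level (published internal inconsistency)
        costs = state_cycle_costs(base_case.costs["panitumumab"])
        printed = base_case.costs["panitumumab"].printed_state_total
        assert costs.total - costs.adverse_event == pytest.approx(printed, abs=0.2)

    def test_dose_reductions_do_not_alter_base_case_costs(self, base_case):
        # regression: the published quarterly MoAb rows equal full-dose
        # arithmetic, so p_dose_reduction must not leak into base costs
        inputs = base_case.costs["cetuximab"]
        assert (
            state_cycle_costs(inputs, p_dose_reduction=0.18).total
            == state_cycle_costs(inputs, p_dose_reduction=0.0).total
        )

    def test_dose_reduction_fraction_scales_drug_cost(self, base_case):
        inputs = dataclasses.replace(
            base_case.costs["cetuximab"], dose_reduction_fraction=0.5
        )
        reduced = state_cycle_costs(inputs, p_dose_reduction=0.18)
        full = state_cycle_costs(inputs, p_dose_reduction=0.0)
        assert reduced.moab == pytest.approx(full.moab * (1 - 0.18 * 0.5), rel=1e-12)

    def test_zero_cost_strategy(self):
        from mcrc_cea import CostInputs

        assert state_cycle_costs(CostInputs(strategy="nil")).total == 0.0
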