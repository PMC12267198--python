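"""Discounting, life-year/QALY accrual, AE burden, and scenario comparison."""

import numpy as np
import pytest

from pdl1_impact.cohort_engine import run_cohort
from pdl1_impact.outcomes_reporting import (
    OUTCOMES,
    OutcomeSet,
    ae_burden,
    compare_scenarios,
    discount_factor,
    round_half_away,
    trace_outcomes,
)
from pdl1_impact.param_model import (
    AdverseEventProfile,
    AdverseEventRow,
    AgeBand,
    HealthState,
    ModelConfig,
    SurvivalSpec,
    TreatmentSetting,
    Tumor,
    UtilitySet,
    ValidationError,
)

from conftest import toy_arm, toy_mixes

NO_AE = AdverseEventProfile(rows={})


def flat_utilities(u=1.0):
    states = {
        "recurrence_free": u,
        "locoregional_recurrence": u,
        "metastatic_1l": u,
        "metastatic_2l": u,
        "dead": 0.0,
    }
    return UtilitySet(
        state_utility={t: dict(states) for t in Tumor},
        age_bands=[AgeBand(min_age=0.0, female=1.0, male=1.0)],
    )


def test_discount_factor_closed_form():
    assert discount_factor(0, 0.015) == 1.0
    assert discount_factor(52, 0.0) == 1.0
    assert discount_factor(52, 0.015) == pytest.approx(1 / 1.015, rel=1e-12)
    with pytest.raises(ValidationError):
        discount_factor(10, -0.1)


def test_round_half_away_from_zero():
    assert round_half_away(2.5) == 3
    assert round_half_away(-2.5) == -3
    assert round_half_away(2.49) == 2
    assert round_half_away(-26.13) == -26
    assert round_half_away(0.0) == 0


def test_undiscounted_survivors_accrue_full_life_years(
    config, zero_life_table, demographics
):
    cfg = ModelConfig(annual_discount_rate=0.0)
    trace = run_cohort(
        100.0, toy_arm(), toy_mixes(), cfg, zero_life_table, demographics
    )
    out = trace_outcomes(trace, flat_utilities(), NO_AE, demographics, cfg)
    # 100 persons alive in RF for 52 cycles contribute 100 life-years per year
    assert out.per_year.loc[2022, "recurrence_free_life_years"] == pytest.approx(100.0)
    assert out.cumulative["total_life_years"] == pytest.approx(1000.0)
    assert out.cumulative["qalys"] == pytest.approx(out.cumulative["total_life_years"])


def test_everyone_dead_accrues_nothing(config, zero_life_table, demographics):
    arm = toy_arm(rf_to_death=SurvivalSpec("exponential", (1000.0,)))
    trace = run_cohort(
        100.0, arm, toy_mixes(), config, zero_life_table, demographics
    )
    out = trace_outcomes(trace, flat_utilities(), NO_AE, demographics, config)
    assert out.cumulative["total_life_years"] == pytest.approx(0.0, abs=1e-9)
    assert out.cumulative["total_deaths"] == pytest.approx(100.0)


def test_life_years_match_analytic_integral(config, zero_life_table, demographics):
    """Weekly Riemann accrual of an exponential decay vs the closed form."""
    lam = 0.005
    cfg = ModelConfig(annual_discount_rate=0.0)
    arm = toy_arm(rf_to_death=SurvivalSpec("exponential", (lam,)))
    trace = run_cohort(100.0, arm, toy_mixes(), cfg, zero_life_table, demographics)
    out = trace_outcomes(trace, flat_utilities(), NO_AE, demographics, cfg)
    T = 520.0
    analytic = 100.0 * (1.0 - np.exp(-lam * T)) / lam / 52.0
    assert out.cumulative["total_life_years"] == pytest.approx(analytic, rel=0.005)


def test_recurrence_counts_match_closed_form(config, zero_life_table, demographics):
    lam = 0.003
    arm = toy_arm(rf_to_lr=SurvivalSpec("exponential", (lam,)))
    trace = run_cohort(100.0, arm, toy_mixes(), config, zero_life_table, demographics)
    out = trace_outcomes(trace, flat_utilities(), NO_AE, demographics, config)
    expected = 100.0 * (1.0 - np.exp(-lam * 520))
    assert out.cumulative["events_or_recurrences"] == pytest.approx(expected, rel=0.005)
    assert out.cumulative["deaths_after_first_event"] == 0.0


def test_constant_utility_scales_life_years(config, zero_life_table, demographics):
    cfg = ModelConfig(annual_discount_rate=0.0)
    trace = run_cohort(100.0, toy_arm(), toy_mixes(), cfg, zero_life_table, demographics)
    out = trace_outcomes(trace, flat_utilities(0.8), NO_AE, demographics, cfg)
    assert out.cumulative["qalys"] == pytest.approx(
        0.8 * out.cumulative["total_life_years"], rel=1e-9
    )
    zero = trace_outcomes(trace, flat_utilities(0.0), NO_AE, demographics, cfg)
    assert zero.cumulative["qalys"] == 0.0


def test_discounting_reduces_life_years(config, zero_life_table, demographics):
    trace = run_cohort(100.0, toy_arm(), toy_mixes(), config, zero_life_table, demographics)
    discounted = trace_outcomes(trace, flat_utilities(), NO_AE, demographics, config)
    cfg0 = ModelConfig(annual_discount_rate=0.0)
    undiscounted = trace_outcomes(trace, flat_utilities(), NO_AE, demographics, cfg0)
    assert (
        discounted.cumulative["total_life_years"]
        < undiscounted.cumulative["total_life_years"]
    )


def test_ae_burden_product_formula():
    row = AdverseEventRow(events_per_patient=0.5, weeks_per_event=4.0, disutility=-0.05)
    count, qaly_loss = ae_burden(100.0, row)
    assert count == pytest.approx(50.0)
    assert qaly_loss == pytest.approx(50.0 * 4.0 * 0.05 / 52.0)
    assert ae_burden(0.0, row) == (0.0, 0.0)


def test_adjuvant_ae_applied_at_entry(config, zero_life_table, demographics):
    cfg = ModelConfig(annual_discount_rate=0.0)
    trace = run_cohort(100.0, toy_arm(), toy_mixes(), cfg, zero_life_table, demographics)
    ae = AdverseEventProfile(
        rows={
            (Tumor.MELANOMA, TreatmentSetting.ADJUVANT, "toy"): AdverseEventRow(
                0.5, 4.0, -0.05
            )
        }
    )
    out = trace_outcomes(trace, flat_utilities(), ae, demographics, cfg)
    assert out.cumulative["adverse_events"] == pytest.approx(50.0)
    expected_loss = 50.0 * 4.0 * 0.05 / 52.0
    assert out.cumulative["qalys"] == pytest.approx(
        out.cumulative["total_life_years"] - expected_loss, rel=1e-9
    )


def test_metastatic_pathway_counts_both_lines(config, zero_life_table, demographics):
    """Every recurring patient reaching 2L contributes two treatments."""
    arm = toy_arm(
        rf_to_met=SurvivalSpec("exponential", (0.01,)),
        m1l_to_m2l={"tx": SurvivalSpec("exponential", (1000.0,))},
        m1l_to_death={"tx": SurvivalSpec("exponential", (1e-12,))},
    )
    trace = run_cohort(100.0, arm, toy_mixes(), config, zero_life_table, demographics)
    out = trace_outcomes(trace, flat_utilities(), NO_AE, demographics, config)
    init_1l = trace.initiations_1l().sum()
    init_2l = trace.initiations_2l().sum()
    # the huge 1L progression rate pushes everyone who can still be observed
    # into 2L one cycle later
    assert init_2l == pytest.approx(
        init_1l - trace.occupancy[HealthState.METASTATIC_1L][-1], rel=1e-9
    )
    assert out.cumulative["active_metastatic_treatments"] == pytest.approx(
        init_1l + init_2l
    )


class TestCompareScenarios:
    def test_published_difference_and_percent(self):
        a = OutcomeSet.from_cumulative({"recurrence_free_life_years": 34755.0})
        b = OutcomeSet.from_cumulative({"recurrence_free_life_years": 38171.0})
        res = compare_scenarios(a, b)
        assert res.difference.cumulative["recurrence_free_life_years"] == 3416.0
        assert res.percent_change["recurrence_free_life_years"] == 10

    def test_negative_difference_and_percent(self):
        a = OutcomeSet.from_cumulative({"active_metastatic_treatments": 4555.0})
        b = OutcomeSet.from_cumulative({"active_metastatic_treatments": 2978.0})
        res = compare_scenarios(a, b)
        assert res.difference.cumulative["active_metastatic_treatments"] == -1577.0
        assert res.percent_change["active_metastatic_treatments"] == -35

    def test_identical_inputs_give_zero(self):
        a = OutcomeSet.from_cumulative({n: 5.0 for n in OUTCOMES})
        res = compare_scenarios(a, a)
        assert all(v == 0.0 for v in res.difference.cumulative)
        assert all(res.percent_change[n] == 0 for n in OUTCOMES)

    def test_zero_baseline_gives_undefined_percent(self):
        a = OutcomeSet.from_cumulative({"qalys": 0.0})
        b = OutcomeSet.from_cumulative({"qalys": 3.0})
        res = compare_scenarios(a, b)
        assert res.percent_change["qalys"] is None
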