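"""Cohort propagation: conservation, closed forms, strata, microsim oracle."""

import numpy as np
import pytest

from pdl1_impact.cohort_engine import (
    microsim_oracle,
    resolve_mix_slice,
    run_cohort,
    split_retreatment_eligibility,
    trace_to_frame,
)
from pdl1_impact.outcomes_reporting import trace_outcomes
from pdl1_impact.param_model import HealthState, ModelConfig, Stratum, SurvivalSpec
from pdl1_impact.synthetic_data import generate_parameter_set

from conftest import toy_arm, toy_mixes


def run_toy(arm, config, life_table, demographics, entry_size=100.0, entry_week=0):
    return run_cohort(
        entry_size, arm, toy_mixes(), config, life_table, demographics, entry_week
    )


def test_zero_entry_gives_zero_trace(config, zero_life_table, demographics):
    trace = run_toy(toy_arm(), config, zero_life_table, demographics, entry_size=0.0)
    assert np.all(trace.total_occupancy() == 0.0)
    assert trace.deaths.sum() == 0.0


def test_no_hazards_means_everyone_stays_recurrence_free(
    config, zero_life_table, demographics
):
    trace = run_toy(toy_arm(), config, zero_life_table, demographics)
    rf = trace.occupancy[HealthState.RECURRENCE_FREE]
    assert rf == pytest.approx(100.0, abs=1e-7)
    assert np.abs(trace.total_occupancy() - 100.0).max() < 1e-9


def test_pure_death_cohort_decays_exponentially(config, zero_life_table, demographics):
    lam = 0.01
    arm = toy_arm(rf_to_death=SurvivalSpec("exponential", (lam,)))
    trace = run_toy(arm, config, zero_life_table, demographics)
    k = np.arange(trace.n_cycles + 1)
    expected = 100.0 * np.exp(-lam * k)
    assert np.abs(trace.occupancy[HealthState.RECURRENCE_FREE] - expected).max() < 1e-6
    # all deaths occur without a prior event
    assert trace.deaths_after_event.sum() == 0.0
    assert trace.recurrences.sum() == 0.0


def test_conservation_and_absorption_on_synthetic_bundles():
    for seed in (1, 2, 3):
        bundle = generate_parameter_set(seed)
        for tumor, arms in bundle.arms.items():
            for arm_label, arm in arms.items():
                mixes = resolve_mix_slice(bundle.shares, tumor, arm_label)
                trace = run_cohort(
                    50.0,
                    arm,
                    mixes,
                    bundle.config,
                    bundle.life_table,
                    bundle.population.demographics,
                )
                assert np.abs(trace.total_occupancy() - 50.0).max() < 1e-9
                dead = trace.occupancy[HealthState.DEAD]
                assert np.all(np.diff(dead) >= -1e-12)
                assert trace.recurrences.sum() <= 50.0 + 1e-9


def test_entry_week_truncates_the_trace(config, zero_life_table, demographics):
    trace = run_toy(
        toy_arm(), config, zero_life_table, demographics, entry_week=9 * 52
    )
    assert trace.n_cycles == 52


def test_retreatment_eligibility_boundary():
    assert split_retreatment_eligibility(77, 78) is Stratum.BEFORE_THRESHOLD
    assert split_retreatment_eligibility(78, 78) is Stratum.AT_OR_AFTER_THRESHOLD
    assert split_retreatment_eligibility(0, 78) is Stratum.BEFORE_THRESHOLD


def test_retreatment_disabled_maps_all_strata_to_restricted_mix(demo_bundle):
    from pdl1_impact.param_model import Tumor

    tumor = Tumor.MELANOMA
    allowed = resolve_mix_slice(demo_bundle.shares, tumor, "anti_pdl1", True)
    disabled = resolve_mix_slice(demo_bundle.shares, tumor, "anti_pdl1", False)
    before = allowed.mix_1l[Stratum.BEFORE_THRESHOLD]
    assert disabled.mix_1l[Stratum.AT_OR_AFTER_THRESHOLD] == before
    assert "anti_pdl1_1l" not in before
    assert "anti_pdl1_1l" in allowed.mix_1l[Stratum.AT_OR_AFTER_THRESHOLD]


def test_identical_arms_produce_bit_identical_traces(
    config, zero_life_table, demographics
):
    spec = SurvivalSpec("weibull", (1.2, 150.0))
    kwargs = dict(rf_to_lr=spec, lr_to_met=SurvivalSpec("exponential", (0.01,)))
    t1 = run_toy(toy_arm(arm_label="a", **kwargs), config, zero_life_table, demographics)
    t2 = run_toy(toy_arm(arm_label="b", **kwargs), config, zero_life_table, demographics)
    for state in HealthState:
        assert np.array_equal(t1.occupancy[state], t2.occupancy[state])
    assert np.array_equal(t1.recurrences, t2.recurrences)


def test_stronger_treatment_effect_never_reduces_rf_life_years(
    config, zero_life_table, demographics
):
    """Dominance: scaling RF-exit hazard ratios below one helps."""
    base = SurvivalSpec("weibull", (1.1, 200.0))
    rf_ly = []
    for hr in (1.0, 0.8, 0.5):
        arm = toy_arm(
            rf_to_lr=base.with_hazard_ratio(hr),
            rf_to_met=SurvivalSpec("exponential", (0.002,), hazard_ratio=hr),
            rf_to_death=SurvivalSpec("exponential", (0.0005,), hazard_ratio=hr),
            lr_to_met=SurvivalSpec("exponential", (0.01,)),
            lr_to_death=SurvivalSpec("exponential", (0.002,)),
        )
        trace = run_toy(arm, config, zero_life_table, demographics)
        rf_ly.append(trace.occupancy[HealthState.RECURRENCE_FREE][:-1].sum() / 52.0)
    assert rf_ly[0] <= rf_ly[1] <= rf_ly[2]


def test_trace_export_is_tidy(config, zero_life_table, demographics):
    trace = run_toy(toy_arm(), config, zero_life_table, demographics)
    frame = trace_to_frame(trace)
    assert set(frame.columns) == {"tumor", "arm", "cycle", "state", "persons"}
    assert len(frame) == 5 * (trace.n_cycles + 1)


class TestMicrosimOracle:
    def test_reproducible_for_fixed_seed(self, config, zero_life_table, demographics):
        arm = toy_arm(rf_to_death=SurvivalSpec("exponential", (0.005,)))
        a = microsim_oracle(
            500, arm, toy_mixes(), config, zero_life_table, demographics, seed=3
        )
        b = microsim_oracle(
            500, arm, toy_mixes(), config, zero_life_table, demographics, seed=3
        )
        assert a.totals == b.totals

    def test_no_hazard_gives_full_life_years(self, zero_life_table, demographics):
        config = ModelConfig(annual_discount_rate=0.0)
        res = microsim_oracle(
            200, toy_arm(), toy_mixes(), config, zero_life_table, demographics, seed=1
        )
        assert res.totals["total_life_years"] == pytest.approx(10 * 200, rel=1e-12)
        assert res.totals["total_deaths"] == 0.0

    def test_agrees_with_cohort_engine_on_toy_model(
        self, config, zero_life_table, demographics
    ):
        arm = toy_arm(
            rf_to_lr=SurvivalSpec("exponential", (0.004,)),
            rf_to_death=SurvivalSpec("exponential", (0.001,)),
            lr_to_met=SurvivalSpec("exponential", (0.01,)),
            lr_to_death=SurvivalSpec("exponential", (0.003,)),
            m1l_to_m2l={"tx": SurvivalSpec("exponential", (0.02,))},
            m1l_to_death={"tx": SurvivalSpec("exponential", (0.008,))},
            m2l_to_death=SurvivalSpec("exponential", (0.02,)),
        )
        n = 20000
        trace = run_cohort(
            float(n), arm, toy_mixes(), config, zero_life_table, demographics
        )
        ms = microsim_oracle(
            n, arm, toy_mixes(), config, zero_life_table, demographics, seed=5
        )
        det = {
            "total_deaths": trace.deaths.sum(),
            "events_or_recurrences": trace.recurrences.sum(),
            "deaths_after_first_event": trace.deaths_after_event.sum(),
            "total_life_years": np.sum(
                trace.alive()[1:]
                / 52.0
                * (1.015 ** (-np.arange(trace.n_cycles) / 52.0))
            ),
        }
        for name, expected in det.items():
            se = ms.se[name]
            assert abs(ms.totals[name] - expected) <= 3.0 * se, name
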