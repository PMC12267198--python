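"""Scenario toggles, subgroup additivity, one-way tornado, determinism."""

import numpy as np
import pytest

from pdl1_impact.outcomes_reporting import OUTCOMES
from pdl1_impact.param_model import Tumor, ValidationError
from pdl1_impact.pipeline import run_comparison
from pdl1_impact.sensitivity_suite import (
    IMPACT_OUTCOMES,
    one_way_sa,
    run_scenario_analysis,
    run_subgroups,
)
from pdl1_impact.synthetic_data import generate_parameter_set


@pytest.fixture(scope="module")
def bundle():
    return generate_parameter_set(11)


@pytest.fixture(scope="module")
def base(bundle):
    return run_comparison(bundle)


def test_repeated_runs_are_bit_identical(bundle, base):
    again = run_comparison(bundle)
    assert np.array_equal(
        base.difference.cumulative.values, again.difference.cumulative.values
    )
    assert base.difference.per_year.equals(again.difference.per_year)


def test_no_toggle_reproduces_base_case(bundle, base):
    res = run_scenario_analysis(bundle, "none", base=base)
    assert (res.table["base_impact"] == res.table["varied_impact"]).all()
    assert (res.table["percent_change"].fillna(0) == 0).all()


def test_unknown_toggle_raises(bundle, base):
    with pytest.raises(ValidationError, match="unknown sensitivity toggle"):
        run_scenario_analysis(bundle, "bogus", base=base)


def test_population_scaling_scales_every_impact_linearly(bundle, base):
    up = run_scenario_analysis(bundle, "pop_up_20", base=base)
    down = run_scenario_analysis(bundle, "pop_down_20", base=base)
    for name in IMPACT_OUTCOMES:
        b = base.difference.cumulative[name]
        assert up.varied.difference.cumulative[name] == pytest.approx(1.2 * b, rel=1e-9)
        assert down.varied.difference.cumulative[name] == pytest.approx(0.8 * b, rel=1e-9)
        # raw signed change relative to |base|: +/-20 times the impact's sign
        sign = 1 if b > 0 else -1
        assert up.table.loc[name, "percent_change"] == 20 * sign
        assert down.table.loc[name, "percent_change"] == -20 * sign
    # scenario-level outcomes scale too, not just the differences
    for name in OUTCOMES:
        assert up.varied.outcomes_i.cumulative[name] == pytest.approx(
            1.2 * base.outcomes_i.cumulative[name], rel=1e-9
        )


def test_full_uptake_amplifies_the_beneficial_impacts(bundle, base):
    res = run_scenario_analysis(bundle, "uptake_100", base=base)
    for name in ("total_life_years", "qalys"):
        assert res.varied.difference.cumulative[name] >= base.difference.cumulative[name]
    for name in ("total_deaths", "events_or_recurrences"):
        assert res.varied.difference.cumulative[name] <= base.difference.cumulative[name]


def test_launch_delay_shrinks_impact_magnitudes(bundle, base):
    res = run_scenario_analysis(bundle, "launch_delay", base=base)
    for name in ("total_life_years", "qalys"):
        assert 0 <= res.varied.difference.cumulative[name] <= base.difference.cumulative[name]


def test_subgroup_additivity(bundle, base):
    results = run_subgroups(bundle)
    assert len(results) == 7
    singles = {t.value: results[t.value].difference.cumulative for t in Tumor}
    for label, res in results.items():
        parts = label.split("+")
        summed = sum((singles[p] for p in parts[1:]), singles[parts[0]].copy())
        assert np.allclose(
            res.difference.cumulative.values, summed.values, rtol=1e-9, atol=1e-6
        ), label
    all_three = results["melanoma+rcc+tnbc"]
    assert np.allclose(
        all_three.difference.cumulative.values,
        base.difference.cumulative.values,
        rtol=1e-12,
    )


@pytest.fixture(scope="module")
def tornado(bundle):
    return one_way_sa(
        bundle,
        variables=[
            "eligible_population_all_years",
            "mean_weight",
            "metastatic_os_hazard_ratio",
            "utility_recurrence_free",
        ],
    )


class TestOneWay:
    def test_inert_variable_has_zero_range(self, tornado):
        long, wide = tornado
        assert wide.set_index("variable").loc["mean_weight", "range"] == 0.0

    def test_population_perturbation_is_exactly_ten_percent(self, tornado, base):
        long, _ = tornado
        rows = long[long["variable"] == "eligible_population_all_years"]
        for _, row in rows.iterrows():
            factor = 0.9 if row["direction"] == "low" else 1.1
            assert row["varied_impact"] == pytest.approx(
                factor * row["base_impact"], rel=1e-9
            )

    def test_tornado_sorted_by_range(self, tornado):
        _, wide = tornado
        assert list(wide["range"]) == sorted(wide["range"], reverse=True)

    def test_hazard_ratio_moves_to_ci_bounds(self, tornado):
        long, _ = tornado
        rows = long[
            (long["variable"] == "metastatic_os_hazard_ratio")
            & (long["outcome"] == "total_life_years")
        ].set_index("direction")
        # a lower metastatic-OS hazard ratio in scenario I's dominant 1L
        # anti-PD-(L)1 mix shrinks the scenario II life-year advantage
        assert rows.loc["low", "varied_impact"] != rows.loc["high", "varied_impact"]

    def test_unknown_variable_rejected(self, bundle):
        with pytest.raises(ValidationError, match="unknown one-way variables"):
            one_way_sa(bundle, variables=["nope"])
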