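"""Survival-law evaluation, discrete conversion, and mortality flooring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pdl1_impact.param_model import LifeTable, SurvivalSpec, ValidationError
from pdl1_impact.survival_engine import (
    background_weekly_mortality,
    competing_exit_normalization,
    cycle_prob_array,
    cycle_transition_prob,
    effective_death_prob,
    survival_at,
)

FAMILY_EXAMPLES = [
    SurvivalSpec("exponential", (0.01,)),
    SurvivalSpec("weibull", (1.4, 120.0)),
    SurvivalSpec("weibull", (0.8, 300.0)),
    SurvivalSpec("lognormal", (4.0, 0.8)),
    SurvivalSpec("loglogistic", (1.8, 100.0)),
    SurvivalSpec("gompertz", (0.01, 0.002)),
    SurvivalSpec("gompertz", (-0.005, 0.004)),
    SurvivalSpec("generalized_gamma", (4.2, 0.7, 0.5)),
    SurvivalSpec("generalized_gamma", (4.2, 0.7, -0.6)),
    SurvivalSpec("exponential", (0.02,), hazard_ratio=0.6, hr_ci=(0.4, 0.9)),
]


@pytest.mark.parametrize("spec", FAMILY_EXAMPLES, ids=lambda s: f"{s.family}{s.params}")
class TestSurvivalLaws:
    def test_valid_non_increasing_curve(self, spec):
        t = np.linspace(0.0, 600.0, 301)
        s = survival_at(spec, t)
        assert s[0] == 1.0
        assert np.all((s >= 0) & (s <= 1))
        assert np.all(np.diff(s) <= 1e-15)

    def test_telescoping_identity(self, spec):
        """Chaining per-cycle survival reproduces S(k) exactly."""
        p = cycle_prob_array(spec, 520)
        chained = np.cumprod(1.0 - p)
        expected = survival_at(spec, np.arange(1.0, 521.0))
        assert np.abs(chained - expected).max() < 1e-10

    def test_unit_hazard_ratio_is_identity(self, spec):
        base = SurvivalSpec(spec.family, spec.params)
        unit = SurvivalSpec(spec.family, spec.params, hazard_ratio=1.0)
        t = np.linspace(0, 400, 81)
        assert np.array_equal(survival_at(base, t), survival_at(unit, t))


def test_exponential_closed_form_with_hazard_ratio():
    spec = SurvivalSpec("exponential", (0.01,), hazard_ratio=2.0)
    assert survival_at(spec, 0.0) == 1.0
    assert survival_at(spec, 100.0) == pytest.approx(np.exp(-2.0), rel=1e-12)


def test_exponential_cycle_prob_is_memoryless():
    spec = SurvivalSpec("exponential", (0.01,))
    expected = 1.0 - np.exp(-0.01)
    for k in (0, 10, 400):
        assert cycle_transition_prob(spec, k) == pytest.approx(expected, rel=1e-12)


def test_weibull_shape_one_degenerates_to_exponential():
    lam = 0.02
    wei = SurvivalSpec("weibull", (1.0, 1.0 / lam))
    exp = SurvivalSpec("exponential", (lam,))
    t = np.linspace(0, 300, 61)
    assert np.abs(survival_at(wei, t) - survival_at(exp, t)).max() < 1e-12


def test_zero_hazard_ratio_limit_gives_zero_transition():
    spec = SurvivalSpec("weibull", (1.5, 100.0), hazard_ratio=0.0)
    assert np.all(cycle_prob_array(spec, 100) == 0.0)


def test_increasing_hazard_gives_increasing_cycle_probs():
    spec = SurvivalSpec("weibull", (2.0, 200.0))
    p = cycle_prob_array(spec, 300)
    assert np.all(np.diff(p) > 0)


def test_generalized_gamma_matches_scipy_parameterization():
    """Independent route: (mu, sigma, Q) mapped onto scipy.stats.gengamma."""
    mu, sigma, q = 4.2, 0.7, 0.5
    t = np.linspace(0.5, 400, 50)
    mine = survival_at(SurvivalSpec("generalized_gamma", (mu, sigma, q)), t)
    a, c = q**-2, q / sigma
    ref = stats.gengamma.sf(t, a, c, scale=np.exp(mu) * a ** (-1.0 / c))
    assert np.abs(mine - ref).max() < 1e-12


def test_generalized_gamma_degeneracies():
    t = np.linspace(0.5, 400, 50)
    gg_wei = survival_at(SurvivalSpec("generalized_gamma", (4.2, 0.7, 1.0)), t)
    wei = survival_at(SurvivalSpec("weibull", (1.0 / 0.7, np.exp(4.2))), t)
    assert np.abs(gg_wei - wei).max() < 1e-12
    gg_ln = survival_at(SurvivalSpec("generalized_gamma", (4.0, 0.8, 0.0)), t)
    ln = survival_at(SurvivalSpec("lognormal", (4.0, 0.8)), t)
    assert np.abs(gg_ln - ln).max() < 1e-12


def test_depleted_state_transitions_with_probability_one():
    # a huge rate drives S to zero within a cycle
    spec = SurvivalSpec("exponential", (1000.0,))
    p = cycle_prob_array(spec, 5)
    assert np.all(p == 1.0)


def test_invalid_parameters_rejected():
    with pytest.raises(ValidationError):
        SurvivalSpec("weibull", (-1.0, 100.0))
    with pytest.raises(ValidationError):
        SurvivalSpec("exponential", (0.0,))
    with pytest.raises(ValidationError):
        SurvivalSpec("nonsense", (1.0,))
    with pytest.raises(ValidationError):
        SurvivalSpec("exponential", (0.01,), hazard_ratio=0.5, hr_ci=(0.6, 0.9))


@given(
    q=st.floats(min_value=0.0, max_value=1.0),
)
@settings(deadline=None, max_examples=50, derandomize=True)
def test_background_mortality_compounds_back_to_annual(q):
    table = _flat_table(q)
    weekly = background_weekly_mortality(table, age=40.0, sex="female")
    assert 0.0 <= weekly <= 1.0
    compounded = 1.0 - (1.0 - weekly) ** 52
    assert compounded == pytest.approx(q, abs=1e-12)


def _flat_table(q):
    col = np.full(101, q)
    col[-1] = 1.0
    return LifeTable(q_female=col, q_male=col.copy())


def test_background_mortality_closed_form_and_pooling():
    table = _flat_table(0.05)
    w = background_weekly_mortality(table, age=40.0, sex="male")
    assert w == pytest.approx(1.0 - 0.95 ** (1.0 / 52.0), rel=1e-12)
    pooled = background_weekly_mortality(table, age=40.0, fraction_female=0.5)
    assert pooled == pytest.approx(w, rel=1e-12)
    with pytest.raises(ValidationError):
        background_weekly_mortality(table, age=40.0)


def test_ages_above_table_use_closing_row():
    table = _flat_table(0.05)
    assert table.annual_q(140.0, "female") == 1.0


@given(
    a=st.floats(min_value=0, max_value=1),
    b=st.floats(min_value=0, max_value=1),
)
@settings(deadline=None, max_examples=50, derandomize=True)
def test_effective_death_prob_is_max(a, b):
    m = effective_death_prob(a, b)
    assert m == max(a, b)
    assert effective_death_prob(m, m) == m
    assert m >= a and m >= b


def test_competing_exit_normalization():
    assert np.array_equal(
        competing_exit_normalization([0.01, 0.02]), np.array([0.01, 0.02])
    )
    rescaled = competing_exit_normalization([0.8, 0.6])
    assert rescaled == pytest.approx([0.8 / 1.4, 0.6 / 1.4])
    assert rescaled.sum() == pytest.approx(1.0)
    assert competing_exit_normalization([]).size == 0
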