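"""Parametric survival laws and their conversion to weekly transition probabilities.

Six families are supported (exponential, Weibull, log-normal, log-logistic,
Gompertz, generalized gamma), each in its standard parameterization with
time in weeks.  A hazard ratio acts on the whole-curve hazard under
proportional hazards, i.e. ``S_hr(t) = S(t) ** hr``.

The discrete-time conversion is exact rather than a rate approximation:
the probability of leaving during cycle ``k`` conditional on occupying the
source state at its start is ``1 - S(k+1)/S(k)``, which makes the
telescoping identity ``prod(1 - p_k) == S(K)`` hold to numerical precision
for every family.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import special, stats

from .param_model import LifeTable, SurvivalSpec, ValidationError

__all__ = [
    "survival_at",
    "cycle_transition_prob",
    "cycle_prob_array",
    "background_weekly_mortality",
    "background_weekly_curve",
    "effective_death_prob",
    "competing_exit_normalization",
]

logger = logging.getLogger(__name__)


def _baseline_survival(family: str, params: tuple[float, ...], t: np.ndarray) -> np.ndarray:
    """Baseline S(t) for one family; t in weeks, vectorized."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValidationError("survival time must be >= 0")
    if family == "exponential":
        (rate,) = params
        return np.exp(-rate * t)
    if family == "weibull":
        shape, scale = params
        return np.exp(-np.power(t / scale, shape))
    if family == "lognormal":
        mu, sigma = params
        with np.errstate(divide="ignore"):
            z = (np.log(t) - mu) / sigma
        return stats.norm.sf(z)
    if family == "loglogistic":
        shape, scale = params
        return 1.0 / (1.0 + np.power(t / scale, shape))
    if family == "gompertz":
        shape, rate = params
        if shape == 0.0:
            return np.exp(-rate * t)
        return np.exp(-(rate / shape) * np.expm1(shape * t))
    if family == "generalized_gamma":
        # (mu, sigma, Q) parameterization; Q = 0 degenerates to log-normal,
        # Q = 1 to Weibull(shape 1/sigma, scale exp(mu)).
        mu, sigma, q = params
        if q == 0.0:
            return _baseline_survival("lognormal", (mu, sigma), t)
        with np.errstate(divide="ignore", over="ignore"):
            w = (np.log(t) - mu) / sigma
            gamma_shape = q**-2
            u = gamma_shape * np.exp(q * w)
        if q > 0:
            return special.gammaincc(gamma_shape, u)
        return special.gammainc(gamma_shape, u)
    raise ValidationError(f"unknown survival family {family!r}")


def survival_at(spec: SurvivalSpec, t) -> np.ndarray | float:
    """Survival probability S(t) at t weeks, hazard ratio applied via PH."""
    scalar = np.isscalar(t)
    base = _baseline_survival(spec.family, spec.params, np.atleast_1d(t))
    s = np.clip(base, 0.0, 1.0) ** spec.hazard_ratio
    return float(s[0]) if scalar else s


def cycle_transition_prob(spec: SurvivalSpec, cycle_index: int) -> float:
    """Probability of transitioning during one weekly cycle.

    Conditional on occupying the source state at the start of
    ``cycle_index``; by convention returns 1 once the survival function has
    reached zero (the state is fully depleted).
    """
    if cycle_index < 0:
        raise ValidationError("cycle_index must be >= 0")
    return float(cycle_prob_array(spec, cycle_index + 1)[cycle_index])


def cycle_prob_array(spec: SurvivalSpec, n_cycles: int) -> np.ndarray:
    """Per-cycle transition probabilities for cycles 0 .. n_cycles-1."""
    s = survival_at(spec, np.arange(n_cycles + 1, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 1.0 - s[1:] / s[:-1]
    p = np.where(s[:-1] <= 0.0, 1.0, p)
    return np.clip(p, 0.0, 1.0)


def background_weekly_mortality(
    table: LifeTable,
    age: float,
    sex: str | None = None,
    fraction_female: float | None = None,
) -> float:
    """Weekly background death probability from an annual life table.

    The annual probability q is converted assuming a constant hazard within
    the year: ``1 - (1 - q) ** (1/52)``.  Either a single sex or a pooled
    cohort (via ``fraction_female``) can be requested.
    """
    if (sex is None) == (fraction_female is None):
        raise ValidationError("provide exactly one of sex or fraction_female")
    if sex is not None:
        q = table.annual_q(age, sex)
    else:
        q = table.pooled_annual_q(age, fraction_female)
    return float(1.0 - (1.0 - q) ** (1.0 / 52.0))


def background_weekly_curve(
    table: LifeTable, entry_age: float, n_cycles: int, fraction_female: float
) -> np.ndarray:
    """Weekly background mortality for cycles 0 .. n_cycles-1.

    Age advances deterministically by 1/52 year per cycle from the cohort's
    mean entry age; sexes are pooled by the configured fraction female.
    """
    ages = entry_age + np.arange(n_cycles) / 52.0
    out = np.empty(n_cycles)
    # q changes only at integer ages; evaluate once per distinct year of age
    floors = np.floor(ages).astype(int)
    for a in np.unique(floors):
        q = table.pooled_annual_q(float(a), fraction_female)
        out[floors == a] = 1.0 - (1.0 - q) ** (1.0 / 52.0)
    return out


def effective_death_prob(trial_p, background_p):
    """Per-cycle death probability: trial-based or background, whichever is larger."""
    return np.maximum(trial_p, background_p)


def competing_exit_normalization(exit_probs) -> np.ndarray:
    """Rescale competing per-cycle exit probabilities whose sum exceeds 1.

    Marginal transition laws are defined per transition, not jointly; at a
    weekly resolution their per-cycle exit probabilities rarely sum past 1.
    When they do, the probabilities are rescaled proportionally to sum to 1
    and a warning is logged.
    """
    probs = np.asarray(exit_probs, dtype=float)
    total = probs.sum()
    if total > 1.0:
        logger.warning(
            "competing per-cycle exit probabilities sum to %.6f > 1; rescaling",
            total,
        )
        probs = probs / total
    return probs
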