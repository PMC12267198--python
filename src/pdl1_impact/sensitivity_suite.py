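"""Scenario-based, subgroup and one-way sensitivity analyses.

Every analysis re-runs the full pipeline on a modified copy of the input
bundle and reports the change in the scenario II minus scenario I impact
relative to the base case.  The one-way analysis perturbs each registered
variable by +/-10% of its value (hazard ratios move to their 95% CI bounds
when available) and ranks variables by the induced impact range (tornado
ordering).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .outcomes_reporting import ComparisonResult, round_half_away
from .param_model import ModelBundle, Tumor, ValidationError
from .pipeline import run_comparison
from .population_scenarios import ANTI_PDL1_ARM

__all__ = [
    "IMPACT_OUTCOMES",
    "SCENARIO_TOGGLES",
    "SensitivityResult",
    "run_scenario_analysis",
    "run_subgroups",
    "one_way_sa",
    "sa_variables",
]

logger = logging.getLogger(__name__)

# the seven impact rows of the scenario-sensitivity table (recurrence-free
# life-years are reported in the base case table but not re-ranked here)
IMPACT_OUTCOMES = (
    "total_life_years",
    "qalys",
    "events_or_recurrences",
    "active_metastatic_treatments",
    "adverse_events",
    "total_deaths",
    "deaths_after_first_event",
)

SCENARIO_TOGGLES = (
    "uptake_100",
    "pop_up_20",
    "pop_down_20",
    "launch_delay",
    "no_retreatment",
)

DEFAULT_LAUNCH_DELAY_YEARS = 2


@dataclass
class SensitivityResult:
    """Base-case vs varied-case impacts for one sensitivity scenario.

    ``table`` has one row per impact outcome with columns base_impact,
    varied_impact and percent_change, where
    percent_change = round(100 * (varied - base) / |base|).
    """

    label: str
    table: pd.DataFrame
    base: ComparisonResult
    varied: ComparisonResult


def _impact_table(base: ComparisonResult, varied: ComparisonResult) -> pd.DataFrame:
    rows = {}
    for name in IMPACT_OUTCOMES:
        b = base.difference.cumulative[name]
        v = varied.difference.cumulative[name]
        pct = None if b == 0 else round_half_away(100.0 * (v - b) / abs(b))
        rows[name] = {"base_impact": b, "varied_impact": v, "percent_change": pct}
    return pd.DataFrame.from_dict(rows, orient="index")


def _apply_toggle(bundle: ModelBundle, toggle: str, launch_delay_years: int) -> ModelBundle:
    varied = bundle.copy()
    if toggle == "uptake_100":
        varied.config.uptake_override = 1.0
    elif toggle == "pop_up_20":
        varied.population = varied.population.scaled(1.2)
    elif toggle == "pop_down_20":
        varied.population = varied.population.scaled(0.8)
    elif toggle == "launch_delay":
        varied.config.launch_delay_years = launch_delay_years
    elif toggle == "no_retreatment":
        varied.config.retreatment_allowed = False
    elif toggle != "none":
        raise ValidationError(
            f"unknown sensitivity toggle {toggle!r}; expected one of "
            f"{SCENARIO_TOGGLES} or 'none'"
        )
    return varied


def run_scenario_analysis(
    bundle: ModelBundle,
    toggle: str,
    base: ComparisonResult | None = None,
    launch_delay_years: int = DEFAULT_LAUNCH_DELAY_YEARS,
) -> SensitivityResult:
    """Re-run the pipeline with exactly one scenario toggle applied.

    Toggles: 100% anti-PD-(L)1 uptake, +/-20% target population (applied to
    both scenarios), delayed launch of early-setting anti-PD-(L)1, and no
    retreatment with the class.  ``toggle='none'`` reproduces the base case.
    """
    base = base or run_comparison(bundle)
    varied = run_comparison(_apply_toggle(bundle, toggle, launch_delay_years))
    return SensitivityResult(
        label=toggle, table=_impact_table(base, varied), base=base, varied=varied
    )


def run_subgroups(bundle: ModelBundle) -> dict[str, ComparisonResult]:
    """Tumor-subgroup analyses: six proper subsets plus all three tumors."""
    tumors = tuple(bundle.config.tumor_subset)
    if not tumors:
        raise ValidationError("tumor subset is empty")
    subsets: list[tuple[Tumor, ...]] = [(t,) for t in tumors]
    subsets += [
        (a, b) for i, a in enumerate(tumors) for b in tumors[i + 1 :]
    ]
    subsets.append(tumors)
    results: dict[str, ComparisonResult] = {}
    for subset in subsets:
        sub_bundle = bundle.copy()
        sub_bundle.config.tumor_subset = subset
        label = "+".join(t.value for t in subset)
        results[label] = run_comparison(sub_bundle)
    return results


# ---------------------------------------------------------------------------
# one-way sensitivity analysis


def _scale_population(bundle: ModelBundle, factor: float) -> None:
    bundle.population = bundle.population.scaled(factor)


def _scale_tumor_population(bundle: ModelBundle, tumor: Tumor, factor: float) -> None:
    counts = bundle.population.eligible[tumor]
    bundle.population.eligible[tumor] = {y: c * factor for y, c in counts.items()}


def _scale_demographic(bundle: ModelBundle, field: str, factor: float) -> None:
    demo = bundle.population.demographics
    value = getattr(demo, field) * factor
    if field == "fraction_female":
        value = min(value, 1.0)
    setattr(demo, field, value)


def _perturb_hr(bundle: ModelBundle, transition: str, direction: str) -> None:
    """Move every anti-PD-(L)1 metastatic hazard ratio to a CI bound.

    Falls back to +/-10% of the point estimate, with a warning, for specs
    that carry no confidence interval.
    """
    for tumor_arms in bundle.arms.values():
        for arm in tumor_arms.values():
            laws = getattr(arm, transition)
            for label, spec in laws.items():
                if spec.hazard_ratio == 1.0 and spec.hr_ci is None:
                    continue
                if spec.hr_ci is not None:
                    hr = spec.hr_ci[0] if direction == "low" else spec.hr_ci[1]
                else:
                    logger.warning(
                        "%s/%s/%s has no hazard-ratio CI; using +/-10%%",
                        arm.tumor.value,
                        arm.arm_label,
                        label,
                    )
                    hr = spec.hazard_ratio * (0.9 if direction == "low" else 1.1)
                laws[label] = spec.with_hazard_ratio(hr)


def _scale_utilities(bundle: ModelBundle, state: str, factor: float) -> None:
    from .param_model import HealthState

    hs = HealthState(state)
    for tumor, states in bundle.utilities.state_utility.items():
        states[hs] = min(states[hs] * factor, 1.0)


def _scale_ae_disutility(bundle: ModelBundle, factor: float) -> None:
    rows = bundle.adverse_events.rows
    for key, row in list(rows.items()):
        rows[key] = dataclasses.replace(row, disutility=row.disutility * factor)


def sa_variables(bundle: ModelBundle) -> dict[str, Callable[[ModelBundle, str], None]]:
    """Registered one-way perturbations: name -> mutate(bundle, 'low'|'high').

    Mean body weight is carried for interface completeness; it does not
    enter the health-outcome calculations (it drove dosing and costs in the
    cost models this projection descends from) and therefore produces a
    zero impact range.
    """
    variables: dict[str, Callable[[ModelBundle, str], None]] = {
        "eligible_population_all_years": lambda b, d: _scale_population(
            b, 0.9 if d == "low" else 1.1
        ),
        "fraction_female": lambda b, d: _scale_demographic(
            b, "fraction_female", 0.9 if d == "low" else 1.1
        ),
        "mean_entry_age": lambda b, d: _scale_demographic(
            b, "mean_entry_age", 0.9 if d == "low" else 1.1
        ),
        "mean_weight": lambda b, d: _scale_demographic(
            b, "mean_weight_kg", 0.9 if d == "low" else 1.1
        ),
        "metastatic_os_hazard_ratio": lambda b, d: _perturb_hr(b, "m1l_to_death", d),
        "metastatic_pfs_hazard_ratio": lambda b, d: _perturb_hr(b, "m1l_to_m2l", d),
        "ae_disutility": lambda b, d: _scale_ae_disutility(b, 0.9 if d == "low" else 1.1),
    }
    for tumor in bundle.config.tumor_subset:
        variables[f"eligible_population_{tumor.value}"] = (
            lambda b, d, t=tumor: _scale_tumor_population(b, t, 0.9 if d == "low" else 1.1)
        )
    for state in ("recurrence_free", "locoregional_recurrence", "metastatic_1l", "metastatic_2l"):
        variables[f"utility_{state}"] = (
            lambda b, d, s=state: _scale_utilities(b, s, 0.9 if d == "low" else 1.1)
        )
    return variables


def one_way_sa(
    bundle: ModelBundle,
    variables: list[str] | None = None,
    sort_outcome: str = "total_life_years",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way sensitivity analysis with tornado ranking.

    Returns (long, tornado): ``long`` has one row per variable x direction
    x outcome with the varied impact; ``tornado`` has one row per variable
    with low/high impact and range for ``sort_outcome``, sorted by range
    descending.
    """
    registry = sa_variables(bundle)
    if variables is None:
        names = list(registry)
    else:
        unknown = set(variables) - set(registry)
        if unknown:
            raise ValidationError(f"unknown one-way variables: {sorted(unknown)}")
        names = list(variables)
    if sort_outcome not in IMPACT_OUTCOMES:
        raise ValidationError(f"sort_outcome must be one of {IMPACT_OUTCOMES}")

    base = run_comparison(bundle)
    rows = []
    tornado_rows = []
    for name in names:
        impacts = {}
        for direction in ("low", "high"):
            varied_bundle = bundle.copy()
            registry[name](varied_bundle, direction)
            varied = run_comparison(varied_bundle)
            impacts[direction] = varied.difference.cumulative
            for outcome in IMPACT_OUTCOMES:
                rows.append(
                    {
                        "variable": name,
                        "direction": direction,
                        "outcome": outcome,
                        "base_impact": base.difference.cumulative[outcome],
                        "varied_impact": varied.difference.cumulative[outcome],
                    }
                )
        lo = impacts["low"][sort_outcome]
        hi = impacts["high"][sort_outcome]
        tornado_rows.append(
            {
                "variable": name,
                "low_impact": lo,
                "high_impact": hi,
                "range": abs(hi - lo),
            }
        )
    long = pd.DataFrame(rows)
    tornado = (
        pd.DataFrame(tornado_rows)
        .sort_values("range", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    return long, tornado
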