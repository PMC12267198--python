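"""Full projection pipeline: cohorts x arms x scenarios -> outcome tables.

The weekly entry cohorts of one (tumor, arm) pair all share the same
transition laws, so a single unit-entry trace over the full horizon serves
every entry week: the per-cycle accrual matrix of that trace is convolved
with the schedule of weekly entry weights and the result is discounted and
attributed to calendar years.  Arms whose accrual matrices are identical
are merged before convolution, which also guarantees exact scenario
equivalence whenever treatment effects and mixes are null.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort_engine import resolve_mix_slice, run_cohort
from .outcomes_reporting import (
    DISCOUNTED_OUTCOMES,
    OUTCOMES,
    ComparisonResult,
    OutcomeSet,
    compare_scenarios,
    cycle_quantities,
)
from .param_model import ModelBundle, Tumor
from .population_scenarios import (
    ScenarioDefinition,
    arm_share_schedule,
    make_scenarios,
)

__all__ = ["run_scenario", "run_comparison", "TraceCache"]

WEEKS_PER_YEAR = 52


class TraceCache:
    """Cache of per-(tumor, arm, retreatment) accrual matrices for one bundle."""

    def __init__(self, bundle: ModelBundle):
        self.bundle = bundle
        self._cache: dict[tuple[Tumor, str, bool], np.ndarray] = {}

    def quantities(self, tumor: Tumor, arm_label: str, retreatment_allowed: bool) -> np.ndarray:
        key = (tumor, arm_label, retreatment_allowed)
        if key not in self._cache:
            bundle = self.bundle
            arm = bundle.arms[tumor][arm_label]
            mixes = resolve_mix_slice(
                bundle.shares, tumor, arm_label, retreatment_allowed
            )
            trace = run_cohort(
                1.0,
                arm,
                mixes,
                bundle.config,
                bundle.life_table,
                bundle.population.demographics,
                entry_week=0,
            )
            self._cache[key] = cycle_quantities(
                trace,
                bundle.utilities,
                bundle.adverse_events,
                bundle.population.demographics,
                bundle.config,
            )
        return self._cache[key]


def run_scenario(
    bundle: ModelBundle,
    scenario: ScenarioDefinition,
    cache: TraceCache | None = None,
) -> OutcomeSet:
    """Project one scenario over the horizon and return its OutcomeSet."""
    config = bundle.config
    K = config.horizon_weeks
    years = config.year_range()
    cache = cache or TraceCache(bundle)

    t = np.arange(K)
    year_idx = t // WEEKS_PER_YEAR
    disc = (1.0 + config.annual_discount_rate) ** (-t / 52.0)
    ones = np.ones(K)

    per_year = np.zeros((config.horizon_years, len(OUTCOMES)))
    subset = scenario.tumor_subset or config.tumor_subset
    for tumor in subset:
        eligible = np.array(
            [bundle.population.eligible[tumor][y] for y in years]
        )
        arm_shares = arm_share_schedule(tumor, scenario, bundle.shares, config)
        # merge arms with identical accrual matrices so that allocation
        # among indistinguishable arms cannot leave floating-point residue
        groups: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}
        for arm_label, share in arm_shares.items():
            if not share.any():
                continue
            q = cache.quantities(tumor, arm_label, scenario.retreatment_allowed)
            key = q.tobytes()
            if key in groups:
                groups[key] = (groups[key][0], groups[key][1] + share)
            else:
                groups[key] = (q, share.copy())
        for q, share in groups.values():
            if np.all(share == 1.0):
                weekly = eligible / WEEKS_PER_YEAR
            else:
                weekly = eligible * share / WEEKS_PER_YEAR
            s_vec = np.repeat(weekly, WEEKS_PER_YEAR)
            for j, name in enumerate(OUTCOMES):
                c = np.convolve(s_vec, q[:, j])[:K]
                discounted = name in DISCOUNTED_OUTCOMES or config.discount_event_counts
                w = disc if discounted else ones
                per_year[:, j] += np.bincount(
                    year_idx, weights=c * w, minlength=config.horizon_years
                )

    frame = pd.DataFrame(per_year, index=years, columns=OUTCOMES)
    return OutcomeSet.from_per_year(frame)


def run_comparison(bundle: ModelBundle) -> ComparisonResult:
    """Run both scenarios on a shared trace cache and compare them."""
    scenario_i, scenario_ii = make_scenarios(bundle.config, bundle.shares)
    cache = TraceCache(bundle)
    outcomes_i = run_scenario(bundle, scenario_i, cache)
    outcomes_ii = run_scenario(bundle, scenario_ii, cache)
    return compare_scenarios(outcomes_i, outcomes_ii)
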