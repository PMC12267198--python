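"""Entry-cohort construction and scenario arm allocation.

Annual eligible populations are divided evenly over 52 weekly entry
cohorts (the model year is exactly 52 weeks).  Under scenario I the whole
cohort goes to the traditional early-setting options; under scenario II an
uptake fraction initiates anti-PD-(L)1 therapy and the remainder is split
among the traditional options.  Launch delays shift the uptake ramp
forward with pre-launch years at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .param_model import (
    ConfigError,
    MarketShareSchedule,
    ModelConfig,
    PopulationProjection,
    Tumor,
    ValidationError,
)

__all__ = [
    "ANTI_PDL1_ARM",
    "ScenarioDefinition",
    "weekly_entry_cohorts",
    "allocate_arms",
    "implied_uptake",
    "apply_launch_delay",
    "make_scenarios",
    "arm_share_schedule",
]

WEEKS_PER_YEAR = 52

# label of the early-setting anti-PD-(L)1 arm in every tumor's arm set
ANTI_PDL1_ARM = "anti_pdl1"


@dataclass
class ScenarioDefinition:
    """One policy scenario: early-setting uptake plus toggles."""

    label: str
    uptake: dict[Tumor, dict[int, float]]
    retreatment_allowed: bool = True
    tumor_subset: tuple[Tumor, ...] = ()

    def __post_init__(self):
        for tumor, sched in self.uptake.items():
            for year, frac in sched.items():
                if not 0.0 <= frac <= 1.0:
                    raise ValidationError(
                        f"{self.label}: uptake[{tumor.value}][{year}] = {frac} "
                        "outside [0, 1]"
                    )


def weekly_entry_cohorts(
    pop: PopulationProjection, config: ModelConfig
) -> list[tuple[int, Tumor, float]]:
    """Split each calendar year's eligible count into 52 equal weekly cohorts.

    Returns (entry_week, tumor, size) triples covering the whole horizon;
    the sizes sum back to the projection total over the horizon.
    """
    cohorts: list[tuple[int, Tumor, float]] = []
    for tumor, counts in pop.eligible.items():
        for yi, year in enumerate(config.year_range()):
            if year not in counts:
                raise ConfigError(
                    f"population projection for {tumor.value} is missing year {year}"
                )
            weekly = counts[year] / WEEKS_PER_YEAR
            for w in range(WEEKS_PER_YEAR):
                cohorts.append((yi * WEEKS_PER_YEAR + w, tumor, weekly))
    cohorts.sort(key=lambda c: (c[0], c[1].value))
    return cohorts


def allocate_arms(
    cohort_size: float,
    tumor: Tumor,
    year: int,
    scenario: ScenarioDefinition,
    shares: MarketShareSchedule,
) -> dict[str, float]:
    """Split one entry cohort across adjuvant arms under a scenario.

    The anti-PD-(L)1 arm receives the scenario's uptake fraction for the
    year (zero under scenario I); traditional options share the remainder
    per the configured allocation.  Sizes sum exactly to the cohort size.
    """
    uptake = scenario.uptake.get(tumor, {}).get(year, 0.0)
    sizes: dict[str, float] = {}
    anti = cohort_size * uptake
    remainder = cohort_size - anti
    alloc = shares.traditional_allocation[tumor]
    labels = sorted(alloc)
    running = 0.0
    for label in labels[:-1]:
        s = remainder * alloc[label]
        sizes[label] = s
        running += s
    # residual assignment keeps the total exact in floating point
    sizes[labels[-1]] = remainder - running
    sizes[ANTI_PDL1_ARM] = anti
    return sizes


def implied_uptake(
    pop: PopulationProjection, treated: dict[int, float]
) -> dict[int, float]:
    """Per-year uptake fractions implied by treated/eligible counts."""
    out: dict[int, float] = {}
    for year in sorted(treated):
        total = pop.year_total(year)
        out[year] = treated[year] / total if total > 0 else 0.0
    return out


def apply_launch_delay(
    schedule: dict[int, float], delay_years: int
) -> dict[int, float]:
    """Shift an uptake ramp forward by a launch delay.

    The first ``delay_years`` years get zero uptake and the original ramp
    is shifted forward, truncated at the end of the schedule.
    """
    if delay_years < 0:
        raise ValidationError("delay_years must be >= 0")
    years = sorted(schedule)
    values = [schedule[y] for y in years]
    shifted = [0.0] * min(delay_years, len(years)) + values[: max(len(years) - delay_years, 0)]
    return dict(zip(years, shifted))


def make_scenarios(
    config: ModelConfig, shares: MarketShareSchedule
) -> tuple[ScenarioDefinition, ScenarioDefinition]:
    """Build the scenario I / scenario II pair from config toggles.

    Scenario I has identically zero early-setting uptake.  Scenario II uses
    the configured uptake schedule, with the optional flat override and
    launch delay applied, and honours the retreatment toggle.
    """
    subset = config.tumor_subset
    zero = {
        tumor: {year: 0.0 for year in config.year_range()} for tumor in subset
    }
    uptake_ii: dict[Tumor, dict[int, float]] = {}
    for tumor in subset:
        sched = {
            year: shares.uptake[tumor][year] for year in config.year_range()
        }
        if config.uptake_override is not None:
            sched = {year: config.uptake_override for year in sched}
        if config.launch_delay_years:
            sched = apply_launch_delay(sched, config.launch_delay_years)
        uptake_ii[tumor] = sched
    scenario_i = ScenarioDefinition(
        label="scenario_I",
        uptake=zero,
        retreatment_allowed=config.retreatment_allowed,
        tumor_subset=subset,
    )
    scenario_ii = ScenarioDefinition(
        label="scenario_II",
        uptake=uptake_ii,
        retreatment_allowed=config.retreatment_allowed,
        tumor_subset=subset,
    )
    return scenario_i, scenario_ii


def arm_share_schedule(
    tumor: Tumor,
    scenario: ScenarioDefinition,
    shares: MarketShareSchedule,
    config: ModelConfig,
) -> dict[str, np.ndarray]:
    """Per-arm share of each calendar year's entry cohorts (sums to 1)."""
    years = config.year_range()
    out: dict[str, np.ndarray] = {}
    for yi, year in enumerate(years):
        sizes = allocate_arms(1.0, tumor, year, scenario, shares)
        for label, s in sizes.items():
            if label not in out:
                out[label] = np.zeros(len(years))
            out[label][yi] = s
    return out
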