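"""Aggregation of cohort traces into the eight reported outcomes.

Outcomes: recurrence-free life-years, total life-years, QALYs, events or
recurrences, active metastatic treatments, adverse events, total deaths,
and deaths after the first event or recurrence.  Life-years and QALYs are
discounted in calendar time from model start; event counts are reported
undiscounted by default (counts of occurrences), switchable via
``ModelConfig.discount_event_counts``.

Scenario comparisons report the scenario II minus scenario I difference
per outcome and the percent change relative to scenario I, rounded half
away from zero to integers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_engine import CohortTrace, STRATA
from .param_model import (
    AdverseEventProfile,
    AdverseEventRow,
    Demographics,
    HealthState,
    ModelConfig,
    TreatmentSetting,
    UtilitySet,
    ValidationError,
)

__all__ = [
    "OUTCOMES",
    "DISCOUNTED_OUTCOMES",
    "OutcomeSet",
    "ComparisonResult",
    "round_half_away",
    "discount_factor",
    "cycle_quantities",
    "attribute_per_year",
    "accumulate_life_years",
    "accumulate_qalys",
    "ae_burden",
    "count_events",
    "trace_outcomes",
    "compare_scenarios",
    "write_comparison",
]

OUTCOMES = (
    "recurrence_free_life_years",
    "total_life_years",
    "qalys",
    "events_or_recurrences",
    "active_metastatic_treatments",
    "adverse_events",
    "total_deaths",
    "deaths_after_first_event",
)

# life-years and QALYs are always discounted; the rest are occurrence counts
DISCOUNTED_OUTCOMES = ("recurrence_free_life_years", "total_life_years", "qalys")

PROVENANCE_NOTE = (
    "synthetic parameter bundle - transition, utility and adverse-event "
    "inputs are generated placeholders, not trial-derived estimates"
)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def discount_factor(cycle: int, annual_rate: float) -> float:
    """Discount factor for a weekly cycle counted from model start."""
    if annual_rate < 0:
        raise ValidationError("annual discount rate must be >= 0")
    return float((1.0 + annual_rate) ** (-cycle / 52.0))


@dataclass
class OutcomeSet:
    """The eight outcomes, cumulative and (optionally) per calendar year."""

    cumulative: pd.Series
    per_year: pd.DataFrame | None = None

    def __post_init__(self):
        self.cumulative = self.cumulative.reindex(OUTCOMES).astype(float)
        if self.per_year is not None:
            self.per_year = self.per_year.reindex(columns=OUTCOMES).astype(float)

    @classmethod
    def from_per_year(cls, per_year: pd.DataFrame) -> "OutcomeSet":
        return cls(cumulative=per_year.sum(axis=0), per_year=per_year)

    @classmethod
    def from_cumulative(cls, values: dict[str, float]) -> "OutcomeSet":
        return cls(cumulative=pd.Series(values, dtype=float))

    @classmethod
    def zeros(cls, years: list[int]) -> "OutcomeSet":
        per_year = pd.DataFrame(0.0, index=years, columns=OUTCOMES)
        return cls.from_per_year(per_year)

    def __sub__(self, other: "OutcomeSet") -> "OutcomeSet":
        per_year = None
        if self.per_year is not None and other.per_year is not None:
            per_year = self.per_year - other.per_year
        return OutcomeSet(cumulative=self.cumulative - other.cumulative, per_year=per_year)

    def __add__(self, other: "OutcomeSet") -> "OutcomeSet":
        per_year = None
        if self.per_year is not None and other.per_year is not None:
            per_year = self.per_year + other.per_year
        return OutcomeSet(cumulative=self.cumulative + other.cumulative, per_year=per_year)

    def scaled(self, factor: float) -> "OutcomeSet":
        return OutcomeSet(
            cumulative=self.cumulative * factor,
            per_year=None if self.per_year is None else self.per_year * factor,
        )


@dataclass
class ComparisonResult:
    """Scenario I vs II outcomes with differences and rounded percent changes."""

    outcomes_i: OutcomeSet
    outcomes_ii: OutcomeSet
    difference: OutcomeSet
    percent_change: dict[str, int | None]
    percent_change_per_year: pd.DataFrame | None = None

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario_I": self.outcomes_i.cumulative,
                "scenario_II": self.outcomes_ii.cumulative,
                "difference": self.difference.cumulative,
                "percent_change": pd.Series(
                    self.percent_change, dtype="object"
                ).reindex(OUTCOMES),
            }
        )


def compare_scenarios(outcomes_i: OutcomeSet, outcomes_ii: OutcomeSet) -> ComparisonResult:
    """Difference (II - I) and integer percent change relative to scenario I.

    Percent changes are rounded half away from zero; a zero scenario I
    value leaves the percent change undefined (reported as None/NaN).
    """
    difference = outcomes_ii - outcomes_i
    pct: dict[str, int | None] = {}
    for name in OUTCOMES:
        base = outcomes_i.cumulative[name]
        if base == 0 or np.isnan(base):
            pct[name] = None
        else:
            pct[name] = round_half_away(100.0 * difference.cumulative[name] / base)
    pct_per_year = None
    if difference.per_year is not None and outcomes_i.per_year is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = 100.0 * difference.per_year.values / outcomes_i.per_year.values
        raw[outcomes_i.per_year.values == 0] = np.nan
        rounded = np.where(
            np.isnan(raw), np.nan, np.copysign(np.floor(np.abs(raw) + 0.5), raw)
        )
        pct_per_year = pd.DataFrame(
            rounded, index=difference.per_year.index, columns=OUTCOMES
        )
    return ComparisonResult(
        outcomes_i=outcomes_i,
        outcomes_ii=outcomes_ii,
        difference=difference,
        percent_change=pct,
        percent_change_per_year=pct_per_year,
    )


# ---------------------------------------------------------------------------
# trace-level accounting


def ae_burden(initiations: float, row: AdverseEventRow) -> tuple[float, float]:
    """Adverse events and undiscounted QALY loss for a block of initiations.

    Events are one-time at treatment initiation: the count is initiations
    times events per patient, and the QALY loss is the event count times the
    average weeks per event times the disutility magnitude, expressed in
    years.
    """
    if initiations < 0:
        raise ValidationError("initiations must be >= 0")
    count = initiations * row.events_per_patient
    qaly_loss = count * row.weeks_per_event * abs(row.disutility) / 52.0
    return count, qaly_loss


def cycle_quantities(
    trace: CohortTrace,
    utilities: UtilitySet,
    adverse_events: AdverseEventProfile,
    demographics: Demographics,
    config: ModelConfig,
) -> np.ndarray:
    """Per-cycle outcome accruals for one trace: array (n_cycles, 8).

    Undiscounted; columns follow :data:`OUTCOMES`.  Life-year columns carry
    person-years accrued during each cycle (start-of-cycle occupancy / 52),
    the QALY column additionally weights by state utility and the age/sex
    adjustment and subtracts adverse-event disutility losses at initiation
    cycles, and count columns carry occurrences.
    """
    K = trace.n_cycles
    q = np.zeros((K, len(OUTCOMES)))
    if K == 0:
        return q
    # a cycle spent in a state is credited once its transitions are resolved
    # (end-of-cycle occupancy), so a cohort that dies during its entry cycle
    # accrues nothing
    occ_rf = trace.occupancy[HealthState.RECURRENCE_FREE][1 : K + 1]
    occ_lr = trace.occupancy[HealthState.LOCOREGIONAL_RECURRENCE][1 : K + 1]
    occ_m1 = trace.occupancy[HealthState.METASTATIC_1L][1 : K + 1]
    occ_m2 = trace.occupancy[HealthState.METASTATIC_2L][1 : K + 1]
    alive = occ_rf + occ_lr + occ_m1 + occ_m2

    q[:, 0] = occ_rf / 52.0
    q[:, 1] = alive / 52.0

    tumor = trace.tumor
    age_factor = utilities.age_factor_curve(
        demographics.mean_entry_age, K, demographics.fraction_female
    )
    u = {
        s: utilities.utility(tumor, s)
        for s in (
            HealthState.RECURRENCE_FREE,
            HealthState.LOCOREGIONAL_RECURRENCE,
            HealthState.METASTATIC_1L,
            HealthState.METASTATIC_2L,
        )
    }
    qaly = (
        occ_rf * u[HealthState.RECURRENCE_FREE]
        + occ_lr * u[HealthState.LOCOREGIONAL_RECURRENCE]
        + occ_m1 * u[HealthState.METASTATIC_1L]
        + occ_m2 * u[HealthState.METASTATIC_2L]
    ) * age_factor / 52.0

    ae_counts = np.zeros(K)
    ae_losses = np.zeros(K)
    adj_row = adverse_events.get(tumor, TreatmentSetting.ADJUVANT, trace.arm_label)
    c0, l0 = ae_burden(trace.entry_size, adj_row)
    ae_counts[0] += c0
    ae_losses[0] += l0
    for setting, ledger in (
        (TreatmentSetting.METASTATIC_1L, trace.init_1l),
        (TreatmentSetting.METASTATIC_2L, trace.init_2l),
    ):
        for s in STRATA:
            for label, inits in ledger[s].items():
                row = adverse_events.get(tumor, setting, label)
                if row.events_per_patient == 0.0:
                    continue
                counts = inits * row.events_per_patient
                ae_counts += counts
                ae_losses += counts * row.weeks_per_event * abs(row.disutility) / 52.0

    q[:, 2] = qaly - ae_losses
    q[:, 3] = trace.recurrences
    q[:, 4] = trace.initiations_1l() + trace.initiations_2l()
    q[:, 5] = ae_counts
    q[:, 6] = trace.deaths
    q[:, 7] = trace.deaths_after_event
    return q


def attribute_per_year(
    values: np.ndarray,
    entry_week: int,
    config: ModelConfig,
    discounted: bool = True,
) -> np.ndarray:
    """Distribute per-cycle accruals over calendar years with discounting.

    Cycle ``k`` of a trace entered at ``entry_week`` falls in absolute week
    ``entry_week + k``; it is attributed to that week's calendar year and
    discounted from model start.
    """
    K = len(values)
    t = entry_week + np.arange(K)
    weights = values
    if discounted:
        weights = weights * (1.0 + config.annual_discount_rate) ** (-t / 52.0)
    return np.bincount(t // 52, weights=weights, minlength=config.horizon_years)


def accumulate_life_years(
    trace: CohortTrace, config: ModelConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Discounted (recurrence-free, total) life-years per calendar year."""
    K = trace.n_cycles
    occ_rf = trace.occupancy[HealthState.RECURRENCE_FREE][1 : K + 1]
    alive = trace.alive()[1 : K + 1]
    rf_ly = attribute_per_year(occ_rf / 52.0, trace.entry_week, config)
    total_ly = attribute_per_year(alive / 52.0, trace.entry_week, config)
    return rf_ly, total_ly


def accumulate_qalys(
    trace: CohortTrace,
    utilities: UtilitySet,
    adverse_events: AdverseEventProfile,
    demographics: Demographics,
    config: ModelConfig,
) -> np.ndarray:
    """Discounted QALYs per calendar year, adverse-event losses included."""
    q = cycle_quantities(trace, utilities, adverse_events, demographics, config)
    return attribute_per_year(q[:, 2], trace.entry_week, config)


def count_events(trace: CohortTrace, config: ModelConfig) -> dict[str, np.ndarray]:
    """Event counts per calendar year (undiscounted unless configured)."""
    disc = config.discount_event_counts
    return {
        "events_or_recurrences": attribute_per_year(
            trace.recurrences, trace.entry_week, config, discounted=disc
        ),
        "active_metastatic_treatments": attribute_per_year(
            trace.initiations_1l() + trace.initiations_2l(),
            trace.entry_week,
            config,
            discounted=disc,
        ),
        "total_deaths": attribute_per_year(
            trace.deaths, trace.entry_week, config, discounted=disc
        ),
        "deaths_after_first_event": attribute_per_year(
            trace.deaths_after_event, trace.entry_week, config, discounted=disc
        ),
    }


def trace_outcomes(
    trace: CohortTrace,
    utilities: UtilitySet,
    adverse_events: AdverseEventProfile,
    demographics: Demographics,
    config: ModelConfig,
) -> OutcomeSet:
    """Full OutcomeSet for a single cohort trace."""
    q = cycle_quantities(trace, utilities, adverse_events, demographics, config)
    per_year = {}
    for j, name in enumerate(OUTCOMES):
        discounted = name in DISCOUNTED_OUTCOMES or config.discount_event_counts
        per_year[name] = attribute_per_year(
            q[:, j], trace.entry_week, config, discounted=discounted
        )
    frame = pd.DataFrame(per_year, index=config.year_range())
    return OutcomeSet.from_per_year(frame)


# ---------------------------------------------------------------------------
# result writers


def write_comparison(result: ComparisonResult, out_dir: str | Path, stem: str = "base_case") -> dict[str, Path]:
    """Write cumulative and per-year comparison tables as CSV and JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    cumulative = result.summary_frame()
    p = out_dir / f"{stem}_cumulative.csv"
    with open(p, "w") as fh:
        fh.write(f"# {PROVENANCE_NOTE}\n")
        cumulative.to_csv(fh, index_label="outcome")
    paths["cumulative_csv"] = p

    if result.difference.per_year is not None:
        per_year = result.difference.per_year.copy()
        p = out_dir / f"{stem}_per_year_difference.csv"
        with open(p, "w") as fh:
            fh.write(f"# {PROVENANCE_NOTE}\n")
            per_year.to_csv(fh, index_label="year")
        paths["per_year_csv"] = p

    payload = {
        "provenance": PROVENANCE_NOTE,
        "cumulative": {
            "scenario_I": result.outcomes_i.cumulative.to_dict(),
            "scenario_II": result.outcomes_ii.cumulative.to_dict(),
            "difference": result.difference.cumulative.to_dict(),
            "percent_change": result.percent_change,
        },
    }
    if result.difference.per_year is not None:
        payload["per_year_difference"] = {
            str(year): row.to_dict()
            for year, row in result.difference.per_year.iterrows()
        }
    p = out_dir / f"{stem}.json"
    with open(p, "w") as fh:
        json.dump(payload, fh, indent=2)
    paths["json"] = p
    return paths
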