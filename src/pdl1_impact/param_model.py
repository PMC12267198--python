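"""Domain types for the projection model and configuration loading/validation.

The model compares two national treatment policies for three early-stage
cancers (melanoma, renal cell carcinoma, triple-negative breast cancer):
anti-PD-(L)1 agents reserved for the advanced/metastatic setting versus
also made available as neoadjuvant/adjuvant therapy.  Every quantitative
input — eligible populations, per-transition survival laws, market shares,
utilities, adverse-event profiles and a background-mortality life table —
is carried by the types defined here and can be round-tripped through a
single YAML configuration file.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Tumor",
    "HealthState",
    "Stratum",
    "TreatmentSetting",
    "SurvivalSpec",
    "LifeTable",
    "ArmTransitionModel",
    "MarketShareSchedule",
    "UtilitySet",
    "AgeBand",
    "AdverseEventRow",
    "AdverseEventProfile",
    "Demographics",
    "PopulationProjection",
    "ModelConfig",
    "ModelBundle",
    "ConfigError",
    "ValidationError",
    "load_config",
    "save_config",
    "bundle_to_dict",
    "bundle_from_dict",
    "validate_shared_transitions",
]

MIX_TOL = 1e-9
WEEKS_PER_YEAR = 52


class ConfigError(Exception):
    """Raised when a configuration file is missing or malformed."""


class ValidationError(ConfigError):
    """Raised when a loaded value violates a model invariant."""


class Tumor(str, Enum):
    MELANOMA = "melanoma"
    RCC = "rcc"
    TNBC = "tnbc"


class HealthState(str, Enum):
    RECURRENCE_FREE = "recurrence_free"
    LOCOREGIONAL_RECURRENCE = "locoregional_recurrence"
    METASTATIC_1L = "metastatic_1l"
    METASTATIC_2L = "metastatic_2l"
    DEAD = "dead"


ALIVE_STATES = (
    HealthState.RECURRENCE_FREE,
    HealthState.LOCOREGIONAL_RECURRENCE,
    HealthState.METASTATIC_1L,
    HealthState.METASTATIC_2L,
)


class Stratum(str, Enum):
    """Retreatment-eligibility stratum at metastatic treatment initiation.

    Patients starting first-line metastatic therapy earlier than the
    retreatment threshold (18 months after adjuvant initiation by default)
    are not eligible for anti-PD-(L)1 retreatment.
    """

    BEFORE_THRESHOLD = "before_threshold"
    AT_OR_AFTER_THRESHOLD = "at_or_after_threshold"


class TreatmentSetting(str, Enum):
    ADJUVANT = "adjuvant"
    METASTATIC_1L = "metastatic_1l"
    METASTATIC_2L = "metastatic_2l"


SURVIVAL_FAMILIES = {
    # family -> (parameter names, positivity constraints per parameter)
    "exponential": (("rate",), (True,)),
    "weibull": (("shape", "scale"), (True, True)),
    "lognormal": (("mu", "sigma"), (False, True)),
    "loglogistic": (("shape", "scale"), (True, True)),
    "gompertz": (("shape", "rate"), (False, True)),
    "generalized_gamma": (("mu", "sigma", "q"), (False, True, False)),
}


@dataclass(frozen=True)
class SurvivalSpec:
    """A parametric time-to-event law governing one transition for one arm.

    Time is measured in weeks.  ``hazard_ratio`` acts multiplicatively on
    the whole-curve hazard (proportional hazards), i.e. the effective
    survival function is the baseline survival raised to the power of the
    hazard ratio.  ``hr_ci`` optionally carries 95% confidence bounds used
    by the one-way sensitivity analysis.
    """

    family: str
    params: tuple[float, ...]
    hazard_ratio: float = 1.0
    hr_ci: tuple[float, float] | None = None

    def __post_init__(self):
        if self.family not in SURVIVAL_FAMILIES:
            raise ValidationError(
                f"unknown survival family {self.family!r}; "
                f"expected one of {sorted(SURVIVAL_FAMILIES)}"
            )
        names, positive = SURVIVAL_FAMILIES[self.family]
        params = tuple(float(p) for p in self.params)
        object.__setattr__(self, "params", params)
        if len(params) != len(names):
            raise ValidationError(
                f"{self.family} expects {len(names)} parameters {names}, "
                f"got {len(params)}"
            )
        for name, pos, value in zip(names, positive, params):
            if not np.isfinite(value):
                raise ValidationError(f"{self.family}.{name} must be finite")
            if pos and value <= 0:
                raise ValidationError(
                    f"{self.family}.{name} must be > 0, got {value}"
                )
        # hazard_ratio == 0 is accepted as the degenerate no-hazard limit
        if not np.isfinite(self.hazard_ratio) or self.hazard_ratio < 0:
            raise ValidationError(
                f"hazard_ratio must be a finite non-negative real, got {self.hazard_ratio}"
            )
        if self.hr_ci is not None:
            lo, hi = (float(b) for b in self.hr_ci)
            object.__setattr__(self, "hr_ci", (lo, hi))
            if not (0 < lo <= self.hazard_ratio <= hi):
                raise ValidationError(
                    f"hazard ratio CI ({lo}, {hi}) must bracket the point "
                    f"estimate {self.hazard_ratio}"
                )

    def with_hazard_ratio(self, hr: float) -> "SurvivalSpec":
        ci = self.hr_ci
        if ci is not None and not (ci[0] <= hr <= ci[1]):
            ci = None
        return dataclasses.replace(self, hazard_ratio=hr, hr_ci=ci)


@dataclass
class LifeTable:
    """Annual background death probabilities q(age, sex) for ages 0-100.

    The table is closed at age 100 (q = 1).  Ages above the last row use
    the closing row.
    """

    q_female: np.ndarray
    q_male: np.ndarray

    MAX_AGE = 100

    def __post_init__(self):
        self.q_female = np.asarray(self.q_female, dtype=float)
        self.q_male = np.asarray(self.q_male, dtype=float)
        for name, q in (("q_female", self.q_female), ("q_male", self.q_male)):
            if q.shape != (self.MAX_AGE + 1,):
                raise ValidationError(
                    f"life table {name} must have {self.MAX_AGE + 1} rows "
                    f"(ages 0-{self.MAX_AGE}), got {q.shape}"
                )
            if np.any(q < 0) or np.any(q > 1):
                raise ValidationError(f"life table {name} has entries outside [0, 1]")
            if q[-1] != 1.0:
                raise ValidationError(
                    f"life table {name} must close with q({self.MAX_AGE}+) = 1"
                )

    def annual_q(self, age: float, sex: str) -> float:
        idx = min(int(np.floor(age)), self.MAX_AGE)
        if idx < 0:
            raise ValidationError(f"age must be >= 0, got {age}")
        if sex == "female":
            return float(self.q_female[idx])
        if sex == "male":
            return float(self.q_male[idx])
        raise ValidationError(f"sex must be 'female' or 'male', got {sex!r}")

    def pooled_annual_q(self, age: float, fraction_female: float) -> float:
        """Sex-weighted annual death probability for a pooled cohort."""
        return fraction_female * self.annual_q(age, "female") + (
            1.0 - fraction_female
        ) * self.annual_q(age, "male")


@dataclass
class ArmTransitionModel:
    """All transition laws for one adjuvant-arm/tumor pair.

    Recurrence-free exits depend on the adjuvant arm; locoregional-
    recurrence exits are shared across arms within a tumor (validated by
    :func:`validate_shared_transitions`).  First-line metastatic exits are
    keyed by the 1L treatment option actually received.
    """

    tumor: Tumor
    arm_label: str
    rf_to_lr: SurvivalSpec
    rf_to_met: SurvivalSpec
    rf_to_death: SurvivalSpec
    lr_to_met: SurvivalSpec
    lr_to_death: SurvivalSpec
    m1l_to_m2l: dict[str, SurvivalSpec]
    m1l_to_death: dict[str, SurvivalSpec]
    m2l_to_death: SurvivalSpec

    def __post_init__(self):
        self.tumor = Tumor(self.tumor)
        if set(self.m1l_to_m2l) != set(self.m1l_to_death):
            raise ValidationError(
                f"{self.tumor.value}/{self.arm_label}: 1L progression and 1L "
                "death laws must be keyed by the same treatment labels"
            )

    @property
    def treatment_labels_1l(self) -> tuple[str, ...]:
        return tuple(sorted(self.m1l_to_m2l))


@dataclass
class MarketShareSchedule:
    """Uptake and treatment-mix schedules.

    ``uptake`` is the fraction of each tumor's eligible population that
    initiates anti-PD-(L)1 therapy in the early setting under scenario II
    for each calendar year (identically zero under scenario I).
    ``traditional_allocation`` splits the remainder among the traditional
    early-setting options.  ``mix_1l`` and ``mix_2l`` give line-specific
    metastatic treatment mixes conditional on the adjuvant arm and the
    retreatment-eligibility stratum.
    """

    uptake: dict[Tumor, dict[int, float]]
    traditional_allocation: dict[Tumor, dict[str, float]]
    mix_1l: dict[Tumor, dict[str, dict[Stratum, dict[str, float]]]]
    mix_2l: dict[Tumor, dict[str, dict[Stratum, dict[str, float]]]]

    def __post_init__(self):
        self.uptake = {
            Tumor(t): {int(y): float(v) for y, v in sched.items()}
            for t, sched in self.uptake.items()
        }
        for tumor, sched in self.uptake.items():
            for year, frac in sched.items():
                if not 0.0 <= frac <= 1.0:
                    raise ValidationError(
                        f"uptake[{tumor.value}][{year}] = {frac} outside [0, 1]"
                    )
        self.traditional_allocation = {
            Tumor(t): dict(v) for t, v in self.traditional_allocation.items()
        }
        for tumor, alloc in self.traditional_allocation.items():
            _check_mix(alloc, f"traditional_allocation[{tumor.value}]")
        self.mix_1l = _normalize_mix_tree(self.mix_1l, "mix_1l")
        self.mix_2l = _normalize_mix_tree(self.mix_2l, "mix_2l")


def _check_mix(mix: Mapping[str, float], where: str) -> None:
    total = 0.0
    for label, frac in mix.items():
        if not 0.0 <= frac <= 1.0:
            raise ValidationError(f"{where}[{label}] = {frac} outside [0, 1]")
        total += frac
    if abs(total - 1.0) > MIX_TOL:
        raise ValidationError(f"{where} sums to {total!r}, expected 1 within {MIX_TOL}")


def _normalize_mix_tree(tree, name):
    out: dict[Tumor, dict[str, dict[Stratum, dict[str, float]]]] = {}
    for t, arms in tree.items():
        tumor = Tumor(t)
        out[tumor] = {}
        for arm, strata in arms.items():
            out[tumor][arm] = {}
            for s, mix in strata.items():
                stratum = Stratum(s)
                mix = {str(k): float(v) for k, v in mix.items()}
                _check_mix(mix, f"{name}[{tumor.value}][{arm}][{stratum.value}]")
                out[tumor][arm][stratum] = mix
    return out


@dataclass(frozen=True)
class AgeBand:
    """Multiplicative utility adjustment for one age band."""

    min_age: float
    female: float
    male: float

    def __post_init__(self):
        for sex in ("female", "male"):
            v = getattr(self, sex)
            if not 0.0 < v <= 1.0:
                raise ValidationError(
                    f"age-band adjustment ({sex}, min_age={self.min_age}) "
                    f"must lie in (0, 1], got {v}"
                )


@dataclass
class UtilitySet:
    """Health-state utilities on the 0-1 scale plus age/sex adjustments."""

    state_utility: dict[Tumor, dict[HealthState, float]]
    age_bands: list[AgeBand]

    def __post_init__(self):
        self.state_utility = {
            Tumor(t): {HealthState(s): float(u) for s, u in states.items()}
            for t, states in self.state_utility.items()
        }
        for tumor, states in self.state_utility.items():
            for state, u in states.items():
                if not 0.0 <= u <= 1.0:
                    raise ValidationError(
                        f"utility[{tumor.value}][{state.value}] = {u} outside [0, 1]"
                    )
            if states.get(HealthState.DEAD, 0.0) != 0.0:
                raise ValidationError(
                    f"utility[{tumor.value}][dead] must be 0"
                )
        self.age_bands = sorted(self.age_bands, key=lambda b: b.min_age)
        if not self.age_bands:
            raise ValidationError("at least one age band is required")

    def utility(self, tumor: Tumor, state: HealthState) -> float:
        states = self.state_utility[Tumor(tumor)]
        if state == HealthState.DEAD:
            return 0.0
        return states[state]

    def age_factor(self, age: float, fraction_female: float) -> float:
        band = self.age_bands[0]
        for candidate in self.age_bands:
            if age >= candidate.min_age:
                band = candidate
            else:
                break
        return fraction_female * band.female + (1.0 - fraction_female) * band.male

    def age_factor_curve(
        self, entry_age: float, n_cycles: int, fraction_female: float
    ) -> np.ndarray:
        ages = entry_age + np.arange(n_cycles) / WEEKS_PER_YEAR
        return np.array([self.age_factor(a, fraction_female) for a in ages])


@dataclass(frozen=True)
class AdverseEventRow:
    """Average adverse-event burden at one treatment initiation.

    Events are one-time: the expected number of grade-3+ events per
    initiating patient, the average duration of one event in weeks, and the
    utility decrement (<= 0) applied for that duration.
    """

    events_per_patient: float
    weeks_per_event: float
    disutility: float

    def __post_init__(self):
        if self.events_per_patient < 0 or self.weeks_per_event < 0:
            raise ValidationError(
                "events_per_patient and weeks_per_event must be >= 0"
            )
        if self.disutility > 0:
            raise ValidationError(f"disutility must be <= 0, got {self.disutility}")


ZERO_AE = AdverseEventRow(0.0, 0.0, 0.0)


@dataclass
class AdverseEventProfile:
    """AE rows keyed by (tumor, treatment setting, arm or treatment label)."""

    rows: dict[tuple[Tumor, TreatmentSetting, str], AdverseEventRow]

    def __post_init__(self):
        self.rows = {
            (Tumor(t), TreatmentSetting(s), str(label)): row
            for (t, s, label), row in self.rows.items()
        }

    def get(self, tumor: Tumor, setting: TreatmentSetting, label: str) -> AdverseEventRow:
        """Row for one initiation; absent rows mean no adverse-event burden."""
        return self.rows.get((Tumor(tumor), TreatmentSetting(setting), label), ZERO_AE)


@dataclass
class Demographics:
    mean_entry_age: float
    fraction_female: float
    mean_weight_kg: float

    def __post_init__(self):
        if not 0.0 <= self.fraction_female <= 1.0:
            raise ValidationError(
                f"fraction_female must lie in [0, 1], got {self.fraction_female}"
            )
        if self.mean_entry_age < 0:
            raise ValidationError("mean_entry_age must be >= 0")
        if self.mean_weight_kg <= 0:
            raise ValidationError("mean_weight_kg must be > 0")


@dataclass
class PopulationProjection:
    """Annual eligible incident patients per tumor plus cohort demographics."""

    eligible: dict[Tumor, dict[int, float]]
    demographics: Demographics
    treated_scenario_ii: dict[int, float] | None = None

    def __post_init__(self):
        self.eligible = {
            Tumor(t): {int(y): float(c) for y, c in counts.items()}
            for t, counts in self.eligible.items()
        }
        for tumor, counts in self.eligible.items():
            years = sorted(counts)
            if any(c < 0 for c in counts.values()):
                raise ValidationError(f"eligible counts for {tumor.value} must be >= 0")
            if years and years != list(range(years[0], years[-1] + 1)):
                raise ValidationError(
                    f"eligible years for {tumor.value} must be contiguous"
                )
        if self.treated_scenario_ii is not None:
            self.treated_scenario_ii = {
                int(y): float(c) for y, c in self.treated_scenario_ii.items()
            }

    def years(self) -> list[int]:
        years: set[int] = set()
        for counts in self.eligible.values():
            years.update(counts)
        return sorted(years)

    def year_total(self, year: int) -> float:
        return sum(counts.get(year, 0.0) for counts in self.eligible.values())

    def total(self) -> float:
        return sum(self.year_total(y) for y in self.years())

    def scaled(self, factor: float) -> "PopulationProjection":
        return PopulationProjection(
            eligible={
                t: {y: c * factor for y, c in counts.items()}
                for t, counts in self.eligible.items()
            },
            demographics=copy.deepcopy(self.demographics),
            treated_scenario_ii=(
                None
                if self.treated_scenario_ii is None
                else {y: c * factor for y, c in self.treated_scenario_ii.items()}
            ),
        )


DEFAULT_TUMOR_SUBSET = (Tumor.MELANOMA, Tumor.RCC, Tumor.TNBC)


@dataclass
class ModelConfig:
    """Global settings: horizon, discounting, retreatment, scenario toggles."""

    horizon_years: int = 10
    start_year: int = 2022
    cycle_length_weeks: int = 1
    annual_discount_rate: float = 0.015
    retreatment_threshold_weeks: int = 78
    discount_event_counts: bool = False
    retreatment_allowed: bool = True
    launch_delay_years: int = 0
    uptake_override: float | None = None
    tumor_subset: tuple[Tumor, ...] = DEFAULT_TUMOR_SUBSET
    seed: int = 0

    def __post_init__(self):
        if self.cycle_length_weeks != 1:
            raise ValidationError("the model runs on weekly cycles (cycle_length_weeks = 1)")
        if self.horizon_years <= 0:
            raise ValidationError("horizon_years must be > 0")
        if self.annual_discount_rate < 0:
            raise ValidationError("annual_discount_rate must be >= 0")
        if self.retreatment_threshold_weeks <= 0:
            raise ValidationError("retreatment_threshold_weeks must be > 0")
        if self.launch_delay_years < 0:
            raise ValidationError("launch_delay_years must be >= 0")
        if self.uptake_override is not None and not 0.0 <= self.uptake_override <= 1.0:
            raise ValidationError("uptake_override must lie in [0, 1]")
        subset = tuple(Tumor(t) for t in self.tumor_subset)
        if not subset:
            raise ValidationError("tumor_subset must be non-empty")
        self.tumor_subset = subset

    @property
    def horizon_weeks(self) -> int:
        return self.horizon_years * WEEKS_PER_YEAR

    def year_range(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.horizon_years))


@dataclass
class ModelBundle:
    """Everything needed to run the projection: settings plus all inputs."""

    config: ModelConfig
    population: PopulationProjection
    life_table: LifeTable
    arms: dict[Tumor, dict[str, ArmTransitionModel]]
    shares: MarketShareSchedule
    utilities: UtilitySet
    adverse_events: AdverseEventProfile

    def __post_init__(self):
        self.arms = {
            Tumor(t): dict(models) for t, models in self.arms.items()
        }
        self._cross_validate()

    def _cross_validate(self):
        for tumor in self.config.tumor_subset:
            if tumor not in self.arms:
                raise ValidationError(f"no arms defined for tumor {tumor.value}")
            if tumor not in self.population.eligible:
                raise ValidationError(f"no population for tumor {tumor.value}")
            if tumor not in self.shares.uptake:
                raise ValidationError(f"no uptake schedule for tumor {tumor.value}")
            for year in self.config.year_range():
                if year not in self.population.eligible[tumor]:
                    raise ValidationError(
                        f"population for {tumor.value} is missing year {year}"
                    )
                if year not in self.shares.uptake[tumor]:
                    raise ValidationError(
                        f"uptake schedule for {tumor.value} is missing year {year}"
                    )
            for arm_label, arm in self.arms[tumor].items():
                for mix_name, tree in (("mix_1l", self.shares.mix_1l), ("mix_2l", self.shares.mix_2l)):
                    if arm_label not in tree.get(tumor, {}):
                        raise ValidationError(
                            f"{mix_name} missing for {tumor.value}/{arm_label}"
                        )
                    for stratum in Stratum:
                        if stratum not in tree[tumor][arm_label]:
                            raise ValidationError(
                                f"{mix_name}[{tumor.value}][{arm_label}] missing "
                                f"stratum {stratum.value}"
                            )
                labels = set(arm.m1l_to_m2l)
                for stratum, mix in self.shares.mix_1l[tumor][arm_label].items():
                    unknown = set(mix) - labels
                    if unknown:
                        raise ValidationError(
                            f"mix_1l[{tumor.value}][{arm_label}][{stratum.value}] "
                            f"references 1L treatments without transition laws: "
                            f"{sorted(unknown)}"
                        )

    def copy(self) -> "ModelBundle":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# serialization


def _spec_to_dict(spec: SurvivalSpec) -> dict:
    d: dict = {"family": spec.family, "params": list(spec.params)}
    if spec.hazard_ratio != 1.0:
        d["hazard_ratio"] = spec.hazard_ratio
    if spec.hr_ci is not None:
        d["hr_ci"] = list(spec.hr_ci)
    return d


def _spec_from_dict(d: Mapping, where: str) -> SurvivalSpec:
    try:
        return SurvivalSpec(
            family=d["family"],
            params=tuple(d["params"]),
            hazard_ratio=float(d.get("hazard_ratio", 1.0)),
            hr_ci=tuple(d["hr_ci"]) if d.get("hr_ci") is not None else None,
        )
    except KeyError as exc:
        raise ConfigError(f"{where}: missing survival-spec field {exc}") from exc


ARM_SPEC_FIELDS = ("rf_to_lr", "rf_to_met", "rf_to_death", "lr_to_met", "lr_to_death")


def bundle_to_dict(bundle: ModelBundle) -> dict:
    cfg = bundle.config
    arms_d: dict = {}
    for tumor, models in bundle.arms.items():
        arms_d[tumor.value] = {}
        for arm_label, arm in models.items():
            d = {f: _spec_to_dict(getattr(arm, f)) for f in ARM_SPEC_FIELDS}
            d["m1l_to_m2l"] = {k: _spec_to_dict(v) for k, v in arm.m1l_to_m2l.items()}
            d["m1l_to_death"] = {k: _spec_to_dict(v) for k, v in arm.m1l_to_death.items()}
            d["m2l_to_death"] = _spec_to_dict(arm.m2l_to_death)
            arms_d[tumor.value][arm_label] = d
    return {
        "settings": {
            "horizon_years": cfg.horizon_years,
            "start_year": cfg.start_year,
            "cycle_length_weeks": cfg.cycle_length_weeks,
            "annual_discount_rate": cfg.annual_discount_rate,
            "retreatment_threshold_weeks": cfg.retreatment_threshold_weeks,
            "discount_event_counts": cfg.discount_event_counts,
            "retreatment_allowed": cfg.retreatment_allowed,
            "launch_delay_years": cfg.launch_delay_years,
            "uptake_override": cfg.uptake_override,
            "tumor_subset": [t.value for t in cfg.tumor_subset],
            "seed": cfg.seed,
        },
        "population": {
            "demographics": {
                "mean_entry_age": bundle.population.demographics.mean_entry_age,
                "fraction_female": bundle.population.demographics.fraction_female,
                "mean_weight_kg": bundle.population.demographics.mean_weight_kg,
            },
            "eligible": {
                t.value: dict(sorted(c.items()))
                for t, c in bundle.population.eligible.items()
            },
            "treated_scenario_ii": (
                None
                if bundle.population.treated_scenario_ii is None
                else dict(sorted(bundle.population.treated_scenario_ii.items()))
            ),
        },
        "life_table": {
            "q_female": [float(v) for v in bundle.life_table.q_female],
            "q_male": [float(v) for v in bundle.life_table.q_male],
        },
        "arms": arms_d,
        "market_shares": {
            "uptake": {t.value: dict(sorted(s.items())) for t, s in bundle.shares.uptake.items()},
            "traditional_allocation": {
                t.value: dict(a) for t, a in bundle.shares.traditional_allocation.items()
            },
            "mix_1l": _mix_tree_to_dict(bundle.shares.mix_1l),
            "mix_2l": _mix_tree_to_dict(bundle.shares.mix_2l),
        },
        "utilities": {
            "states": {
                t.value: {s.value: u for s, u in states.items()}
                for t, states in bundle.utilities.state_utility.items()
            },
            "age_bands": [
                {"min_age": b.min_age, "female": b.female, "male": b.male}
                for b in bundle.utilities.age_bands
            ],
        },
        "adverse_events": [
            {
                "tumor": t.value,
                "setting": s.value,
                "label": label,
                "events_per_patient": row.events_per_patient,
                "weeks_per_event": row.weeks_per_event,
                "disutility": row.disutility,
            }
            for (t, s, label), row in sorted(
                bundle.adverse_events.rows.items(),
                key=lambda kv: (kv[0][0].value, kv[0][1].value, kv[0][2]),
            )
        ],
    }


def _mix_tree_to_dict(tree) -> dict:
    return {
        t.value: {
            arm: {s.value: dict(mix) for s, mix in strata.items()}
            for arm, strata in arms.items()
        }
        for t, arms in tree.items()
    }


def _require(section: Mapping, key: str, where: str):
    if key not in section or section[key] is None:
        raise ConfigError(f"missing required section {where!r}")
    return section[key]


def bundle_from_dict(raw: Mapping) -> ModelBundle:
    settings = dict(_require(raw, "settings", "settings"))
    subset = settings.pop("tumor_subset", [t.value for t in DEFAULT_TUMOR_SUBSET])
    config = ModelConfig(tumor_subset=tuple(Tumor(t) for t in subset), **settings)

    pop_raw = _require(raw, "population", "population")
    demo_raw = _require(pop_raw, "demographics", "population.demographics")
    population = PopulationProjection(
        eligible=_require(pop_raw, "eligible", "population.eligible"),
        demographics=Demographics(**demo_raw),
        treated_scenario_ii=pop_raw.get("treated_scenario_ii"),
    )

    lt_raw = _require(raw, "life_table", "life_table")
    life_table = LifeTable(
        q_female=_require(lt_raw, "q_female", "life_table.q_female"),
        q_male=_require(lt_raw, "q_male", "life_table.q_male"),
    )

    arms_raw = _require(raw, "arms", "arms")
    arms: dict[Tumor, dict[str, ArmTransitionModel]] = {}
    for t, models in arms_raw.items():
        tumor = Tumor(t)
        arms[tumor] = {}
        for arm_label, d in models.items():
            where = f"arms.{t}.{arm_label}"
            kwargs = {
                f: _spec_from_dict(_require(d, f, f"{where}.{f}"), f"{where}.{f}")
                for f in ARM_SPEC_FIELDS
            }
            arms[tumor][arm_label] = ArmTransitionModel(
                tumor=tumor,
                arm_label=arm_label,
                m1l_to_m2l={
                    k: _spec_from_dict(v, f"{where}.m1l_to_m2l.{k}")
                    for k, v in _require(d, "m1l_to_m2l", f"{where}.m1l_to_m2l").items()
                },
                m1l_to_death={
                    k: _spec_from_dict(v, f"{where}.m1l_to_death.{k}")
                    for k, v in _require(d, "m1l_to_death", f"{where}.m1l_to_death").items()
                },
                m2l_to_death=_spec_from_dict(
                    _require(d, "m2l_to_death", f"{where}.m2l_to_death"),
                    f"{where}.m2l_to_death",
                ),
                **kwargs,
            )

    ms_raw = _require(raw, "market_shares", "market_shares")
    shares = MarketShareSchedule(
        uptake=_require(ms_raw, "uptake", "market_shares.uptake"),
        traditional_allocation=_require(
            ms_raw, "traditional_allocation", "market_shares.traditional_allocation"
        ),
        mix_1l=_require(ms_raw, "mix_1l", "market_shares.mix_1l"),
        mix_2l=_require(ms_raw, "mix_2l", "market_shares.mix_2l"),
    )

    util_raw = _require(raw, "utilities", "utilities")
    utilities = UtilitySet(
        state_utility=_require(util_raw, "states", "utilities.states"),
        age_bands=[AgeBand(**b) for b in _require(util_raw, "age_bands", "utilities.age_bands")],
    )

    ae_raw = _require(raw, "adverse_events", "adverse_events")
    ae_rows = {}
    for row in ae_raw:
        key = (Tumor(row["tumor"]), TreatmentSetting(row["setting"]), row["label"])
        ae_rows[key] = AdverseEventRow(
            events_per_patient=row["events_per_patient"],
            weeks_per_event=row["weeks_per_event"],
            disutility=row["disutility"],
        )
    adverse_events = AdverseEventProfile(rows=ae_rows)

    return ModelBundle(
        config=config,
        population=population,
        life_table=life_table,
        arms=arms,
        shares=shares,
        utilities=utilities,
        adverse_events=adverse_events,
    )


def load_config(path: str | Path) -> ModelBundle:
    """Load and validate a full model configuration from a YAML file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"configuration file {path} does not contain a mapping")
    return bundle_from_dict(raw)


def save_config(bundle: ModelBundle, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(bundle_to_dict(bundle), fh, sort_keys=False)
    return path


# ---------------------------------------------------------------------------
# shared-transition validation


@dataclass
class SharedTransitionReport:
    passed: bool
    mismatches: list[str]

    def __bool__(self) -> bool:
        return self.passed


def validate_shared_transitions(
    models: Iterable[ArmTransitionModel],
) -> SharedTransitionReport:
    """Check that post-recurrence transition laws are arm-independent.

    Transitions out of the locoregional-recurrence state are assumed to be
    equivalent across adjuvant treatment arms within a tumor; this report
    lists any arm whose laws deviate from the tumor's reference arm.
    """
    by_tumor: dict[Tumor, list[ArmTransitionModel]] = {}
    for m in models:
        by_tumor.setdefault(m.tumor, []).append(m)
    mismatches: list[str] = []
    for tumor, arms in by_tumor.items():
        ref = arms[0]
        for other in arms[1:]:
            for fld in ("lr_to_met", "lr_to_death"):
                if getattr(ref, fld) != getattr(other, fld):
                    mismatches.append(
                        f"{tumor.value}: {fld} differs between arms "
                        f"{ref.arm_label!r} and {other.arm_label!r}"
                    )
    return SharedTransitionReport(passed=not mismatches, mismatches=mismatches)
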