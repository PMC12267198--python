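"""Synthetic, internally consistent parameter bundles for the projection model.

The real model's transition inputs were fitted to patient-level data from
pivotal adjuvant/neoadjuvant trials that are not publicly deposited, and
its market shares and utilities are likewise unpublished.  This module
generates complete stand-in bundles with documented plausible magnitudes:
arm-dependent recurrence-free survival with anti-PD-(L)1 hazard ratios
below one, arm-independent post-recurrence transitions, line-specific
metastatic survival, adverse-event rates and durations, health-state
utilities, and a Gompertz-shaped background-mortality life table.  Every
generated bundle passes full configuration validation, and all outputs
carry a provenance note marking them as synthetic.

The annual eligible population and the scenario II treated counts are the
published national projections and ship verbatim; their split across the
three tumors is not published and is a documented synthetic assumption.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .outcomes_reporting import OutcomeSet
from .param_model import (
    AdverseEventProfile,
    AdverseEventRow,
    AgeBand,
    ArmTransitionModel,
    Demographics,
    LifeTable,
    MarketShareSchedule,
    ModelBundle,
    ModelConfig,
    PopulationProjection,
    Stratum,
    SurvivalSpec,
    TreatmentSetting,
    Tumor,
    UtilitySet,
    ValidationError,
)
from .population_scenarios import ANTI_PDL1_ARM, implied_uptake

__all__ = [
    "DEMO_SEED",
    "TUMOR_SPLIT",
    "generate_life_table",
    "table2_fixture",
    "generate_parameter_set",
    "reported_cumulative_outcomes",
    "write_population_csv",
]

DEMO_SEED = 1234

YEARS = tuple(range(2022, 2032))

# national 10-year projection of eligible incident patients and of patients
# initiating early-setting anti-PD-(L)1 therapy under scenario II, by year
ELIGIBLE_TOTALS = (978, 1001, 1021, 1042, 1062, 1082, 1103, 1123, 1123, 1123)
TREATED_TOTALS = (619, 776, 877, 917, 939, 959, 977, 996, 996, 996)

# synthetic three-way split of the published totals: the per-tumor
# breakdown is not published; these fractions are a documented assumption
# and every per-tumor number downstream is synthetic
TUMOR_SPLIT = {Tumor.MELANOMA: 0.34, Tumor.RCC: 0.22, Tumor.TNBC: 0.44}

TRADITIONAL_ARMS = {
    Tumor.MELANOMA: {"watchful_waiting": 0.80, "dabrafenib_trametinib": 0.20},
    Tumor.RCC: {"watchful_waiting": 1.0},
    Tumor.TNBC: {"chemotherapy": 1.0},
}

LABELS_1L = {
    Tumor.MELANOMA: ("anti_pdl1_1l", "targeted_1l", "chemo_1l"),
    Tumor.RCC: ("anti_pdl1_1l", "tki_1l"),
    Tumor.TNBC: ("anti_pdl1_1l", "chemo_1l"),
}
LABELS_2L = {
    Tumor.MELANOMA: ("chemo_2l",),
    Tumor.RCC: ("tki_2l",),
    Tumor.TNBC: ("chemo_2l",),
}

# published adverse-event disutilities by tumor and setting
AE_DISUTILITY = {
    Tumor.MELANOMA: {"adjuvant": -0.05, "1l": -0.13, "2l": -0.14},
    Tumor.RCC: {"adjuvant": -0.06, "1l": -0.05, "2l": -0.05},
    Tumor.TNBC: {"adjuvant": -0.02, "1l": -0.03, "2l": -0.03},
}

KNOWN_OVERRIDES = {"rf_hazard_ratio", "null_effect", "tumor_split", "horizon_years", "seed"}


def generate_life_table(
    a_female: float = 1.6e-5,
    a_male: float = 2.4e-5,
    b: float = 0.10,
) -> LifeTable:
    """Synthetic Gompertz-shaped life table closed at age 100.

    Annual death probability q(age) = a * exp(b * age), capped at 1; the
    defaults give q(40) < 0.001 and q(80) around 5%, a realistic adult
    mortality schedule for a high-income country.
    """
    ages = np.arange(101)
    qf = np.minimum(a_female * np.exp(b * ages), 1.0)
    qm = np.minimum(a_male * np.exp(b * ages), 1.0)
    qf[-1] = 1.0
    qm[-1] = 1.0
    return LifeTable(q_female=qf, q_male=qm)


def table2_fixture(
    tumor_split: dict[Tumor, float] | None = None,
) -> PopulationProjection:
    """The published annual eligible population, split across tumors.

    Annual totals are reproduced verbatim; the per-tumor split uses the
    documented synthetic fractions (configurable).  Treated counts under
    scenario II are exposed for uptake calibration via
    :func:`pdl1_impact.population_scenarios.implied_uptake`.
    """
    split = tumor_split or TUMOR_SPLIT
    if abs(sum(split.values()) - 1.0) > 1e-9:
        raise ValidationError("tumor split fractions must sum to 1")
    tumors = sorted(split, key=lambda t: t.value)
    eligible: dict[Tumor, dict[int, float]] = {t: {} for t in tumors}
    for year, total in zip(YEARS, ELIGIBLE_TOTALS):
        running = 0.0
        for tumor in tumors[:-1]:
            c = total * split[tumor]
            eligible[tumor][year] = c
            running += c
        eligible[tumors[-1]][year] = total - running
    return PopulationProjection(
        eligible=eligible,
        demographics=Demographics(
            mean_entry_age=60.0, fraction_female=0.5037, mean_weight_kg=75.0
        ),
        treated_scenario_ii=dict(zip(YEARS, (float(v) for v in TREATED_TOTALS))),
    )


def _rf_specs(rng: np.random.Generator, hr: float | None):
    """Recurrence-free exits: Weibull recurrence laws plus a small death rate."""
    shape = rng.uniform(0.9, 1.3)
    # weeks; multi-year median recurrence-free survival so that a high-risk
    # early-stage cohort sees roughly 40-60% of events within the window
    scale_lr = rng.uniform(450.0, 650.0)
    scale_met = rng.uniform(550.0, 800.0)
    death_rate = rng.uniform(1e-4, 3e-4)
    if hr is None:
        hr_kwargs = {}
    else:
        hr_kwargs = {
            "hazard_ratio": hr,
            "hr_ci": (hr * float(np.exp(-0.25)), hr * float(np.exp(0.25))),
        }
    return (
        SurvivalSpec("weibull", (shape, scale_lr), **hr_kwargs),
        SurvivalSpec("weibull", (shape, scale_met), **hr_kwargs),
        SurvivalSpec("exponential", (death_rate,), **hr_kwargs),
    )


def generate_parameter_set(seed: int, overrides: dict | None = None) -> ModelBundle:
    """Deterministic synthetic bundle for one seed.

    Treatment benefit is encoded as anti-PD-(L)1 recurrence-free hazard
    ratios drawn in [0.55, 0.80] (matching the direction of effect in the
    adjuvant trials), metastatic 1L anti-PD-(L)1 hazard ratios in
    [0.55, 0.80] for survival and progression, and utilities ordered
    recurrence-free > locoregional > metastatic 1L > 2L.

    Supported overrides: ``rf_hazard_ratio`` (applied to every anti-PD-(L)1
    arm), ``null_effect`` (hazard ratios of 1 plus mixes and adverse-event
    profiles identical across arms, so the two scenarios coincide),
    ``tumor_split``, ``horizon_years``, ``seed`` (config seed).
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - KNOWN_OVERRIDES
    if unknown:
        raise ValidationError(f"unknown overrides: {sorted(unknown)}")
    null_effect = bool(overrides.get("null_effect", False))

    rng = np.random.default_rng(seed)
    population = table2_fixture(overrides.get("tumor_split"))
    life_table = generate_life_table()

    uptake_sched = implied_uptake(population, population.treated_scenario_ii)

    arms: dict[Tumor, dict[str, ArmTransitionModel]] = {}
    mix_1l: dict = {}
    mix_2l: dict = {}
    ae_rows: dict = {}
    state_utils: dict = {}
    uptake: dict = {}

    for tumor in sorted(TUMOR_SPLIT, key=lambda t: t.value):
        uptake[tumor] = dict(uptake_sched)

        # shared post-recurrence laws (arm-independent within tumor)
        lr_to_met = SurvivalSpec("exponential", (rng.uniform(0.006, 0.012),))
        lr_to_death = SurvivalSpec("exponential", (rng.uniform(0.001, 0.003),))

        labels_1l = LABELS_1L[tumor]
        labels_2l = LABELS_2L[tumor]
        base_prog = rng.uniform(0.015, 0.030)  # /week; 1L progression
        base_os = rng.uniform(0.006, 0.010)  # /week; 1L mortality
        m1l_to_m2l: dict[str, SurvivalSpec] = {}
        m1l_to_death: dict[str, SurvivalSpec] = {}
        for lab in labels_1l:
            if lab == "anti_pdl1_1l" and not null_effect:
                hr_p = rng.uniform(0.55, 0.80)
                hr_o = rng.uniform(0.55, 0.80)
                m1l_to_m2l[lab] = SurvivalSpec(
                    "exponential",
                    (base_prog,),
                    hazard_ratio=hr_p,
                    hr_ci=(hr_p * float(np.exp(-0.2)), hr_p * float(np.exp(0.2))),
                )
                m1l_to_death[lab] = SurvivalSpec(
                    "exponential",
                    (base_os,),
                    hazard_ratio=hr_o,
                    hr_ci=(hr_o * float(np.exp(-0.2)), hr_o * float(np.exp(0.2))),
                )
            else:
                m1l_to_m2l[lab] = SurvivalSpec("exponential", (base_prog,))
                m1l_to_death[lab] = SurvivalSpec("exponential", (base_os,))
        m2l_to_death = SurvivalSpec("exponential", (rng.uniform(0.012, 0.022),))

        rf_hr = overrides.get("rf_hazard_ratio", rng.uniform(0.55, 0.80))
        if null_effect:
            rf_hr = 1.0

        tumor_arms: dict[str, ArmTransitionModel] = {}
        rf_lr_base, rf_met_base, rf_death_base = _rf_specs(rng, None)
        for arm_label in TRADITIONAL_ARMS[tumor]:
            tumor_arms[arm_label] = ArmTransitionModel(
                tumor=tumor,
                arm_label=arm_label,
                rf_to_lr=rf_lr_base,
                rf_to_met=rf_met_base,
                rf_to_death=rf_death_base,
                lr_to_met=lr_to_met,
                lr_to_death=lr_to_death,
                m1l_to_m2l=dict(m1l_to_m2l),
                m1l_to_death=dict(m1l_to_death),
                m2l_to_death=m2l_to_death,
            )
        anti_kwargs = (
            {}
            if null_effect or rf_hr == 1.0
            else {
                "hazard_ratio": rf_hr,
                "hr_ci": (rf_hr * float(np.exp(-0.25)), rf_hr * float(np.exp(0.25))),
            }
        )
        tumor_arms[ANTI_PDL1_ARM] = ArmTransitionModel(
            tumor=tumor,
            arm_label=ANTI_PDL1_ARM,
            rf_to_lr=SurvivalSpec(rf_lr_base.family, rf_lr_base.params, **anti_kwargs),
            rf_to_met=SurvivalSpec(rf_met_base.family, rf_met_base.params, **anti_kwargs),
            rf_to_death=SurvivalSpec(rf_death_base.family, rf_death_base.params, **anti_kwargs),
            lr_to_met=lr_to_met,
            lr_to_death=lr_to_death,
            m1l_to_m2l=dict(m1l_to_m2l),
            m1l_to_death=dict(m1l_to_death),
            m2l_to_death=m2l_to_death,
        )
        arms[tumor] = tumor_arms

        # metastatic mixes: traditional-arm patients mostly receive
        # anti-PD-(L)1 at 1L; adjuvant anti-PD-(L)1 patients progressing
        # before the retreatment threshold cannot be retreated with the class
        other_1l = [lab for lab in labels_1l if lab != "anti_pdl1_1l"]
        trad_mix = {"anti_pdl1_1l": 0.75}
        rest = 0.25 / len(other_1l)
        for lab in other_1l:
            trad_mix[lab] = rest
        no_retreat_mix = {lab: 1.0 / len(other_1l) for lab in other_1l}
        retreat_mix = {"anti_pdl1_1l": 0.50}
        rest = 0.50 / len(other_1l)
        for lab in other_1l:
            retreat_mix[lab] = rest
        mix2 = {lab: 1.0 / len(labels_2l) for lab in labels_2l}

        mix_1l[tumor] = {}
        mix_2l[tumor] = {}
        for arm_label in TRADITIONAL_ARMS[tumor]:
            mix_1l[tumor][arm_label] = {
                Stratum.BEFORE_THRESHOLD: dict(trad_mix),
                Stratum.AT_OR_AFTER_THRESHOLD: dict(trad_mix),
            }
            mix_2l[tumor][arm_label] = {
                Stratum.BEFORE_THRESHOLD: dict(mix2),
                Stratum.AT_OR_AFTER_THRESHOLD: dict(mix2),
            }
        if null_effect:
            anti_mix = {
                Stratum.BEFORE_THRESHOLD: dict(trad_mix),
                Stratum.AT_OR_AFTER_THRESHOLD: dict(trad_mix),
            }
        else:
            anti_mix = {
                Stratum.BEFORE_THRESHOLD: dict(no_retreat_mix),
                Stratum.AT_OR_AFTER_THRESHOLD: dict(retreat_mix),
            }
        mix_1l[tumor][ANTI_PDL1_ARM] = anti_mix
        mix_2l[tumor][ANTI_PDL1_ARM] = {
            Stratum.BEFORE_THRESHOLD: dict(mix2),
            Stratum.AT_OR_AFTER_THRESHOLD: dict(mix2),
        }

        # utilities ordered RF > LR > metastatic 1L > 2L > 0
        u_rf = rng.uniform(0.82, 0.88)
        u_lr = u_rf - rng.uniform(0.06, 0.10)
        u_m1 = u_lr - rng.uniform(0.06, 0.10)
        u_m2 = u_m1 - rng.uniform(0.06, 0.10)
        state_utils[tumor] = {
            "recurrence_free": u_rf,
            "locoregional_recurrence": u_lr,
            "metastatic_1l": u_m1,
            "metastatic_2l": u_m2,
            "dead": 0.0,
        }

        # adverse events: grade-3+ burden per initiation; anti-PD-(L)1 has a
        # higher adjuvant event rate than surveillance/chemotherapy, which is
        # what drives the early-years excess of events under scenario II
        dis = AE_DISUTILITY[tumor]
        anti_adj = AdverseEventRow(
            events_per_patient=rng.uniform(0.6, 0.9),
            weeks_per_event=rng.uniform(4.0, 8.0),
            disutility=dis["adjuvant"],
        )
        ae_rows[(tumor, TreatmentSetting.ADJUVANT, ANTI_PDL1_ARM)] = anti_adj
        for arm_label in TRADITIONAL_ARMS[tumor]:
            if null_effect:
                row = anti_adj
            elif arm_label == "watchful_waiting":
                row = AdverseEventRow(0.0, 0.0, 0.0)
            else:
                row = AdverseEventRow(
                    events_per_patient=rng.uniform(0.3, 0.6),
                    weeks_per_event=rng.uniform(3.0, 6.0),
                    disutility=dis["adjuvant"],
                )
            ae_rows[(tumor, TreatmentSetting.ADJUVANT, arm_label)] = row
        for lab in labels_1l:
            ae_rows[(tumor, TreatmentSetting.METASTATIC_1L, lab)] = AdverseEventRow(
                events_per_patient=rng.uniform(0.8, 1.4),
                weeks_per_event=rng.uniform(3.0, 6.0),
                disutility=dis["1l"],
            )
        for lab in labels_2l:
            ae_rows[(tumor, TreatmentSetting.METASTATIC_2L, lab)] = AdverseEventRow(
                events_per_patient=rng.uniform(0.8, 1.4),
                weeks_per_event=rng.uniform(3.0, 6.0),
                disutility=dis["2l"],
            )

    shares = MarketShareSchedule(
        uptake=uptake,
        traditional_allocation={t: dict(a) for t, a in TRADITIONAL_ARMS.items()},
        mix_1l=mix_1l,
        mix_2l=mix_2l,
    )
    utilities = UtilitySet(
        state_utility=state_utils,
        age_bands=[
            AgeBand(min_age=0.0, female=1.0, male=1.0),
            AgeBand(min_age=50.0, female=0.97, male=0.96),
            AgeBand(min_age=60.0, female=0.94, male=0.93),
            AgeBand(min_age=70.0, female=0.90, male=0.88),
            AgeBand(min_age=80.0, female=0.85, male=0.82),
        ],
    )
    config = ModelConfig(
        horizon_years=int(overrides.get("horizon_years", 10)),
        seed=int(overrides.get("seed", seed)),
    )
    return ModelBundle(
        config=config,
        population=population,
        life_table=life_table,
        arms=arms,
        shares=shares,
        utilities=utilities,
        adverse_events=AdverseEventProfile(rows=ae_rows),
    )


def reported_cumulative_outcomes() -> tuple[OutcomeSet, OutcomeSet]:
    """Published cumulative scenario outcomes of the national projection.

    Reference values for validating the comparison layer (differences and
    percent changes); they are inputs here, not model output.
    """
    scenario_i = OutcomeSet.from_cumulative(
        {
            "recurrence_free_life_years": 34755.0,
            "total_life_years": 42443.0,
            "qalys": 35616.0,
            "events_or_recurrences": 4292.0,
            "active_metastatic_treatments": 4555.0,
            "adverse_events": 8606.0,
            "total_deaths": 2301.0,
            "deaths_after_first_event": 2040.0,
        }
    )
    scenario_ii = OutcomeSet.from_cumulative(
        {
            "recurrence_free_life_years": 38171.0,
            "total_life_years": 43722.0,
            "qalys": 37038.0,
            "events_or_recurrences": 3149.0,
            "active_metastatic_treatments": 2978.0,
            "adverse_events": 8497.0,
            "total_deaths": 1772.0,
            "deaths_after_first_event": 1507.0,
        }
    )
    return scenario_i, scenario_ii


def write_population_csv(pop: PopulationProjection, path: str | Path) -> Path:
    """Population fixture as CSV: tumor, year, eligible_count, treated_count."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    years = pop.years()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["tumor", "year", "eligible_count", "treated_count"])
        for tumor in sorted(pop.eligible, key=lambda t: t.value):
            for year in years:
                treated = ""
                if pop.treated_scenario_ii and year in pop.treated_scenario_ii:
                    # treated counts are published as totals across tumors
                    treated = (
                        pop.treated_scenario_ii[year]
                        * pop.eligible[tumor][year]
                        / pop.year_total(year)
                    )
                writer.writerow([tumor.value, year, pop.eligible[tumor][year], treated])
    return path
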