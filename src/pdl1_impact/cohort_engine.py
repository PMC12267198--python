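"""Deterministic cohort propagation and a patient-level microsimulation oracle.

One entry cohort is pushed through five health states — recurrence-free,
locoregional recurrence, first-line metastatic, second-line metastatic,
dead — in weekly cycles.  Recurrence-free exits are clocked from adjuvant
initiation; post-recurrence states are semi-Markov: their exits are clocked
from state entry, implemented by expanding each state over time-in-state
tunnels.  Deaths are resolved before progressions within a cycle, and every
death probability is floored at background mortality (the larger of the
trial-based and life-table estimates is applied).

Patients entering first-line metastatic therapy are assigned a treatment
mix conditional on the adjuvant arm and on whether entry occurs before or
at/after the retreatment threshold (18 months after adjuvant initiation by
default): early progressors after adjuvant anti-PD-(L)1 are not retreated
with the same class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .param_model import (
    ArmTransitionModel,
    Demographics,
    HealthState,
    LifeTable,
    MarketShareSchedule,
    ModelConfig,
    Stratum,
    Tumor,
    ValidationError,
)
from .survival_engine import (
    background_weekly_curve,
    competing_exit_normalization,
    cycle_prob_array,
    effective_death_prob,
)

__all__ = [
    "MixSlice",
    "CohortTrace",
    "resolve_mix_slice",
    "split_retreatment_eligibility",
    "run_cohort",
    "trace_to_frame",
    "microsim_oracle",
    "MicrosimResult",
]

logger = logging.getLogger(__name__)

NEGATIVE_TOL = 1e-9

STRATA = (Stratum.BEFORE_THRESHOLD, Stratum.AT_OR_AFTER_THRESHOLD)


@dataclass(frozen=True)
class MixSlice:
    """Metastatic treatment mixes for one tumor/arm, retreatment-resolved."""

    mix_1l: dict[Stratum, dict[str, float]]
    mix_2l: dict[Stratum, dict[str, float]]


def resolve_mix_slice(
    shares: MarketShareSchedule,
    tumor: Tumor,
    arm_label: str,
    retreatment_allowed: bool = True,
) -> MixSlice:
    """Pick the 1L/2L mixes for one arm, honouring the retreatment toggle.

    With retreatment disabled, every stratum uses the no-retreatment mix
    (the before-threshold mix, which excludes anti-PD-(L)1 retreatment).
    """
    mix_1l = {s: dict(shares.mix_1l[tumor][arm_label][s]) for s in STRATA}
    mix_2l = {s: dict(shares.mix_2l[tumor][arm_label][s]) for s in STRATA}
    if not retreatment_allowed:
        mix_1l[Stratum.AT_OR_AFTER_THRESHOLD] = dict(mix_1l[Stratum.BEFORE_THRESHOLD])
        mix_2l[Stratum.AT_OR_AFTER_THRESHOLD] = dict(mix_2l[Stratum.BEFORE_THRESHOLD])
    return MixSlice(mix_1l=mix_1l, mix_2l=mix_2l)


def split_retreatment_eligibility(cycle_of_entry: int, threshold_weeks: int) -> Stratum:
    """Stratum of a patient starting 1L metastatic therapy at a given cycle.

    ``cycle_of_entry`` counts weeks since adjuvant/neoadjuvant initiation.
    """
    if cycle_of_entry < 0:
        raise ValidationError("cycle_of_entry must be >= 0")
    if cycle_of_entry < threshold_weeks:
        return Stratum.BEFORE_THRESHOLD
    return Stratum.AT_OR_AFTER_THRESHOLD


@dataclass
class CohortTrace:
    """Weekly state-occupancy and event-count ledger for one entry cohort.

    ``occupancy[state]`` has length ``n_cycles + 1`` and holds start-of-cycle
    person counts (index ``n_cycles`` is the end-of-horizon distribution).
    Event arrays have length ``n_cycles`` and count occurrences during each
    cycle.  1L/2L treatment initiations are further keyed by retreatment-
    eligibility stratum and treatment label.
    """

    tumor: Tumor
    arm_label: str
    entry_week: int
    entry_size: float
    n_cycles: int
    occupancy: dict[HealthState, np.ndarray]
    recurrences: np.ndarray
    deaths: np.ndarray
    deaths_after_event: np.ndarray
    init_1l: dict[Stratum, dict[str, np.ndarray]]
    init_2l: dict[Stratum, dict[str, np.ndarray]]

    def alive(self) -> np.ndarray:
        return (
            self.occupancy[HealthState.RECURRENCE_FREE]
            + self.occupancy[HealthState.LOCOREGIONAL_RECURRENCE]
            + self.occupancy[HealthState.METASTATIC_1L]
            + self.occupancy[HealthState.METASTATIC_2L]
        )

    def total_occupancy(self) -> np.ndarray:
        return self.alive() + self.occupancy[HealthState.DEAD]

    def initiations_1l(self) -> np.ndarray:
        out = np.zeros(self.n_cycles)
        for per_label in self.init_1l.values():
            for arr in per_label.values():
                out += arr
        return out

    def initiations_2l(self) -> np.ndarray:
        out = np.zeros(self.n_cycles)
        for per_label in self.init_2l.values():
            for arr in per_label.values():
                out += arr
        return out


def _mix_arrays(mix: dict[str, float], labels: tuple[str, ...]) -> np.ndarray:
    return np.array([mix.get(lab, 0.0) for lab in labels])


def run_cohort(
    entry_size: float,
    arm: ArmTransitionModel,
    mixes: MixSlice,
    config: ModelConfig,
    life_table: LifeTable,
    demographics: Demographics,
    entry_week: int = 0,
) -> CohortTrace:
    """Propagate one weekly entry cohort until the end of the horizon.

    The trace covers cycles from entry to the end of the reporting window,
    so a cohort entering in the final model year contributes at most 52
    cycles.
    """
    if entry_size < 0:
        raise ValidationError("entry_size must be >= 0")
    K = config.horizon_weeks - entry_week
    if K < 0:
        raise ValidationError("entry_week lies beyond the model horizon")

    labels_1l = arm.treatment_labels_1l
    labels_2l = tuple(
        sorted({lab for s in STRATA for lab in mixes.mix_2l[s]})
    )
    n1 = len(labels_1l)

    # per-cycle transition probabilities, indexed by the relevant clock
    p_rf_lr = cycle_prob_array(arm.rf_to_lr, K) if K else np.zeros(0)
    p_rf_met = cycle_prob_array(arm.rf_to_met, K) if K else np.zeros(0)
    p_rf_death = cycle_prob_array(arm.rf_to_death, K) if K else np.zeros(0)
    p_lr_met = cycle_prob_array(arm.lr_to_met, K) if K else np.zeros(0)
    p_lr_death = cycle_prob_array(arm.lr_to_death, K) if K else np.zeros(0)
    p_1l_prog = {lab: cycle_prob_array(arm.m1l_to_m2l[lab], K) for lab in labels_1l} if K else {}
    p_1l_death = {lab: cycle_prob_array(arm.m1l_to_death[lab], K) for lab in labels_1l} if K else {}
    p_2l_death = cycle_prob_array(arm.m2l_to_death, K) if K else np.zeros(0)
    bg = background_weekly_curve(
        life_table, demographics.mean_entry_age, K, demographics.fraction_female
    ) if K else np.zeros(0)

    mix1 = {s: _mix_arrays(mixes.mix_1l[s], labels_1l) for s in STRATA}
    mix2 = {s: _mix_arrays(mixes.mix_2l[s], labels_2l) for s in STRATA}

    occupancy = {state: np.zeros(K + 1) for state in HealthState}
    recurrences = np.zeros(K)
    deaths = np.zeros(K)
    deaths_after_event = np.zeros(K)
    init_1l = {s: {lab: np.zeros(K) for lab in labels_1l} for s in STRATA}
    init_2l = {s: {lab: np.zeros(K) for lab in labels_2l} for s in STRATA}

    # per-1L-label death/progression prob matrices for vectorized tunnel math
    p_1l_prog_m = (
        np.array([p_1l_prog[lab] for lab in labels_1l]) if K and n1 else np.zeros((n1, K))
    )
    p_1l_death_m = (
        np.array([p_1l_death[lab] for lab in labels_1l]) if K and n1 else np.zeros((n1, K))
    )

    rf = float(entry_size)
    # time-in-state tunnels: index = weeks already spent in the state;
    # entrants appear at index 0 at the start of the cycle after transition
    lr = np.zeros(K) if K else np.zeros(0)
    m1l = {s: np.zeros((n1, K)) for s in STRATA}
    m2l = {s: np.zeros(K) for s in STRATA}
    dead = 0.0

    for k in range(K):
        occupancy[HealthState.RECURRENCE_FREE][k] = rf
        occupancy[HealthState.LOCOREGIONAL_RECURRENCE][k] = lr.sum()
        occupancy[HealthState.METASTATIC_1L][k] = sum(m1l[s].sum() for s in STRATA)
        occupancy[HealthState.METASTATIC_2L][k] = sum(m2l[s].sum() for s in STRATA)
        occupancy[HealthState.DEAD][k] = dead

        bgk = bg[k]

        # --- deaths first (background-mortality floor on every state) -----
        d_rf = rf * effective_death_prob(p_rf_death[k], bgk)
        rf -= d_rf

        d_lr_vec = lr * effective_death_prob(p_lr_death, bgk)
        lr -= d_lr_vec
        d_lr = d_lr_vec.sum()

        d_m1l = 0.0
        p_1l_death_eff = effective_death_prob(p_1l_death_m, bgk)
        for s in STRATA:
            dv = m1l[s] * p_1l_death_eff
            m1l[s] -= dv
            d_m1l += dv.sum()

        d_m2l = 0.0
        p_2l_death_eff = effective_death_prob(p_2l_death, bgk)
        for s in STRATA:
            dv = m2l[s] * p_2l_death_eff
            m2l[s] -= dv
            d_m2l += dv.sum()

        cycle_deaths = d_rf + d_lr + d_m1l + d_m2l
        dead += cycle_deaths
        deaths[k] = cycle_deaths
        deaths_after_event[k] = d_lr + d_m1l + d_m2l

        # --- progressions among survivors ---------------------------------
        p_lr_k, p_met_k = competing_exit_normalization([p_rf_lr[k], p_rf_met[k]])
        new_lr = rf * p_lr_k
        rf_to_met = rf * p_met_k
        rf -= new_lr + rf_to_met

        lr_exit = lr * p_lr_met
        lr -= lr_exit
        lr_to_met = lr_exit.sum()

        new_met = rf_to_met + lr_to_met
        recurrences[k] = new_lr + rf_to_met

        stratum_k = split_retreatment_eligibility(k, config.retreatment_threshold_weeks)

        # age the LR tunnel and admit this cycle's entrants at index 0
        lr = np.roll(lr, 1)
        lr[0] = new_lr

        # 1L progression to 2L, then age tunnels and admit entrants
        to_2l = {}
        for s in STRATA:
            prog = m1l[s] * p_1l_prog_m
            m1l[s] -= prog
            to_2l[s] = prog.sum()
            m1l[s] = np.roll(m1l[s], 1, axis=1)
            m1l[s][:, 0] = 0.0

        if new_met > 0:
            entrants = new_met * mix1[stratum_k]
            m1l[stratum_k][:, 0] += entrants
            for i, lab in enumerate(labels_1l):
                init_1l[stratum_k][lab][k] = entrants[i]

        for s in STRATA:
            m2l[s] = np.roll(m2l[s], 1)
            m2l[s][0] = to_2l[s]
            if to_2l[s] > 0:
                for i, lab in enumerate(labels_2l):
                    init_2l[s][lab][k] = to_2l[s] * mix2[s][i]

        # floating-point guard
        if rf < 0:
            if rf < -NEGATIVE_TOL:
                logger.warning("negative RF occupancy %.3e clamped at cycle %d", rf, k)
            rf = 0.0

    # end-of-horizon distribution
    occupancy[HealthState.RECURRENCE_FREE][K] = rf
    occupancy[HealthState.LOCOREGIONAL_RECURRENCE][K] = lr.sum() if K else 0.0
    occupancy[HealthState.METASTATIC_1L][K] = (
        sum(m1l[s].sum() for s in STRATA) if K else 0.0
    )
    occupancy[HealthState.METASTATIC_2L][K] = (
        sum(m2l[s].sum() for s in STRATA) if K else 0.0
    )
    occupancy[HealthState.DEAD][K] = dead

    return CohortTrace(
        tumor=arm.tumor,
        arm_label=arm.arm_label,
        entry_week=entry_week,
        entry_size=entry_size,
        n_cycles=K,
        occupancy=occupancy,
        recurrences=recurrences,
        deaths=deaths,
        deaths_after_event=deaths_after_event,
        init_1l=init_1l,
        init_2l=init_2l,
    )


def trace_to_frame(trace: CohortTrace) -> pd.DataFrame:
    """Tidy export: one row per cycle x state (strata pooled per state)."""
    rows = []
    for state in HealthState:
        occ = trace.occupancy[state]
        for k in range(trace.n_cycles + 1):
            rows.append(
                {
                    "tumor": trace.tumor.value,
                    "arm": trace.arm_label,
                    "cycle": trace.entry_week + k,
                    "state": state.value,
                    "persons": occ[k],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# patient-level microsimulation oracle


@dataclass
class MicrosimResult:
    """Monte-Carlo outcome estimates with standard errors.

    ``totals[name]`` is the population-level estimate (sum over simulated
    patients, rescaled if entry_size != n); ``se[name]`` the Monte-Carlo
    standard error of that total.
    """

    n: int
    totals: dict[str, float]
    se: dict[str, float]


RF, LR, M1L, M2L, DEAD = 0, 1, 2, 3, 4


def microsim_oracle(
    entry_n: int,
    arm: ArmTransitionModel,
    mixes: MixSlice,
    config: ModelConfig,
    life_table: LifeTable,
    demographics: Demographics,
    seed: int,
    utilities=None,
    adverse_events=None,
) -> MicrosimResult:
    """Simulate individual patient trajectories under the same laws.

    An independent validation path for the deterministic cohort engine:
    each of ``entry_n`` patients is pushed through the same weekly
    transition probabilities by Bernoulli sampling, and the same outcome
    measures are accumulated per patient.  Adverse-event counts are
    expected counts per initiation (the event rate is a per-initiation
    intensity, not a per-patient lottery).  QALYs are reported only when a
    utility set is supplied.
    """
    if entry_n < 1:
        raise ValidationError("entry_n must be >= 1")
    rng = np.random.default_rng(seed)
    K = config.horizon_weeks
    labels_1l = arm.treatment_labels_1l
    n1 = len(labels_1l)

    p_rf_lr = cycle_prob_array(arm.rf_to_lr, K)
    p_rf_met = cycle_prob_array(arm.rf_to_met, K)
    p_rf_death = cycle_prob_array(arm.rf_to_death, K)
    p_lr_met = cycle_prob_array(arm.lr_to_met, K)
    p_lr_death = cycle_prob_array(arm.lr_to_death, K)
    p_1l_prog = np.array([cycle_prob_array(arm.m1l_to_m2l[lab], K) for lab in labels_1l])
    p_1l_death = np.array([cycle_prob_array(arm.m1l_to_death[lab], K) for lab in labels_1l])
    p_2l_death = cycle_prob_array(arm.m2l_to_death, K)
    bg = background_weekly_curve(
        life_table, demographics.mean_entry_age, K, demographics.fraction_female
    )

    mix1 = {s: _mix_arrays(mixes.mix_1l[s], labels_1l) for s in STRATA}
    labels_2l = tuple(sorted({lab for s in STRATA for lab in mixes.mix_2l[s]}))
    mix2 = {s: _mix_arrays(mixes.mix_2l[s], labels_2l) for s in STRATA}

    disc = (1.0 + config.annual_discount_rate) ** (-np.arange(K) / 52.0)
    count_disc = disc if config.discount_event_counts else np.ones(K)

    # AE burden per initiation, by setting and label
    track_qaly = utilities is not None
    if adverse_events is not None:
        from .param_model import TreatmentSetting

        adj_row = adverse_events.get(arm.tumor, TreatmentSetting.ADJUVANT, arm.arm_label)
        ae_1l = [adverse_events.get(arm.tumor, TreatmentSetting.METASTATIC_1L, lab) for lab in labels_1l]
        ae_2l = [adverse_events.get(arm.tumor, TreatmentSetting.METASTATIC_2L, lab) for lab in labels_2l]
    else:
        adj_row = None

    state = np.zeros(entry_n, dtype=np.int64)
    tis = np.zeros(entry_n, dtype=np.int64)  # time in state (weeks)
    treat = np.full(entry_n, -1, dtype=np.int64)
    strat = np.full(entry_n, -1, dtype=np.int64)  # 0 = before, 1 = at/after

    ly = np.zeros(entry_n)
    rf_ly = np.zeros(entry_n)
    qaly = np.zeros(entry_n)
    rec = np.zeros(entry_n)
    mets = np.zeros(entry_n)
    ae = np.zeros(entry_n)
    died = np.zeros(entry_n)
    dae = np.zeros(entry_n)

    if track_qaly:
        age_factor = utilities.age_factor_curve(
            demographics.mean_entry_age, K, demographics.fraction_female
        )
        u_by_state = np.array(
            [
                utilities.utility(arm.tumor, HealthState.RECURRENCE_FREE),
                utilities.utility(arm.tumor, HealthState.LOCOREGIONAL_RECURRENCE),
                utilities.utility(arm.tumor, HealthState.METASTATIC_1L),
                utilities.utility(arm.tumor, HealthState.METASTATIC_2L),
                0.0,
            ]
        )
    if adj_row is not None:
        ae += adj_row.events_per_patient * count_disc[0]
        if track_qaly:
            qaly -= (
                adj_row.events_per_patient
                * adj_row.weeks_per_event
                * abs(adj_row.disutility)
                / 52.0
            ) * disc[0]

    for k in range(K):
        alive = state != DEAD
        if not alive.any():
            break
        in_rf = state == RF

        # deaths first, floored at background mortality
        p_death = np.zeros(entry_n)
        p_death[in_rf] = max(p_rf_death[k], bg[k])
        in_lr = state == LR
        if in_lr.any():
            p_death[in_lr] = np.maximum(p_lr_death[tis[in_lr]], bg[k])
        in_m1 = state == M1L
        if in_m1.any():
            p_death[in_m1] = np.maximum(p_1l_death[treat[in_m1], tis[in_m1]], bg[k])
        in_m2 = state == M2L
        if in_m2.any():
            p_death[in_m2] = np.maximum(p_2l_death[tis[in_m2]], bg[k])
        dies = alive & (rng.random(entry_n) < p_death)
        died[dies] = count_disc[k]
        dae[dies & (state != RF)] = count_disc[k]
        state[dies] = DEAD

        # progressions among survivors
        u = rng.random(entry_n)
        in_rf = state == RF
        plr, pmet = competing_exit_normalization([p_rf_lr[k], p_rf_met[k]])
        go_lr = in_rf & (u < plr)
        go_met_rf = in_rf & (u >= plr) & (u < plr + pmet)

        in_lr = state == LR
        go_met_lr = np.zeros(entry_n, dtype=bool)
        if in_lr.any():
            go_met_lr[in_lr] = u[in_lr] < p_lr_met[tis[in_lr]]

        in_m1 = state == M1L
        go_2l = np.zeros(entry_n, dtype=bool)
        if in_m1.any():
            go_2l[in_m1] = u[in_m1] < p_1l_prog[treat[in_m1], tis[in_m1]]

        moved = go_lr | go_met_rf | go_met_lr | go_2l
        tis[~moved] += 1

        rec[go_lr | go_met_rf] = count_disc[k]
        state[go_lr] = LR
        tis[go_lr] = 0

        go_met = go_met_rf | go_met_lr
        n_met = int(go_met.sum())
        if n_met:
            s_k = split_retreatment_eligibility(k, config.retreatment_threshold_weeks)
            s_idx = 0 if s_k == Stratum.BEFORE_THRESHOLD else 1
            chosen = rng.choice(n1, size=n_met, p=mix1[s_k] / mix1[s_k].sum())
            state[go_met] = M1L
            tis[go_met] = 0
            treat[go_met] = chosen
            strat[go_met] = s_idx
            mets[go_met] += count_disc[k]
            if adj_row is not None:
                epp = np.array([r.events_per_patient for r in ae_1l])
                ae[go_met] += epp[chosen] * count_disc[k]
                if track_qaly:
                    loss = np.array(
                        [
                            r.events_per_patient * r.weeks_per_event * abs(r.disutility) / 52.0
                            for r in ae_1l
                        ]
                    )
                    qaly[go_met] -= loss[chosen] * disc[k]

        n_2l = int(go_2l.sum())
        if n_2l:
            state[go_2l] = M2L
            tis[go_2l] = 0
            mets[go_2l] += count_disc[k]
            for s_idx, s in enumerate(STRATA):
                sel = go_2l & (strat == s_idx)
                n_sel = int(sel.sum())
                if not n_sel:
                    continue
                chosen = rng.choice(len(labels_2l), size=n_sel, p=mix2[s] / mix2[s].sum())
                if adj_row is not None:
                    epp = np.array([r.events_per_patient for r in ae_2l])
                    ae[sel] += epp[chosen] * count_disc[k]
                    if track_qaly:
                        loss = np.array(
                            [
                                r.events_per_patient * r.weeks_per_event * abs(r.disutility) / 52.0
                                for r in ae_2l
                            ]
                        )
                        qaly[sel] -= loss[chosen] * disc[k]

        # life-years accrue once the cycle's transitions are resolved
        # (end-of-cycle state), matching the cohort engine's convention
        alive = state != DEAD
        ly[alive] += disc[k] / 52.0
        rf_ly[state == RF] += disc[k] / 52.0
        if track_qaly:
            qaly[alive] += u_by_state[state[alive]] * age_factor[k] * disc[k] / 52.0

    per_patient = {
        "recurrence_free_life_years": rf_ly,
        "total_life_years": ly,
        "events_or_recurrences": rec,
        "active_metastatic_treatments": mets,
        "adverse_events": ae,
        "total_deaths": died,
        "deaths_after_first_event": dae,
    }
    if track_qaly:
        per_patient["qalys"] = qaly
    totals = {name: float(arr.sum()) for name, arr in per_patient.items()}
    se = {
        name: float(arr.std(ddof=1) * np.sqrt(entry_n)) for name, arr in per_patient.items()
    }
    return MicrosimResult(n=entry_n, totals=totals, se=se)
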