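"""Markov cohort engine with time-since-diagnosis tunnel states.

State space
-----------
* ``no_cancer``
* undetected local/regional/distal cancer, each subdivided by a dwell year
  ``0 .. progression_interval - 1`` (undetected cancer progresses
  local -> regional -> distal, and undetected distal cancer dies of cancer,
  after completing its dwell)
* detected local/regional/distal cancer, each subdivided by a tunnel year
  (years since diagnosis) so monitoring costs and the Weibull excess death
  probability can depend on elapsed time; the last tunnel layer absorbs
* ``dead_cancer`` and ``dead_other`` (absorbing; separated only for
  validation bookkeeping)

Within each annual cycle events are applied in a fixed order: screening
detection, background (symptomatic) detection, progression of still
undetected cancer, incidence, mortality (other-cause first, then excess
cancer mortality for detected states), then tunnel/dwell increments.  New
diagnoses enter tunnel year 0 at the next cycle start, which realises the
assumption that cancer death occurs no earlier than a year after reaching
the relevant state.

Payoffs (costs, life-years, utility-weighted life-years) accrue per cycle
and are discounted at the cycle midpoint (half-cycle correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import ModelSettings, ParameterSet, Schedules, StrategySpec
from .screening import screen_event

__all__ = [
    "CohortModel",
    "CohortTrace",
    "OutcomeSummary",
    "run_cohort",
    "discount",
    "validation_summary",
    "ValidationSummary",
]

STAGES = ("local", "regional", "distal")
CONSERVATION_TOL = 1e-9

#: Age bands used when summarising the ages at which cancers are diagnosed.
AGE_BANDS = ((35, 44), (45, 54), (55, 64), (65, 74), (75, 84), (85, 200))


def discount(value: float, rate: float, cycle_index: int) -> float:
    """Present value of a payoff accrued during cycle ``cycle_index`` (1-based).

    Half-cycle correction: the payoff is valued at the cycle midpoint,
    ``(1 + rate) ** -(cycle_index - 0.5)``.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if cycle_index < 1:
        raise ValueError("cycle_index is 1-based")
    return value * (1.0 + rate) ** -(cycle_index - 0.5)


@dataclass
class CohortTrace:
    """Per-cycle occupancy and expected event counts for one strategy run."""

    strategy: StrategySpec
    ages: np.ndarray  # cycle-start ages, length n_cycles
    occupancy: np.ndarray  # (n_cycles + 1, n_states), rows sum to 1
    state_labels: list[str]
    events: pd.DataFrame  # one row per cycle

    def occupancy_frame(self) -> pd.DataFrame:
        idx = np.append(self.ages, self.ages[-1] + 1)
        return pd.DataFrame(self.occupancy, index=pd.Index(idx, name="age"),
                            columns=self.state_labels)

    def to_csv(self, path: str | Path) -> None:
        self.occupancy_frame().to_csv(path)


@dataclass
class OutcomeSummary:
    """Lifetime outcomes for one strategy, per person entering at start age."""

    strategy_label: str
    cost_undiscounted: float
    cost_discounted: float
    life_years_undiscounted: float
    life_years_discounted: float
    qalys_undiscounted: float
    qalys_discounted: float
    diagnoses: dict[str, float]  # expected lifetime diagnoses per stage
    localized_fraction: float  # of all detected cancers
    screens: float
    false_positives: float

    @property
    def total_diagnoses(self) -> float:
        return float(sum(self.diagnoses.values()))

    def as_row(self) -> dict:
        row = {
            "strategy": self.strategy_label,
            "cost_undiscounted": self.cost_undiscounted,
            "cost_discounted": self.cost_discounted,
            "life_years_undiscounted": self.life_years_undiscounted,
            "life_years_discounted": self.life_years_discounted,
            "qalys_undiscounted": self.qalys_undiscounted,
            "qalys_discounted": self.qalys_discounted,
            "localized_fraction": self.localized_fraction,
            "screens": self.screens,
            "false_positives": self.false_positives,
        }
        for s in STAGES:
            row[f"diagnoses_{s}"] = self.diagnoses[s]
        return row


class CohortModel:
    """Transition machinery for one (parameters, settings, schedules) triple."""

    def __init__(
        self,
        params: ParameterSet,
        settings: ModelSettings,
        schedules: Schedules,
    ) -> None:
        schedules.validate_for(settings)
        self.params = params
        self.settings = settings
        self.schedules = schedules
        n = settings.n_cycles
        d = params.progression_interval_years

        # --- state indexing ---------------------------------------------
        labels: list[str] = ["no_cancer"]
        self.i_well = 0
        self.undet: dict[str, np.ndarray] = {}
        for s in STAGES:
            idx = np.arange(len(labels), len(labels) + d)
            self.undet[s] = idx
            labels += [f"undetected_{s}_dwell{k}" for k in range(d)]
        self.det: dict[str, np.ndarray] = {}
        for s in STAGES:
            idx = np.arange(len(labels), len(labels) + n)
            self.det[s] = idx
            labels += [f"detected_{s}_year{k}" for k in range(n)]
        self.i_dead_cancer = len(labels)
        labels.append("dead_cancer")
        self.i_dead_other = len(labels)
        labels.append("dead_other")
        self.state_labels = labels
        self.n_states = len(labels)
        self._undet_all = np.concatenate([self.undet[s] for s in STAGES])
        self._alive = np.arange(self.n_states - 2)

        # --- precomputed vectors ----------------------------------------
        u = np.zeros(self.n_states)
        u[self.i_well] = params.utility_no_cancer
        for s in STAGES:
            u[self.undet[s]] = params.utility(s)
            tunnel_u = np.full(n, params.utility_no_cancer)
            tunnel_u[: params.treatment_utility_years] = params.utility(s)
            u[self.det[s]] = tunnel_u
        self.utility = u

        mon = np.zeros(self.n_states)
        sched = params.monitoring_cost_schedule
        for s in STAGES:
            for k in range(min(len(sched), n)):
                mon[self.det[s][k]] = sched[k]
        self.monitoring = mon

        # excess (cancer-attributable) annual death probability by tunnel year
        self.excess = np.zeros(self.n_states)
        for s in STAGES:
            curve = schedules.survival[s]
            self.excess[self.det[s]] = [curve.annual_death_prob(t) for t in range(n)]

        self.incidence = schedules.incidence.as_array(settings.start_age, settings.max_age)
        self.mortality = schedules.other_cause_mortality.as_array(
            settings.start_age, settings.max_age
        )

        # stage treatment cost at diagnosis (workup + treatment; a fraction
        # of localized cancers gets local excision instead of chemoradiation)
        local_treat = (
            (1.0 - params.surgical_excision_fraction) * params.cost_treat_local
            + params.surgical_excision_fraction * params.cost_local_excision
        )
        self.dx_cost = {
            "local": params.cost_workup + local_treat,
            "regional": params.cost_workup + params.cost_treat_regional,
            "distal": params.cost_workup + params.cost_treat_distal,
        }

    # ------------------------------------------------------------------
    def initial_occupancy(self) -> np.ndarray:
        occ = np.zeros(self.n_states)
        occ[self.i_well] = 1.0
        return occ

    def step(
        self, occupancy: np.ndarray, age: int, strategy: StrategySpec
    ) -> tuple[np.ndarray, dict[str, float]]:
        """Advance the cohort one annual cycle starting at ``age``."""
        p = self.params
        occ = occupancy.astype(float).copy()
        k = age - self.settings.start_age
        ev: dict[str, float] = {"age": age}
        new_dx = {s: 0.0 for s in STAGES}

        # 1. screening ---------------------------------------------------
        undet_mass = float(occ[self._undet_all].sum())
        screened_mass = float(occ[self.i_well]) + undet_mass
        screen_occ = {"no_cancer": float(occ[self.i_well])}
        for s in STAGES:
            screen_occ[s] = float(occ[self.undet[s]].sum())
        se = screen_event(
            screen_occ, strategy, age, p, uptake=self.settings.screening_uptake
        )
        fp_events = 0.0
        if se.due:
            for s in STAGES:
                dx = occ[self.undet[s]] * se.detection_prob[s]
                occ[self.undet[s]] -= dx
                new_dx[s] += float(dx.sum())
                ev[f"dx_screen_{s}"] = float(dx.sum())
            fp_events = float(occ[self.i_well]) * se.fp_per_noncancer
        ev["screens"] = se.screens_per_person * screened_mass if se.due else 0.0
        ev["fp_referrals"] = fp_events
        for s in STAGES:
            ev.setdefault(f"dx_screen_{s}", 0.0)

        # 2. background (symptomatic) detection --------------------------
        for s in STAGES:
            dx = occ[self.undet[s]] * p.background_detect(s)
            occ[self.undet[s]] -= dx
            new_dx[s] += float(dx.sum())
            ev[f"dx_background_{s}"] = float(dx.sum())

        # 3. progression of still-undetected cancer ----------------------
        # The final dwell layer of each stage progresses; others advance one
        # dwell year.  Undetected distal cancer dies of cancer after its dwell.
        d = p.progression_interval_years
        graduating = {s: float(occ[self.undet[s][d - 1]]) for s in STAGES}
        cancer_deaths_undetected = graduating["distal"]
        for s in STAGES:
            slots = self.undet[s]
            occ[slots[1:]] = occ[slots[:-1]]
            occ[slots[0]] = 0.0
        occ[self.undet["regional"][0]] += graduating["local"]
        occ[self.undet["distal"][0]] += graduating["regional"]

        # 4. incidence ----------------------------------------------------
        inc = self.incidence[k]
        new_cancer = float(occ[self.i_well]) * inc
        occ[self.i_well] -= new_cancer
        occ[self.undet["local"][0]] += new_cancer
        ev["incident"] = new_cancer

        # 5. mortality ----------------------------------------------------
        q = self.mortality[k]
        # undetected-cancer deaths this cycle die of cancer; other-cause
        # mortality applies to everyone still alive, including the newly
        # diagnosed held aside in new_dx
        alive_mass = float(occ[self._alive].sum()) + sum(new_dx.values())
        deaths_other = alive_mass * q
        occ[self._alive] *= 1.0 - q
        for s in STAGES:
            new_dx[s] *= 1.0 - q
        # excess cancer mortality for detected states, after other-cause
        cancer_deaths_detected = float((occ * self.excess).sum())
        occ[self._alive] *= 1.0 - self.excess[self._alive]
        ev["deaths_other"] = deaths_other
        ev["deaths_cancer"] = cancer_deaths_undetected + cancer_deaths_detected
        occ[self.i_dead_other] += deaths_other
        occ[self.i_dead_cancer] += cancer_deaths_undetected + cancer_deaths_detected

        # 6. tunnel increments and entry of new diagnoses -----------------
        for s in STAGES:
            slots = self.det[s]
            last = float(occ[slots[-1]])
            occ[slots[1:]] = occ[slots[:-1]]
            occ[slots[-1]] += last  # final layer absorbs
            occ[slots[0]] = new_dx[s]
            ev[f"dx_{s}"] = ev[f"dx_screen_{s}"] + ev[f"dx_background_{s}"]

        total = float(occ.sum())
        if abs(total - 1.0) > CONSERVATION_TOL:
            raise RuntimeError(
                f"probability mass not conserved at age {age}: sum = {total!r}"
            )
        return occ, ev

    # ------------------------------------------------------------------
    def run(self, strategy: StrategySpec) -> tuple[CohortTrace, OutcomeSummary]:
        st = self.settings
        p = self.params
        occ = self.initial_occupancy()
        rows = [occ.copy()]
        events: list[dict[str, float]] = []
        tot = {
            "cost_u": 0.0, "cost_d": 0.0,
            "ly_u": 0.0, "ly_d": 0.0,
            "qaly_u": 0.0, "qaly_d": 0.0,
        }
        dx_totals = {s: 0.0 for s in STAGES}
        screens = 0.0
        fps = 0.0
        for k in range(st.n_cycles):
            age = st.start_age + k
            start = occ
            occ, ev = self.step(occ, age, strategy)

            ly = float(start[self._alive].sum())
            qaly = float(start @ self.utility) - ev["fp_referrals"] * p.fp_disutility
            cost = (
                ev["screens"] * p.cost_screen
                + ev["fp_referrals"] * p.cost_false_positive
                + sum(ev[f"dx_{s}"] * self.dx_cost[s] for s in STAGES)
                + float(start @ self.monitoring)
            )
            ev["cost"] = cost
            df = (1.0 + st.discount_rate) ** -(k + 0.5)
            tot["cost_u"] += cost
            tot["cost_d"] += cost * df
            tot["ly_u"] += ly
            tot["ly_d"] += ly * df
            tot["qaly_u"] += qaly
            tot["qaly_d"] += qaly * df
            for s in STAGES:
                dx_totals[s] += ev[f"dx_{s}"]
            screens += ev["screens"]
            fps += ev["fp_referrals"]
            rows.append(occ.copy())
            events.append(ev)

        trace = CohortTrace(
            strategy=strategy,
            ages=np.arange(st.start_age, st.max_age),
            occupancy=np.vstack(rows),
            state_labels=self.state_labels,
            events=pd.DataFrame(events),
        )
        n_dx = sum(dx_totals.values())
        summary = OutcomeSummary(
            strategy_label=strategy.label,
            cost_undiscounted=tot["cost_u"],
            cost_discounted=tot["cost_d"],
            life_years_undiscounted=tot["ly_u"],
            life_years_discounted=tot["ly_d"],
            qalys_undiscounted=tot["qaly_u"],
            qalys_discounted=tot["qaly_d"],
            diagnoses=dx_totals,
            localized_fraction=(dx_totals["local"] / n_dx) if n_dx > 0 else float("nan"),
            screens=screens,
            false_positives=fps,
        )
        return trace, summary


def run_cohort(
    strategy: StrategySpec,
    params: ParameterSet,
    settings: ModelSettings,
    schedules: Schedules,
) -> tuple[CohortTrace, OutcomeSummary]:
    """Run one strategy through the cohort model (convenience wrapper)."""
    return CohortModel(params, settings, schedules).run(strategy)


@dataclass
class ValidationSummary:
    """Face-validity quantities: stage mix, lifetime risk, ages at diagnosis."""

    stage_distribution: dict[str, float]
    lifetime_risk: float
    age_band_distribution: dict[str, float]
    defined: bool  # False when the run produced no diagnoses


def validation_summary(trace: CohortTrace) -> ValidationSummary:
    """Stage-at-diagnosis mix, lifetime diagnosis risk and age profile."""
    ev = trace.events
    by_stage = {s: float(ev[f"dx_{s}"].sum()) for s in STAGES}
    total = sum(by_stage.values())
    dx_by_age = ev.set_index("age")[[f"dx_{s}" for s in STAGES]].sum(axis=1)
    bands: dict[str, float] = {}
    for lo, hi in AGE_BANDS:
        label = f"{lo}-{hi}" if hi < 150 else f">{lo - 1}"
        mass = float(dx_by_age[(dx_by_age.index >= lo) & (dx_by_age.index <= hi)].sum())
        bands[label] = mass / total if total > 0 else float("nan")
    if total == 0:
        return ValidationSummary(
            stage_distribution={s: float("nan") for s in STAGES},
            lifetime_risk=0.0,
            age_band_distribution=bands,
            defined=False,
        )
    return ValidationSummary(
        stage_distribution={s: by_stage[s] / total for s in STAGES},
        lifetime_risk=total,
        age_band_distribution=bands,
        defined=True,
    )
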