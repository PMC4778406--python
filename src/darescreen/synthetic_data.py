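"""Synthetic age schedules, survival datasets and strategy tables.

The cohort model needs three empirical inputs that are not shipped with the
package: an age-specific anal-cancer incidence schedule, an age-specific
other-cause mortality schedule for an HIV-positive cohort, and
stage-specific relative-survival curves.  This module generates stand-ins
with the statistical structure the analysis assumes:

* incidence rises smoothly with age (registry data show roughly nine-fold
  higher incidence at ages 50-64 than at 35-49) and plateaus after 65; a
  global multiplier can be calibrated by bisection so the no-screening
  cohort's lifetime risk of a cancer diagnosis hits a target (3 % in the
  reference fixture);
* other-cause mortality is Gompertz-shaped (log-linear in age), scaled by a
  multiplier so the cohort's discounted life expectancy matches the
  published no-screening value of ~24.2 discounted years at 3 %;
* relative survival follows a Weibull curve with optional truncated noise.

Everything is deterministic given a seed.  The generated objects are
fixtures for testing and demonstration, not the source study's true inputs.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .engine import CohortModel
from .parameters import (
    AgeSchedule,
    ModelSettings,
    ParameterSet,
    Schedules,
    StrategySpec,
)
from .survival import SurvivalDataset, WeibullParams, default_stage_params

__all__ = [
    "gen_incidence_schedule",
    "gen_mortality_schedule",
    "gen_survival_dataset",
    "gen_strategy_table",
    "reference_schedules",
    "discounted_life_expectancy",
    "CalibrationError",
]

STAGES = ("local", "regional", "distal")

# Logistic ramp for the incidence age profile: midpoint and width in years,
# with a plateau after PLATEAU_AGE.  Chosen so the 50-64 / 35-49 mean ratio
# is ~9 (see tests); the absolute level is set by peak_annual_prob and, when
# a lifetime-risk target is given, by the calibration multiplier.
_INCIDENCE_MIDPOINT = 56.0
_INCIDENCE_WIDTH = 4.4
_PLATEAU_AGE = 65
_MAX_ANNUAL_INCIDENCE = 0.05

# Gompertz baseline for HIV-cohort other-cause mortality: annual probability
# b * exp(theta * (age - 35)), capped at 1.
_GOMPERTZ_B = 0.004
_GOMPERTZ_THETA = 0.082

_JITTER_SD = 0.03  # smooth multiplicative jitter applied by the generators


class CalibrationError(RuntimeError):
    """A bisection target cannot be reached under the given schedules."""


def _smooth_jitter(rng: np.random.Generator, n: int, sd: float = _JITTER_SD) -> np.ndarray:
    """Smooth multiplicative noise: white noise convolved with a Hann window."""
    if sd == 0.0:
        return np.ones(n)
    white = rng.normal(0.0, sd, size=n + 10)
    win = np.hanning(11)
    win /= win.sum()
    eps = np.convolve(white, win, mode="valid")
    return np.exp(eps - eps.mean())


def _ages(settings: ModelSettings) -> np.ndarray:
    return np.arange(settings.start_age, settings.max_age + 1)


def gen_incidence_schedule(
    seed: int,
    peak_annual_prob: float = 2.0e-3,
    target_lifetime_risk: float | None = None,
    *,
    mortality: AgeSchedule | None = None,
    survival: dict[str, WeibullParams] | None = None,
    params: ParameterSet | None = None,
    settings: ModelSettings | None = None,
    tolerance: float = 0.002,
) -> AgeSchedule:
    """Smooth age-rising annual incidence over the model's age range.

    If ``target_lifetime_risk`` is given, the schedule is rescaled by
    bisection on a global multiplier until the no-screening cohort's
    lifetime cumulative probability of a cancer *diagnosis* is within
    ``tolerance`` of the target; this requires a mortality schedule
    (survival curves and parameters default to the package defaults).
    """
    settings = settings or ModelSettings()
    ages = _ages(settings)
    if peak_annual_prob == 0.0:
        return AgeSchedule.from_array("incidence", settings.start_age,
                                      np.zeros(len(ages)))
    if not 0.0 < peak_annual_prob <= _MAX_ANNUAL_INCIDENCE:
        raise ValueError(
            f"peak_annual_prob must lie in (0, {_MAX_ANNUAL_INCIDENCE}]"
        )
    rng = np.random.default_rng(seed)
    a_eff = np.minimum(ages, _PLATEAU_AGE).astype(float)
    shape = 1.0 / (1.0 + np.exp(-(a_eff - _INCIDENCE_MIDPOINT) / _INCIDENCE_WIDTH))
    probs = peak_annual_prob * shape * _smooth_jitter(rng, len(ages))
    probs = np.clip(probs, 0.0, _MAX_ANNUAL_INCIDENCE)
    schedule = AgeSchedule.from_array("incidence", settings.start_age, probs)
    if target_lifetime_risk is None:
        return schedule

    if mortality is None:
        raise ValueError("calibrating to a lifetime risk requires a mortality schedule")
    survival = survival or default_stage_params()
    params = params or ParameterSet()
    no_screen = StrategySpec(label="No screening", screening=False)

    def lifetime_risk(mult: float) -> float:
        sched = schedule.scaled(mult)
        model = CohortModel(params, settings,
                            Schedules(sched, mortality, survival))
        _, summary = model.run(no_screen)
        return summary.total_diagnoses

    # keep every calibrated probability inside the generator's cap
    hi = _MAX_ANNUAL_INCIDENCE / float(probs.max())
    lo = 0.0
    if lifetime_risk(hi) < target_lifetime_risk - tolerance:
        raise CalibrationError(
            f"lifetime risk {lifetime_risk(hi):.4f} at the maximum feasible "
            f"incidence is below the target {target_lifetime_risk}"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        risk = lifetime_risk(mid)
        if abs(risk - target_lifetime_risk) <= 0.25 * tolerance:
            lo = hi = mid
            break
        if risk < target_lifetime_risk:
            lo = mid
        else:
            hi = mid
    mult = 0.5 * (lo + hi)
    final = schedule.scaled(mult)
    achieved = lifetime_risk(mult)
    if abs(achieved - target_lifetime_risk) > tolerance:
        raise CalibrationError(
            f"calibration converged to lifetime risk {achieved:.4f}, outside "
            f"target {target_lifetime_risk} +/- {tolerance}"
        )
    return final


def gen_mortality_schedule(
    seed: int,
    multiplier: float = 1.0,
    settings: ModelSettings | None = None,
) -> AgeSchedule:
    """Gompertz-shaped annual other-cause death probabilities.

    ``multiplier`` scales the whole curve (pre-cap), so doubling it doubles
    every age's probability until the cap at 1.  multiplier = 0 produces the
    degenerate immortal schedule.
    """
    if multiplier < 0:
        raise ValueError("multiplier must be >= 0")
    settings = settings or ModelSettings()
    ages = _ages(settings)
    rng = np.random.default_rng(seed)
    base = _GOMPERTZ_B * np.exp(_GOMPERTZ_THETA * (ages - 35.0))
    probs = np.minimum(1.0, multiplier * base * _smooth_jitter(rng, len(ages)))
    return AgeSchedule.from_array("other_cause_mortality", settings.start_age, probs)


def gen_survival_dataset(
    stage: str,
    shape: float,
    scale: float,
    horizon_years: int = 30,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_at_risk: int = 2000,
) -> SurvivalDataset:
    """Weibull relative-survival points with truncated noise.

    Noise is added to each post-baseline point, the series is clipped to
    [0, 1] and made non-increasing (isotonic clipping), and
    ``relative_survival(0)`` is pinned at 1.
    """
    if shape <= 0 or scale <= 0:
        raise ValueError("shape and scale must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(horizon_years + 1)
    s_true = np.exp(-((t / scale) ** shape))
    s = s_true + np.concatenate([[0.0], rng.normal(0.0, noise_sd, horizon_years)])
    s = np.clip(s, 0.0, 1.0)
    s = np.minimum.accumulate(s)
    s[0] = 1.0
    at_risk = np.maximum(1, np.rint(n_at_risk * s_true).astype(int))
    records = tuple(
        (int(ti), float(si), int(ni)) for ti, si, ni in zip(t, s, at_risk)
    )
    return SurvivalDataset(stage=stage, records=records)


def gen_strategy_table(
    seed: int, n_strategies: int = 8
) -> list[tuple[str, float, float]]:
    """Random (label, cost, effect) tables for frontier testing.

    Construction guarantees at least one strictly dominated strategy for
    n >= 2 and additionally one extended-dominated strategy for n >= 4: a
    convex frontier is laid down first, then a point is duplicated at a
    higher cost (strict dominance) and a point is placed above the chord
    between two frontier neighbours but below the costlier one (extended
    dominance).
    """
    if n_strategies < 2:
        raise ValueError("need at least 2 strategies")
    rng = np.random.default_rng(seed)
    n = n_strategies
    if n == 2:
        effect = float(rng.uniform(1.0, 10.0))
        cost = float(rng.uniform(100.0, 5000.0))
        rows = [("S1", cost, effect), ("S2", cost * float(rng.uniform(1.1, 2.0)), effect)]
        return rows

    n_frontier = n - 2 if n >= 4 else n - 1
    effects = np.cumsum(rng.uniform(0.05, 0.5, size=n_frontier)) + rng.uniform(0.5, 2.0)
    icer_steps = np.cumsum(rng.uniform(1000.0, 20000.0, size=n_frontier - 1))
    costs = [float(rng.uniform(100.0, 800.0))]
    for i in range(1, n_frontier):
        costs.append(costs[-1] + icer_steps[i - 1] * (effects[i] - effects[i - 1]))
    pts = [(float(c), float(e)) for c, e in zip(costs, effects)]

    # strictly dominated: same effect as a frontier point, strictly costlier
    j = int(rng.integers(0, n_frontier))
    pts.append((pts[j][0] * float(rng.uniform(1.2, 2.0)), pts[j][1]))
    if n >= 4:
        # extended dominated: between two frontier neighbours, above the chord
        # but cheaper than the costlier neighbour
        j = int(rng.integers(1, n_frontier))
        (c0, e0), (c1, e1) = pts[j - 1], pts[j]
        theta = float(rng.uniform(0.3, 0.7))
        e_mid = e0 + theta * (e1 - e0)
        chord = c0 + theta * (c1 - c0)
        pts.append((chord + float(rng.uniform(0.1, 0.8)) * (c1 - chord), e_mid))

    rng.shuffle(pts)
    return [(f"S{i + 1}", c, e) for i, (c, e) in enumerate(pts)]


def discounted_life_expectancy(
    mortality: AgeSchedule, settings: ModelSettings, rate: float | None = None
) -> float:
    """Discounted life expectancy of a cancer-free cohort, half-cycle corrected.

    Uses the same accounting as the engine: a person alive at a cycle start
    contributes one life-year for that cycle, valued at the cycle midpoint.
    """
    rate = settings.discount_rate if rate is None else rate
    q = mortality.as_array(settings.start_age, settings.max_age)
    alive = np.concatenate([[1.0], np.cumprod(1.0 - q)[:-1]])
    df = (1.0 + rate) ** -(np.arange(settings.n_cycles) + 0.5)
    return float(np.sum(alive * df))


def reference_schedules(
    seed: int = 1,
    settings: ModelSettings | None = None,
    params: ParameterSet | None = None,
    target_discounted_le: float = 24.20,
    target_lifetime_risk: float = 0.03,
) -> Schedules:
    """The calibrated synthetic reference fixture.

    The mortality multiplier is tuned by bisection so the cancer-free
    discounted (3 %) life expectancy matches the published no-screening
    value of ~24.2 discounted life-years, then the incidence schedule is
    calibrated so the no-screening lifetime diagnosis risk is 3 %.  The
    result is a fixture with the right macro-structure, not the source
    study's true inputs.
    """
    settings = settings or ModelSettings()
    params = params or ParameterSet()

    lo, hi = 0.05, 30.0
    le_lo = discounted_life_expectancy(gen_mortality_schedule(seed, lo, settings), settings)
    le_hi = discounted_life_expectancy(gen_mortality_schedule(seed, hi, settings), settings)
    if not le_hi <= target_discounted_le <= le_lo:
        raise CalibrationError(
            f"target discounted life expectancy {target_discounted_le} outside "
            f"attainable range [{le_hi:.2f}, {le_lo:.2f}]"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        le = discounted_life_expectancy(gen_mortality_schedule(seed, mid, settings), settings)
        if le > target_discounted_le:
            lo = mid
        else:
            hi = mid
    mortality = gen_mortality_schedule(seed, 0.5 * (lo + hi), settings)

    survival = default_stage_params()
    incidence = gen_incidence_schedule(
        seed,
        target_lifetime_risk=target_lifetime_risk,
        mortality=mortality,
        survival=survival,
        params=params,
        settings=settings,
    )
    return Schedules(incidence=incidence, other_cause_mortality=mortality,
                     survival=survival)


def write_fixture(
    outdir: str | Path, seed: int = 1, settings: ModelSettings | None = None
) -> Schedules:
    """Write the reference fixture schedules as CSV plus a metadata sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    settings = settings or ModelSettings()
    scheds = reference_schedules(seed=seed, settings=settings)
    scheds.incidence.to_csv(outdir / "incidence.csv")
    scheds.other_cause_mortality.to_csv(outdir / "other_cause_mortality.csv")
    meta = {
        "seed": seed,
        "start_age": settings.start_age,
        "max_age": settings.max_age,
        "survival": {
            s: {"shape": w.shape, "scale": w.scale}
            for s, w in scheds.survival.items()
        },
        "synthetic": True,
    }
    (outdir / "fixture_meta.json").write_text(json.dumps(meta, indent=2))
    return scheds
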