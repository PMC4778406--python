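"""The DARE screening test: detection, Bayes revision and false positives.

The test's published operating characteristics are a sensitivity (0.9 for
cancers < 2 cm) and a referral positive predictive value of 0.25 — the
fraction of colorectal-surgeon referrals that turn out to be cancer.  The PPV
is converted each screening cycle into a per-screen false-positive referral
probability consistent with the cohort's current undetected-cancer
prevalence, so the referral PPV is held constant over the lifetime of the
programme.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import ParameterSet, StrategySpec

__all__ = [
    "posttest_probability",
    "fp_rate_from_ppv",
    "screen_event",
    "ScreenEvent",
    "UndefinedPosteriorError",
    "InfeasibleCalibrationError",
]

STAGES = ("local", "regional", "distal")


class UndefinedPosteriorError(ZeroDivisionError):
    """The requested test result has probability zero under the prior."""


class InfeasibleCalibrationError(ValueError):
    """No false-positive probability in [0, 1] reproduces the target PPV."""


def posttest_probability(
    prior: float, sensitivity: float, fp_rate: float, result: str
) -> float:
    """Bayes posterior probability of cancer after a DARE result.

    ``fp_rate`` is the probability a cancer-free person is referred
    (1 - specificity in the conventional sense).
    """
    for name, v in (("prior", prior), ("sensitivity", sensitivity), ("fp_rate", fp_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} = {v} must lie in [0, 1]")
    if result == "positive":
        num = prior * sensitivity
        den = num + (1.0 - prior) * fp_rate
    elif result == "negative":
        num = prior * (1.0 - sensitivity)
        den = num + (1.0 - prior) * (1.0 - fp_rate)
    else:
        raise ValueError(f"result must be 'positive' or 'negative', got {result!r}")
    if den == 0.0:
        raise UndefinedPosteriorError(
            f"a {result} result has probability zero under prior={prior}, "
            f"sensitivity={sensitivity}, fp_rate={fp_rate}"
        )
    return num / den


def fp_rate_from_ppv(prevalence: float, sensitivity: float, ppv: float) -> float:
    """Per-screen false-positive probability implied by a referral PPV.

    Solves ppv = prev*sens / (prev*sens + (1-prev)*f) for f:

        f = prev * sens * (1 - ppv) / (ppv * (1 - prev))

    At prevalence 0 the false-positive rate is 0 (no referrals at all keeps
    any PPV vacuously); ppv = 1 likewise gives f = 0.
    """
    if not 0.0 <= prevalence < 1.0:
        raise ValueError(f"prevalence = {prevalence} must lie in [0, 1)")
    if not 0.0 < ppv <= 1.0:
        raise ValueError(f"ppv = {ppv} must lie in (0, 1]")
    if not 0.0 <= sensitivity <= 1.0:
        raise ValueError(f"sensitivity = {sensitivity} must lie in [0, 1]")
    f = prevalence * sensitivity * (1.0 - ppv) / (ppv * (1.0 - prevalence))
    if f > 1.0:
        raise InfeasibleCalibrationError(
            f"prevalence {prevalence} and sensitivity {sensitivity} cannot "
            f"yield PPV {ppv} with a false-positive probability <= 1 (needs {f:.4g})"
        )
    return f


@dataclass(frozen=True)
class ScreenEvent:
    """What one screening cycle does to the cohort.

    detection_prob applies to every undetected-cancer occupant;
    fp_per_noncancer is the expected false-positive referrals per cancer-free
    person present; screens_per_person is the fraction of each screened
    occupant that actually receives a DARE (the uptake).
    """

    due: bool
    detection_prob: dict[str, float]
    fp_per_noncancer: float
    screens_per_person: float


def screen_event(
    occupancy: dict[str, float],
    strategy: StrategySpec,
    age: int,
    params: ParameterSet,
    uptake: float = 1.0,
) -> ScreenEvent:
    """Per-screen detection and false-positive rates for one cycle.

    ``occupancy`` maps ``no_cancer`` and each undetected stage to its
    cohort fraction at cycle start.  The false-positive rate is
    recalibrated each screening cycle against the cohort's current
    undetected-cancer prevalence so the referral PPV stays at
    ``params.dare_ppv`` throughout the lifetime of the programme: with
    per-stage sensitivities the true-positive probability per screened
    person is ``TP = sum_s prev_s * sens_s`` and the false-positive
    probability per cancer-free person is

        f = TP * (1 - ppv) / (ppv * (1 - prev))

    which reduces to ``fp_rate_from_ppv(prev, sens, ppv)`` when a single
    sensitivity applies to all undetected stages.
    """
    if not strategy.screens_at(age):
        return ScreenEvent(
            due=False,
            detection_prob={s: 0.0 for s in STAGES},
            fp_per_noncancer=0.0,
            screens_per_person=0.0,
        )
    well = occupancy.get("no_cancer", 0.0)
    undet = {s: occupancy.get(s, 0.0) for s in STAGES}
    screened = well + sum(undet.values())
    if screened > 0:
        prev = sum(undet.values()) / screened
        tp = sum(undet[s] * params.screen_sensitivity(s) for s in STAGES) / screened
    else:
        prev = tp = 0.0
    ppv = params.dare_ppv
    if prev >= 1.0:
        fp = 0.0  # nobody cancer-free to misrefer
    else:
        fp = uptake * tp * (1.0 - ppv) / (ppv * (1.0 - prev))
        if fp / max(uptake, 1e-300) > 1.0:
            raise InfeasibleCalibrationError(
                f"implied false-positive probability {fp:.4g} exceeds 1 at "
                f"age {age} (prevalence {prev:.4g}, ppv {ppv})"
            )
    return ScreenEvent(
        due=True,
        detection_prob={s: uptake * params.screen_sensitivity(s) for s in STAGES},
        fp_per_noncancer=fp,
        screens_per_person=uptake,
    )
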