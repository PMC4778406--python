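"""Model parameters, settings, age-indexed schedules and screening strategies.

All quantities are expressed in the units the analysis reports: costs in 2014
Australian dollars, probabilities and utility weights on [0, 1], ages and
intervals in whole years.  ``base_case_parameters`` returns the published
base-case configuration; ``load_config``/``save_config`` round-trip a YAML
document losslessly.

A note on nomenclature: the DARE "specificity" figure of 0.25 is, by the
source study's own definition, the proportion of surgical referrals that turn
out to be cancer — a positive-predictive-value-like quantity.  It is stored
here as ``dare_ppv`` and converted to a per-screen false-positive probability
in :mod:`darescreen.screening`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .survival import WeibullParams

__all__ = [
    "ParameterSet",
    "ModelSettings",
    "AgeSchedule",
    "StrategySpec",
    "Schedules",
    "ValidationError",
    "base_case_parameters",
    "standard_strategies",
    "sensitivity_range",
    "SENSITIVITY_RANGES",
    "load_config",
    "save_config",
]

STAGES = ("local", "regional", "distal")


class ValidationError(ValueError):
    """A configuration value violates a model invariant; names the field."""


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} = {value} must lie in [0, 1]")


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValidationError(f"{name} = {value} must be >= 0")


@dataclass(frozen=True)
class ParameterSet:
    """Base-case parameter values with published sensitivity ranges.

    Defaults are the published base case; fields without a published value
    (background detection of regional/distal cancer, monitoring schedule,
    local-excision cost, false-positive disutility) carry documented
    package defaults — see docs/methods.md.
    """

    # DARE test characteristics.  The published sensitivity is defined for
    # cancers < 2 cm, i.e. localized tumours; screen detection of regional
    # and distal undetected cancer defaults to 0 (advanced disease presents
    # symptomatically via the background-detection probabilities) and can be
    # switched on per stage.
    dare_sensitivity: float = 0.90
    dare_sensitivity_regional: float = 0.0
    dare_sensitivity_distal: float = 0.0
    dare_ppv: float = 0.25  # fraction of surgical referrals that are cancer
    # Annual probability an undetected cancer presents symptomatically
    p_background_detect_local: float = 0.20
    p_background_detect_regional: float = 0.15
    p_background_detect_distal: float = 0.10
    # Natural history
    progression_interval_years: int = 1
    surgical_excision_fraction: float = 0.05
    # Costs, AUD 2014
    cost_screen: float = 16.0
    cost_false_positive: float = 218.0
    cost_workup: float = 1864.0
    cost_treat_local: float = 10386.0
    cost_treat_regional: float = 11093.0
    cost_treat_distal: float = 14638.0
    cost_local_excision: float = 1864.0
    monitoring_cost_schedule: tuple[float, ...] = (500.0, 250.0, 250.0, 250.0, 250.0)
    # Utility weights
    utility_no_cancer: float = 0.76
    utility_local: float = 0.71
    utility_regional: float = 0.66
    utility_distal: float = 0.52
    fp_disutility: float = 0.0
    # Years after diagnosis during which the stage utility applies before
    # reverting to the cancer-free weight
    treatment_utility_years: int = 1

    def __post_init__(self) -> None:
        for name in (
            "dare_sensitivity",
            "dare_sensitivity_regional",
            "dare_sensitivity_distal",
            "dare_ppv",
            "p_background_detect_local",
            "p_background_detect_regional",
            "p_background_detect_distal",
            "surgical_excision_fraction",
            "utility_no_cancer",
            "utility_local",
            "utility_regional",
            "utility_distal",
        ):
            _check_prob(name, getattr(self, name))
        for name in (
            "cost_screen",
            "cost_false_positive",
            "cost_workup",
            "cost_treat_local",
            "cost_treat_regional",
            "cost_treat_distal",
            "cost_local_excision",
            "fp_disutility",
        ):
            _check_nonneg(name, getattr(self, name))
        for i, c in enumerate(self.monitoring_cost_schedule):
            _check_nonneg(f"monitoring_cost_schedule[{i}]", c)
        if self.progression_interval_years < 1:
            raise ValidationError(
                f"progression_interval_years = {self.progression_interval_years} must be >= 1"
            )
        if self.treatment_utility_years < 0:
            raise ValidationError("treatment_utility_years must be >= 0")

    def background_detect(self, stage: str) -> float:
        return getattr(self, f"p_background_detect_{stage}")

    def screen_sensitivity(self, stage: str) -> float:
        if stage == "local":
            return self.dare_sensitivity
        return getattr(self, f"dare_sensitivity_{stage}")

    def treatment_cost(self, stage: str) -> float:
        return getattr(self, f"cost_treat_{stage}")

    def utility(self, stage: str) -> float:
        return getattr(self, f"utility_{stage}")

    def replace(self, **changes) -> "ParameterSet":
        return replace(self, **changes)


#: Published one-way sensitivity ranges (low, high) by parameter name.
SENSITIVITY_RANGES: dict[str, tuple[float, float]] = {
    "dare_sensitivity": (0.70, 1.00),
    "dare_ppv": (0.10, 0.50),
    "p_background_detect_local": (0.10, 0.55),
    "cost_screen": (10.0, 30.0),
    "cost_false_positive": (100.0, 500.0),
    "cost_workup": (1000.0, 3000.0),
    "cost_treat_local": (5000.0, 15000.0),
    "cost_treat_regional": (5000.0, 15000.0),
    "cost_treat_distal": (10000.0, 20000.0),
    "utility_no_cancer": (0.66, 0.86),
    "utility_local": (0.56, 0.76),
    "utility_regional": (0.56, 0.76),
    "utility_distal": (0.42, 0.62),
}


def sensitivity_range(name: str) -> tuple[float, float]:
    """The published one-way range for a parameter, or KeyError."""
    return SENSITIVITY_RANGES[name]


@dataclass(frozen=True)
class ModelSettings:
    """Cohort and discounting settings (annual cycles, lifetime horizon)."""

    start_age: int = 35
    max_age: int = 100
    cycle_length: int = 1
    discount_rate: float = 0.03
    screening_uptake: float = 1.0

    def __post_init__(self) -> None:
        if self.start_age >= self.max_age:
            raise ValidationError(
                f"start_age = {self.start_age} must be < max_age = {self.max_age}"
            )
        if self.cycle_length != 1:
            raise ValidationError("cycle_length is fixed at 1 year")
        if self.discount_rate < 0:
            raise ValidationError(f"discount_rate = {self.discount_rate} must be >= 0")
        _check_prob("screening_uptake", self.screening_uptake)

    @property
    def n_cycles(self) -> int:
        return self.max_age - self.start_age

    def replace(self, **changes) -> "ModelSettings":
        return replace(self, **changes)


@dataclass(frozen=True)
class AgeSchedule:
    """Annual probability indexed by integer age over [age_min, age_max]."""

    kind: str  # {"incidence", "other_cause_mortality"}
    ages: tuple[int, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("incidence", "other_cause_mortality"):
            raise ValidationError(f"AgeSchedule.kind {self.kind!r} unknown")
        if len(self.ages) != len(self.probs):
            raise ValidationError("AgeSchedule ages and probs differ in length")
        if list(self.ages) != list(range(self.ages[0], self.ages[-1] + 1)):
            raise ValidationError(f"{self.kind} schedule has gaps or unsorted ages")
        for a, p in zip(self.ages, self.probs):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(
                    f"{self.kind} schedule value {p} at age {a} outside [0, 1]"
                )

    @classmethod
    def from_mapping(cls, kind: str, values: Mapping[int, float]) -> "AgeSchedule":
        ages = tuple(sorted(int(a) for a in values))
        return cls(kind=kind, ages=ages, probs=tuple(float(values[a]) for a in ages))

    @classmethod
    def from_array(cls, kind: str, age_min: int, probs: Sequence[float]) -> "AgeSchedule":
        ages = tuple(range(age_min, age_min + len(probs)))
        return cls(kind=kind, ages=ages, probs=tuple(float(p) for p in probs))

    def prob(self, age: int) -> float:
        if not self.ages[0] <= age <= self.ages[-1]:
            raise ValidationError(
                f"{self.kind} schedule undefined at age {age} "
                f"(covers {self.ages[0]}-{self.ages[-1]})"
            )
        return self.probs[age - self.ages[0]]

    def as_array(self, age_min: int, age_max: int) -> np.ndarray:
        """Vector of probabilities for ages age_min .. age_max - 1."""
        return np.array([self.prob(a) for a in range(age_min, age_max)])

    def scaled(self, factor: float) -> "AgeSchedule":
        return AgeSchedule(
            kind=self.kind,
            ages=self.ages,
            probs=tuple(min(1.0, factor * p) for p in self.probs),
        )

    def covers(self, settings: ModelSettings) -> bool:
        return self.ages[0] <= settings.start_age and self.ages[-1] >= settings.max_age - 1

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"age": self.ages, "value": self.probs}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str) -> "AgeSchedule":
        import pandas as pd

        df = pd.read_csv(path)
        if not {"age", "value"} <= set(df.columns):
            raise ValidationError(f"{path}: AgeSchedule CSV needs columns age,value")
        return cls.from_mapping(kind, dict(zip(df["age"].astype(int), df["value"])))


@dataclass(frozen=True)
class StrategySpec:
    """A screening policy: an age window and an interval, or no screening."""

    label: str
    screening: bool
    screen_start_age: int = 0
    screen_end_age: int = 0
    interval_years: int = 1

    def __post_init__(self) -> None:
        if self.screening:
            if self.screen_start_age > self.screen_end_age:
                raise ValidationError(
                    f"strategy {self.label!r}: screen_start_age > screen_end_age"
                )
            if self.interval_years < 1:
                raise ValidationError(
                    f"strategy {self.label!r}: interval_years must be >= 1"
                )

    def screens_at(self, age: int) -> bool:
        """True when a screen is due at this age under the policy."""
        return (
            self.screening
            and self.screen_start_age <= age <= self.screen_end_age
            and (age - self.screen_start_age) % self.interval_years == 0
        )


def standard_strategies(settings: ModelSettings | None = None) -> list[StrategySpec]:
    """The eleven-strategy menu: no screening plus intervals 1-5 years for
    ages 35-49 and for ages >= 50 (to the model horizon)."""
    settings = settings or ModelSettings()
    menu = [StrategySpec(label="No screening", screening=False)]
    for lo, hi, band in ((35, 49, "35-49"), (50, settings.max_age - 1, ">=50")):
        for k in (5, 4, 3, 2, 1):
            unit = "year" if k == 1 else f"{k} years"
            menu.append(
                StrategySpec(
                    label=f"Age {band} every {unit}",
                    screening=True,
                    screen_start_age=lo,
                    screen_end_age=hi,
                    interval_years=k,
                )
            )
    return menu


@dataclass(frozen=True)
class Schedules:
    """Age-indexed inputs plus stage-specific survival curves."""

    incidence: AgeSchedule
    other_cause_mortality: AgeSchedule
    survival: Mapping[str, object]  # stage -> WeibullParams or compatible hazard

    def __post_init__(self) -> None:
        missing = [s for s in STAGES if s not in self.survival]
        if missing:
            raise ValidationError(f"survival curves missing for stages: {missing}")

    def validate_for(self, settings: ModelSettings) -> None:
        for sched in (self.incidence, self.other_cause_mortality):
            if not sched.covers(settings):
                raise ValidationError(
                    f"{sched.kind} schedule covers ages {sched.ages[0]}-"
                    f"{sched.ages[-1]} but model needs {settings.start_age}-"
                    f"{settings.max_age - 1}"
                )


def base_case_parameters() -> tuple[ParameterSet, ModelSettings]:
    """The published base case: Table-1 values plus documented defaults."""
    return ParameterSet(), ModelSettings()


# ---------------------------------------------------------------------------
# Configuration I/O
# ---------------------------------------------------------------------------

def _params_to_dict(params: ParameterSet) -> dict:
    d = dataclasses.asdict(params)
    d["monitoring_cost_schedule"] = list(params.monitoring_cost_schedule)
    return d


def save_config(
    path: str | Path,
    params: ParameterSet,
    settings: ModelSettings,
    strategies: Sequence[StrategySpec] | None = None,
    schedules: Schedules | None = None,
) -> None:
    """Write a complete, human-editable YAML configuration document."""
    doc: dict = {
        "parameters": _params_to_dict(params),
        "settings": dataclasses.asdict(settings),
    }
    if strategies is not None:
        doc["strategies"] = [dataclasses.asdict(s) for s in strategies]
    if schedules is not None:
        doc["schedules"] = {
            "incidence": {
                "values": {int(a): float(p) for a, p in
                           zip(schedules.incidence.ages, schedules.incidence.probs)}
            },
            "other_cause_mortality": {
                "values": {int(a): float(p) for a, p in
                           zip(schedules.other_cause_mortality.ages,
                               schedules.other_cause_mortality.probs)}
            },
            "survival": {
                stage: {"shape": float(w.shape), "scale": float(w.scale)}
                for stage, w in schedules.survival.items()
            },
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def _require(doc: Mapping, key: str, where: str) -> object:
    if key not in doc:
        raise ValidationError(f"missing key {key!r} in {where}")
    return doc[key]


def _load_schedule(spec: Mapping, kind: str, base_dir: Path, seed: int) -> AgeSchedule:
    if "values" in spec:
        return AgeSchedule.from_mapping(kind, {int(a): float(p) for a, p in spec["values"].items()})
    if "csv" in spec:
        return AgeSchedule.from_csv(base_dir / str(spec["csv"]), kind)
    if "synthetic" in spec:
        from . import synthetic_data

        syn = dict(spec["synthetic"])
        syn.setdefault("seed", seed)
        if kind == "incidence":
            return synthetic_data.gen_incidence_schedule(**syn)
        return synthetic_data.gen_mortality_schedule(**syn)
    raise ValidationError(
        f"schedules.{kind}: provide 'values', a 'csv' path, or a 'synthetic' "
        "generator spec"
    )


def load_config(
    path: str | Path, seed: int = 0
) -> tuple[ParameterSet, ModelSettings, list[StrategySpec], Schedules]:
    """Load and fully validate a YAML configuration.

    Raises :class:`ValidationError` naming the offending field for any
    missing key or out-of-range value.
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, Mapping):
        raise ValidationError(f"{path}: configuration must be a mapping")
    pdoc = dict(_require(doc, "parameters", str(path)))
    sdoc = dict(_require(doc, "settings", str(path)))
    known = {f.name for f in dataclasses.fields(ParameterSet)}
    unknown = set(pdoc) - known
    if unknown:
        raise ValidationError(f"unknown parameter keys: {sorted(unknown)}")
    if "monitoring_cost_schedule" in pdoc:
        pdoc["monitoring_cost_schedule"] = tuple(pdoc["monitoring_cost_schedule"])
    params = ParameterSet(**pdoc)
    settings = ModelSettings(**sdoc)

    strategies = [StrategySpec(**s) for s in doc.get("strategies", [])] or standard_strategies(settings)

    scheds_doc = _require(doc, "schedules", str(path))
    inc = _load_schedule(dict(_require(scheds_doc, "incidence", "schedules")),
                         "incidence", path.parent, seed)
    mort = _load_schedule(dict(_require(scheds_doc, "other_cause_mortality", "schedules")),
                          "other_cause_mortality", path.parent, seed)
    surv_doc = _require(scheds_doc, "survival", "schedules")
    surv = {
        stage: WeibullParams(stage=stage, shape=float(w["shape"]), scale=float(w["scale"]))
        for stage, w in dict(surv_doc).items()
    }
    schedules = Schedules(incidence=inc, other_cause_mortality=mort, survival=surv)
    schedules.validate_for(settings)
    return params, settings, strategies, schedules
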