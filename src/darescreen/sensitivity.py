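"""One-way sensitivity analysis and probabilistic sensitivity analysis.

The PSA is a second-order Monte Carlo: each iteration draws one parameter
set (gamma distributions for costs, beta for utilities and probabilities,
moments matched to mean = base value and SD = ``sd_fraction`` x base unless
overridden), applies it to every strategy (common random parameters within
an iteration), runs the cohort, and records discounted cost and QALYs.
Cost-effectiveness acceptability curves (CEACs) summarise the draws: for a
willingness-to-pay grid, the fraction of iterations in which each strategy
is cost-effective, either pairwise against a comparator (the default — the
published curves are reported per strategy independently) or as the
probability of maximising net monetary benefit across all strategies.

One-way analysis re-runs the full pipeline over a grid of values for a
single parameter and reports the ICER of each screening strategy against
the next-less-intensive comparator in the tornado-table layout ("every two
years compared with every three years").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .economics import StrategyOutcome, frontier
from .engine import CohortModel
from .parameters import ModelSettings, ParameterSet, Schedules, StrategySpec
from .survival import ScaledExcessHazard

__all__ = [
    "PsaSettings",
    "PsaDraws",
    "sample_parameters",
    "run_psa",
    "ceac",
    "owsa",
    "shift_survival",
    "PSA_PARAMETERS",
]

#: Parameters varied by default in the PSA, with their distribution family.
PSA_PARAMETERS: dict[str, str] = {
    "dare_sensitivity": "beta",
    "dare_ppv": "beta",
    "p_background_detect_local": "beta",
    "p_background_detect_regional": "beta",
    "p_background_detect_distal": "beta",
    "cost_screen": "gamma",
    "cost_false_positive": "gamma",
    "cost_workup": "gamma",
    "cost_treat_local": "gamma",
    "cost_treat_regional": "gamma",
    "cost_treat_distal": "gamma",
    "utility_no_cancer": "beta",
    "utility_local": "beta",
    "utility_regional": "beta",
    "utility_distal": "beta",
}


@dataclass(frozen=True)
class PsaSettings:
    """Second-order Monte Carlo settings (10,000 iterations, +/-30 % SD)."""

    n_iterations: int = 10_000
    seed: int = 0
    sd_fraction: float = 0.30
    sd_overrides: Mapping[str, float] = field(default_factory=dict)
    parameters: Mapping[str, str] = field(default_factory=lambda: dict(PSA_PARAMETERS))

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.sd_fraction <= 0:
            raise ValueError("sd_fraction must be > 0")


def _draw_gamma(rng: np.random.Generator, mean: float, sd: float) -> float:
    if mean == 0.0 or sd == 0.0:
        return mean
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return float(rng.gamma(shape, scale))


def _draw_beta(rng: np.random.Generator, mean: float, sd: float, name: str) -> float:
    if mean in (0.0, 1.0) or sd == 0.0:
        return mean
    var = sd**2
    vmax = mean * (1.0 - mean)
    if var >= vmax:
        warnings.warn(
            f"{name}: requested SD {sd:.4g} infeasible for a beta with mean "
            f"{mean:.4g}; clipping variance to 0.95 * mean*(1-mean)",
            RuntimeWarning,
            stacklevel=3,
        )
        var = 0.95 * vmax
    if var <= 0:
        raise ValueError(f"{name}: beta variance non-positive after clipping")
    nu = vmax / var - 1.0
    a = mean * nu
    b = (1.0 - mean) * nu
    return float(rng.beta(a, b))


def sample_parameters(
    base: ParameterSet, settings: PsaSettings, iteration: int
) -> ParameterSet:
    """One PSA parameter draw; deterministic in (settings.seed, iteration)."""
    rng = np.random.default_rng([settings.seed, iteration])
    changes: dict[str, float] = {}
    for name, family in settings.parameters.items():
        mean = float(getattr(base, name))
        sd = settings.sd_overrides.get(name, settings.sd_fraction * mean)
        if family == "gamma":
            changes[name] = _draw_gamma(rng, mean, sd)
        elif family == "beta":
            changes[name] = _draw_beta(rng, mean, sd, name)
        else:
            raise ValueError(f"unknown distribution family {family!r} for {name}")
    return base.replace(**changes)


@dataclass
class PsaDraws:
    """Discounted (cost, QALY) per iteration x strategy plus sampled values."""

    strategies: list[str]
    costs: np.ndarray  # (n_iterations, n_strategies)
    qalys: np.ndarray
    sampled: pd.DataFrame  # one row per iteration, sampled parameter values
    settings: PsaSettings

    def scatter(self, comparator: str) -> pd.DataFrame:
        """CE-plane cloud: per-iteration incremental cost and QALYs."""
        j = self.strategies.index(comparator)
        rows = []
        for i, s in enumerate(self.strategies):
            if i == j:
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "strategy": s,
                        "delta_cost": self.costs[:, i] - self.costs[:, j],
                        "delta_qaly": self.qalys[:, i] - self.qalys[:, j],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def run_psa(
    strategies: Sequence[StrategySpec],
    base: ParameterSet,
    settings: ModelSettings,
    schedules: Schedules,
    psa: PsaSettings,
) -> PsaDraws:
    """Second-order Monte Carlo over parameters, common across strategies."""
    n = psa.n_iterations
    costs = np.empty((n, len(strategies)))
    qalys = np.empty((n, len(strategies)))
    sampled_rows = []
    varied = list(psa.parameters)
    for it in range(n):
        params = sample_parameters(base, psa, it)
        sampled_rows.append({k: getattr(params, k) for k in varied})
        model = CohortModel(params, settings, schedules)
        for j, strat in enumerate(strategies):
            _, summary = model.run(strat)
            costs[it, j] = summary.cost_discounted
            qalys[it, j] = summary.qalys_discounted
    return PsaDraws(
        strategies=[s.label for s in strategies],
        costs=costs,
        qalys=qalys,
        sampled=pd.DataFrame(sampled_rows),
        settings=psa,
    )


def ceac(
    draws: PsaDraws,
    comparator: str,
    wtp_grid: Sequence[float],
    method: str = "pairwise",
) -> pd.DataFrame:
    """Probability each strategy is cost-effective along a WTP grid.

    pairwise (default): fraction of iterations with positive incremental net
    monetary benefit, lambda * dQALY - dCost > 0, against ``comparator``.
    multiway: fraction of iterations in which the strategy maximises net
    monetary benefit among all strategies in the draws.
    """
    if len(wtp_grid) == 0:
        raise ValueError("willingness-to-pay grid is empty")
    if comparator not in draws.strategies:
        raise ValueError(f"comparator {comparator!r} not among PSA strategies")
    lam = np.asarray(wtp_grid, dtype=float)
    out = {}
    if method == "pairwise":
        j = draws.strategies.index(comparator)
        for i, s in enumerate(draws.strategies):
            if i == j:
                continue
            dq = draws.qalys[:, i] - draws.qalys[:, j]
            dc = draws.costs[:, i] - draws.costs[:, j]
            nmb = lam[:, None] * dq[None, :] - dc[None, :]
            out[s] = (nmb > 0).mean(axis=1)
    elif method == "multiway":
        for li, l in enumerate(lam):
            nmb = l * draws.qalys - draws.costs
            best = nmb.argmax(axis=1)
            for i, s in enumerate(draws.strategies):
                out.setdefault(s, np.zeros(len(lam)))[li] = (best == i).mean()
    else:
        raise ValueError("method must be 'pairwise' or 'multiway'")
    return pd.DataFrame(out, index=pd.Index(lam, name="wtp"))


def shift_survival(schedules: Schedules, hazard_factor: float) -> Schedules:
    """Scenario variant with every stage's annual excess death probability
    multiplied by ``hazard_factor`` (>1 worse survival, <1 better)."""
    return Schedules(
        incidence=schedules.incidence,
        other_cause_mortality=schedules.other_cause_mortality,
        survival={
            s: ScaledExcessHazard(base=w, factor=hazard_factor)
            for s, w in schedules.survival.items()
        },
    )


def _apply_value(
    name: str,
    value: float,
    params: ParameterSet,
    settings: ModelSettings,
    schedules: Schedules,
) -> tuple[ParameterSet, ModelSettings, Schedules]:
    import dataclasses

    if name == "survival_hazard_factor":
        return params, settings, shift_survival(schedules, value)
    if name in {f.name for f in dataclasses.fields(ModelSettings)}:
        return params, settings.replace(**{name: value}), schedules
    if name in {f.name for f in dataclasses.fields(ParameterSet)}:
        if name == "progression_interval_years":
            value = int(value)
        return params.replace(**{name: value}), settings, schedules
    raise KeyError(f"unknown parameter {name!r}")


def owsa(
    parameter_name: str,
    value_range: tuple[float, float],
    n_points: int,
    strategies: Sequence[StrategySpec],
    base: ParameterSet,
    settings: ModelSettings,
    schedules: Schedules,
    effect: str = "qaly",
) -> pd.DataFrame:
    """One-way sensitivity analysis in the tornado-table layout.

    Re-runs the pipeline at each grid value of one parameter, holding all
    else at base, and reports the discounted ICER of each screening
    strategy against the next-less-intensive comparator in the supplied
    list (the least intensive is compared with no screening when present).
    This is the published tornado layout — "every two years compared with
    every three years" — and is defined for every grid value, unlike a
    frontier ICER, which disappears when a strategy is dominated.  Frontier
    status at each grid value is available through
    :func:`darescreen.economics.frontier` on the same outcomes.
    """
    lo, hi = value_range
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    values = np.linspace(lo, hi, n_points) if n_points > 1 else np.array([lo])
    rows = []
    for v in values:
        p, s, sch = _apply_value(parameter_name, float(v), base, settings, schedules)
        model = CohortModel(p, s, sch)
        outcomes = []
        for strat in strategies:
            _, summary = model.run(strat)
            eff = summary.qalys_discounted if effect == "qaly" else summary.life_years_discounted
            outcomes.append(StrategyOutcome(label=strat.label, cost=summary.cost_discounted,
                                            effect=eff))
        row: dict[str, float] = {parameter_name: float(v)}
        for prev_o, o in zip(outcomes[:-1], outcomes[1:]):
            de = o.effect - prev_o.effect
            row[f"icer[{o.label} vs {prev_o.label}]"] = (
                float("nan") if de == 0 else (o.cost - prev_o.cost) / de
            )
        rows.append(row)
    return pd.DataFrame(rows)
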