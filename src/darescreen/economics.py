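"""Efficiency-frontier analysis: ACERs, dominance, ICERs, CE plane.

The ranking algorithm is the standard one for cost-effectiveness league
tables: sort strategies by increasing effectiveness, remove strictly
dominated strategies (another strategy is at least as effective and no more
costly, with one inequality strict), then iteratively remove strategies
exhibiting extended dominance — a strategy whose incremental
cost-effectiveness ratio (ICER) against its frontier predecessor is not
strictly below the ICER of the next frontier member — until the ICERs along
the frontier are strictly increasing.

Because published league tables print costs to the dollar and effects to a
handful of decimals, two consecutive ICERs recomputed from printed cells can
tie to within a dollar while the unrounded values did not.  ICER comparisons
therefore treat values within ``tie_tolerance`` (default $1, the reporting
resolution) as tied, and a tied intermediate strategy is removed as weakly
extended-dominated: it adds no value at any willingness-to-pay threshold
distinguishable at the reporting resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "StrategyOutcome",
    "StrategyEvaluation",
    "FrontierResult",
    "acer",
    "frontier",
    "ce_plane",
    "round_dollar",
    "UndefinedRatioError",
]


class UndefinedRatioError(ZeroDivisionError):
    """Cost-effectiveness ratio requested between equally effective strategies."""


def round_dollar(x: float) -> int:
    """Round to the nearest dollar, halves away from zero (table convention)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class StrategyOutcome:
    """One strategy's lifetime cost and effect (QALYs or life-years)."""

    label: str
    cost: float
    effect: float

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError(f"strategy {self.label!r}: cost must be >= 0")


@dataclass
class StrategyEvaluation:
    """Frontier annotation for one strategy."""

    outcome: StrategyOutcome
    status: str  # {"frontier", "dominated", "extended_dominated"}
    acer: float | None = None  # vs baseline, None for the baseline itself
    icer: float | None = None  # vs preceding frontier strategy (frontier only)
    comparator: str | None = None  # label the ICER is taken against
    dominated_by: str | None = None  # strict dominance witness
    witness_pair: tuple[str, str] | None = None  # extended-dominance witnesses

    @property
    def label(self) -> str:
        return self.outcome.label


@dataclass
class FrontierResult:
    """All strategies ordered by effect, with dominance status and ratios."""

    evaluations: list[StrategyEvaluation]
    baseline: str

    @property
    def frontier_labels(self) -> list[str]:
        return [e.label for e in self.evaluations if e.status == "frontier"]

    def __getitem__(self, label: str) -> StrategyEvaluation:
        for e in self.evaluations:
            if e.label == label:
                return e
        raise KeyError(label)

    def icer(self, label: str, rounded: bool = True) -> float | None:
        v = self[label].icer
        if v is None or not rounded:
            return v
        return round_dollar(v)

    def acer(self, label: str, rounded: bool = True) -> float | None:
        v = self[label].acer
        if v is None or not rounded:
            return v
        return round_dollar(v)

    def table(self, rounded: bool = True) -> pd.DataFrame:
        rows = []
        for e in self.evaluations:
            rows.append(
                {
                    "strategy": e.label,
                    "cost": e.outcome.cost,
                    "effect": e.outcome.effect,
                    "status": e.status,
                    "icer": (round_dollar(e.icer) if rounded and e.icer is not None
                             else e.icer),
                    "acer": (round_dollar(e.acer) if rounded and e.acer is not None
                             else e.acer),
                    "dominated_by": e.dominated_by,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path, rounded: bool = True) -> None:
        self.table(rounded=rounded).to_csv(path, index=False)


def acer(strategy: StrategyOutcome, baseline: StrategyOutcome) -> float:
    """Average cost-effectiveness ratio versus the no-intervention baseline."""
    de = strategy.effect - baseline.effect
    if de == 0:
        raise UndefinedRatioError(
            f"strategies {strategy.label!r} and {baseline.label!r} have equal "
            "effects; the ratio is undefined"
        )
    return (strategy.cost - baseline.cost) / de


def _icer(a: StrategyOutcome, b: StrategyOutcome) -> float:
    """ICER of b versus a (b the more effective)."""
    de = b.effect - a.effect
    if de == 0:
        raise UndefinedRatioError(f"{a.label!r} and {b.label!r} have equal effects")
    return (b.cost - a.cost) / de


def frontier(
    outcomes: Sequence[StrategyOutcome],
    baseline: str | None = None,
    tie_tolerance: float = 1.0,
) -> FrontierResult:
    """Rank strategies, remove dominated ones, compute frontier ICERs.

    ``baseline`` names the comparator for ACERs; by default the least
    effective (then cheapest) strategy.  ``tie_tolerance`` is the dollar
    resolution below which consecutive ICERs count as tied (see module
    docstring).
    """
    if not outcomes:
        raise ValueError("need at least one strategy")
    labels = [o.label for o in outcomes]
    if len(set(labels)) != len(labels):
        raise ValueError("strategy labels must be unique")

    ordered = sorted(outcomes, key=lambda o: (o.effect, o.cost, o.label))
    base = ordered[0] if baseline is None else next(
        o for o in ordered if o.label == baseline
    )
    evals = {o.label: StrategyEvaluation(outcome=o, status="frontier") for o in ordered}

    # ACERs vs baseline (undefined for equal effects, including the baseline)
    for o in ordered:
        if o.label != base.label and o.effect != base.effect:
            evals[o.label].acer = acer(o, base)

    # strict dominance (exact-tie duplicates collapse onto the first copy)
    for o in ordered:
        for other in ordered:
            if other.label == o.label:
                continue
            leq_cost = other.cost <= o.cost
            geq_eff = other.effect >= o.effect
            strict = other.cost < o.cost or other.effect > o.effect
            tie_dup = (
                other.cost == o.cost
                and other.effect == o.effect
                and ordered.index(other) < ordered.index(o)
            )
            if (leq_cost and geq_eff and strict) or tie_dup:
                evals[o.label].status = "dominated"
                evals[o.label].dominated_by = other.label
                break

    survivors = [o for o in ordered if evals[o.label].status == "frontier"]

    # extended dominance: drop members until ICERs strictly increase beyond
    # the tie tolerance
    changed = True
    while changed and len(survivors) > 2:
        changed = False
        icers = [_icer(survivors[i - 1], survivors[i]) for i in range(1, len(survivors))]
        for i in range(len(icers) - 1):
            if icers[i] >= icers[i + 1] - tie_tolerance:
                victim = survivors[i + 1]
                evals[victim.label].status = "extended_dominated"
                evals[victim.label].witness_pair = (
                    survivors[i].label,
                    survivors[i + 2].label,
                )
                del survivors[i + 1]
                changed = True
                break

    for i in range(1, len(survivors)):
        e = evals[survivors[i].label]
        e.icer = _icer(survivors[i - 1], survivors[i])
        e.comparator = survivors[i - 1].label

    return FrontierResult(evaluations=[evals[o.label] for o in ordered],
                          baseline=base.label)


def ce_plane(
    outcomes: Sequence[StrategyOutcome],
    baseline: str | None = None,
    tie_tolerance: float = 1.0,
) -> pd.DataFrame:
    """Incremental cost and effect of every strategy versus the baseline,
    with frontier status flags (the cost-effectiveness plane of the league
    table)."""
    res = frontier(outcomes, baseline=baseline, tie_tolerance=tie_tolerance)
    base = res[res.baseline].outcome
    rows = []
    for e in res.evaluations:
        rows.append(
            {
                "strategy": e.label,
                "delta_cost": e.outcome.cost - base.cost,
                "delta_effect": e.outcome.effect - base.effect,
                "status": e.status,
                "on_frontier": e.status == "frontier",
            }
        )
    return pd.DataFrame(rows)


def outcomes_from_csv(path: str | Path) -> list[StrategyOutcome]:
    """Read a label,cost,effect CSV into strategy outcomes."""
    df = pd.read_csv(path)
    missing = {"label", "cost", "effect"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        StrategyOutcome(label=str(r.label), cost=float(r.cost), effect=float(r.effect))
        for r in df.itertuples()
    ]
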