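"""Published base-case league tables for the eleven DARE strategies.

These are the printed lifetime cost, life-year and QALY values (AUD 2014,
per person entering the cohort at age 35) from the original Australian
base-case analysis, undiscounted and discounted at 3 % per year.  They serve
two purposes: as reference inputs for exercising the frontier arithmetic on
real published cells (a "printed-cells" mode that bypasses the engine), and
as calibration anchors for the synthetic fixture.

Effects are printed to four decimals and costs to the dollar, so ratios
recomputed from these cells can differ from unrounded values in the last
digit.
"""

from __future__ import annotations

import pandas as pd

from .economics import StrategyOutcome

__all__ = ["published_base_case", "published_outcomes"]

# label, undiscounted (cost, LY, QALY), discounted 3% (cost, LY, QALY)
_ROWS = [
    ("No screening",          373, 46.2328, 35.1146,  195, 24.2034, 18.3857),
    ("Age 35-49 every 5 years", 755, 46.2434, 35.1225,  529, 24.2091, 18.3899),
    ("Age 35-49 every 4 years", 883, 46.2487, 35.1264,  629, 24.2118, 18.3919),
    ("Age 35-49 every 3 years", 1008, 46.2528, 35.1295,  736, 24.2139, 18.3936),
    ("Age 35-49 every 2 years", 1385, 46.2642, 35.1382, 1033, 24.2191, 18.3977),
    ("Age 35-49 every year",   2250, 46.2722, 35.1445, 1745, 24.2229, 18.4008),
    ("Age >=50 every 5 years", 1279, 46.2953, 35.1607,  600, 24.2217, 18.3993),
    ("Age >=50 every 4 years", 1495, 46.3102, 35.1717,  692, 24.2259, 18.4024),
    ("Age >=50 every 3 years", 1833, 46.3304, 35.1877,  837, 24.2314, 18.4069),
    ("Age >=50 every 2 years", 2506, 46.3600, 35.2104, 1119, 24.2394, 18.4131),
    ("Age >=50 every year",    4468, 46.3938, 35.2379, 1915, 24.2483, 18.4206),
]


def published_base_case() -> pd.DataFrame:
    """The full published base-case table as a DataFrame."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "strategy",
            "cost_undiscounted",
            "life_years_undiscounted",
            "qalys_undiscounted",
            "cost_discounted",
            "life_years_discounted",
            "qalys_discounted",
        ],
    )


def published_outcomes(
    discounting: str = "discounted", effect: str = "qaly"
) -> list[StrategyOutcome]:
    """Published cells as StrategyOutcome inputs for the frontier algorithm.

    discounting: "discounted" (3 %) or "undiscounted";
    effect: "qaly" or "life_years".
    """
    if discounting not in ("discounted", "undiscounted"):
        raise ValueError("discounting must be 'discounted' or 'undiscounted'")
    if effect not in ("qaly", "life_years"):
        raise ValueError("effect must be 'qaly' or 'life_years'")
    df = published_base_case()
    cost_col = f"cost_{discounting}"
    eff_col = ("qalys_" if effect == "qaly" else "life_years_") + discounting
    return [
        StrategyOutcome(label=r["strategy"], cost=float(r[cost_col]),
                        effect=float(r[eff_col]))
        for _, r in df.iterrows()
    ]
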