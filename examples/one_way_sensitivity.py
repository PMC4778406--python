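"""One-way sensitivity of the screening ICERs to the false-positive cost.

Re-runs the pipeline for men aged >=50 with the cost of a false-positive
referral at $100, $218 (base) and $500, and prints the tornado-table ICERs
of each interval against the next-less-intensive one.  The ICERs rise with
the false-positive cost because the referral burden scales with the number
of screens performed.
"""

from darescreen import (
    base_case_parameters,
    reference_schedules,
    standard_strategies,
)
from darescreen.sensitivity import owsa

params, settings = base_case_parameters()
schedules = reference_schedules(seed=1, settings=settings, params=params)
menu = [
    s for s in standard_strategies(settings)
    if (not s.screening) or s.screen_start_age == 50
]
menu.sort(key=lambda s: -s.interval_years if s.screening else -99)

table = owsa(
    "cost_false_positive", (100.0, 500.0), 3, menu, params, settings, schedules
)
shorter = {c: c.replace("icer[Age >=50 every ", "").replace("]", "")
           for c in table.columns}
print(table.rename(columns=shorter).round(0).to_string(index=False))
print()
print(
    "Each column is the extra dollars per extra QALY from tightening the\n"
    "screening interval one notch, at the given false-positive cost."
)
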