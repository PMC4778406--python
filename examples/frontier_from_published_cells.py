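"""Efficiency-frontier arithmetic on the published base-case league table.

Feeds the eleven published (lifetime cost, QALY) pairs — discounted at 3 % —
through strict- and extended-dominance ranking and prints each strategy's
status, frontier ICER ($ per QALY gained versus the preceding frontier
strategy) and ACER ($ per QALY gained versus no screening).  Strategies
marked 'dominated' are costlier and less effective than another option;
'extended_dominated' strategies are never the best buy at any willingness
to pay.
"""

from darescreen import frontier, published_outcomes

outcomes = published_outcomes(discounting="discounted", effect="qaly")
result = frontier(outcomes)

print(result.table().to_string(index=False))
print()
print("Frontier (best-buy sequence):", " -> ".join(result.frontier_labels))
print(
    "Reading: at a willingness to pay between $29,760 and $32,222 per QALY,\n"
    "screening men aged >=50 every four years is the optimal strategy."
)
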