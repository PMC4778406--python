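"""Independent brute-force oracles shared across test modules."""

from __future__ import annotations


def frontier_oracle(outcomes, tol=0.0):
    """Exhaustive dominance check: a strategy is on the efficiency frontier
    iff no other strategy, and no convex combination of two other
    strategies, attains at least its effect at strictly lower cost (or the
    same cost with strictly more effect).  Returns (frontier labels ordered
    by effect, {label: ICER vs predecessor})."""
    members = []
    for o in outcomes:
        others = [p for p in outcomes if p.label != o.label]
        dominated = any(
            p.cost <= o.cost and p.effect >= o.effect
            and (p.cost < o.cost or p.effect > o.effect)
            for p in others
        )
        extended = False
        for j, a in enumerate(others):
            for b in others[j + 1:]:
                lo, hi = sorted((a, b), key=lambda s: s.effect)
                if not (lo.effect <= o.effect <= hi.effect) or lo.effect == hi.effect:
                    continue
                th = (o.effect - lo.effect) / (hi.effect - lo.effect)
                chord = lo.cost + th * (hi.cost - lo.cost)
                if chord < o.cost - tol:
                    extended = True
        if not dominated and not extended:
            members.append(o)
    members.sort(key=lambda s: s.effect)
    icers = {
        b.label: (b.cost - a.cost) / (b.effect - a.effect)
        for a, b in zip(members, members[1:])
    }
    return [m.label for m in members], icers
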