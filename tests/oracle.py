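"""Independent brute-force reference implementation of the table score.

Deliberately written without reusing tablesim.metric internals: plain
math, exhaustive enumeration of duplicate matchings via permutations.
Only feasible for tiny setups; used to cross-check the package.
"""

from __future__ import annotations

import itertools
import math


def brute_force_score(a, b, w_trans=1.0, w_rot=1.0, w_miss=1000.0):
    """Normalized pair score: matched pairs (min-total-cost over all
    injective matchings per instrument identity) plus one penalty per
    unmatched instance, divided by sum of max(m, n) over identities."""
    by_id_a: dict[str, list] = {}
    by_id_b: dict[str, list] = {}
    for p in a.placements:
        by_id_a.setdefault(p.instrument_id, []).append(p)
    for p in b.placements:
        by_id_b.setdefault(p.instrument_id, []).append(p)

    total = 0.0
    n_slots = 0
    for iid in set(by_id_a) | set(by_id_b):
        pa = by_id_a.get(iid, [])
        pb = by_id_b.get(iid, [])
        m, n = len(pa), len(pb)
        n_slots += max(m, n)
        if m == 0 or n == 0:
            total += w_miss * (m + n)
            continue
        if m > n:  # enumerate over the larger side's subsets via permutations
            pa, pb = pb, pa
            m, n = n, m
        best = math.inf
        for perm in itertools.permutations(range(n), m):
            cost = 0.0
            for i, j in enumerate(perm):
                dx = pa[i].x - pb[j].x
                dy = pa[i].y - pb[j].y
                dt = math.sqrt(dx * dx + dy * dy)
                da = abs(pa[i].angle - pb[j].angle)
                dr = min(da, 360.0 - da)
                cost += w_trans * dt + w_rot * dr
            best = min(best, cost)
        total += best + w_miss * (n - m)
    if n_slots == 0:
        raise ZeroDivisionError("both setups empty")
    return total / n_slots
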