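"""Independent brute-force oracles used to validate the package's
implementations.  These deliberately avoid the library's own code paths
(edlib, union-find) so that agreement is meaningful."""

from __future__ import annotations

import itertools


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook full-DP Levenshtein distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def brute_force_assign(observed: str, whitelist: list[str]):
    """Literal application of the two printed assignment rules using the
    DP oracle: assigned iff L1 < 3 and L1 < L2 - 1."""
    dists = sorted((dp_levenshtein(observed, bc), bc) for bc in whitelist)
    l1, best = dists[0]
    l2 = dists[1][0] if len(dists) > 1 else float("inf")
    if l1 < 3 and l1 < l2 - 1:
        return best, l1, l2
    return None, l1, l2


def transitive_closure_groups(items, linked) -> list[list]:
    """Partition ``items`` into groups by repeated expansion of the
    pairwise ``linked`` predicate (no union-find)."""
    remaining = list(items)
    groups = []
    while remaining:
        group = [remaining.pop(0)]
        changed = True
        while changed:
            changed = False
            for other in list(remaining):
                if any(linked(member, other) for member in group):
                    group.append(other)
                    remaining.remove(other)
                    changed = True
        groups.append(group)
    return groups


def chi2_closed_form_2x2(table) -> float:
    """n(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) for a 2x2 table."""
    (a, b), (c, d) = table
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def pairwise_min_distance(barcodes: list[str]) -> int:
    return min(
        dp_levenshtein(x, y) for x, y in itertools.combinations(barcodes, 2)
    )
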