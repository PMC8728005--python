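"""Independent reference implementations used only to check the package.

These are deliberately written as plain transcriptions (scalar loops, no
shared code with the package) so they can serve as second routes to the
same quantities.
"""

from __future__ import annotations

import math


def wc_site_components(pop_genotypes: list[list[int]]) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) a, b, c for one biallelic site.

    ``pop_genotypes``: one list of diploid alt-allele dosages (0/1/2) per
    population; missing genotypes are simply absent from the lists.
    Direct transcription of the published variance components for diploids
    with observed heterozygosity.
    """
    pops = [p for p in pop_genotypes if len(p) > 0]
    r = len(pops)
    if r < 2:
        raise ValueError("need two informative populations")
    n = [len(p) for p in pops]
    p_freq = [sum(p) / (2 * len(p)) for p in pops]
    h_freq = [sum(1 for g in p if g == 1) / len(p) for p in pops]

    nbar = sum(n) / r
    nsum = sum(n)
    nc = (nsum - sum(x * x for x in n) / nsum) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p_freq)) / nsum
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p_freq)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h_freq)) / nsum

    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2.0
    return a, b, c


def transitive_closure_merge(
    intervals: list[tuple[int, int]], max_gap: int
) -> list[list[tuple[int, int]]]:
    """Brute-force clustering: link every pair of intervals whose gap is
    strictly below ``max_gap``, then take connected components."""
    n = len(intervals)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            s1, e1 = intervals[i]
            s2, e2 = intervals[j]
            gap = max(s1, s2) - min(e1, e2)
            if gap < max_gap:
                adj[i][j] = True
    seen = [False] * n
    clusters = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            k = stack.pop()
            comp.append(intervals[k])
            for j in range(n):
                if adj[k][j] and not seen[j]:
                    seen[j] = True
                    stack.append(j)
        clusters.append(sorted(comp))
    return clusters


def jukes_cantor(p: float) -> float:
    return -0.75 * math.log(1 - 4 * p / 3)
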