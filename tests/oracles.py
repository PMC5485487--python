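"""Independent reference implementations used to cross-check the package.

These deliberately avoid the package's own code paths: the odds-ratio
reference is direct arithmetic on the four cells, and the Ward oracle
re-derives every candidate merge cost from the *original* squared distance
matrix instead of running Lance-Williams updates.
"""

from __future__ import annotations

import math

import numpy as np


def odds_ratio_reference(h_taxon: int, h_total: int, l_taxon: int, l_total: int) -> float:
    """(H_arc/H_narc) / (L_arc/L_narc) computed cell by cell; NaN when any
    required denominator is zero."""
    h_narc = h_total - h_taxon
    l_narc = l_total - l_taxon
    if h_narc == 0 or l_narc == 0:
        return math.nan
    heavy_odds = h_taxon / h_narc
    light_odds = l_taxon / l_narc
    if light_odds == 0:
        return math.nan
    return heavy_odds / light_odds


def ward_oracle(dm: np.ndarray) -> list[tuple[int, int, float]]:
    """Exhaustive minimum-variance agglomeration.

    At every step, the cost of merging clusters A and B is evaluated from
    the original squared distances via the centroid identity

        cost(A,B) = (2|A||B|/(|A|+|B|)) *
                    (X/(|A||B|) - W_A/|A|^2 - W_B/|B|^2)

    with X the sum of squared distances across the pair and W the within-
    cluster sums; the cheapest pair merges (lowest-id pair on ties) and the
    merge height is sqrt(cost).  Node ids follow the leaves-then-merges
    numbering.
    """
    d2 = np.asarray(dm, dtype=float) ** 2
    n = d2.shape[0]
    clusters: list[tuple[int, ...]] = [(i,) for i in range(n)]
    ids = list(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n

    def cost(a: tuple[int, ...], b: tuple[int, ...]) -> float:
        na, nb = len(a), len(b)
        cross = sum(d2[i, j] for i in a for j in b)
        wa = sum(d2[i, j] for p, i in enumerate(a) for j in a[p + 1 :])
        wb = sum(d2[i, j] for p, i in enumerate(b) for j in b[p + 1 :])
        return (2 * na * nb / (na + nb)) * (
            cross / (na * nb) - wa / na**2 - wb / nb**2
        )

    while len(clusters) > 1:
        best = None
        best_cost = math.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                c = cost(clusters[i], clusters[j])
                if c < best_cost:
                    best_cost = c
                    best = (i, j)
        i, j = best
        merges.append((ids[i], ids[j], math.sqrt(max(best_cost, 0.0))))
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        ids = [x for k, x in enumerate(ids) if k not in (i, j)]
        clusters.append(merged)
        ids.append(next_id)
        next_id += 1
    return merges


def pearson_reference(x, y) -> float:
    """Textbook Pearson correlation, written out longhand."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x)) * math.sqrt(
        sum((b - my) ** 2 for b in y)
    )
    return num / den
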