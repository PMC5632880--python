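"""Independent brute-force oracles used to check the implementation.

Each oracle recomputes a statistic from its definition (full enumeration,
textbook step-up, O(n^3) agglomeration) and deliberately shares no code
with the package's implementation paths.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy.stats import binom


def minlike_binomial_p(x1: int, x2: int, n1: float, n2: float) -> float:
    """Two-sided conditional-binomial p by full point-mass enumeration."""
    n = x1 + x2
    if n == 0:
        return 1.0
    pi = n1 / (n1 + n2)
    pmf = binom.pmf(np.arange(n + 1), n, pi)
    return min(float(pmf[pmf <= pmf[x1] * (1 + 1e-12)].sum()), 1.0)


def step_up_q(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values from the step-up definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = running
    q = np.empty(m)
    q[order] = q_sorted
    return q


def hypergeom_upper_tail(m_univ: int, k_path: int, n_draw: int, k_obs: int) -> float:
    """P(overlap >= k_obs) by exact enumeration of hypergeometric masses."""
    denom = comb(m_univ, n_draw)
    total = 0
    for i in range(k_obs, min(n_draw, k_path) + 1):
        if n_draw - i <= m_univ - k_path:
            total += comb(k_path, i) * comb(m_univ - k_path, n_draw - i)
    return total / denom


def average_linkage_heights(dist: np.ndarray) -> list[float]:
    """Merge heights of average-linkage agglomeration, O(n^3) recomputation."""
    n = dist.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None
        for a_pos, a in enumerate(ids):
            for b in ids[a_pos + 1:]:
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(float(d))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return heights
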