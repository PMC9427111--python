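"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expectations from first principles (per-cell
event enumeration, exact Markov-chain absorption) without touching the
package's engine code, so simulator tests compare two independent routes.
"""

from __future__ import annotations

import heapq

import numpy as np
from scipy.stats import hypergeom


def brute_force_cycle_composition(n_fast: int, n_slow: int, d_fast: float,
                                  d_slow: float, m_t: float) -> tuple[int, int]:
    """Deterministic two-type composition at the population cap.

    Per-cell event queue: every cell of a type divides its own doubling
    time after birth; the cap check runs after each division, exactly as
    the growth-cycle contract states.  With zero mutation rates and
    unlimited replicative age the within-cycle dynamics are
    deterministic, so this enumerates the exact cap composition.
    """
    n0 = n_fast + n_slow
    cap = round(2.0 ** m_t * n0)
    heap = []
    cnt = 0
    for _ in range(n_fast):
        heap.append((d_fast, cnt, "f")); cnt += 1
    for _ in range(n_slow):
        heap.append((d_slow, cnt, "s")); cnt += 1
    heapq.heapify(heap)
    comp = {"f": n_fast, "s": n_slow}
    total = n0
    while total < cap and heap:
        due, _, typ = heapq.heappop(heap)
        d = d_fast if typ == "f" else d_slow
        heapq.heappush(heap, (due + d, cnt, typ)); cnt += 1
        heapq.heappush(heap, (due + d, cnt, typ)); cnt += 1
        comp[typ] += 1
        total += 1
    return comp["f"], comp["s"]


def two_type_chain(n: int, d_fast: float, d_slow: float, m_t: float):
    """Exact serial-bottleneck Markov chain for a two-type population.

    State = number of fast cells among the ``n`` bottleneck survivors.
    Returns (fixation probability of the fast type from each state,
    conditional mean cycles to fast fixation from each state).
    """
    cap = round(2.0 ** m_t * n)
    P = np.zeros((n + 1, n + 1))
    for i in range(n + 1):
        if i in (0, n):
            P[i, i] = 1.0
            continue
        f, s = brute_force_cycle_composition(i, n - i, d_fast, d_slow, m_t)
        for j in range(n + 1):
            P[i, j] = hypergeom.pmf(j, cap, f, n)
    # iterate the chain, tracking absorption flux into the fast state
    p_fix = np.zeros(n + 1)
    t_cond = np.zeros(n + 1)
    for start in range(1, n):
        dist = np.zeros(n + 1)
        dist[start] = 1.0
        absorbed_fast = 0.0
        weighted_time = 0.0
        for step in range(1, 100_000):
            new = dist @ P
            flux_fast = new[n] - dist[n]
            absorbed_fast += flux_fast
            weighted_time += step * flux_fast
            dist = new
            if dist[1:n].sum() < 1e-14:
                break
        p_fix[start] = absorbed_fast
        t_cond[start] = weighted_time / absorbed_fast if absorbed_fast > 0 else np.nan
    p_fix[n] = 1.0
    return p_fix, t_cond


def exhaustive_topk_enrichment_tail(labels, k: int, observed_count: int) -> float:
    """Exact P(X >= observed_count) for random k-subsets, by enumeration."""
    from itertools import combinations

    labels = list(labels)
    n = len(labels)
    hits = 0
    total = 0
    for subset in combinations(range(n), k):
        total += 1
        if sum(labels[i] for i in subset) >= observed_count:
            hits += 1
    return hits / total
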