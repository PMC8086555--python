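"""Independent from-definition oracles used to cross-check the package.

Everything here is written straight from the mathematical definitions with
naive loops / library calls, deliberately avoiding the implementation's
vectorized code paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import comb


# ---------------------------------------------------------------------------
# nestedness temperature, no vectorization
# ---------------------------------------------------------------------------


def nestedness_temperature_naive(packed: np.ndarray) -> float:
    """Matrix temperature of an already-packed matrix, computed cell-by-cell
    with scalar root finding and numerically integrated isocline areas
    (packing canonicalization is exercised by separate invariance tests)."""
    packed = np.asarray(packed)
    n_rows, n_cols = packed.shape
    fill = packed.sum() / packed.size

    def area_of(p: float) -> float:
        val, _ = quad(
            lambda x: (1 - x**p) ** (1.0 / p), 0.0, 1.0,
            limit=400, epsabs=1e-13, epsrel=1e-13,
        )
        return val

    p = brentq(lambda lp: area_of(math.exp(lp)) - fill, math.log(1e-4), math.log(1e4),
               xtol=1e-13)
    p = math.exp(p)

    def g(x: float) -> float:
        x = min(max(x, 0.0), 1.0)
        return (1 - x**p) ** (1.0 / p)

    total = 0.0
    for i in range(n_rows):
        for j in range(n_cols):
            v = (i + 0.5) / n_rows
            u = (j + 0.5) / n_cols
            expected = 1 if v < g(u) else 0
            if packed[i, j] == expected:
                continue
            t0 = -min(u, v)
            t1 = 1.0 - max(u, v)
            t_star = brentq(lambda t: (v + t) - g(u + t), t0, t1, xtol=1e-14)
            total += (t_star / (t1 - t0)) ** 2
    return min(100.0, 100.0 * (total / packed.size) / 0.04145)


# ---------------------------------------------------------------------------
# graph statistics from their definitions
# ---------------------------------------------------------------------------


def assortativity_naive(edges: list[tuple]) -> float | None:
    """Pearson correlation of end degrees over both edge orientations,
    computed from the raw sum formulas."""
    deg: dict = {}
    for a, b in edges:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    xs, ys = [], []
    for a, b in edges:
        xs += [deg[a], deg[b]]
        ys += [deg[b], deg[a]]
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    if sxx == 0 or syy == 0:
        return None
    return sxy / math.sqrt(sxx * syy)


def clustering_naive(adj: np.ndarray) -> float:
    """Mean local clustering by explicit triangle counting."""
    n = adj.shape[0]
    vals = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        t = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b]
        )
        vals.append(2.0 * t / (k * (k - 1)))
    return float(np.mean(vals))


def mean_path_naive(adj: np.ndarray) -> float:
    """Mean shortest-path length by breadth-first search from every node."""
    n = adj.shape[0]
    total, count = 0, 0
    for src in range(n):
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in range(n):
                    if adj[u, v] and v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for v, d in dist.items():
            if v != src:
                total += d
                count += 1
    return total / count


# ---------------------------------------------------------------------------
# occurrence set algebra and sampling expectations
# ---------------------------------------------------------------------------


def overlap_counts_naive(
    occurrence_sets: dict[str, set[str]]
) -> dict[tuple[str, ...], int]:
    """Exclusive Venn counts by exhaustive enumeration of group combinations."""
    labels = sorted(occurrence_sets)
    out = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = set.intersection(*(occurrence_sets[g] for g in combo))
            for g in labels:
                if g not in combo:
                    inside = inside - occurrence_sets[g]
            out[combo] = len(inside)
    return out


def expected_rarefied_richness(counts: np.ndarray, depth: int) -> float:
    """Hypergeometric expectation of retained richness at a rarefaction depth."""
    counts = np.asarray(counts)
    total = counts.sum()
    return float(
        sum(1.0 - comb(total - c, depth) / comb(total, depth) for c in counts)
    )


def expected_accumulation(presence: np.ndarray, t: int) -> float:
    """Exact sample-based rarefaction: expected richness after t samples."""
    n = presence.shape[1]
    occ = presence.sum(axis=1)
    return float(sum(1.0 - comb(n - m, t) / comb(n, t) for m in occ))


def raup_crick_pair_naive(
    mat: np.ndarray, i: int, j: int, n_null: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo Raup-Crick for one taxon pair using numpy's weighted
    choice without replacement (a different sampler than the package's)."""
    n_samples = mat.shape[1]
    w = mat.sum(axis=0).astype(float)
    w = w / w.sum()
    occ_i, occ_j = int(mat[i].sum()), int(mat[j].sum())
    s_obs = int((mat[i] & mat[j]).sum())
    less = equal = 0
    for _ in range(n_null):
        a = set(rng.choice(n_samples, size=occ_i, replace=False, p=w))
        b = set(rng.choice(n_samples, size=occ_j, replace=False, p=w))
        s = len(a & b)
        if s < s_obs:
            less += 1
        elif s == s_obs:
            equal += 1
    return (less + 0.5 * equal) / n_null
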