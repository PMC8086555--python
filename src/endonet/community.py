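"""Distance matrices, NMDS ordination, ANOSIM and PERMANOVA.

Abundance-based comparisons use Bray-Curtis dissimilarity on square-root
transformed relative read abundances; occurrence-based comparisons use
Jaccard distance on the presence-absence matrix.  The permutation tests are
delegated to scikit-bio (Clarke's ANOSIM, Anderson's PERMANOVA) behind this
module's interface, with explicit seeding for bit-reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix as _SkbioDM
from skbio.stats.distance import anosim as _skbio_anosim
from skbio.stats.distance import permanova as _skbio_permanova

from .otu import OtuTable, PresenceMatrix

__all__ = [
    "DistanceMatrix",
    "Ordination",
    "bray_curtis",
    "jaccard_distance",
    "nmds",
    "anosim",
    "permanova",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with zero diagonal, entries in [0, 1]."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(self.values, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def _to_skbio(self) -> _SkbioDM:
        return _SkbioDM(self.values, ids=self.sample_ids)


def bray_curtis(table: OtuTable, sqrt_transform: bool = True) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    With ``sqrt_transform`` each sample is first converted to relative
    abundances and square-rooted (the transform used for the ordinations).
    """
    totals = table.counts.sum(axis=0)
    zero = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if zero:
        raise ValueError(f"zero-total sample(s): {zero}")
    x = table.counts.T.astype(float)  # samples x taxa
    if sqrt_transform:
        x = np.sqrt(x / x.sum(axis=1, keepdims=True))
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(list(table.sample_ids), d)


def jaccard_distance(presence: PresenceMatrix) -> DistanceMatrix:
    """Pairwise Jaccard distance (1 - |A & B| / |A | B|) on occurrence sets."""
    occ = presence.presence.T.astype(bool)  # samples x taxa
    empty = [s for s, row in zip(presence.sample_ids, occ) if not row.any()]
    if empty:
        raise ValueError(f"all-zero sample(s): {empty}")
    d = squareform(pdist(occ, metric="jaccard"))
    return DistanceMatrix(list(presence.sample_ids), d)


@dataclass
class Ordination:
    """NMDS configuration with its Kruskal stress-1."""

    sample_ids: list[str]
    coordinates: np.ndarray
    stress: float
    n_restarts: int
    best_seed: int

    def to_frame(self) -> pd.DataFrame:
        cols = [f"nmds{k + 1}" for k in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson classical scaling, used as the first NMDS start."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    seed: int = 0,
) -> Ordination:
    """Nonmetric MDS: isotonic regression of distances on dissimilarity ranks.

    Runs one start from the classical-scaling solution plus ``n_restarts``
    seeded random starts, and returns the configuration with the lowest
    Kruskal stress-1.  Deterministic given ``seed``.
    """
    from sklearn.manifold import MDS

    n = len(d.sample_ids)
    if n < 3 or n <= k:
        raise ValueError(f"NMDS in {k} dimensions needs at least {max(3, k + 1)} samples")

    def _run(init, random_state):
        model = MDS(
            n_components=k,
            metric=False,
            dissimilarity="precomputed",
            n_init=1,
            max_iter=max_iter,
            random_state=random_state,
            normalized_stress=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords = model.fit_transform(d.values, init=init)
        return coords, float(model.stress_)

    best_coords, best_stress, best_seed = None, np.inf, -1
    coords, stress = _run(_classical_mds(d.values, k), seed)
    if stress < best_stress:
        best_coords, best_stress, best_seed = coords, stress, -1
    for r in range(n_restarts):
        coords, stress = _run(None, seed + r)
        if stress < best_stress:
            best_coords, best_stress, best_seed = coords, stress, seed + r
    return Ordination(
        sample_ids=list(d.sample_ids),
        coordinates=best_coords,
        stress=best_stress,
        n_restarts=n_restarts,
        best_seed=best_seed,
    )


def _grouping_series(d: DistanceMatrix, grouping) -> pd.Series:
    if isinstance(grouping, pd.Series):
        g = grouping.loc[d.sample_ids]
    else:
        g = pd.Series({s: grouping[s] for s in d.sample_ids})
    counts = g.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"group(s) with fewer than 2 samples: {small}")
    return g.loc[d.sample_ids]


def anosim(
    d: DistanceMatrix, grouping, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Clarke's ANOSIM: rank-based separation statistic R and permutation p.

    R = (mean between-group rank - mean within-group rank) / (M / 4) over the
    M pairwise distances; p = (b + 1) / (n_perm + 1) over label shuffles.
    """
    g = _grouping_series(d, grouping)
    state = np.random.get_state()
    try:
        np.random.seed(seed % 2**32)
        res = _skbio_anosim(d._to_skbio(), g.to_numpy(), permutations=n_perm)
    finally:
        np.random.set_state(state)
    return float(res["test statistic"]), float(res["p-value"])


def permanova(
    d: DistanceMatrix, grouping, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """PERMANOVA pseudo-F from a distance matrix, p by free label permutation."""
    g = _grouping_series(d, grouping)
    state = np.random.get_state()
    try:
        np.random.seed(seed % 2**32)
        res = _skbio_permanova(d._to_skbio(), g.to_numpy(), permutations=n_perm)
    finally:
        np.random.set_state(state)
    return float(res["test statistic"]), float(res["p-value"])
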