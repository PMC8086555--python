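"""Plant-fungi and fungi-fungi co-occurrence networks and their indices.

The analysis builds, per plant organ, a bipartite network of plant samples
vs fungal taxa from the occurrence matrix, projects it onto a fungi-fungi
graph, scores every taxon pair with a Raup-Crick null-model similarity
(999 null draws weighted by per-sample richness), partitions pairs into
positive (rc > 0.5) and negative (rc < 0.49) co-occurrence networks, and
summarizes each network with five indices: connectance, nestedness
temperature, small-world sigma, rich-club coefficient and degree
assortativity.  Organ differences in any index are tested by permuting
organ labels over samples and rebuilding both networks per replicate.

Randomness policy: every public operation takes one integer seed; internal
replicates derive child seeds from ``numpy.random.SeedSequence(seed).spawn``
in replicate order, so any replicate can be reproduced in isolation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

from .otu import OtuValidationError, PresenceMatrix

logger = logging.getLogger("endonet")

__all__ = [
    "BipartiteNetwork",
    "TaxonNetwork",
    "RaupCrickMatrix",
    "NetworkIndexReport",
    "OrganIndexReport",
    "PermutationTestResult",
    "build_bipartite",
    "connectance",
    "nestedness_temperature",
    "project_to_taxa",
    "raup_crick_matrix",
    "partition_cooccurrence",
    "assortativity",
    "rich_club",
    "small_world",
    "organ_index_report",
    "permutation_compare",
    "BIPARTITE_INDICES",
    "TAXON_INDICES",
]

#: Atmar-Patterson normalizer: mean unexpectedness of a maximally
#: disordered matrix, so T spans [0, 100].
UNEXPECTEDNESS_NORMALIZER = 0.04145


# ---------------------------------------------------------------------------
# network containers
# ---------------------------------------------------------------------------


@dataclass
class BipartiteNetwork:
    """Plant samples of one organ vs fungal taxa, linked by occurrence."""

    plant_nodes: list[str]
    fungus_nodes: list[str]
    links: set[tuple[str, str]]
    organ: str | None = None

    def __post_init__(self) -> None:
        plants, fungi = set(self.plant_nodes), set(self.fungus_nodes)
        for s, t in self.links:
            if s not in plants or t not in fungi:
                raise ValueError(f"link ({s}, {t}) outside the declared layers")
        linked = {t for _, t in self.links}
        isolated = fungi - linked
        if isolated:
            logger.info("excluding %d fungus nodes without links", len(isolated))
            self.fungus_nodes = [t for t in self.fungus_nodes if t in linked]

    def presence_array(self) -> np.ndarray:
        """Taxa x samples 0/1 array over the network's nodes."""
        out = np.zeros((len(self.fungus_nodes), len(self.plant_nodes)), dtype=np.int8)
        ti = {t: i for i, t in enumerate(self.fungus_nodes)}
        si = {s: j for j, s in enumerate(self.plant_nodes)}
        for s, t in self.links:
            out[ti[t], si[s]] = 1
        return out


@dataclass
class TaxonNetwork:
    """Unipartite fungi-fungi graph (projection / positive / negative)."""

    nodes: list[str]
    edges: set[frozenset]
    kind: str = "projection"
    edge_scores: dict[frozenset, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("projection", "positive", "negative"):
            raise ValueError(f"unknown network kind {self.kind!r}")
        node_set = set(self.nodes)
        for e in self.edges:
            if len(e) != 2:
                raise ValueError("self-loop or malformed edge")
            if not e <= node_set:
                raise ValueError(f"edge {set(e)} outside the node set")
        if self.kind == "projection" and self.edge_scores is not None:
            raise ValueError("projection networks carry no edge scores")
        if self.kind != "projection":
            if self.edge_scores is None or set(self.edge_scores) != self.edges:
                raise ValueError("positive/negative networks need one score per edge")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            a, b = sorted(e)
            attrs = {}
            if self.edge_scores is not None:
                attrs["raup_crick"] = self.edge_scores[e]
            g.add_edge(a, b, **attrs)
        return g

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class RaupCrickMatrix:
    """Symmetric taxon x taxon Raup-Crick similarities in [0, 1]."""

    taxon_ids: list[str]
    rc: np.ndarray
    n_null: int
    seed: int

    def __post_init__(self) -> None:
        self.rc = np.asarray(self.rc, dtype=float)
        n = len(self.taxon_ids)
        if self.rc.shape != (n, n):
            raise ValueError("rc matrix shape mismatch")
        if not np.allclose(self.rc, self.rc.T, atol=1e-12):
            raise ValueError("rc matrix must be symmetric")
        off = self.rc[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < 0 or off.max() > 1):
            raise ValueError("rc entries must lie in [0, 1]")


@dataclass
class NetworkIndexReport:
    """The five network indices; ``None`` marks an undefined value."""

    connectance: float | None = None
    nestedness_T: float | None = None
    small_world: float | None = None
    rich_club: float | None = None
    assortativity: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "connectance": self.connectance,
            "nestedness_T": self.nestedness_T,
            "small_world": self.small_world,
            "rich_club": self.rich_club,
            "assortativity": self.assortativity,
        }


@dataclass
class OrganIndexReport:
    """Per-organ index report: bipartite + projection, plus the
    positive/negative co-occurrence variants."""

    organ: str
    main: NetworkIndexReport
    positive: NetworkIndexReport
    negative: NetworkIndexReport
    params: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "organ": self.organ,
            "main": self.main.as_dict(),
            "positive": self.positive.as_dict(),
            "negative": self.negative.as_dict(),
            "params": self.params,
        }


@dataclass
class PermutationTestResult:
    """Organ-difference permutation test for one network index."""

    index: str
    network: str
    delta_observed: float
    null_deltas: np.ndarray
    p: float
    tail: str
    n_perm: int
    n_dropped: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "index": self.index,
            "network": self.network,
            "delta_observed": self.delta_observed,
            "p": self.p,
            "tail": self.tail,
            "n_perm": self.n_perm,
            "n_dropped": self.n_dropped,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# bipartite network and its indices
# ---------------------------------------------------------------------------


def build_bipartite(presence: PresenceMatrix, organ: str) -> BipartiteNetwork:
    """Bipartite sample-taxon network for one organ's samples."""
    sub, samples = presence.organ_submatrix(organ)
    if len(samples) < 2:
        raise ValueError(f"organ {organ!r} has fewer than 2 samples")
    links = {
        (samples[j], presence.taxon_ids[i])
        for i, j in zip(*np.nonzero(sub))
    }
    return BipartiteNetwork(
        plant_nodes=samples,
        fungus_nodes=list(presence.taxon_ids),
        links=links,
        organ=organ,
    )


def connectance(net: BipartiteNetwork) -> float:
    """Realized links over all possible plant x fungus links."""
    if not net.plant_nodes or not net.fungus_nodes:
        raise ValueError("connectance undefined for an empty layer")
    return len(net.links) / (len(net.plant_nodes) * len(net.fungus_nodes))


def _isocline_exponent(fill: float) -> float:
    """Superellipse exponent p whose curve (x^p + y^p = 1) encloses ``fill``.

    The area under y = (1 - x^p)^(1/p) on the unit square is
    Gamma(1 + 1/p)^2 / Gamma(1 + 2/p), increasing in p from 0 to 1.
    """

    def area(log_p: float) -> float:
        p = math.exp(log_p)
        return math.exp(2 * gammaln(1 + 1 / p) - gammaln(1 + 2 / p)) - fill

    return math.exp(brentq(area, math.log(1e-4), math.log(1e4), xtol=1e-13))


def pack_matrix(mat: np.ndarray) -> np.ndarray:
    """Sort rows and columns by descending marginal totals.

    Ties in a marginal total are broken by the row/column occurrence
    pattern (presences packed first), iterating row and column sorts to a
    fixed point; rows or columns that still tie are identical, so the
    packed matrix does not depend on the input ordering.
    """
    mat = np.asarray(mat)
    n_rows, n_cols = mat.shape
    rt, ct = mat.sum(axis=1), mat.sum(axis=0)

    # refine tie classes with order-invariant multiset signatures
    # (rows keyed by the class multiset of their presence columns and vice
    # versa, iterated to a fixed partition)
    def _dense(keys):
        ranking = {k: r for r, k in enumerate(sorted(set(keys)))}
        return [ranking[k] for k in keys]

    rclass = _dense([-t for t in rt])
    cclass = _dense([-t for t in ct])
    for _ in range(n_rows + n_cols):
        rsig = [
            (rclass[i], tuple(sorted(cclass[j] for j in range(n_cols) if mat[i, j])))
            for i in range(n_rows)
        ]
        csig = [
            (cclass[j], tuple(sorted(rclass[i] for i in range(n_rows) if mat[i, j])))
            for j in range(n_cols)
        ]
        new_r, new_c = _dense(rsig), _dense(csig)
        if new_r == rclass and new_c == cclass:
            break
        rclass, cclass = new_r, new_c

    row_order = np.array(sorted(range(n_rows), key=lambda i: rclass[i]))
    col_order = np.array(sorted(range(n_cols), key=lambda j: cclass[j]))
    # polish: break residual (structurally equivalent) ties by the pattern
    # itself, iterating row and column sorts to a fixed point
    for _ in range(50):
        prev = (row_order.tolist(), col_order.tolist())
        row_order = np.array(
            sorted(
                range(n_rows),
                key=lambda i: (rclass[i], tuple(-mat[i, col_order])),
            )
        )
        col_order = np.array(
            sorted(
                range(n_cols),
                key=lambda j: (cclass[j], tuple(-mat[row_order, j])),
            )
        )
        if (row_order.tolist(), col_order.tolist()) == prev:
            break
    return mat[row_order][:, col_order]


def nestedness_temperature(mat: np.ndarray) -> float:
    """Matrix-temperature nestedness index T in [0, 100] (0 = perfectly nested).

    Deterministic variant of the Atmar-Patterson calculation:

    1. pack the matrix by sorting rows and columns by marginal totals
       (descending, ties keeping input order);
    2. place the fill isocline: the superellipse x^p + y^p = 1 in the unit
       square whose enclosed area equals the observed fill, separating the
       expected-presence (upper-left) from the expected-absence region;
    3. every cell disagreeing with the isocline's prediction contributes its
       squared distance from the isocline, measured along the cell's
       diagonal (direction parallel to the matrix's main diagonal) and
       normalized by that diagonal's length;
    4. T = 100 * mean contribution / 0.04145, clipped to [0, 100].

    Packing is the order induced by the marginal totals (no combinatorial
    re-packing), which keeps the index deterministic and permutation
    invariant.
    """
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("nestedness temperature needs at least a 2 x 2 matrix")
    if not np.isin(mat, (0, 1)).all():
        raise ValueError("matrix must be binary")
    fill = mat.mean()
    if fill in (0.0, 1.0):
        raise ValueError("temperature undefined for all-zero or all-one matrices")
    packed = pack_matrix(mat)
    n_rows, n_cols = packed.shape
    p = _isocline_exponent(fill)

    # cell centers in the unit square; v runs down the rows (0 = richest row)
    v = (np.arange(n_rows) + 0.5)[:, None] / n_rows * np.ones((1, n_cols))
    u = np.ones((n_rows, 1)) * (np.arange(n_cols) + 0.5)[None, :] / n_cols

    def g(x: np.ndarray) -> np.ndarray:
        return (1.0 - np.clip(x, 0.0, 1.0) ** p) ** (1.0 / p)

    expected = (v < g(u)).astype(np.int8)
    unexpected = packed != expected
    # diagonal through each cell: (u + t, v + t), clipped to the unit square
    t0 = -np.minimum(u, v)
    t1 = 1.0 - np.maximum(u, v)
    # bisection for the isocline crossing t*: v + t = g(u + t), monotone in t
    lo, hi = t0.copy(), t1.copy()
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        high = (v + mid) > g(u + mid)
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    t_star = 0.5 * (lo + hi)
    with np.errstate(invalid="ignore"):
        contrib = np.where(unexpected, (t_star / (t1 - t0)) ** 2, 0.0)
    temperature = 100.0 * contrib.mean() / UNEXPECTEDNESS_NORMALIZER
    return float(np.clip(temperature, 0.0, 100.0))


# ---------------------------------------------------------------------------
# fungi-fungi networks
# ---------------------------------------------------------------------------


def project_to_taxa(net: BipartiteNetwork) -> TaxonNetwork:
    """Fungi-fungi projection: taxa adjacent iff they share >= 1 sample."""
    by_sample: dict[str, list[str]] = {s: [] for s in net.plant_nodes}
    for s, t in net.links:
        by_sample[s].append(t)
    edges: set[frozenset] = set()
    for taxa in by_sample.values():
        taxa = sorted(taxa)
        for i in range(len(taxa)):
            for j in range(i + 1, len(taxa)):
                edges.add(frozenset((taxa[i], taxa[j])))
    return TaxonNetwork(nodes=list(net.fungus_nodes), edges=edges, kind="projection")


def raup_crick_matrix(
    presence: PresenceMatrix | np.ndarray,
    n_null: int = 999,
    seed: int = 0,
    taxon_ids: list[str] | None = None,
) -> RaupCrickMatrix:
    """Raup-Crick co-occurrence similarity for every taxon pair.

    For a pair (A, B) with observed shared-sample count s_obs, each of the
    ``n_null`` replicates redraws, independently for every taxon, a random
    sample set of the taxon's observed occupancy, picking samples without
    replacement with probability proportional to sample richness.  Then

        rc(A, B) = [#(s_null < s_obs) + 0.5 #(s_null = s_obs)] / n_null,

    so rc near 1 means A and B share more samples than the null expects
    (aggregation) and rc near 0 fewer (segregation); ties count half.

    The weighted sampling uses exponential sort keys (draws with the
    smallest Exp(1)/weight come first), which realizes successive
    probability-proportional-to-weight draws without replacement and
    vectorizes over replicates and taxa.
    """
    if isinstance(presence, PresenceMatrix):
        mat = presence.presence
        taxon_ids = list(presence.taxon_ids)
    else:
        mat = np.asarray(presence)
        if taxon_ids is None:
            taxon_ids = [f"t{i}" for i in range(mat.shape[0])]
    n_taxa, n_samples = mat.shape
    if n_samples < 3:
        raise ValueError("Raup-Crick needs at least 3 samples")
    occ = mat.sum(axis=1).astype(int)
    if (occ == 0).any():
        raise ValueError("taxa with zero occupancy must be dropped upstream")
    weights = mat.sum(axis=0).astype(float)  # per-sample richness
    if weights.sum() == 0:
        raise ValueError("empty presence matrix")
    weights = np.where(weights == 0, 1e-12, weights)  # degenerate empty samples

    s_obs = (mat.astype(np.int64) @ mat.T.astype(np.int64)).astype(np.int64)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    less = np.zeros((n_taxa, n_taxa), dtype=np.int64)
    equal = np.zeros((n_taxa, n_taxa), dtype=np.int64)
    occ_col = occ[:, None]
    # process replicates in blocks to bound memory
    block = max(1, min(n_null, int(2e6 / (n_taxa * n_samples)) or 1))
    done = 0
    while done < n_null:
        b = min(block, n_null - done)
        keys = rng.exponential(size=(b, n_taxa, n_samples)) / weights
        ranks = np.argsort(np.argsort(keys, axis=2), axis=2)
        z = (ranks < occ_col).astype(np.int64)
        for r in range(b):
            s_null = z[r] @ z[r].T
            less += s_null < s_obs
            equal += s_null == s_obs
        done += b
    rc = (less + 0.5 * equal) / n_null
    rc = np.clip((rc + rc.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(rc, 0.0)
    return RaupCrickMatrix(taxon_ids=taxon_ids, rc=rc, n_null=n_null, seed=seed)


def partition_cooccurrence(
    rc: RaupCrickMatrix, pos_threshold: float = 0.5, neg_threshold: float = 0.49
) -> tuple[TaxonNetwork, TaxonNetwork]:
    """Split taxon pairs into positive (rc > 0.5) and negative (rc < 0.49)
    co-occurrence networks; pairs in the in-between band join neither."""
    if neg_threshold > pos_threshold:
        raise ValueError("neg_threshold must not exceed pos_threshold")
    n = len(rc.taxon_ids)
    pos_edges: dict[frozenset, float] = {}
    neg_edges: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            value = rc.rc[i, j]
            e = frozenset((rc.taxon_ids[i], rc.taxon_ids[j]))
            if value > pos_threshold:
                pos_edges[e] = float(value)
            elif value < neg_threshold:
                neg_edges[e] = float(value)
    return (
        TaxonNetwork(list(rc.taxon_ids), set(pos_edges), "positive", pos_edges),
        TaxonNetwork(list(rc.taxon_ids), set(neg_edges), "negative", neg_edges),
    )


# ---------------------------------------------------------------------------
# unipartite indices
# ---------------------------------------------------------------------------


def _edge_index_arrays(net: TaxonNetwork) -> tuple[np.ndarray, np.ndarray, int]:
    """Edges as two integer index arrays over the network's node list."""
    pos = {t: i for i, t in enumerate(net.nodes)}
    if net.n_edges == 0:
        return np.empty(0, int), np.empty(0, int), len(net.nodes)
    pairs = np.array([sorted((pos[a], pos[b])) for a, b in map(sorted, net.edges)])
    return pairs[:, 0], pairs[:, 1], len(net.nodes)


def assortativity(net: TaxonNetwork) -> float | None:
    """Newman degree assortativity: Pearson correlation of end degrees over
    edges counted in both orientations; ``None`` when a marginal variance
    is zero (e.g. regular graphs)."""
    if net.n_edges == 0:
        raise ValueError("assortativity undefined for an edgeless network")
    u, v, n = _edge_index_arrays(net)
    deg = np.bincount(np.concatenate([u, v]), minlength=n)
    x = np.concatenate([deg[u], deg[v]]).astype(float)  # both orientations
    y = np.concatenate([deg[v], deg[u]]).astype(float)
    if x.std() == 0 or y.std() == 0:
        return None
    r = np.corrcoef(x, y)[0, 1]
    if not np.isfinite(r):
        return None
    return float(r)


def _rewired_edges(
    u: np.ndarray, v: np.ndarray, n_attempts: int, rng: np.random.Generator
) -> set[tuple[int, int]]:
    """Degree-preserving double-edge swaps: ``n_attempts`` proposals, each
    exchanging the endpoints of two random edges when no self-loop or
    duplicate edge would result."""
    edges = [(int(a), int(b)) for a, b in zip(u, v)]
    edge_set = set(edges)
    m = len(edges)
    if m < 2:
        return edge_set
    picks = rng.integers(0, m, size=(n_attempts, 2))
    flips = rng.random(n_attempts) < 0.5
    for (i, j), flip in zip(picks, flips):
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flip:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        e1 = (a, d) if a < d else (d, a)
        e2 = (c, b) if c < b else (b, c)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i], edges[j] = e1, e2
    return edge_set


def rich_club(
    net: TaxonNetwork, n_rand: int = 100, seed: int = 0, percentile: float = 75.0
) -> float | None:
    """Normalized rich-club coefficient at the 75th-percentile degree.

    phi(k) is the density of the subgraph of nodes with degree above the
    percentile threshold; it is divided by the mean phi over ``n_rand``
    degree-preserving double-edge-swap randomizations (10 x |edges| swap
    attempts each).  For regular graphs, where no node sits strictly above
    the threshold, the club is the whole graph (rewiring preserves it, so
    the normalized value is 1 for e.g. complete graphs).  ``None`` when the
    club has < 2 members or the null density is zero.
    """
    if net.n_edges == 0:
        raise ValueError("rich club undefined for an edgeless network")
    u, v, n = _edge_index_arrays(net)
    deg = np.bincount(np.concatenate([u, v]), minlength=n)
    k = float(np.percentile(deg, percentile))
    members = np.nonzero(deg > k)[0]
    if members.size == 0 and deg.min() == deg.max():
        members = np.arange(n)  # regular graph: the club is everyone
    if members.size < 2:
        return None
    in_club = np.zeros(n, dtype=bool)
    in_club[members] = True
    denom = members.size * (members.size - 1)

    def phi_of(edge_set) -> float:
        e = sum(1 for a, b in edge_set if in_club[a] and in_club[b])
        return 2.0 * e / denom

    phi = phi_of(zip(u, v))
    ss = np.random.SeedSequence(seed)
    m = len(u)
    phis = [
        phi_of(_rewired_edges(u, v, 10 * m, np.random.default_rng(child)))
        for child in ss.spawn(n_rand)
    ]
    if not phis or np.mean(phis) == 0:
        return None
    return float(phi / np.mean(phis))


def _adjacency(u: np.ndarray, v: np.ndarray, n: int) -> np.ndarray:
    adj = np.zeros((n, n), dtype=np.int8)
    adj[u, v] = 1
    adj[v, u] = 1
    return adj


def _lcc_stats(adj: np.ndarray) -> tuple[float, float, int, int] | None:
    """(mean clustering, mean shortest path, n, m) of the largest component.

    Clustering counts triangles through the cubed adjacency matrix; path
    lengths come from unweighted breadth-first shortest paths.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components, shortest_path

    deg_all = adj.sum(axis=1)
    keep = deg_all > 0
    if not keep.any():
        return None
    adj = adj[np.ix_(keep, keep)]
    sparse = csr_matrix(adj)
    n_comp, labels = connected_components(sparse, directed=False)
    sizes = np.bincount(labels)
    comp = labels == sizes.argmax()
    adj = adj[np.ix_(comp, comp)]
    n = adj.shape[0]
    if n < 2:
        return None
    a = adj.astype(np.int64)
    deg = a.sum(axis=1)
    triangles = np.diag(a @ a @ a)  # 2 * triangles through each node
    possible = deg * (deg - 1)
    local = np.where(possible > 0, triangles / np.maximum(possible, 1), 0.0)
    c = float(local.mean())
    dist = shortest_path(csr_matrix(adj), method="D", unweighted=True, directed=False)
    iu = np.triu_indices(n, 1)
    length = float(dist[iu].mean())
    return c, length, n, int(a.sum() // 2)


def small_world(net: TaxonNetwork, n_rand: int = 100, seed: int = 0) -> float | None:
    """Small-world sigma = (C / C_rand) / (L / L_rand) on the largest component.

    C is the mean local clustering coefficient and L the mean shortest-path
    length of the largest connected component; the null values are means
    over ``n_rand`` Erdos-Renyi G(n, m) graphs matched on the component's
    node and edge counts, each reduced to its own largest component the
    same way.  ``None`` when C_rand = 0 or L degenerates.
    """
    if net.n_edges == 0:
        raise ValueError("small-world sigma undefined for an edgeless network")
    u, v, n_nodes = _edge_index_arrays(net)
    stats = _lcc_stats(_adjacency(u, v, n_nodes))
    if stats is None or stats[2] < 4:
        raise ValueError("largest connected component has fewer than 4 nodes")
    c_obs, l_obs, n, m = stats
    ss = np.random.SeedSequence(seed)
    n_pairs = n * (n - 1) // 2
    iu_all = np.triu_indices(n, 1)
    cs, ls = [], []
    for child in ss.spawn(n_rand):
        rng = np.random.default_rng(child)
        chosen = rng.choice(n_pairs, size=m, replace=False)
        adj = np.zeros((n, n), dtype=np.int8)
        adj[iu_all[0][chosen], iu_all[1][chosen]] = 1
        adj |= adj.T
        st = _lcc_stats(adj)
        if st is None:
            continue
        cs.append(st[0])
        ls.append(st[1])
    if not cs:
        return None
    c_rand, l_rand = float(np.mean(cs)), float(np.mean(ls))
    if c_rand == 0 or l_rand == 0 or l_obs == 0:
        return None
    return float((c_obs / c_rand) / (l_obs / l_rand))


# ---------------------------------------------------------------------------
# per-organ reports and the organ-difference permutation test
# ---------------------------------------------------------------------------

BIPARTITE_INDICES = ("connectance", "nestedness_T")
TAXON_INDICES = ("small_world", "rich_club", "assortativity")


def _taxon_network_for(
    sub: np.ndarray,
    taxon_ids: list[str],
    network: str,
    n_null: int,
    seed: int,
    pos_threshold: float,
    neg_threshold: float,
) -> TaxonNetwork:
    keep = sub.sum(axis=1) > 0
    sub = sub[keep]
    ids = [t for t, k in zip(taxon_ids, keep) if k]
    if network == "projection":
        adj = (sub.astype(np.int64) @ sub.T.astype(np.int64)) > 0
        edges = {
            frozenset((ids[i], ids[j]))
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
            if adj[i, j]
        }
        return TaxonNetwork(ids, edges, "projection")
    rc = raup_crick_matrix(sub, n_null=n_null, seed=seed, taxon_ids=ids)
    pos, neg = partition_cooccurrence(rc, pos_threshold, neg_threshold)
    return pos if network == "positive" else neg


def _taxon_index_value(
    tnet: TaxonNetwork, index: str, n_rand: int, seed: int
) -> float | None:
    if tnet.n_edges == 0:
        return None
    try:
        if index == "assortativity":
            return assortativity(tnet)
        if index == "rich_club":
            return rich_club(tnet, n_rand=n_rand, seed=seed)
        if index == "small_world":
            return small_world(tnet, n_rand=n_rand, seed=seed)
    except ValueError:
        return None
    raise ValueError(f"unknown taxon-network index {index!r}")


def _index_value(
    sub: np.ndarray,
    taxon_ids: list[str],
    index: str,
    network: str,
    n_null: int,
    n_rand: int,
    seed: int,
    pos_threshold: float,
    neg_threshold: float,
    sample_ids: list[str] | None = None,
) -> float | None:
    """One scalar index on one organ's presence submatrix; None = undefined."""
    if index in BIPARTITE_INDICES:
        if network != "bipartite":
            raise ValueError(f"index {index!r} is defined on the bipartite network")
        keep = sub.sum(axis=1) > 0
        sub = sub[keep]
        if index == "connectance":
            if sub.size == 0:
                return None
            return float(sub.mean())
        try:
            return nestedness_temperature(sub)
        except ValueError:
            return None
    if network not in ("projection", "positive", "negative"):
        raise ValueError(f"unknown network variant {network!r}")
    tnet = _taxon_network_for(
        sub, taxon_ids, network, n_null, seed, pos_threshold, neg_threshold
    )
    return _taxon_index_value(tnet, index, n_rand, seed)


def organ_index_report(
    presence: PresenceMatrix,
    organ: str,
    n_null: int = 999,
    n_rand: int = 100,
    seed: int = 0,
    pos_threshold: float = 0.5,
    neg_threshold: float = 0.49,
) -> OrganIndexReport:
    """All indices for one organ: connectance and nestedness temperature on
    the bipartite network, sigma / rich-club / assortativity on the
    fungi-fungi projection, and the same three on the positive and negative
    Raup-Crick partitions.  Undefined values are carried as ``None``."""
    net = build_bipartite(presence, organ)
    sub = net.presence_array()
    ids = net.fungus_nodes
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)]
    main = NetworkIndexReport(
        connectance=connectance(net),
        nestedness_T=_index_value(
            sub, ids, "nestedness_T", "bipartite", n_null, n_rand, seeds[0],
            pos_threshold, neg_threshold,
        ),
    )
    proj = project_to_taxa(net)
    main.small_world = _taxon_index_value(proj, "small_world", n_rand, seeds[0])
    main.rich_club = _taxon_index_value(proj, "rich_club", n_rand, seeds[1])
    main.assortativity = _taxon_index_value(proj, "assortativity", n_rand, seeds[1])

    rc = raup_crick_matrix(sub, n_null=n_null, seed=seeds[2], taxon_ids=ids)
    pos, neg = partition_cooccurrence(rc, pos_threshold, neg_threshold)
    variants = {}
    for name, tnet in (("positive", pos), ("negative", neg)):
        variants[name] = NetworkIndexReport(
            small_world=_taxon_index_value(tnet, "small_world", n_rand, seeds[3]),
            rich_club=_taxon_index_value(tnet, "rich_club", n_rand, seeds[3]),
            assortativity=_taxon_index_value(tnet, "assortativity", n_rand, seeds[3]),
        )
    return OrganIndexReport(
        organ=organ,
        main=main,
        positive=variants["positive"],
        negative=variants["negative"],
        params={
            "n_null": n_null,
            "n_rand": n_rand,
            "seed": seed,
            "pos_threshold": pos_threshold,
            "neg_threshold": neg_threshold,
        },
    )


def permutation_compare(
    presence: PresenceMatrix,
    index: str,
    network: str = "bipartite",
    n_perm: int = 999,
    seed: int = 0,
    n_null: int = 199,
    n_rand: int = 10,
    pos_threshold: float = 0.5,
    neg_threshold: float = 0.49,
    organ_order: tuple[str, str] | None = None,
    strict: bool = False,
) -> PermutationTestResult:
    """One-tailed permutation test for an organ difference in a network index.

    The observed delta is index(second organ) - index(first organ) with the
    organs in sorted label order by default, so for bud/twig data the delta
    is twig - bud.  Each of the ``n_perm`` replicates shuffles the organ
    labels over samples (group sizes preserved), rebuilds both organ
    networks from scratch — including any internal null models, re-seeded
    per replicate from a spawned child seed — and records the replicate
    delta.  The tail follows the sign of the observed delta and
    p = (b + 1) / (m + 1) over the m replicates whose delta was defined;
    replicates where either index is undefined are dropped and counted.

    ``n_null`` and ``n_rand`` here control the null models *inside* each
    replicate; they default lower than the reporting defaults because the
    inner nulls multiply with ``n_perm``.
    """
    organs = sorted(presence.metadata["organ"].unique())
    if organ_order is not None:
        organs = list(organ_order)
    if len(organs) != 2:
        raise ValueError(f"need exactly 2 organs, got {organs}")
    labels = presence.metadata["organ"].to_numpy()
    for o in organs:
        if (labels == o).sum() < 2:
            raise ValueError(f"organ {o!r} has fewer than 2 samples")
    mat = presence.presence
    ids = list(presence.taxon_ids)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_perm + 1)

    def delta_for(lab: np.ndarray, child) -> float | None:
        sub_seeds = [int(c.generate_state(1)[0] % 2**31) for c in child.spawn(2)]
        values = []
        for o, s in zip(organs, sub_seeds):
            sub = mat[:, lab == o]
            values.append(
                _index_value(
                    sub, ids, index, network, n_null, n_rand, s,
                    pos_threshold, neg_threshold,
                )
            )
        if values[0] is None or values[1] is None:
            return None
        return values[1] - values[0]

    observed = delta_for(labels, children[0])
    if observed is None:
        raise ValueError(f"index {index!r} undefined on the observed networks")

    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 0xA5)))
    nulls = []
    dropped = 0
    for r in range(n_perm):
        lab = rng.permutation(labels)
        d = delta_for(lab, children[r + 1])
        if d is None:
            dropped += 1
        else:
            nulls.append(d)
    if n_perm and dropped / n_perm > 0.2:
        msg = f"{dropped}/{n_perm} permutation replicates had undefined indices"
        if strict:
            raise RuntimeError(msg)
        warnings.warn(msg)
    nulls_arr = np.asarray(nulls)
    tail = "right" if observed >= 0 else "left"
    if tail == "right":
        b = int((nulls_arr >= observed - 1e-12).sum())
    else:
        b = int((nulls_arr <= observed + 1e-12).sum())
    p = (b + 1) / (len(nulls_arr) + 1)
    return PermutationTestResult(
        index=index,
        network=network,
        delta_observed=float(observed),
        null_deltas=nulls_arr,
        p=float(p),
        tail=tail,
        n_perm=n_perm,
        n_dropped=dropped,
        seed=seed,
    )
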