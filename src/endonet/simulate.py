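"""Synthetic occurrence/count tables with known ground truth.

The generator emulates the sampling design the analysis targets: two sites
(valley, mountain) x two organs (bud, twig) x a handful of trees, on the
order of a hundred fungal taxa, log-normal read abundances, per-sample
sequencing depths spanning a wide log-normal range, a decreasing occupancy
gradient over taxa (which produces nested occurrence matrices), a
per-taxon organ preference, and configurable pairwise competitive-exclusion
and facilitation relationships.  Every dataset ships with the ground truth
needed to score recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .networks import partition_cooccurrence, permutation_compare, raup_crick_matrix
from .otu import OtuTable, to_presence

__all__ = ["CommunityParams", "GroundTruth", "generate_community", "recovery_suite"]


@dataclass
class CommunityParams:
    """Knobs of the community generator.

    Defaults mirror the targeted study system: 2 sites x 2 organs x 4 trees
    = 16 samples, 113 taxa, read depths log-normally spread and clamped to
    7,766-122,310 reads, a strong occupancy gradient, and a mild
    twig-preference on average (twigs richer than buds).
    """

    n_taxa: int = 113
    n_trees_per_site: int = 4
    sites: tuple[str, ...] = ("valley", "mountain")
    organs: tuple[str, ...] = ("bud", "twig")
    occupancy_base: float = 0.9  # occurrence prob of the most common taxon
    occupancy_gradient: float = 3.0  # e-folding of occupancy over the taxon rank
    organ_effect_mu: float = 0.5  # mean twig-preference (logit shift)
    organ_effect_sd: float = 1.0  # spread of per-taxon organ preference
    abundance_logmean: float = 0.0
    abundance_logsd: float = 1.5  # taxon-level log-normal abundance spread
    abundance_noise_sd: float = 0.7  # per-cell log-normal noise
    depth_logmean: float = 10.3  # median depth ~ 30k reads
    depth_logsd: float = 0.7
    depth_bounds: tuple[int, int] = (7766, 122310)
    exclusion_pairs: list = field(default_factory=list)  # (taxon_a, taxon_b, strength)
    facilitation_pairs: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2 or self.n_trees_per_site < 1:
            raise ValueError("need n_taxa >= 2 and n_trees_per_site >= 1")
        lo, hi = self.depth_bounds
        if lo < 1 or hi < lo:
            raise ValueError("depth bounds must be positive and ordered")
        if self.occupancy_gradient < 0:
            raise ValueError("occupancy gradient must be >= 0")
        for name in ("exclusion_pairs", "facilitation_pairs"):
            for a, b, s in getattr(self, name):
                if not 0 <= s <= 1:
                    raise ValueError(f"{name} strength {s} outside [0, 1]")
        declared = {self._pair_key(p) for p in self.exclusion_pairs}
        for p in self.facilitation_pairs:
            if self._pair_key(p) in declared:
                raise ValueError(
                    f"pair {p[:2]} declared as both exclusion and facilitation"
                )

    @staticmethod
    def _pair_key(pair) -> frozenset:
        return frozenset(pair[:2])

    def taxon_ids(self) -> list[str]:
        width = len(str(self.n_taxa))
        return [f"otu{i + 1:0{width}d}" for i in range(self.n_taxa)]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CommunityParams":
        d = dict(d)
        for key in ("sites", "organs", "depth_bounds"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("exclusion_pairs", "facilitation_pairs"):
            if key in d:
                d[key] = [tuple(p) for p in d[key]]
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery scoring."""

    organ_preference: dict[str, float]  # per-taxon twig-preference logit shift
    exclusion_pairs: list[tuple[str, str, float]]
    facilitation_pairs: list[tuple[str, str, float]]
    intended_depths: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "organ_preference": self.organ_preference,
            "exclusion_pairs": [list(p) for p in self.exclusion_pairs],
            "facilitation_pairs": [list(p) for p in self.facilitation_pairs],
            "intended_depths": self.intended_depths,
        }


def _resolve_pairs(pairs, taxa: list[str]) -> list[tuple[str, str, float]]:
    index = {t: t for t in taxa}
    out = []
    for a, b, s in pairs:
        a = taxa[a] if isinstance(a, int) else a
        b = taxa[b] if isinstance(b, int) else b
        if a not in index or b not in index or a == b:
            raise ValueError(f"invalid interaction pair ({a}, {b})")
        out.append((a, b, float(s)))
    return out


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``, with at
    least 1 unit per positive weight (largest-remainder rounding)."""
    positive = weights > 0
    n_pos = int(positive.sum())
    out = np.zeros(len(weights), dtype=np.int64)
    if n_pos == 0 or total < n_pos:
        raise ValueError("depth too small to give every present taxon a read")
    out[positive] = 1
    rest = total - n_pos
    shares = weights[positive] / weights[positive].sum() * rest
    base = np.floor(shares).astype(np.int64)
    remainder = shares - base
    short = rest - int(base.sum())
    order = np.argsort(-remainder, kind="stable")[:short]
    base[order] += 1
    out[positive] += base
    return out


def generate_community(params: CommunityParams) -> tuple[OtuTable, GroundTruth]:
    """Draw one synthetic OTU table plus its ground truth.

    Occurrence: taxon t's base probability decays exponentially along the
    taxon rank (the occupancy gradient); a per-taxon Gaussian logit shift
    moves twig samples up and bud samples down by half the preference.
    Facilitation (A, B, s) then adds B where A occurs with probability s,
    and exclusion (A, B, s) removes B where both occur with probability s
    (applied last, so strength-1 exclusion guarantees zero co-occurrence).
    Reads: per-taxon log-normal abundances with per-cell noise, scaled to a
    log-normal per-sample depth clamped to the configured bounds and
    allocated by largest-remainder rounding (every present taxon gets at
    least one read, so counts > 0 exactly reproduces the occurrence draw).
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    taxa = params.taxon_ids()
    samples, organs, sites, trees = [], [], [], []
    for site in params.sites:
        for k in range(1, params.n_trees_per_site + 1):
            for organ in params.organs:
                samples.append(f"{site}-{organ}-t{k}")
                organs.append(organ)
                sites.append(site)
                trees.append(f"{site[0].upper()}{k}")
    meta = pd.DataFrame(
        {"organ": organs, "site": sites, "tree": trees}, index=pd.Index(samples, name="sample")
    )
    n_taxa, n_samples = params.n_taxa, len(samples)

    rank = np.arange(n_taxa) / max(n_taxa - 1, 1)
    p_base = np.clip(params.occupancy_base * np.exp(-params.occupancy_gradient * rank),
                     5e-3, 0.995)
    pref = rng.normal(params.organ_effect_mu, params.organ_effect_sd, n_taxa)
    shift = np.where(np.array(organs) == params.organs[-1], 0.5, -0.5)  # twig up, bud down
    prob = expit(logit(p_base)[:, None] + pref[:, None] * shift[None, :])
    occurrence = rng.random((n_taxa, n_samples)) < prob

    taxon_row = {t: i for i, t in enumerate(taxa)}
    facilitation = _resolve_pairs(params.facilitation_pairs, taxa)
    exclusion = _resolve_pairs(params.exclusion_pairs, taxa)
    for a, b, s in facilitation:
        ia, ib = taxon_row[a], taxon_row[b]
        add = occurrence[ia] & (rng.random(n_samples) < s)
        occurrence[ib] |= add
    for a, b, s in exclusion:
        ia, ib = taxon_row[a], taxon_row[b]
        both = occurrence[ia] & occurrence[ib]
        occurrence[ib, both & (rng.random(n_samples) < s)] = False

    # guarantee every sample hosts at least one taxon
    empty = ~occurrence.any(axis=0)
    occurrence[0, empty] = True

    abundance = rng.lognormal(params.abundance_logmean, params.abundance_logsd, n_taxa)
    cells = abundance[:, None] * rng.lognormal(
        0.0, params.abundance_noise_sd, (n_taxa, n_samples)
    )
    cells *= occurrence

    lo, hi = params.depth_bounds
    depths = np.clip(
        np.round(rng.lognormal(params.depth_logmean, params.depth_logsd, n_samples)),
        lo, hi,
    ).astype(np.int64)
    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    for j in range(n_samples):
        counts[:, j] = _largest_remainder(cells[:, j], int(depths[j]))

    table = OtuTable(taxon_ids=taxa, sample_ids=samples, counts=counts, metadata=meta)
    truth = GroundTruth(
        organ_preference=dict(zip(taxa, pref.round(6).tolist())),
        exclusion_pairs=exclusion,
        facilitation_pairs=facilitation,
        intended_depths=dict(zip(samples, depths.tolist())),
    )
    return table, truth


def recovery_suite(
    grid: Sequence[CommunityParams],
    n_reps: int = 20,
    seed: int = 0,
    n_null: int = 199,
    n_perm: int = 99,
    organ_index: str = "connectance",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Power / type-I summary of the full inference chain over a parameter grid.

    For every parameter point and replicate the suite regenerates a
    community, scores all taxon pairs with the Raup-Crick null, partitions
    them, and tallies: the fraction of declared exclusion pairs recovered as
    negative-network edges, the fraction of declared facilitation pairs
    recovered as positive edges, the background positive/negative edge rates
    among undeclared pairs, and the rejection rate of the organ-difference
    permutation test on ``organ_index``.
    """
    if not len(grid):
        raise ValueError("empty parameter grid")
    if n_reps < 10:
        warnings.warn("recovery_suite with n_reps < 10 gives noisy rates")
    root = np.random.SeedSequence(seed)
    rows = []
    for point, params in enumerate(grid):
        child_seeds = root.spawn(n_reps)
        excl_hits = excl_total = fac_hits = fac_total = 0
        bg_neg = bg_pos = bg_total = 0
        rejections = 0
        for rep in range(n_reps):
            rep_seed = int(child_seeds[rep].generate_state(1)[0] % 2**31)
            p = CommunityParams.from_dict({**params.to_dict(), "seed": rep_seed})
            table, truth = generate_community(p)
            presence = to_presence(table)
            rc = raup_crick_matrix(presence, n_null=n_null, seed=rep_seed)
            pos, neg = partition_cooccurrence(rc)
            declared = {
                frozenset((a, b)) for a, b, _ in truth.exclusion_pairs
            } | {frozenset((a, b)) for a, b, _ in truth.facilitation_pairs}
            present = set(presence.taxon_ids)
            for a, b, _ in truth.exclusion_pairs:
                if a in present and b in present:
                    excl_total += 1
                    excl_hits += frozenset((a, b)) in neg.edges
            for a, b, _ in truth.facilitation_pairs:
                if a in present and b in present:
                    fac_total += 1
                    fac_hits += frozenset((a, b)) in pos.edges
            ids = presence.taxon_ids
            n = len(ids)
            n_pairs = n * (n - 1) // 2
            n_declared = sum(1 for e in declared if e <= present)
            bg_total += n_pairs - n_declared
            bg_neg += len(neg.edges - declared)
            bg_pos += len(pos.edges - declared)
            test = permutation_compare(
                presence, organ_index, network="bipartite",
                n_perm=n_perm, seed=rep_seed,
            )
            rejections += test.p <= alpha
        rows.append(
            {
                "grid_point": point,
                "n_reps": n_reps,
                "exclusion_recovery": excl_hits / excl_total if excl_total else np.nan,
                "facilitation_recovery": fac_hits / fac_total if fac_total else np.nan,
                "background_negative_rate": bg_neg / bg_total if bg_total else np.nan,
                "background_positive_rate": bg_pos / bg_total if bg_total else np.nan,
                "organ_rejection_rate": rejections / n_reps,
            }
        )
    return pd.DataFrame(rows)
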