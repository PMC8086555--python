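"""Per-sample diversity indices, accumulation curves, and group tests.

Shannon entropy uses the natural logarithm throughout, so the second Hill
number is exactly exp(H).  Fisher's alpha is the log-series parameter
solving S = alpha * ln(1 + N / alpha) for a sample with S taxa and N reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .otu import OtuTable, PresenceMatrix, rarefy

__all__ = [
    "shannon",
    "fisher_alpha",
    "hill_numbers",
    "diversity_table",
    "rarefied_diversity",
    "AccumulationCurve",
    "accumulation_curve",
    "GroupTestResult",
    "index_group_test",
]


def _relative(counts) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1:
        raise ValueError("expected a 1-D count vector")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero count vector")
    return counts / total


def shannon(counts) -> float:
    """Shannon entropy H = -sum p ln p (nats) over taxa with positive counts."""
    p = _relative(counts)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def fisher_alpha(S: int, N: int) -> float:
    """Fisher's log-series alpha for S taxa among N reads.

    Solved by bracketing root search (brentq) on f(a) = a ln(1 + N/a) - S,
    expanding the bracket by doubling until it straddles the root; relative
    tolerance 1e-10.  Undefined for S <= 1 or S >= N.
    """
    if S <= 1 or S >= N:
        raise ValueError(f"fisher_alpha undefined for S={S}, N={N} (need 1 < S < N)")

    def f(a: float) -> float:
        return a * np.log1p(N / a) - S

    lo, hi = 1e-8, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - cannot happen for valid S < N
            raise RuntimeError("bracket expansion failed")
    return float(brentq(f, lo, hi, rtol=1e-10))


def hill_numbers(counts) -> tuple[float, float, float]:
    """The first three Hill numbers: richness, exp(Shannon), inverse Simpson."""
    p = _relative(counts)
    p = p[p > 0]
    n1 = float(len(p))
    n2 = float(np.exp(-(p * np.log(p)).sum()))
    n3 = float(1.0 / (p**2).sum())
    return n1, n2, n3


def diversity_table(table: OtuTable) -> pd.DataFrame:
    """Per-sample richness, Shannon, Fisher's alpha and Hill numbers.

    Fisher's alpha is NaN where its domain condition (1 < S < N) fails.
    """
    rows = []
    for j, sample in enumerate(table.sample_ids):
        col = table.counts[:, j]
        n1, n2, n3 = hill_numbers(col)
        s, n = int((col > 0).sum()), int(col.sum())
        try:
            alpha = fisher_alpha(s, n)
        except ValueError:
            alpha = float("nan")
        rows.append(
            {
                "sample": sample,
                "richness": s,
                "shannon": shannon(col),
                "fisher_alpha": alpha,
                "hill_n1": n1,
                "hill_n2": n2,
                "hill_n3": n3,
            }
        )
    out = pd.DataFrame(rows).set_index("sample")
    return out.join(table.metadata)


def rarefied_diversity(
    table: OtuTable, depth: int | None = None, n_draws: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Mean per-sample diversity over ``n_draws`` seeded rarefactions.

    ``depth`` defaults to the minimum sample depth (the study-style common
    depth).  Draw r uses seed ``seed + r`` so individual draws can be
    reproduced in isolation.
    """
    if depth is None:
        depth = int(table.sample_depths().min())
    acc: pd.DataFrame | None = None
    numeric = ["richness", "shannon", "fisher_alpha", "hill_n1", "hill_n2", "hill_n3"]
    for r in range(n_draws):
        d = diversity_table(rarefy(table, depth, seed=seed + r))[numeric]
        acc = d if acc is None else acc + d
    out = acc / n_draws
    out.insert(0, "depth", depth)
    return out.join(table.metadata)


@dataclass
class AccumulationCurve:
    """Sample-based accumulation curve: E[richness] after t samples."""

    t: np.ndarray
    expected_richness: np.ndarray
    sd: np.ndarray
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "expected_richness": self.expected_richness, "sd": self.sd}
        )


def accumulation_curve(
    presence: PresenceMatrix, n_perm: int = 999, seed: int = 0
) -> AccumulationCurve:
    """Expected pooled richness after t samples, by permuting sample order.

    The mean over ``n_perm`` random orderings estimates the classic
    sample-based rarefaction curve; the endpoint at t = n is the pooled
    richness exactly under every ordering.
    """
    mat = presence.presence
    n = mat.shape[1]
    if n < 2:
        raise ValueError("accumulation curve needs at least 2 samples")
    rng = np.random.default_rng(seed)
    richness = np.zeros((n_perm, n))
    for r in range(n_perm):
        order = rng.permutation(n)
        seen = np.cumsum(mat[:, order], axis=1) > 0
        richness[r] = seen.sum(axis=0)
    return AccumulationCurve(
        t=np.arange(1, n + 1),
        expected_richness=richness.mean(axis=0),
        sd=richness.std(axis=0, ddof=1),
        n_perm=n_perm,
    )


@dataclass
class GroupTestResult:
    index: str
    group_a: str
    group_b: str
    observed_diff: float
    p: float
    n_perm: int
    seed: int


def index_group_test(
    records: pd.DataFrame,
    grouping: str | pd.Series,
    index: str,
    n_perm: int = 999,
    seed: int = 0,
) -> GroupTestResult:
    """Two-sided permutation test for a mean difference in a diversity index.

    ``records`` is a per-sample table (e.g. from :func:`diversity_table`);
    ``grouping`` names a column of it or supplies a label per sample.  The
    p-value is (b + 1) / (n_perm + 1) where b counts label shuffles whose
    absolute mean difference reaches the observed one.
    """
    labels = records[grouping] if isinstance(grouping, str) else grouping.loc[records.index]
    values = records[index].to_numpy(dtype=float)
    groups = sorted(pd.unique(labels))
    if len(groups) != 2:
        raise ValueError(f"index_group_test needs exactly 2 groups, got {groups}")
    mask = (labels == groups[1]).to_numpy()
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    if np.isnan(values).any():
        raise ValueError(f"index {index!r} has missing values")
    obs = values[mask].mean() - values[~mask].mean()
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(mask)
        sim = values[perm].mean() - values[~perm].mean()
        if abs(sim) >= abs(obs) - 1e-12:
            b += 1
    return GroupTestResult(
        index=index,
        group_a=groups[0],
        group_b=groups[1],
        observed_diff=float(obs),
        p=(b + 1) / (n_perm + 1),
        n_perm=n_perm,
        seed=seed,
    )
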