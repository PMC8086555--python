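"""Minimal figure export: accumulation curves and NMDS scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .community import Ordination
from .diversity import AccumulationCurve

__all__ = ["plot_accumulation", "plot_nmds"]


def plot_accumulation(curve: AccumulationCurve, path, label: str = "pooled") -> None:
    """Accumulation curve with a +/- 1 SD band across sample orderings."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.t, curve.expected_richness, marker="o", label=label)
    ax.fill_between(
        curve.t,
        curve.expected_richness - curve.sd,
        curve.expected_richness + curve.sd,
        alpha=0.25,
    )
    ax.set_xlabel("samples")
    ax.set_ylabel("expected richness")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_nmds(ordination: Ordination, metadata, path, hue: str = "organ") -> None:
    """2-D NMDS scatter colored by a metadata column; stress in the title."""
    coords = ordination.to_frame()
    fig, ax = plt.subplots(figsize=(5, 4))
    for value, block in coords.join(metadata).groupby(hue):
        ax.scatter(block.iloc[:, 0], block.iloc[:, 1], label=str(value))
    ax.set_xlabel("NMDS1")
    ax.set_ylabel("NMDS2")
    ax.set_title(f"stress = {ordination.stress:.3f}")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
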