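"""End-to-end pipeline: filter -> presence -> diversity -> community tests
-> organ networks -> co-occurrence partitions -> index reports ->
permutation comparisons -> guild summaries.

A single YAML config drives everything; one top-level seed is split into
per-stage child seeds (recorded in the manifest), and identical config +
seed produces byte-identical JSON/TSV reports (no timestamps are written).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from . import __version__
from .community import anosim, bray_curtis, jaccard_distance, nmds, permanova
from .diversity import accumulation_curve, diversity_table, rarefied_diversity
from .guilds import assign_guilds, guild_abundance, read_guild_table
from .networks import (
    BIPARTITE_INDICES,
    TAXON_INDICES,
    build_bipartite,
    organ_index_report,
    partition_cooccurrence,
    permutation_compare,
    project_to_taxa,
    raup_crick_matrix,
)
from .otu import (
    filter_otus,
    filter_samples_by_depth,
    group_overlap_counts,
    read_otu_table,
    to_presence,
    write_otu_table,
)
from .simulate import CommunityParams, generate_community

logger = logging.getLogger("endonet")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str
    counts: str | None = None
    metadata: str | None = None
    synthetic: dict | None = None  # CommunityParams fields
    min_total_reads: int = 10
    min_samples: int = 2
    min_depth: int | None = None
    max_depth: int | None = None
    rarefaction_depth: int | str = "min"  # "min" = lowest sample depth
    rarefaction_draws: int = 100
    n_null: int = 999
    n_rand: int = 100
    n_perm: int = 999
    inner_n_null: int = 199
    inner_n_rand: int = 10
    pos_threshold: float = 0.5
    neg_threshold: float = 0.49
    nmds_k: int = 2
    nmds_restarts: int = 20
    accumulation_perms: int = 999
    guild_table: str | None = None
    strict: bool = False
    comparisons: list = field(
        default_factory=lambda: [["connectance", "bipartite"], ["nestedness_T", "bipartite"]]
        + [[i, net] for net in ("projection", "positive", "negative") for i in TAXON_INDICES]
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config must set a seed")
        if self.neg_threshold > self.pos_threshold:
            raise ValueError("neg_threshold must not exceed pos_threshold")
        for value, name in (
            (self.n_null, "n_null"), (self.n_rand, "n_rand"), (self.n_perm, "n_perm"),
            (self.inner_n_null, "inner_n_null"), (self.inner_n_rand, "inner_n_rand"),
            (self.min_total_reads, "min_total_reads"), (self.min_samples, "min_samples"),
        ):
            if value < 1:
                raise ValueError(f"{name} must be >= 1")
        if (self.counts is None) == (self.synthetic is None):
            raise ValueError("config must set either counts/metadata or synthetic")
        if self.counts is not None and self.metadata is None:
            raise ValueError("counts input needs a metadata path")
        for index, net in self.comparisons:
            if index in BIPARTITE_INDICES:
                if net != "bipartite":
                    raise ValueError(f"{index} is a bipartite index")
            elif index in TAXON_INDICES:
                if net not in ("projection", "positive", "negative"):
                    raise ValueError(f"bad network {net!r} for {index}")
            else:
                raise ValueError(f"unknown index {index!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def param_hash(self) -> str:
        """Hash of all analysis parameters (the output location is excluded,
        so runs into different directories are recognizably identical)."""
        doc = asdict(self)
        doc.pop("out_dir")
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2)
        fh.write("\n")


def _write_taxon_network(tnet, stem: Path) -> None:
    g = tnet.to_networkx()
    rows = ["taxon_a\ttaxon_b\traup_crick"]
    for a, b, data in sorted(g.edges(data=True)):
        score = data.get("raup_crick", "")
        rows.append(f"{a}\t{b}\t{score}")
    stem.with_suffix(".tsv").write_text("\n".join(rows) + "\n")
    nx.write_graphml(g, stem.with_suffix(".graphml"))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and return the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    stage_names = [
        "synthetic", "rarefaction", "accumulation", "community",
        "networks", "comparisons",
    ]
    stage_seed = {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(stage_names, root.spawn(len(stage_names)))
    }

    # ---- input ----
    if config.synthetic is not None:
        params = CommunityParams.from_dict(
            {**config.synthetic, "seed": config.synthetic.get("seed", stage_seed["synthetic"])}
        )
        table, truth = generate_community(params)
        _json_dump(truth.as_dict(), out / "ground_truth.json")
    else:
        table = read_otu_table(config.counts, config.metadata)

    # ---- filtering ----
    if config.min_depth is not None or config.max_depth is not None:
        table = filter_samples_by_depth(table, config.min_depth, config.max_depth)
    table = filter_otus(table, config.min_total_reads, config.min_samples)
    write_otu_table(table, out / "filtered_counts.tsv", out / "metadata.tsv")
    presence = to_presence(table)

    # ---- diversity ----
    div = diversity_table(table)
    div.to_csv(out / "diversity.tsv", sep="\t")
    depth = (
        int(table.sample_depths().min())
        if config.rarefaction_depth == "min"
        else int(config.rarefaction_depth)
    )
    rarefied_diversity(
        table, depth=depth, n_draws=config.rarefaction_draws,
        seed=stage_seed["rarefaction"],
    ).to_csv(out / "diversity_rarefied.tsv", sep="\t")
    accumulation_curve(
        presence, n_perm=config.accumulation_perms, seed=stage_seed["accumulation"]
    ).to_frame().to_csv(out / "accumulation.tsv", sep="\t", index=False)

    # ---- overlap counts (Venn-style site-organ groups) ----
    grouping = {
        s: f"{presence.metadata.loc[s, 'site']}-{presence.metadata.loc[s, 'organ']}"
        for s in presence.sample_ids
    }
    group_overlap_counts(presence, grouping).to_csv(
        out / "overlap_counts.tsv", sep="\t", index=False
    )

    # ---- community composition ----
    bray = bray_curtis(table, sqrt_transform=True)
    jac = jaccard_distance(presence)
    bray.to_frame().to_csv(out / "bray_curtis.tsv", sep="\t")
    jac.to_frame().to_csv(out / "jaccard.tsv", sep="\t")
    seed_c = stage_seed["community"]
    community = {}
    for factor in ("organ", "site"):
        labels = table.metadata[factor]
        r, p_r = anosim(jac, labels, n_perm=config.n_perm, seed=seed_c)
        f, p_f = permanova(bray, labels, n_perm=config.n_perm, seed=seed_c + 1)
        community[factor] = {
            "anosim_R": r, "anosim_p": p_r,
            "permanova_F": f, "permanova_p": p_f,
            "n_perm": config.n_perm,
        }
    ordination = nmds(
        bray, k=config.nmds_k, n_restarts=config.nmds_restarts, seed=seed_c + 2
    )
    coords = ordination.to_frame()
    with open(out / "nmds_coordinates.tsv", "w") as fh:
        fh.write(f"# stress={ordination.stress!r}\n")
        coords.to_csv(fh, sep="\t")
    community["nmds_stress"] = ordination.stress
    _json_dump(community, out / "community_tests.json")

    # ---- networks ----
    organs = sorted(presence.metadata["organ"].unique())
    reports = {}
    for i, organ in enumerate(organs):
        seed_n = stage_seed["networks"] + i
        report = organ_index_report(
            presence, organ,
            n_null=config.n_null, n_rand=config.n_rand, seed=seed_n,
            pos_threshold=config.pos_threshold, neg_threshold=config.neg_threshold,
        )
        reports[organ] = report.as_dict()
        net = build_bipartite(presence, organ)
        _write_taxon_network(project_to_taxa(net), out / f"{organ}_projection")
        rc = raup_crick_matrix(
            net.presence_array(), n_null=config.n_null, seed=seed_n,
            taxon_ids=net.fungus_nodes,
        )
        pos, neg = partition_cooccurrence(
            rc, config.pos_threshold, config.neg_threshold
        )
        _write_taxon_network(pos, out / f"{organ}_positive")
        _write_taxon_network(neg, out / f"{organ}_negative")
    if len(organs) == 2:
        a, b = organs
        reports["delta"] = {
            variant: {
                key: (
                    reports[b][variant][key] - reports[a][variant][key]
                    if reports[a][variant][key] is not None
                    and reports[b][variant][key] is not None
                    else None
                )
                for key in reports[a][variant]
            }
            for variant in ("main", "positive", "negative")
        }
    _json_dump(reports, out / "network_indices.json")

    # ---- organ-difference permutation comparisons ----
    comparisons = {}
    if len(organs) == 2:
        for i, (index, net_kind) in enumerate(config.comparisons):
            result = permutation_compare(
                presence, index, network=net_kind,
                n_perm=config.n_perm, seed=stage_seed["comparisons"] + i,
                n_null=config.inner_n_null, n_rand=config.inner_n_rand,
                pos_threshold=config.pos_threshold,
                neg_threshold=config.neg_threshold,
                strict=config.strict,
            )
            comparisons[f"{net_kind}:{index}"] = result.as_dict()
    _json_dump(comparisons, out / "comparisons.json")

    # ---- guilds ----
    if config.guild_table is not None:
        labels = assign_guilds(table, read_guild_table(config.guild_table))
        guild_abundance(table, labels, ("organ", "site")).to_csv(
            out / "guild_abundance.tsv", sep="\t"
        )
        guild_abundance(table, labels, "organ").to_csv(
            out / "guild_abundance_by_organ.tsv", sep="\t"
        )

    manifest = {
        "package": "endonet",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": stage_seed,
        "param_hash": config.param_hash(),
        "config": asdict(config),
        "n_taxa": len(table.taxon_ids),
        "n_samples": len(table.sample_ids),
    }
    _json_dump(manifest, out / "manifest.json")
    return out
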