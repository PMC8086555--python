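"""OTU tables: reading, validation, filtering, binarization, rarefaction.

The sample-by-taxon count matrix is the single source of truth for every
downstream stage.  Counts are held taxa x samples (rows = taxa), matching
the usual orientation of exported OTU tables; per-sample metadata records
the plant organ (bud / twig), the site (valley / mountain) and the tree.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("endonet")

__all__ = [
    "OtuTable",
    "PresenceMatrix",
    "OtuValidationError",
    "read_otu_table",
    "read_biom_json",
    "write_otu_table",
    "filter_otus",
    "filter_samples_by_depth",
    "to_presence",
    "rarefy",
    "group_overlap_counts",
]

METADATA_COLUMNS = ("organ", "site", "tree")


class OtuValidationError(ValueError):
    """Raised when a count table or its metadata violate an invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise OtuValidationError(f"duplicate {what} id(s): {dupes}")


@dataclass
class OtuTable:
    """Taxa x samples integer count matrix with per-sample metadata.

    ``metadata`` is a DataFrame indexed by sample id with at least the
    columns ``organ``, ``site`` and ``tree``.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.taxon_ids),
            len(self.sample_ids),
        ):
            raise OtuValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.round(self.counts)
            if not np.allclose(self.counts, rounded, atol=0, rtol=0):
                bad = np.argwhere(self.counts != rounded)[0]
                raise OtuValidationError(
                    f"non-integer count at taxon {self.taxon_ids[bad[0]]}, "
                    f"sample {self.sample_ids[bad[1]]}"
                )
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)[0]
            raise OtuValidationError(
                f"negative count at taxon {self.taxon_ids[bad[0]]}, "
                f"sample {self.sample_ids[bad[1]]}"
            )
        missing = [s for s in self.sample_ids if s not in self.metadata.index]
        if missing:
            raise OtuValidationError(f"metadata missing for sample(s): {missing}")
        extra = [s for s in self.metadata.index if s not in set(self.sample_ids)]
        if extra:
            raise OtuValidationError(f"metadata for unknown sample(s): {extra}")
        if self.metadata.index.has_duplicates:
            raise OtuValidationError("duplicate sample rows in metadata")
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise OtuValidationError(f"metadata lacks required column {col!r}")
        # align metadata row order with the count columns
        self.metadata = self.metadata.loc[self.sample_ids]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_depths(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=0), index=self.sample_ids, name="depth")

    def subset_samples(self, keep: Sequence[str]) -> "OtuTable":
        keep = list(keep)
        idx = [self.sample_ids.index(s) for s in keep]
        return OtuTable(
            taxon_ids=list(self.taxon_ids),
            sample_ids=keep,
            counts=self.counts[:, idx].copy(),
            metadata=self.metadata.loc[keep].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)


@dataclass
class PresenceMatrix:
    """Binary taxa x samples occurrence matrix.

    Taxa absent from every sample are dropped at construction (and logged),
    so no all-zero rows survive.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    presence: np.ndarray
    metadata: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence)
        if self.presence.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise OtuValidationError("presence matrix shape mismatch")
        if not np.isin(self.presence, (0, 1)).all():
            raise OtuValidationError("presence matrix must be 0/1")
        self.presence = self.presence.astype(np.int8)
        occupied = self.presence.sum(axis=1) > 0
        if not occupied.all():
            dropped = [t for t, k in zip(self.taxon_ids, occupied) if not k]
            logger.info("dropping %d taxa absent everywhere: %s", len(dropped), dropped)
            self.taxon_ids = [t for t, k in zip(self.taxon_ids, occupied) if k]
            self.presence = self.presence[occupied]
        self.metadata = self.metadata.loc[self.sample_ids]

    @property
    def shape(self) -> tuple[int, int]:
        return self.presence.shape

    def organ_submatrix(self, organ: str) -> tuple[np.ndarray, list[str]]:
        """Presence columns for one organ; returns (matrix, sample ids)."""
        keep = [s for s in self.sample_ids if self.metadata.loc[s, "organ"] == organ]
        if not keep:
            raise OtuValidationError(f"no samples with organ {organ!r}")
        idx = [self.sample_ids.index(s) for s in keep]
        return self.presence[:, idx], keep


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_metadata(metadata_path) -> pd.DataFrame:
    try:
        meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise OtuValidationError(f"cannot parse metadata TSV {metadata_path}: {exc}")
    cols = {c.lower(): c for c in meta.columns}
    if "sample" not in cols:
        raise OtuValidationError("metadata TSV needs a 'sample' column")
    meta = meta.rename(columns={cols["sample"]: "sample"})
    for col in METADATA_COLUMNS:
        if col not in cols:
            raise OtuValidationError(f"metadata TSV needs a {col!r} column")
        meta = meta.rename(columns={cols[col]: col})
    return meta.set_index("sample")


def read_otu_table(counts_path, metadata_path) -> OtuTable:
    """Read a counts TSV (rows = taxa, header column ``taxon``) plus metadata.

    If the first column of the counts file holds sample ids found in the
    metadata, the table is transposed automatically (exports differ in
    orientation); the flip is logged.
    """
    meta = _read_metadata(metadata_path)
    try:
        frame = pd.read_csv(counts_path, sep="\t", index_col=0)
    except Exception as exc:
        raise OtuValidationError(f"cannot parse counts TSV {counts_path}: {exc}")
    if frame.index.astype(str).isin(meta.index).any():
        logger.info("counts file has samples as rows; transposing")
        frame = frame.T
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    for col in frame.columns:
        bad = pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()
        if bad.any():
            line = frame.index[bad.to_numpy().nonzero()[0][0]]
            raise OtuValidationError(
                f"non-numeric count in column {col!r} at taxon row {line!r}"
            )
    return OtuTable(
        taxon_ids=frame.index.tolist(),
        sample_ids=frame.columns.tolist(),
        counts=frame.to_numpy(),
        metadata=meta,
    )


def read_biom_json(biom_path, metadata_path) -> OtuTable:
    """Read a BIOM v1 (JSON) table together with a metadata TSV."""
    meta = _read_metadata(metadata_path)
    with open(biom_path) as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(taxa), len(samples)))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat[:] = np.asarray(doc["data"])
    return OtuTable(taxon_ids=taxa, sample_ids=samples, counts=mat, metadata=meta)


def write_otu_table(table: OtuTable, counts_path, metadata_path=None) -> None:
    frame = table.to_frame()
    frame.index.name = "taxon"
    frame.to_csv(counts_path, sep="\t")
    if metadata_path is not None:
        out = table.metadata.copy()
        out.index.name = "sample"
        out.to_csv(metadata_path, sep="\t")


# ---------------------------------------------------------------------------
# filters and transforms
# ---------------------------------------------------------------------------


def filter_otus(table: OtuTable, min_total_reads: int = 10, min_samples: int = 2) -> OtuTable:
    """Drop rare and near-unique taxa in a single joint pass.

    A taxon is retained iff its total reads are >= ``min_total_reads`` AND it
    occurs (count > 0) in at least ``min_samples`` samples.  The defaults
    remove singleton-sample taxa and taxa with fewer than ten reads.
    """
    if min_total_reads < 1 or min_samples < 1:
        raise ValueError("min_total_reads and min_samples must be >= 1")
    totals = table.counts.sum(axis=1)
    occupancy = (table.counts > 0).sum(axis=1)
    keep = (totals >= min_total_reads) & (occupancy >= min_samples)
    n_rare = int(((totals < min_total_reads) & (occupancy >= min_samples)).sum())
    n_unique = int(((occupancy < min_samples) & (totals >= min_total_reads)).sum())
    n_both = int(((totals < min_total_reads) & (occupancy < min_samples)).sum())
    logger.info(
        "filter_otus: removed %d rare-only, %d low-occupancy-only, %d both; kept %d/%d",
        n_rare, n_unique, n_both, int(keep.sum()), len(table.taxon_ids),
    )
    return OtuTable(
        taxon_ids=[t for t, k in zip(table.taxon_ids, keep) if k],
        sample_ids=list(table.sample_ids),
        counts=table.counts[keep].copy(),
        metadata=table.metadata.copy(),
    )


def filter_samples_by_depth(
    table: OtuTable, min_depth: int | None = None, max_depth: int | None = None
) -> OtuTable:
    """Drop outlier samples by sequencing depth (explicit, user-set cutoffs)."""
    depths = table.sample_depths()
    keep = pd.Series(True, index=depths.index)
    if min_depth is not None:
        keep &= depths >= min_depth
    if max_depth is not None:
        keep &= depths <= max_depth
    dropped = depths.index[~keep].tolist()
    if dropped:
        logger.info("filter_samples_by_depth: dropped %s", dropped)
    if keep.sum() == 0:
        raise OtuValidationError("depth filter removed every sample")
    return table.subset_samples(depths.index[keep].tolist())


def to_presence(table: OtuTable) -> PresenceMatrix:
    """Binarize a count table (presence = count > 0)."""
    if len(table.taxon_ids) == 0 or len(table.sample_ids) == 0:
        raise OtuValidationError("cannot binarize an empty table")
    return PresenceMatrix(
        taxon_ids=list(table.taxon_ids),
        sample_ids=list(table.sample_ids),
        presence=(table.counts > 0).astype(np.int8),
        metadata=table.metadata.copy(),
    )


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Each column is drawn from the multivariate hypergeometric distribution
    over that sample's reads, so a sample whose total equals ``depth`` is
    returned unchanged.  Fully reproducible given ``seed``.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    depths = table.sample_depths()
    short = depths[depths < depth]
    if len(short):
        raise ValueError(
            f"depth {depth} exceeds total reads of sample(s) {short.index.tolist()}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for j in range(len(table.sample_ids)):
        col = table.counts[:, j]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return OtuTable(
        taxon_ids=list(table.taxon_ids),
        sample_ids=list(table.sample_ids),
        counts=out,
        metadata=table.metadata.copy(),
    )


def group_overlap_counts(
    presence: PresenceMatrix, grouping: Mapping[str, str]
) -> pd.DataFrame:
    """Per-group and exclusive-combination taxon counts (Venn-style).

    Returns a DataFrame with one row per non-empty group combination:
    ``groups`` (a ``+``-joined sorted label string), ``n_taxa`` (taxa present
    in exactly those groups and no others), and one row per single group
    labelled in ``group_total`` style via the companion columns.  The
    combination counts partition the taxon set, so they sum to the total
    richness.
    """
    unassigned = [s for s in presence.sample_ids if s not in grouping]
    if unassigned:
        raise OtuValidationError(f"samples missing a group label: {unassigned}")
    labels = sorted({grouping[s] for s in presence.sample_ids})
    # taxa occurrence set per group
    group_sets: dict[str, set[str]] = {}
    for g in labels:
        cols = [i for i, s in enumerate(presence.sample_ids) if grouping[s] == g]
        occ = presence.presence[:, cols].sum(axis=1) > 0
        group_sets[g] = {t for t, k in zip(presence.taxon_ids, occ) if k}
    rows = []
    for g in labels:
        rows.append({"groups": g, "kind": "group_total", "n_taxa": len(group_sets[g])})
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = set.intersection(*(group_sets[g] for g in combo))
            outside = set.union(
                set(), *(group_sets[g] for g in labels if g not in combo)
            )
            rows.append(
                {
                    "groups": "+".join(combo),
                    "kind": "exclusive",
                    "n_taxa": len(inside - outside),
                }
            )
    return pd.DataFrame(rows)
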