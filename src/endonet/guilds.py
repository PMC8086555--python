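"""Trophic-guild assignment and guild relative-abundance summaries.

Guild codes follow the trophic-mode shorthand: P (pathotroph),
PSa (patho-saprotroph), PSSy (patho-sapro-symbiotroph), Sa (saprotroph),
SSy (sapro-symbiotroph) and U (unassigned).  Assignments come from a local
lookup table (e.g. an exported FUNGuild snapshot as a two-column TSV);
taxa without a match fall back to their genus token, then to U.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .otu import OtuTable, OtuValidationError

__all__ = ["GUILD_CODES", "read_guild_table", "assign_guilds", "guild_abundance"]

GUILD_CODES = ("P", "PSa", "PSSy", "Sa", "SSy", "U")


def read_guild_table(path) -> dict[str, str]:
    """Read a taxon -> guild TSV (columns ``taxon`` and ``guild``)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in frame.columns}
    if "taxon" not in cols or "guild" not in cols:
        raise OtuValidationError("guild TSV needs 'taxon' and 'guild' columns")
    table = dict(zip(frame[cols["taxon"]], frame[cols["guild"]]))
    bad = sorted({g for g in table.values() if g not in GUILD_CODES})
    if bad:
        raise OtuValidationError(f"unknown guild code(s): {bad}")
    return table


def _genus_token(taxon: str) -> str:
    for sep in (" ", "_", "."):
        if sep in taxon:
            return taxon.split(sep)[0]
    return taxon


def assign_guilds(table: OtuTable, guilds: Mapping[str, str]) -> dict[str, str]:
    """Label every taxon with a guild code: exact name match first, then the
    genus token, otherwise U."""
    if not guilds:
        raise ValueError("empty guild table")
    labels = {}
    for taxon in table.taxon_ids:
        code = guilds.get(taxon)
        if code is None:
            code = guilds.get(_genus_token(taxon), "U")
        if code not in GUILD_CODES:
            raise OtuValidationError(f"unknown guild code {code!r} for {taxon!r}")
        labels[taxon] = code
    return labels


def guild_abundance(
    table: OtuTable,
    labels: Mapping[str, str],
    grouping: str | Sequence[str] = ("organ", "site"),
) -> pd.DataFrame:
    """Relative read abundance of each guild per sample group.

    ``grouping`` names metadata columns (organ and/or site); rows are
    groups, columns guild codes, and each row sums to 1.
    """
    missing = [t for t in table.taxon_ids if t not in labels]
    if missing:
        raise ValueError(f"taxa without a guild label: {missing}")
    if isinstance(grouping, str):
        grouping = [grouping]
    guild_of = pd.Series([labels[t] for t in table.taxon_ids], index=table.taxon_ids)
    reads = table.to_frame().T  # samples x taxa
    keys = table.metadata[list(grouping)]
    rows = []
    for group_values, sample_index in keys.groupby(list(grouping)).groups.items():
        if not isinstance(group_values, tuple):
            group_values = (group_values,)
        block = reads.loc[sample_index]
        total = block.to_numpy().sum()
        if total == 0:
            raise ValueError(f"group {group_values} has zero reads")
        per_guild = block.sum(axis=0).groupby(guild_of).sum() / total
        row = dict(zip(grouping, group_values))
        for code in GUILD_CODES:
            row[code] = float(per_guild.get(code, 0.0))
        rows.append(row)
    return pd.DataFrame(rows).set_index(list(grouping))
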