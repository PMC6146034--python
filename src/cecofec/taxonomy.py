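"""Greengenes-style lineage parsing and rank-level aggregation.

Lineage strings are semicolon-separated rank tokens, optionally prefixed
("k__", "p__", ...).  Tokens are mapped positionally onto the seven
canonical ranks; an empty token (or a bare prefix) leaves that rank
unassigned.  Aggregation pools each sample's counts by the taxon label at
a chosen rank — OTUs unassigned at that rank go to "Unknown" — and then
converts to relative abundances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cecofec.core_tables import TAXONOMY_RANKS, OtuTable, TableError

__all__ = ["Lineage", "RankTable", "parse_lineage", "aggregate_to_rank"]

UNKNOWN = "Unknown"


@dataclass(frozen=True)
class Lineage:
    """One OTU's taxonomy, positionally mapped to the 7 canonical ranks."""

    kingdom: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def at_rank(self, rank: str) -> str:
        key = "class_" if rank == "class" else rank
        return getattr(self, key)


@dataclass(frozen=True)
class RankTable:
    """Relative abundances (samples x taxa) at one taxonomic rank.

    Rows sum to 1; taxa labels are kept verbatim (e.g. "rc4-4"), with
    unassigned mass pooled under "Unknown".
    """

    abundances: np.ndarray
    sample_ids: tuple[str, ...]
    taxa: tuple[str, ...]
    rank: str

    def __post_init__(self) -> None:
        a = np.asarray(self.abundances, dtype=float)
        if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
            raise TableError("relative abundances must lie in [0, 1]")
        if not np.allclose(a.sum(axis=1), 1.0, atol=1e-9):
            raise TableError("relative abundances must sum to 1 per sample")
        object.__setattr__(self, "abundances", a)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.abundances, index=list(self.sample_ids), columns=list(self.taxa))


def parse_lineage(s: str) -> Lineage:
    """Parse a Greengenes-style lineage string into a 7-rank record."""
    tokens = [t.strip() for t in s.split(";")] if s.strip() else []
    if len(tokens) > len(TAXONOMY_RANKS):
        raise TableError(f"lineage has {len(tokens)} tokens, more than 7 ranks: {s!r}")
    values = []
    for i, rank in enumerate(TAXONOMY_RANKS):
        token = tokens[i] if i < len(tokens) else ""
        for pre in (rank[0] + "__",):
            if token.startswith(pre):
                token = token[len(pre):]
        values.append(token)
    return Lineage(*values)


def aggregate_to_rank(table: OtuTable, taxonomy: dict[str, str], rank: str) -> RankTable:
    """Pool counts by taxon label at ``rank`` and convert to fractions.

    OTUs with no taxonomy record or unassigned at ``rank`` contribute to
    "Unknown".  Taxon columns are ordered alphabetically with "Unknown"
    last.
    """
    if rank not in TAXONOMY_RANKS:
        raise TableError(f"unknown rank {rank!r}")
    labels = []
    for otu in table.otu_ids:
        lineage = parse_lineage(taxonomy.get(otu, ""))
        name = lineage.at_rank(rank)
        labels.append(name if name else UNKNOWN)
    df = pd.DataFrame(table.counts, index=list(table.sample_ids), columns=labels)
    pooled = df.T.groupby(level=0).sum().T
    taxa = sorted(t for t in pooled.columns if t != UNKNOWN)
    if UNKNOWN in pooled.columns:
        taxa.append(UNKNOWN)
    pooled = pooled[taxa]
    totals = pooled.sum(axis=1).to_numpy()
    if np.any(totals == 0):
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise TableError(f"samples with zero total counts: {bad}")
    rel = pooled.to_numpy(dtype=float) / totals[:, None]
    return RankTable(rel, table.sample_ids, tuple(taxa), rank)
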