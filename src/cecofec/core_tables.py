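"""Data model and I/O for OTU tables, metadata, taxonomy and trees.

The in-memory orientation is samples x OTUs.  On disk the table follows the
QIIME-classic convention (OTUs as rows, samples as columns, first header
cell ``#OTU ID``); a dense BIOM-JSON reader/writer is provided as well.

Also implements the study-design filters: minimum per-sample depth,
rare-OTU removal by fraction of total counts, prevalence filtering, and the
pairing rule that keeps only animals with both a cecal and a fecal sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import ceil
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

ORIGINS = ("cecum", "feces")
REGIMES = ("ad_libitum", "restricted")
SIZE_CLASSES = ("big", "small")

TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

METADATA_COLUMNS = ("sample_id", "animal_id", "origin", "regime", "size_class")


class TableError(ValueError):
    """Raised for malformed tables, metadata or designs."""


@dataclass(frozen=True)
class OtuTable:
    """Non-negative integer OTU counts, oriented samples x OTUs."""

    counts: np.ndarray
    sample_ids: tuple[str, ...]
    otu_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise TableError("counts must be a 2-D matrix (samples x OTUs)")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise TableError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise TableError(
                f"negative count at sample {self.sample_ids[i]!r}, OTU {self.otu_ids[j]!r}"
            )
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "otu_ids", tuple(str(o) for o in self.otu_ids))
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise TableError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        for name, ids in (("sample", self.sample_ids), ("OTU", self.otu_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))
                raise TableError(f"duplicate {name} id {dup!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_depths(self) -> np.ndarray:
        """Total reads per sample."""
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        """Samples x OTUs DataFrame with id indexes."""
        return pd.DataFrame(self.counts, index=list(self.sample_ids), columns=list(self.otu_ids))

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(self.counts[idx, :], tuple(sample_ids), self.otu_ids)

    def select_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        idx = [self.otu_ids.index(o) for o in otu_ids]
        return OtuTable(self.counts[:, idx], self.sample_ids, tuple(otu_ids))


@dataclass(frozen=True)
class SampleMetadata:
    """Design factors attached to one sample."""

    sample_id: str
    animal_id: str
    origin: str
    regime: str
    size_class: str

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise TableError(f"sample {self.sample_id!r}: origin {self.origin!r} not in {ORIGINS}")
        if self.regime not in REGIMES:
            raise TableError(f"sample {self.sample_id!r}: regime {self.regime!r} not in {REGIMES}")
        if self.size_class not in SIZE_CLASSES:
            raise TableError(
                f"sample {self.sample_id!r}: size_class {self.size_class!r} not in {SIZE_CLASSES}"
            )


@dataclass(frozen=True)
class PairedDesign:
    """Animals retained with exactly one cecal and one fecal sample each.

    ``excluded`` records (animal_id, reason) for animals dropped because one
    or both samples are missing from the table.
    """

    pairs: tuple[tuple[str, str, str], ...]  # (animal_id, cecum_sample, feces_sample)
    animal_regime: Mapping[str, str] = field(default_factory=dict)
    excluded: tuple[tuple[str, str], ...] = ()

    @property
    def n_animals(self) -> int:
        return len(self.pairs)

    @property
    def animal_ids(self) -> tuple[str, ...]:
        return tuple(p[0] for p in self.pairs)

    @property
    def cecum_samples(self) -> tuple[str, ...]:
        return tuple(p[1] for p in self.pairs)

    @property
    def feces_samples(self) -> tuple[str, ...]:
        return tuple(p[2] for p in self.pairs)

    def sample_ids(self) -> tuple[str, ...]:
        """All retained sample ids, cecum samples first."""
        return self.cecum_samples + self.feces_samples


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_otu_table(path, format: str = "tsv") -> OtuTable:
    """Read an OTU table from QIIME-classic TSV or dense BIOM-JSON.

    The TSV layout is OTUs as rows and samples as columns with the first
    header cell ``#OTU ID``; the returned table is transposed to the
    in-memory samples x OTUs orientation.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment=None)
        try:
            values = df.to_numpy(dtype=np.float64)
        except ValueError as exc:
            raise TableError(f"non-numeric count in {path}: {exc}") from exc
        if np.any(values != np.floor(values)):
            i, j = np.argwhere(values != np.floor(values))[0]
            raise TableError(
                f"non-integer count at OTU {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise TableError(f"negative count at OTU {df.index[i]!r}, sample {df.columns[j]!r}")
        return OtuTable(values.T.astype(np.int64), tuple(df.columns), tuple(df.index))
    if format == "biom_json":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("matrix_type") != "dense":
            raise TableError("only dense BIOM-JSON is supported")
        otu_ids = tuple(r["id"] for r in doc["rows"])
        sample_ids = tuple(c["id"] for c in doc["columns"])
        data = np.asarray(doc["data"], dtype=np.float64)
        return OtuTable(data.T, sample_ids, otu_ids)
    raise TableError(f"unknown OTU table format {format!r}")


def write_otu_table(table: OtuTable, path, format: str = "tsv") -> None:
    """Write in QIIME-classic TSV (OTUs x samples) or dense BIOM-JSON."""
    if format == "tsv":
        df = pd.DataFrame(
            table.counts.T, index=list(table.otu_ids), columns=list(table.sample_ids)
        )
        df.index.name = "#OTU ID"
        df.to_csv(path, sep="\t")
        return
    if format == "biom_json":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [table.n_otus, table.n_samples],
            "rows": [{"id": o, "metadata": None} for o in table.otu_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.counts.T.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
        return
    raise TableError(f"unknown OTU table format {format!r}")


def read_metadata(path) -> dict[str, SampleMetadata]:
    """Read the sample metadata TSV (complete factors required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise TableError(f"metadata missing columns {missing}")
    if df[list(METADATA_COLUMNS)].isna().any().any():
        raise TableError("metadata contains missing values; complete factors are required")
    records = {}
    for row in df.itertuples(index=False):
        if row.sample_id in records:
            raise TableError(f"duplicate metadata record for sample {row.sample_id!r}")
        records[row.sample_id] = SampleMetadata(
            row.sample_id, row.animal_id, row.origin, row.regime, row.size_class
        )
    return records


def write_metadata(meta: Mapping[str, SampleMetadata], path) -> None:
    rows = [
        {c: getattr(m, c) for c in METADATA_COLUMNS}
        for m in meta.values()
    ]
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> dict[str, str]:
    """Read the OTU -> Greengenes-style lineage TSV (stored verbatim)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["otu_id", "lineage"], dtype=str)
    df["lineage"] = df["lineage"].fillna("")
    return dict(zip(df["otu_id"], df["lineage"]))


def write_taxonomy(taxonomy: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for otu, lineage in taxonomy.items():
            fh.write(f"{otu}\t{lineage}\n")


def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree whose tips are OTU ids."""
    tree = TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        raise TableError("tree has duplicate tip names")
    return tree


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_samples_by_depth(table: OtuTable, min_depth: int) -> OtuTable:
    """Drop samples with fewer than ``min_depth`` total reads (strict)."""
    if min_depth < 0:
        raise TableError("min_depth must be >= 0")
    keep = table.sample_depths() >= min_depth
    return OtuTable(
        table.counts[keep, :],
        tuple(s for s, k in zip(table.sample_ids, keep) if k),
        table.otu_ids,
    )


def filter_rare_otus(table: OtuTable, min_fraction: float) -> OtuTable:
    """Drop OTUs holding less than ``min_fraction`` of all counts (strict)."""
    if not 0.0 <= min_fraction <= 1.0:
        raise TableError("min_fraction must be in [0, 1]")
    grand_total = table.counts.sum()
    if grand_total == 0:
        raise TableError("cannot filter rare OTUs from an empty table")
    keep = table.counts.sum(axis=0) >= min_fraction * grand_total
    return OtuTable(
        table.counts[:, keep],
        table.sample_ids,
        tuple(o for o, k in zip(table.otu_ids, keep) if k),
    )


def filter_by_prevalence(table: OtuTable, min_prevalence: float) -> OtuTable:
    """Keep OTUs detected in at least ceil(min_prevalence * n_samples) samples."""
    if not 0.0 <= min_prevalence <= 1.0:
        raise TableError("min_prevalence must be in [0, 1]")
    needed = ceil(min_prevalence * table.n_samples)
    keep = (table.counts > 0).sum(axis=0) >= needed
    return OtuTable(
        table.counts[:, keep],
        table.sample_ids,
        tuple(o for o, k in zip(table.otu_ids, keep) if k),
    )


def build_paired_design(meta: Mapping[str, SampleMetadata], table: OtuTable) -> PairedDesign:
    """Keep only animals with exactly one retained cecal and one fecal sample.

    Animals missing either sample (e.g. one discarded by the depth filter)
    are excluded and recorded with the side that is missing; two retained
    samples of the same origin for one animal is an error.
    """
    missing_meta = [s for s in table.sample_ids if s not in meta]
    if missing_meta:
        raise TableError(f"samples without metadata: {missing_meta}")
    by_animal: dict[str, dict[str, str]] = {}
    for sample_id in table.sample_ids:
        m = meta[sample_id]
        slot = by_animal.setdefault(m.animal_id, {})
        if m.origin in slot:
            raise TableError(
                f"animal {m.animal_id!r} has two retained {m.origin} samples: "
                f"{slot[m.origin]!r} and {sample_id!r}"
            )
        slot[m.origin] = sample_id
    pairs = []
    excluded = []
    regimes: dict[str, str] = {}
    for animal_id, slot in by_animal.items():
        if "cecum" in slot and "feces" in slot:
            pairs.append((animal_id, slot["cecum"], slot["feces"]))
            regimes[animal_id] = meta[slot["cecum"]].regime
        else:
            have = next(iter(slot)) if slot else "none"
            excluded.append((animal_id, f"missing {'feces' if have == 'cecum' else 'cecum'} sample"))
    return PairedDesign(tuple(pairs), regimes, tuple(excluded))


def drop_unpaired_samples(table: OtuTable, design: PairedDesign) -> OtuTable:
    """Restrict the table to samples that belong to a complete pair."""
    keep = [s for s in table.sample_ids if s in set(design.sample_ids())]
    return table.select_samples(keep)
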