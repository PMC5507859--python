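"""OTU count-table containers, I/O, replicate pooling and QC filters.

The central object is :class:`CountTable`, an OTU x sample matrix of raw read
counts backed by a :class:`pandas.DataFrame`.  Samples carry study metadata in
:class:`SampleRecord` objects (microbial niche, days post-hatching, sample
type, technical-replicate group).  Fry samples are binned into four
developmental stages relative to the parental mucus-feeding window:
before (0-3 DPH), during (4-20 DPH), early after (50-80 DPH) and late after
(80-100 DPH) mucus feeding.

Supported on-disk dialects: wide TSV (``otu_id`` + one column per sample),
mothur ``.shared`` (samples as rows), and BIOM-JSON v1.0 (dense or sparse).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NICHES",
    "SAMPLE_TYPES",
    "FRY_NICHES",
    "Stage",
    "SampleRecord",
    "CountTable",
    "TaxonomyMap",
    "assign_stage",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "records_to_frame",
    "pool_replicates",
    "pooled_records",
    "filter_otus",
    "filter_samples",
    "to_relative_abundance",
]

NICHES = (
    "water",
    "breeding_mucus",
    "nonbreeding_mucus",
    "adult_feces",
    "adult_diet",
    "whole_fry",
    "fry_feces",
)

SAMPLE_TYPES = ("whole_organism", "feces", "mucus", "water", "diet")

#: niches whose samples come from developing fry and therefore must carry a DPH
FRY_NICHES = ("whole_fry", "fry_feces")


class Stage(str, Enum):
    """Developmental stage bins relative to the mucus-feeding window."""

    PRE = "pre_mucus_0_3"
    MUCUS = "mucus_4_20"
    POST_EARLY = "post_early_50_80"
    POST_LATE = "post_late_80_100"


STAGE_ORDER = (Stage.PRE, Stage.MUCUS, Stage.POST_EARLY, Stage.POST_LATE)


def assign_stage(dph: int) -> Stage:
    """Map days post-hatching onto a developmental stage bin.

    Bins: 0-3 -> PRE, 4-20 -> MUCUS, 50-79 -> POST_EARLY, 80-100 -> POST_LATE.
    Day 80 belongs to the late bin (the latest early-bin sampling was 75 DPH,
    the earliest late-bin sampling 82 DPH).  Days inside the unsampled gap
    (21-49) or beyond 100 raise ``ValueError``.
    """
    dph = int(dph)
    if dph < 0:
        raise ValueError(f"dph must be non-negative, got {dph}")
    if 0 <= dph <= 3:
        return Stage.PRE
    if 4 <= dph <= 20:
        return Stage.MUCUS
    if 50 <= dph < 80:
        return Stage.POST_EARLY
    if 80 <= dph <= 100:
        return Stage.POST_LATE
    raise ValueError(f"dph={dph} falls in an unsampled interval (21-49 or >100)")


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample study metadata.

    ``dph`` may be ``None`` only for non-fry samples (e.g. adults at T0).
    Technical replicates of one biological sample share ``replicate_group``.
    """

    sample_id: str
    niche: str
    dph: int | None
    sample_type: str
    replicate_group: str

    def __post_init__(self) -> None:
        if self.niche not in NICHES:
            raise ValueError(f"unknown niche {self.niche!r}; expected one of {NICHES}")
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(
                f"unknown sample_type {self.sample_type!r}; expected one of {SAMPLE_TYPES}"
            )
        if self.dph is None and self.niche in FRY_NICHES:
            raise ValueError(f"fry sample {self.sample_id!r} must carry a dph")
        if self.dph is not None and self.dph < 0:
            raise ValueError("dph must be >= 0")

    @property
    def stage(self) -> Stage | None:
        if self.niche not in FRY_NICHES or self.dph is None:
            return None
        return assign_stage(self.dph)


class CountTable:
    """An OTU x sample matrix of non-negative integer read counts.

    Wraps a :class:`pandas.DataFrame` whose index holds OTU identifiers and
    whose columns hold sample identifiers.  Identifiers must be unique and
    counts non-negative integers; row/column order is preserved through all
    operations and round-trips losslessly through every supported format.
    """

    def __init__(self, counts: pd.DataFrame, *, validate: bool = True) -> None:
        data = counts.copy()
        if validate:
            if data.index.has_duplicates:
                raise ValueError("duplicate OTU identifiers")
            if data.columns.has_duplicates:
                raise ValueError("duplicate sample identifiers")
            values = data.to_numpy()
            if values.size and not np.issubdtype(values.dtype, np.integer):
                if not np.allclose(values, np.round(values), atol=1e-9):
                    raise ValueError("counts must be integers")
                data = data.round().astype(np.int64)
            if values.size and (data.to_numpy() < 0).any():
                raise ValueError("counts must be non-negative")
        self.data = data.astype(np.int64) if data.size else data
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.data.index.name = "otu_id"

    # -- basic protocol ----------------------------------------------------
    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def depths(self) -> pd.Series:
        """Per-sample sequencing depth (column sums)."""
        return self.data.sum(axis=0)

    def total_reads(self) -> int:
        return int(self.data.to_numpy().sum())

    def copy(self) -> "CountTable":
        return CountTable(self.data.copy(), validate=False)

    def subset(self, otus: Sequence[str] | None = None,
               samples: Sequence[str] | None = None) -> "CountTable":
        data = self.data
        if otus is not None:
            data = data.loc[list(otus)]
        if samples is not None:
            data = data[list(samples)]
        return CountTable(data, validate=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.otu_ids == other.otu_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.data.to_numpy(), other.data.to_numpy())
        )

    def __repr__(self) -> str:
        return f"CountTable({self.shape[0]} OTUs x {self.shape[1]} samples)"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_tsv_wide(path: Path) -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            bad = df.index[coerced.isna()][0]
            raise ValueError(f"non-numeric count for OTU {bad!r} in column {col!r}")
        df[col] = coerced
    return CountTable(df)


def _read_mothur_shared(path: Path) -> CountTable:
    """Parse a mothur ``.shared`` file (label, Group, numOtus, per-OTU counts).

    Samples are rows in this dialect; the label and numOtus columns are
    consumed and discarded.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[1].lower() != "group":
            raise ValueError(f"not a mothur shared file: header {header[:3]}")
        otu_ids = header[3:]
        rows: dict[str, list[int]] = {}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"line {lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            sample = parts[1]
            try:
                counts = [int(x) for x in parts[3:]]
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer count ({exc})") from None
            rows[sample] = counts
    df = pd.DataFrame(rows, index=otu_ids)
    return CountTable(df)


def _read_biom_json(path: Path) -> CountTable:
    """Read a BIOM-JSON v1.0 table (dense or sparse matrix_type)."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        n_rows, n_cols = doc["shape"]
        otu_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        matrix_type = doc["matrix_type"]
        data = doc["data"]
    except KeyError as exc:
        raise ValueError(f"malformed BIOM-JSON: missing key {exc}") from None
    mat = np.zeros((n_rows, n_cols))
    if matrix_type == "dense":
        mat[:] = np.asarray(data)
    elif matrix_type == "sparse":
        for r, c, v in data:
            mat[int(r), int(c)] = v
    else:
        raise ValueError(f"unsupported BIOM matrix_type {matrix_type!r}")
    return CountTable(pd.DataFrame(mat, index=otu_ids, columns=sample_ids))


def read_count_table(path: str | Path, format: str = "tsv_wide") -> CountTable:
    """Read an OTU count table in the declared dialect.

    Parameters
    ----------
    path : file path
    format : one of ``tsv_wide``, ``mothur_shared``, ``biom_json``
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    readers = {
        "tsv_wide": _read_tsv_wide,
        "mothur_shared": _read_mothur_shared,
        "biom_json": _read_biom_json,
    }
    if format not in readers:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(readers)}")
    return readers[format](path)


def write_count_table(table: CountTable, path: str | Path,
                      format: str = "tsv_wide", label: str = "0.03") -> None:
    """Write a count table; ``label`` is the OTU-definition label for mothur."""
    path = Path(path)
    if format == "tsv_wide":
        table.data.to_csv(path, sep="\t")
    elif format == "mothur_shared":
        with open(path, "w") as fh:
            fh.write("label\tGroup\tnumOtus\t" + "\t".join(table.otu_ids) + "\n")
            n = len(table.otu_ids)
            for sample in table.sample_ids:
                counts = "\t".join(str(int(v)) for v in table.data[sample])
                fh.write(f"{label}\t{sample}\t{n}\t{counts}\n")
    elif format == "biom_json":
        values = table.data.to_numpy()
        rows, cols = np.nonzero(values)
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "fryflora",
            "date": "",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": list(table.shape),
            "rows": [{"id": o, "metadata": None} for o in table.otu_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": [[int(r), int(c), int(values[r, c])] for r, c in zip(rows, cols)],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read sample metadata TSV (sample_id, niche, dph, sample_type, replicate_group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "niche", "dph", "sample_type", "replicate_group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata file missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        dph_raw = row["dph"]
        dph = None if pd.isna(dph_raw) or str(dph_raw).strip() == "" else int(float(dph_raw))
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                niche=str(row["niche"]),
                dph=dph,
                sample_type=str(row["sample_type"]),
                replicate_group=str(row["replicate_group"]),
            )
        )
    return records


def records_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "niche": [r.niche for r in records],
            "dph": [r.dph for r in records],
            "sample_type": [r.sample_type for r in records],
            "replicate_group": [r.replicate_group for r in records],
        }
    )


def write_metadata(records: Sequence[SampleRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Replicate pooling and QC filters
# ---------------------------------------------------------------------------

def pool_replicates(table: CountTable, meta: Sequence[SampleRecord]) -> CountTable:
    """Sum technical replicates into one column per replicate group.

    Each output column is the element-wise sum of the member columns and is
    named after the replicate group.  Replicate groups spanning different
    niches are rejected.  Output column order follows first appearance of each
    group in the input table.
    """
    by_id = {r.sample_id: r for r in meta}
    missing = [s for s in table.sample_ids if s not in by_id]
    if missing:
        raise ValueError(f"samples without metadata record: {missing[:5]}")
    group_order: list[str] = []
    members: dict[str, list[str]] = {}
    for s in table.sample_ids:
        g = by_id[s].replicate_group
        if g not in members:
            members[g] = []
            group_order.append(g)
        members[g].append(s)
    for g, ss in members.items():
        niches = {by_id[s].niche for s in ss}
        if len(niches) > 1:
            raise ValueError(f"replicate group {g!r} spans niches {sorted(niches)}")
    pooled = pd.DataFrame(
        {g: table.data[members[g]].sum(axis=1) for g in group_order},
        index=table.data.index,
    )
    return CountTable(pooled, validate=False)


def pooled_records(meta: Sequence[SampleRecord]) -> list[SampleRecord]:
    """One metadata record per replicate group (sample_id = replicate group)."""
    seen: dict[str, SampleRecord] = {}
    out = []
    for r in meta:
        if r.replicate_group not in seen:
            rec = replace(r, sample_id=r.replicate_group)
            seen[r.replicate_group] = rec
            out.append(rec)
    return out


def filter_otus(table: CountTable, min_total_reads: int = 50, min_samples: int = 2,
                min_presence_count: int = 1) -> CountTable:
    """Drop low-information OTUs.

    An OTU is retained iff its total read count across samples is at least
    ``min_total_reads`` AND it is present (count >= ``min_presence_count``) in
    at least ``min_samples`` samples.  The defaults implement the standard
    accuracy filter: discard OTUs with fewer than 50 reads or occurring in a
    single sample.  OTU order is preserved; removing every OTU warns rather
    than raises.
    """
    values = table.data.to_numpy()
    totals = values.sum(axis=1)
    prevalence = (values >= min_presence_count).sum(axis=1)
    keep = (totals >= min_total_reads) & (prevalence >= min_samples)
    if not keep.any():
        warnings.warn("all OTUs removed by filter_otus", stacklevel=2)
    return CountTable(table.data.loc[keep], validate=False)


def filter_samples(table: CountTable, min_depth: int = 500) -> CountTable:
    """Drop samples whose sequencing depth (column sum) is below ``min_depth``."""
    keep = table.depths() >= min_depth
    if not keep.any():
        warnings.warn("all samples removed by filter_samples", stacklevel=2)
    return CountTable(table.data.loc[:, keep], validate=False)


def to_relative_abundance(table: CountTable | pd.DataFrame) -> pd.DataFrame:
    """Column-normalize counts to per-sample proportions (each column sums to 1)."""
    data = table.data if isinstance(table, CountTable) else table
    depths = data.sum(axis=0)
    zero = depths[depths == 0]
    if len(zero):
        raise ValueError(f"zero-depth samples cannot be normalized: {list(zero.index)[:5]}")
    return data.astype(float) / depths


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIXES = dict(zip("kpcofgs", RANKS))


class TaxonomyMap:
    """OTU -> ranked lineage, with explicit missing ranks.

    Lineages are stored as a tuple of 7 strings (kingdom..species); missing
    ranks are empty strings, never dropped.  Display labels report the lowest
    assigned rank, Greengenes-prefixed (``f__Rhodobacteraceae``) when the rank
    is above genus.
    """

    def __init__(self, lineages: Mapping[str, Sequence[str]]) -> None:
        self._lineages: dict[str, tuple[str, ...]] = {}
        for otu, lineage in lineages.items():
            lin = [str(x).strip() for x in lineage]
            if len(lin) > len(RANKS):
                raise ValueError(f"lineage for {otu!r} has more than {len(RANKS)} ranks")
            lin += [""] * (len(RANKS) - len(lin))
            self._lineages[str(otu)] = tuple(lin)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyMap":
        """Parse a 2-column TSV: otu_id <tab> semicolon lineage.

        Accepts Greengenes-style prefixes (``k__Bacteria;p__...``) or plain
        semicolon-separated names.
        """
        lineages: dict[str, list[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                otu, _, lineage = line.partition("\t")
                parts = [p.strip() for p in lineage.split(";")]
                ranks = [""] * len(RANKS)
                for i, part in enumerate(parts):
                    if len(part) >= 3 and part[1:3] == "__" and part[0] in _RANK_PREFIXES:
                        rank = _RANK_PREFIXES[part[0]]
                        ranks[RANKS.index(rank)] = part[3:]
                    elif i < len(RANKS):
                        ranks[i] = part
                lineages[otu] = ranks
        return cls(lineages)

    def lineage(self, otu_id: str) -> tuple[str, ...]:
        return self._lineages[otu_id]

    def label(self, otu_id: str) -> str:
        """Lowest non-empty rank, rank-prefixed when above genus."""
        lineage = self._lineages.get(otu_id)
        if lineage is None:
            return otu_id
        for rank, name in reversed(list(zip(RANKS, lineage))):
            if name:
                if rank in ("genus", "species"):
                    return name
                return f"{rank[0]}__{name}"
        return otu_id

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self._lineages

    def __len__(self) -> int:
        return len(self._lineages)
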