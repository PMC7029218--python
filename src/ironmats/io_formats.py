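"""Readers and writers for every on-disk artifact the pipeline touches.

Coordinate conventions
----------------------
GFF3 is 1-based inclusive on disk; BED is 0-based half-open on disk.  In
memory everything is 0-based half-open, so ``end - start`` is always the
feature length.  The conversion happens in this module only — nothing
downstream ever sees a 1-based coordinate.

Tables (read counts, bin quality, kinetics, geochemistry) are plain
tab-separated files with a header row.  Floats are written with the
shortest representation that round-trips exactly, so counts and measured
concentrations survive a write/read cycle losslessly.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

VALID_STRANDS = ("+", "-", ".")

#: GFF3 attribute that carries the functional label (e.g. "cyc2_cluster1").
#: Labels are inputs here; free-text annotation parsing is out of scope.
DEFAULT_LABEL_ATTRIBUTE = "product_label"


class FormatError(ValueError):
    """An input file violates its declared dialect."""


class SchemaError(FormatError):
    """A table is missing a required column or contains an invalid cell."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene's coordinates on a contig plus its functional label and bin.

    ``start``/``end`` are 0-based half-open; ``length == end - start``.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "."
    bin_id: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"gene {self.gene_id!r}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignmentInterval:
    """One mapped-read placement on a contig (0-based half-open)."""

    contig_id: str
    start: int
    end: int
    read_id: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"read {self.read_id!r}: invalid interval [{self.start}, {self.end})"
            )


@dataclass
class GenomeBin:
    """A metagenome-assembled genome with quality metrics and gene inventory.

    ``gene_labels`` is a multiset: copy number is preserved, though most
    consumers only care about presence/absence.
    """

    bin_id: str
    zotu: str | None = None
    completeness: float = float("nan")
    redundancy: float = float("nan")
    gene_labels: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if not math.isnan(self.completeness) and not 0.0 <= self.completeness <= 100.0:
            raise ValueError(
                f"bin {self.bin_id!r}: completeness {self.completeness} outside [0, 100]"
            )
        if not math.isnan(self.redundancy) and self.redundancy < 0.0:
            raise ValueError(f"bin {self.bin_id!r}: negative redundancy {self.redundancy}")
        if not isinstance(self.gene_labels, Counter):
            self.gene_labels = Counter(self.gene_labels)

    def has_label(self, label: str) -> bool:
        return self.gene_labels.get(label, 0) > 0


class SampleTable:
    """Entity-by-sample numeric table (gene counts, concentrations, tracers).

    Wraps a wide :class:`pandas.DataFrame` whose index is the entity id and
    whose columns are sample ids.  ``kind='count'`` enforces non-negative
    integers; other kinds only require finite values.
    """

    def __init__(self, values: pd.DataFrame, kind: str = "count"):
        values = values.copy()
        values.index = values.index.astype(str)
        values.columns = values.columns.astype(str)
        if values.index.has_duplicates:
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate entity ids: {dupes}")
        if values.columns.has_duplicates:
            dupes = values.columns[values.columns.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample ids: {dupes}")
        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise SchemaError("non-numeric cell in table")
        if not np.all(np.isfinite(arr)):
            raise SchemaError("non-finite value in table")
        if kind == "count":
            if np.any(arr < 0):
                raise SchemaError("negative value in count table")
            if not np.allclose(arr, np.rint(arr)):
                raise SchemaError("non-integer value in count table")
            values = values.astype(np.int64)
        self.values = values
        self.kind = kind

    @property
    def entity_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def equals(self, other: "SampleTable") -> bool:
        return self.kind == other.kind and self.values.equals(other.values)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        r, c = self.values.shape
        return f"SampleTable(kind={self.kind!r}, {r} entities x {c} samples)"


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _parse_gff_attributes(text: str, path, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise FormatError(f"{path}: line {lineno}: malformed attribute {chunk!r}")
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(path, label_attribute: str = DEFAULT_LABEL_ATTRIBUTE) -> list[GeneModel]:
    """Read gene models from GFF3, converting to 0-based half-open coordinates.

    The functional label is taken from ``label_attribute`` when present; bin
    membership from a ``bin_id`` attribute when present.  Malformed lines
    raise :class:`FormatError` naming the offending line number.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(parts)}"
                )
            seqid, _src, _type, start_s, end_s, _score, strand, _phase, attr_s = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates {start_s!r}..{end_s!r}"
                ) from None
            if start < 1:
                raise FormatError(f"{path}: line {lineno}: start {start} < 1")
            if end < start:
                raise FormatError(f"{path}: line {lineno}: end {end} < start {start}")
            attrs = _parse_gff_attributes(attr_s, path, lineno)
            gene_id = attrs.get("ID", f"gene_{lineno}")
            if gene_id in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    contig_id=seqid,
                    start=start - 1,  # 1-based inclusive -> 0-based half-open
                    end=end,
                    strand=strand if strand in VALID_STRANDS else ".",
                    bin_id=attrs.get("bin_id"),
                    label=attrs.get(label_attribute) or None,
                )
            )
    return genes


def write_gff3(
    genes: Iterable[GeneModel],
    path,
    label_attribute: str = DEFAULT_LABEL_ATTRIBUTE,
    source: str = "ironmats",
    feature_type: str = "gene",
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = [f"ID={g.gene_id}"]
            if g.bin_id is not None:
                attrs.append(f"bin_id={g.bin_id}")
            if g.label is not None:
                attrs.append(f"{label_attribute}={g.label}")
            fh.write(
                "\t".join(
                    [
                        g.contig_id,
                        source,
                        feature_type,
                        str(g.start + 1),  # back to 1-based inclusive
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path) -> list[AlignmentInterval]:
    """Read BED3+ alignment intervals (0-based half-open, preserved exactly).

    Column 4 is used as the read id when present; otherwise a deterministic
    ``read_<line>`` id is synthesized.
    """
    intervals: list[AlignmentInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields"
                )
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if start < 0:
                raise FormatError(f"{path}: line {lineno}: negative chromStart {start}")
            if start >= end:
                raise FormatError(
                    f"{path}: line {lineno}: chromStart {start} >= chromEnd {end}"
                )
            read_id = parts[3] if len(parts) >= 4 and parts[3] else f"read_{lineno}"
            intervals.append(AlignmentInterval(chrom, start, end, read_id))
    return intervals


def write_bed(intervals: Iterable[AlignmentInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig_id}\t{iv.start}\t{iv.end}\t{iv.read_id}\n")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_table(path, kind: str = "count", index_col: str = "entity_id") -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if index_col not in df.columns:
        raise SchemaError(f"{path}: missing required column {index_col!r}")
    df = df.set_index(index_col)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise SchemaError(f"{path}: non-numeric cell in column {col!r}")
    return SampleTable(df, kind=kind)


def write_table(table: SampleTable, path, index_col: str = "entity_id") -> None:
    table.values.rename_axis(index_col).to_csv(path, sep="\t")


def read_tsv(path, required_columns: Sequence[str] = ()) -> pd.DataFrame:
    """Read a generic TSV, raising :class:`SchemaError` naming any missing column."""
    df = pd.read_csv(path, sep="\t")
    for col in required_columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_contig_lengths(path) -> dict[str, int]:
    df = read_tsv(path, required_columns=("contig_id", "length"))
    lengths = {}
    for row in df.itertuples(index=False):
        length = int(row.length)
        if length <= 0:
            raise SchemaError(f"{path}: contig {row.contig_id!r} has length {length}")
        lengths[str(row.contig_id)] = length
    return lengths


def write_contig_lengths(lengths: Mapping[str, int], path) -> None:
    write_tsv(
        pd.DataFrame(
            {"contig_id": list(lengths), "length": [lengths[c] for c in lengths]}
        ),
        path,
    )


def read_bins(path, labels_path=None) -> list[GenomeBin]:
    """Read bin quality/taxonomy, optionally joined with a gene-label inventory.

    ``labels_path`` is a TSV with columns ``bin_id``, ``label`` and optional
    ``copies`` (default 1).
    """
    df = read_tsv(path, required_columns=("bin_id", "completeness", "redundancy"))
    if df["completeness"].isna().any() or df["redundancy"].isna().any():
        bad = df.loc[
            df["completeness"].isna() | df["redundancy"].isna(), "bin_id"
        ].tolist()
        raise SchemaError(f"{path}: missing quality metric for bins {bad}")
    labels: dict[str, Counter] = {}
    if labels_path is not None:
        ldf = read_tsv(labels_path, required_columns=("bin_id", "label"))
        copies = ldf["copies"] if "copies" in ldf.columns else pd.Series(1, index=ldf.index)
        for (b, lab), n in zip(zip(ldf["bin_id"], ldf["label"]), copies):
            labels.setdefault(str(b), Counter())[str(lab)] += int(n)
    bins = []
    for row in df.itertuples(index=False):
        zotu = getattr(row, "zotu", None)
        if zotu is not None and (pd.isna(zotu) or zotu == ""):
            zotu = None
        bins.append(
            GenomeBin(
                bin_id=str(row.bin_id),
                zotu=None if zotu is None else str(zotu),
                completeness=float(row.completeness),
                redundancy=float(row.redundancy),
                gene_labels=labels.get(str(row.bin_id), Counter()),
            )
        )
    return bins


def write_bins(bins: Iterable[GenomeBin], path) -> None:
    rows = [
        {
            "bin_id": b.bin_id,
            "zotu": "" if b.zotu is None else b.zotu,
            "completeness": b.completeness,
            "redundancy": b.redundancy,
        }
        for b in bins
    ]
    write_tsv(pd.DataFrame(rows), path)


def write_gene_labels(bins: Iterable[GenomeBin], path) -> None:
    rows = []
    for b in bins:
        for label, copies in sorted(b.gene_labels.items()):
            rows.append({"bin_id": b.bin_id, "label": label, "copies": copies})
    write_tsv(pd.DataFrame(rows, columns=["bin_id", "label", "copies"]), path)


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------


def read_config(path) -> dict:
    """Read a plain-text ``key: value`` configuration file (YAML mapping)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: config must be a key: value mapping")
    return data


def write_config(config: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)
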