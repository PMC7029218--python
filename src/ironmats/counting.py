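"""Per-gene read counting and the coverage/quality filters applied before it.

The counting rule is the plain region-count convention: a read interval is
counted once for every gene it overlaps by at least one base, so a read
spanning a gene boundary increments both genes.  Strand is ignored
throughout (library strandedness is treated as unknown).

Contigs enter downstream analysis only if at least ``min_depth`` reads cover
at least 90% of their length; genome bins only if they are more than 70%
complete and less than 10% redundant (strict inequalities).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import AlignmentInterval, GeneModel, GenomeBin, SampleTable

logger = logging.getLogger(__name__)

DEFAULT_MIN_BREADTH = 0.9
DEFAULT_MIN_DEPTH = 1
DEFAULT_MIN_COMPLETENESS = 70.0
DEFAULT_MAX_REDUNDANCY = 10.0


@dataclass(frozen=True)
class ContigCoverage:
    """Coverage summary for one contig at a given depth threshold."""

    contig_id: str
    length: int
    breadth_covered: float  # fraction of positions with depth >= threshold
    mean_depth: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.breadth_covered <= 1.0:
            raise ValueError(
                f"contig {self.contig_id!r}: breadth {self.breadth_covered} outside [0, 1]"
            )
        if self.mean_depth < 0:
            raise ValueError(f"contig {self.contig_id!r}: negative mean depth")


def contig_coverage(
    alignments: Iterable[AlignmentInterval],
    contig_lengths: Mapping[str, int],
    depth_threshold: int = DEFAULT_MIN_DEPTH,
) -> list[ContigCoverage]:
    """Exact per-contig breadth and mean depth from aligned-read intervals.

    Depth is accumulated with a difference array and cumulative sum, so the
    breadth equals a position-by-position count exactly.  An alignment on a
    contig absent from ``contig_lengths`` is an error naming the contig.
    """
    diffs: dict[str, np.ndarray] = {}
    for iv in alignments:
        if iv.contig_id not in contig_lengths:
            raise ValueError(f"alignment on undeclared contig {iv.contig_id!r}")
        length = contig_lengths[iv.contig_id]
        if iv.end > length:
            raise ValueError(
                f"alignment {iv.read_id!r} extends past contig {iv.contig_id!r} "
                f"({iv.end} > {length})"
            )
        diff = diffs.get(iv.contig_id)
        if diff is None:
            diff = diffs.setdefault(iv.contig_id, np.zeros(length + 1, dtype=np.int64))
        diff[iv.start] += 1
        diff[iv.end] -= 1
    out = []
    for contig_id, length in contig_lengths.items():
        diff = diffs.get(contig_id)
        if diff is None:
            out.append(ContigCoverage(contig_id, length, 0.0, 0.0))
            continue
        depth = np.cumsum(diff[:-1])
        out.append(
            ContigCoverage(
                contig_id=contig_id,
                length=length,
                breadth_covered=float(np.mean(depth >= depth_threshold)),
                mean_depth=float(np.mean(depth)),
            )
        )
    return out


def filter_contigs(
    coverages: Iterable[ContigCoverage],
    min_breadth: float = DEFAULT_MIN_BREADTH,
) -> set[str]:
    """Contigs whose covered breadth is at least ``min_breadth`` (inclusive)."""
    return {c.contig_id for c in coverages if c.breadth_covered >= min_breadth}


def filter_bins(
    bins: Iterable[GenomeBin],
    min_completeness: float = DEFAULT_MIN_COMPLETENESS,
    max_redundancy: float = DEFAULT_MAX_REDUNDANCY,
) -> list[GenomeBin]:
    """High-quality bins: completeness strictly above and redundancy strictly
    below the thresholds (the printed '>70% complete, <10% redundant' rule)."""
    kept = []
    for b in bins:
        if np.isnan(b.completeness) or np.isnan(b.redundancy):
            raise ValueError(f"bin {b.bin_id!r}: missing quality metric")
        if b.completeness > min_completeness and b.redundancy < max_redundancy:
            kept.append(b)
    return kept


def count_reads_per_gene(
    alignments: Iterable[AlignmentInterval],
    genes: Sequence[GeneModel],
    kept_contigs: set[str] | None = None,
    sample_id: str = "sample",
) -> SampleTable:
    """Count read intervals overlapping each gene by >=1 bp (one sample).

    Genes on contigs outside ``kept_contigs`` are dropped (the coverage
    filter); alignments on dropped contigs are ignored.  A read overlapping
    two genes increments both; genes with no overlapping read get 0.
    """
    if kept_contigs is not None:
        genes = [g for g in genes if g.contig_id in kept_contigs]
    trees: dict[str, IntervalTree] = {}
    counts = {g.gene_id: 0 for g in genes}
    if len(counts) != len(genes):
        raise ValueError("duplicate gene ids in gene set")
    for g in genes:
        trees.setdefault(g.contig_id, IntervalTree()).addi(g.start, g.end, g.gene_id)
    for iv in alignments:
        tree = trees.get(iv.contig_id)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            counts[hit.data] += 1
    df = pd.DataFrame(
        {sample_id: [counts[g.gene_id] for g in genes]},
        index=pd.Index([g.gene_id for g in genes], name="entity_id"),
    )
    return SampleTable(df, kind="count")


def count_samples(
    alignments_by_sample: Mapping[str, Iterable[AlignmentInterval]],
    genes: Sequence[GeneModel],
    kept_contigs: set[str] | None = None,
) -> SampleTable:
    """Assemble a gene x sample count matrix from per-sample alignments."""
    columns = {}
    for sample_id, alignments in alignments_by_sample.items():
        table = count_reads_per_gene(alignments, genes, kept_contigs, sample_id)
        columns[sample_id] = table.values[sample_id]
    df = pd.DataFrame(columns)
    df.index.name = "entity_id"
    return SampleTable(df, kind="count")
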