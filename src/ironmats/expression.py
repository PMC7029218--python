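"""Expression normalization: TPM, constitutive (housekeeping) normalization,
within-bin percentile ranks, series max-normalization and fold changes.

Three normalizations are supported, mirroring common metatranscriptome
practice:

1. **TPM** — transcripts per million.  ``rate_g = count_g / length_g(kb)``
   and ``TPM_g = 1e6 * rate_g / sum(rates)`` per sample, with the
   denominator taken over *all* genes in the community mapping (not per
   bin), so per-bin values remain comparable across bins.
2. **Constitutive-normalized** — TPM divided by the mean TPM of six
   constitutively expressed housekeeping genes (adk, gyrA, recA, rpoB,
   rpoC, secA) detected in the same genome bin and sample.  This corrects
   for changes in a bin's relative abundance; a value of 1 means baseline
   expression.  When fewer than ``min_genes`` of the six are detected the
   baseline is undefined and every value in that (bin, sample) is NA.
3. **Max-normalized** — each value in an ordered series divided by the
   series maximum, for visual comparison of time courses.

Percentile ranks are computed within (bin, sample) with mid-rank tie
handling; "high expression" means strictly above the 90th percentile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import SampleTable

logger = logging.getLogger(__name__)

#: The six constitutively expressed genes used as the expression baseline.
CONSTITUTIVE_LABELS = frozenset({"adk", "gyrA", "recA", "rpoB", "rpoC", "secA"})

DEFAULT_MIN_CONSTITUTIVE_GENES = 3
DEFAULT_HIGH_PERCENTILE = 90.0


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values of one normalization kind."""

    values: pd.DataFrame
    kind: str  # "TPM" | "constitutive_normalized" | "max_normalized"
    gene_lengths: pd.Series | None = None
    all_zero_samples: tuple[str, ...] = ()


@dataclass(frozen=True)
class ConstitutiveBaseline:
    """Mean TPM of the detected housekeeping genes for one (bin, sample)."""

    bin_id: str
    sample_id: str
    baseline: float  # NaN when undefined
    n_used: int


def tpm(counts: SampleTable, gene_lengths: Mapping[str, int] | pd.Series) -> ExpressionMatrix:
    """Transcripts-per-million from raw counts and gene lengths (bp).

    A sample with no counts at all yields an all-zero column, recorded in
    ``all_zero_samples``.  A gene with a nonzero count but no length is an
    error.
    """
    lengths = pd.Series(gene_lengths, dtype=float)
    idx = counts.values.index
    missing = idx.difference(lengths.index)
    if len(missing):
        has_count = counts.values.loc[missing].to_numpy().sum(axis=1) > 0
        if has_count.any():
            bad = list(missing[has_count])
            raise ValueError(f"genes with counts but no length: {bad}")
        lengths = lengths.reindex(idx).fillna(1.0)
    lengths = lengths.reindex(idx)
    if (lengths < 1).any():
        bad = list(idx[lengths < 1])
        raise ValueError(f"gene lengths < 1 bp: {bad}")
    rates = counts.values.div(lengths / 1000.0, axis=0)
    totals = rates.sum(axis=0)
    zero = totals == 0
    safe_totals = totals.mask(zero, 1.0)
    values = rates.div(safe_totals, axis=1) * 1e6
    values.loc[:, zero] = 0.0
    all_zero = tuple(values.columns[zero])
    if all_zero:
        logger.warning("samples with no counts (all-zero TPM): %s", list(all_zero))
    return ExpressionMatrix(values, "TPM", gene_lengths=lengths, all_zero_samples=all_zero)


def constitutive_normalize(
    expr: ExpressionMatrix,
    gene_bins: Mapping[str, str],
    gene_labels: Mapping[str, str],
    constitutive_labels: frozenset[str] = CONSTITUTIVE_LABELS,
    min_genes: int = DEFAULT_MIN_CONSTITUTIVE_GENES,
    min_baseline_tpm: float = 0.0,
) -> tuple[ExpressionMatrix, list[ConstitutiveBaseline]]:
    """Divide each gene's TPM by its bin's housekeeping baseline.

    The baseline for a (bin, sample) is the arithmetic mean TPM of that
    bin's constitutive genes *detected* in the sample (TPM > 0).  If fewer
    than ``min_genes`` are detected, or the baseline does not exceed
    ``min_baseline_tpm``, every value in that (bin, sample) is NA — NA is a
    value here, not an error.  Genes without a bin assignment are NA.
    """
    if expr.kind != "TPM":
        raise ValueError(f"constitutive normalization requires TPM input, got {expr.kind}")
    values = expr.values
    out = pd.DataFrame(np.nan, index=values.index, columns=values.columns)
    baselines: list[ConstitutiveBaseline] = []
    bin_of = pd.Series({g: gene_bins.get(g) for g in values.index})
    for bin_id in sorted({b for b in bin_of if b is not None}):
        members = bin_of.index[bin_of == bin_id]
        const = [g for g in members if gene_labels.get(g) in constitutive_labels]
        for sample_id in values.columns:
            tpm_const = values.loc[const, sample_id] if const else pd.Series(dtype=float)
            detected = tpm_const[tpm_const > 0]
            n_used = int(len(detected))
            if n_used >= min_genes:
                baseline = float(detected.mean())
            else:
                baseline = float("nan")
            if np.isnan(baseline) or baseline <= min_baseline_tpm:
                baselines.append(ConstitutiveBaseline(bin_id, sample_id, float("nan"), n_used))
                continue
            baselines.append(ConstitutiveBaseline(bin_id, sample_id, baseline, n_used))
            out.loc[members, sample_id] = values.loc[members, sample_id] / baseline
    return ExpressionMatrix(out, "constitutive_normalized", expr.gene_lengths), baselines


def percentile_rank(
    expr: ExpressionMatrix,
    gene_bins: Mapping[str, str],
    high_threshold: float = DEFAULT_HIGH_PERCENTILE,
    scope: str = "bin",
) -> pd.DataFrame:
    """Mid-rank percentile of each gene within its (bin, sample) group.

    A gene with ``l`` strictly lower and ``t`` tied values (excluding
    itself) among ``n`` genes gets ``100 * (l + 0.5 t) / (n - 1)``, so a
    unique maximum scores 100 and a full tie scores 50.  ``scope='sample'``
    ranks against every gene in the sample instead of within the bin.
    Single-gene groups have an undefined percentile (NA, flagged by the NaN
    itself); high expression means percentile strictly above the threshold.
    """
    if scope not in ("bin", "sample"):
        raise ValueError(f"unknown percentile scope {scope!r}")
    values = expr.values
    rows = []
    for sample_id in values.columns:
        col = values[sample_id]
        if scope == "sample":
            groups = {"__all__": list(col.index)}
        else:
            groups = {}
            for g in col.index:
                b = gene_bins.get(g)
                if b is not None:
                    groups.setdefault(b, []).append(g)
        for group_key, members in sorted(groups.items()):
            sub = col[members]
            sub = sub[sub.notna()]
            n = len(sub)
            if n == 0:
                continue
            if n == 1:
                pct = np.array([np.nan])
            else:
                # average ranks are 1..n; rank-1 == n_lower + 0.5 * n_ties
                pct = 100.0 * (rankdata(sub.to_numpy(), method="average") - 1.0) / (n - 1)
            for g, p in zip(sub.index, pct):
                rows.append(
                    {
                        "gene_id": g,
                        "bin_id": gene_bins.get(g),
                        "sample_id": sample_id,
                        "percentile": p,
                        "high_expression": bool(p > high_threshold) if np.isfinite(p) else False,
                    }
                )
    return pd.DataFrame(
        rows, columns=["gene_id", "bin_id", "sample_id", "percentile", "high_expression"]
    )


def max_normalize_series(values: Sequence[float]) -> np.ndarray:
    """Divide an ordered series by its maximum (output max is exactly 1)."""
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size == 0 or finite.max() <= 0:
        raise ValueError("max-normalization requires at least one positive finite value")
    return arr / finite.max()


@dataclass
class FoldChange:
    """Per-timepoint fold changes against a reference point in the series."""

    folds: np.ndarray
    max_fold: float
    reference_index: int
    defined: bool


def fold_change_series(values: Sequence[float], reference_index: int = 0) -> FoldChange:
    """Fold change of each point relative to the (pre-amendment) reference.

    The maximum is taken over points *after* the reference.  A zero or NA
    reference leaves the result undefined (flagged, all-NaN folds).
    """
    arr = np.asarray(values, dtype=float)
    ref = arr[reference_index]
    if not np.isfinite(ref) or ref <= 0:
        return FoldChange(np.full_like(arr, np.nan), float("nan"), reference_index, False)
    folds = arr / ref
    post = folds[reference_index + 1 :]
    post = post[np.isfinite(post)]
    max_fold = float(post.max()) if post.size else float("nan")
    return FoldChange(folds, max_fold, reference_index, True)


def geneset_mean_expression(
    expr: ExpressionMatrix,
    label_sets: Mapping[str, Iterable[str]],
    gene_labels: Mapping[str, str],
) -> dict[str, float]:
    """Mean expression over genes carrying any label in each set.

    The mean pools all (gene, sample) values after NA removal; an empty set
    yields NaN.
    """
    out = {}
    for name, labels in label_sets.items():
        labels = set(labels)
        members = [g for g in expr.values.index if gene_labels.get(g) in labels]
        vals = expr.values.loc[members].to_numpy().ravel() if members else np.array([])
        vals = vals[np.isfinite(vals)]
        out[name] = float(vals.mean()) if vals.size else float("nan")
    return out


def geneset_ratio_per_bin(
    expr: ExpressionMatrix,
    labels_a: Iterable[str],
    labels_b: Iterable[str],
    gene_labels: Mapping[str, str],
    gene_bins: Mapping[str, str],
) -> pd.Series:
    """Per-bin ratio of mean expression between two label sets.

    Only bins where both sets have at least one non-NA value appear.
    """
    labels_a, labels_b = set(labels_a), set(labels_b)
    per_bin: dict[str, float] = {}
    bins = sorted({b for b in (gene_bins.get(g) for g in expr.values.index) if b})
    for bin_id in bins:
        members = [g for g in expr.values.index if gene_bins.get(g) == bin_id]
        a = [g for g in members if gene_labels.get(g) in labels_a]
        b = [g for g in members if gene_labels.get(g) in labels_b]
        va = expr.values.loc[a].to_numpy().ravel() if a else np.array([])
        vb = expr.values.loc[b].to_numpy().ravel() if b else np.array([])
        va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
        if va.size and vb.size and vb.mean() > 0:
            per_bin[bin_id] = float(va.mean() / vb.mean())
    return pd.Series(per_bin, dtype=float)
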