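"""Stage orchestration: simulate -> count -> express -> compare -> kinetics /
mixing -> report, driven by a plain ``key: value`` config file.

Each stage reads only files written by upstream stages (or the simulator),
so any stage can be re-run in isolation; a missing upstream file raises
:class:`PipelineError` naming the stage and the file.  Runs are
deterministic: the same config produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import comparative, counting, expression, kinetics_geochem, synthetic_data
from .io_formats import (
    SampleTable,
    SchemaError,
    read_bed,
    read_bins,
    read_config,
    read_contig_lengths,
    read_gff3,
    read_table,
    read_tsv,
    write_bed,
    write_bins,
    write_contig_lengths,
    write_gene_labels,
    write_gff3,
    write_table,
    write_tsv,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "count", "express", "compare", "kinetics", "mixing", "report")

CYC2_LABELS = ("cyc2_cluster1", "cyc2_cluster3")


class PipelineError(RuntimeError):
    """A stage cannot run; carries the stage name for actionable messages."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


class ConfigError(SchemaError):
    """The run configuration does not validate."""


@dataclass
class PipelineOptions:
    """Analysis thresholds, at their published defaults."""

    min_depth: int = 1
    min_breadth: float = 0.9
    min_completeness: float = 70.0
    max_redundancy: float = 10.0
    percentile_high: float = 90.0
    min_constitutive_genes: int = 3
    percentile_scope: str = "bin"
    read_length: int = 150
    insitu_samples: tuple[str, ...] = ("S1", "S2")


_SIM_KEYS = {
    "seed",
    "n_zotus",
    "genomes_per_zotu",
    "n_background_genes",
    "gene_length_range",
    "gene_gap",
    "baseline_mu",
    "dispersion",
    "background_log_sigma",
    "timepoints",
    "occupancy_probs",
    "fold_map",
}
_OPT_KEYS = {f.name for f in dataclasses.fields(PipelineOptions)}


@dataclass
class RunConfig:
    sim: synthetic_data.SimulationConfig
    opts: PipelineOptions
    outdir: Path

    @property
    def seed(self) -> int:
        return self.sim.seed


def default_config_path() -> Path:
    """The packaged default run configuration."""
    return Path(resources.files("ironmats") / "data" / "default_config.yaml")


def load_run_config(path, outdir_override=None, seed_override=None) -> RunConfig:
    data = read_config(path)
    unknown = set(data) - _SIM_KEYS - _OPT_KEYS - {"outdir"}
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    sim_kwargs = {}
    for key in _SIM_KEYS & set(data):
        value = data[key]
        if key in ("gene_length_range", "timepoints") and isinstance(value, list):
            value = tuple(value)
        sim_kwargs[key] = value
    if seed_override is not None:
        sim_kwargs["seed"] = int(seed_override)
    sim = synthetic_data.SimulationConfig(**sim_kwargs)
    opt_kwargs = {k: data[k] for k in _OPT_KEYS & set(data)}
    if "insitu_samples" in opt_kwargs:
        opt_kwargs["insitu_samples"] = tuple(opt_kwargs["insitu_samples"])
    opts = PipelineOptions(**opt_kwargs)
    outdir = Path(outdir_override or data.get("outdir", "ironmats_run"))
    return RunConfig(sim=sim, opts=opts, outdir=outdir)


@dataclass
class StageRecord:
    name: str
    outputs: list[str] = field(default_factory=list)
    rows: dict[str, int] = field(default_factory=dict)


@dataclass
class RunManifest:
    config_digest: str
    seed: int
    stages: list[StageRecord] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "config_digest": self.config_digest,
            "seed": self.seed,
            "stages": [dataclasses.asdict(s) for s in self.stages],
            "warnings": self.warnings,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _digest(cfg: RunConfig) -> str:
    payload = synthetic_data.config_digest(cfg.sim) + json.dumps(
        dataclasses.asdict(cfg.opts), sort_keys=True, default=str
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _require(stage: str, path: Path) -> Path:
    if not path.exists():
        raise PipelineError(stage, f"missing upstream input {path}")
    return path


def _emit(record: StageRecord, path: Path, df: pd.DataFrame | None = None) -> None:
    record.outputs.append(str(path))
    if df is not None:
        record.rows[path.name] = int(len(df))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig) -> StageRecord:
    rec = StageRecord("simulate")
    indir = cfg.outdir / "inputs"
    (indir / "alignments").mkdir(parents=True, exist_ok=True)
    sim = synthetic_data.simulate_catalog(cfg.sim)

    write_gff3(sim.genes, indir / "genes.gff3")
    rec.outputs.append(str(indir / "genes.gff3"))
    rec.rows["genes.gff3"] = len(sim.genes)
    write_contig_lengths(sim.contig_lengths, indir / "contigs.tsv")
    rec.outputs.append(str(indir / "contigs.tsv"))
    write_bins(sim.catalog.bins, indir / "bins.tsv")
    rec.outputs.append(str(indir / "bins.tsv"))
    write_gene_labels(sim.catalog.bins, indir / "gene_labels.tsv")
    rec.outputs.append(str(indir / "gene_labels.tsv"))

    insitu = synthetic_data.simulate_expression_counts(sim, cfg.opts.insitu_samples)
    series = synthetic_data.simulate_timeseries(sim)
    times = synthetic_data.timeseries_sample_ids(cfg.sim)
    samples = pd.DataFrame(
        [{"sample_id": s, "time_min": np.nan, "role": "insitu"} for s in insitu.sample_ids]
        + [{"sample_id": s, "time_min": t, "role": "timeseries"} for s, t in times.items()]
    )
    write_tsv(samples, indir / "samples.tsv")
    _emit(rec, indir / "samples.tsv", samples)

    for stream, (table, sample_id) in enumerate(
        [(insitu, s) for s in insitu.sample_ids] + [(series, s) for s in series.sample_ids]
    ):
        intervals = synthetic_data.simulate_alignments(
            sim, table, sample_id, cfg.opts.read_length, stream=stream
        )
        bed = indir / "alignments" / f"{sample_id}.bed"
        write_bed(intervals, bed)
        rec.outputs.append(str(bed))
        rec.rows[bed.name] = len(intervals)

    decay = synthetic_data.simulate_fe_decay(cfg.sim)
    write_tsv(decay, indir / "kinetics.tsv")
    _emit(rec, indir / "kinetics.tsv", decay)
    geochem = synthetic_data.simulate_mixing(cfg.sim)
    write_tsv(geochem, indir / "geochem.tsv")
    _emit(rec, indir / "geochem.tsv", geochem)
    return rec


def stage_count(cfg: RunConfig) -> StageRecord:
    rec = StageRecord("count")
    indir = cfg.outdir / "inputs"
    outdir = cfg.outdir / "counts"
    outdir.mkdir(parents=True, exist_ok=True)
    genes = read_gff3(_require("count", indir / "genes.gff3"))
    contig_lengths = read_contig_lengths(_require("count", indir / "contigs.tsv"))
    samples = read_tsv(
        _require("count", indir / "samples.tsv"), required_columns=("sample_id",)
    )
    alignments = {}
    for sample_id in samples["sample_id"]:
        bed = _require("count", indir / "alignments" / f"{sample_id}.bed")
        alignments[sample_id] = read_bed(bed)

    pooled = [iv for ivs in alignments.values() for iv in ivs]
    coverages = counting.contig_coverage(pooled, contig_lengths, cfg.opts.min_depth)
    kept = counting.filter_contigs(coverages, cfg.opts.min_breadth)
    pct = 100.0 * len(kept) / max(len(contig_lengths), 1)
    logger.info("contig coverage filter: %d/%d contigs retained (%.1f%%)",
                len(kept), len(contig_lengths), pct)
    cov_df = pd.DataFrame(
        [
            {
                "contig_id": c.contig_id,
                "length": c.length,
                "breadth_covered": c.breadth_covered,
                "mean_depth": c.mean_depth,
                "kept": c.contig_id in kept,
            }
            for c in coverages
        ]
    )
    write_tsv(cov_df, outdir / "coverage.tsv")
    _emit(rec, outdir / "coverage.tsv", cov_df)

    counts = counting.count_samples(alignments, genes, kept)
    write_table(counts, outdir / "counts.tsv")
    _emit(rec, outdir / "counts.tsv", counts.values)
    return rec


def _gene_maps(cfg: RunConfig):
    indir = cfg.outdir / "inputs"
    genes = read_gff3(_require("express", indir / "genes.gff3"))
    gene_bins = {g.gene_id: g.bin_id for g in genes if g.bin_id is not None}
    gene_labels = {g.gene_id: g.label for g in genes if g.label is not None}
    return genes, gene_bins, gene_labels


def stage_express(cfg: RunConfig) -> StageRecord:
    rec = StageRecord("express")
    outdir = cfg.outdir / "expression"
    outdir.mkdir(parents=True, exist_ok=True)
    counts = read_table(_require("express", cfg.outdir / "counts" / "counts.tsv"))
    genes, gene_bins, gene_labels = _gene_maps(cfg)
    lengths = pd.Series({g.gene_id: float(g.length) for g in genes})

    tpm = expression.tpm(counts, lengths)
    tpm_table = tpm.values.rename_axis("entity_id")
    tpm_table.to_csv(outdir / "tpm.tsv", sep="\t")
    _emit(rec, outdir / "tpm.tsv", tpm_table)

    const, baselines = expression.constitutive_normalize(
        tpm, gene_bins, gene_labels, min_genes=cfg.opts.min_constitutive_genes
    )
    const.values.rename_axis("entity_id").to_csv(
        outdir / "const_norm.tsv", sep="\t"
    )
    _emit(rec, outdir / "const_norm.tsv", const.values)
    base_df = pd.DataFrame(
        [dataclasses.asdict(b) for b in baselines],
        columns=["bin_id", "sample_id", "baseline", "n_used"],
    )
    write_tsv(base_df, outdir / "baselines.tsv")
    _emit(rec, outdir / "baselines.tsv", base_df)

    samples = read_tsv(cfg.outdir / "inputs" / "samples.tsv")
    insitu = [s for s, r in zip(samples["sample_id"], samples["role"]) if r == "insitu"]
    pct = expression.percentile_rank(
        expression.ExpressionMatrix(tpm.values[insitu], "TPM"),
        gene_bins,
        high_threshold=cfg.opts.percentile_high,
        scope=cfg.opts.percentile_scope,
    )
    write_tsv(pct, outdir / "percentiles.tsv")
    _emit(rec, outdir / "percentiles.tsv", pct)

    ts_samples = {
        s: t
        for s, t, r in zip(samples["sample_id"], samples["time_min"], samples["role"])
        if r == "timeseries"
    }
    folds = amendment_fold_table(tpm, gene_labels, ts_samples)
    write_tsv(folds, outdir / "timeseries_folds.tsv")
    _emit(rec, outdir / "timeseries_folds.tsv", folds)
    return rec


def amendment_fold_table(
    tpm: expression.ExpressionMatrix,
    gene_labels: Mapping[str, str],
    sample_times: Mapping[str, float],
    labels: Iterable[str] | None = None,
    constitutive_labels: frozenset = expression.CONSTITUTIVE_LABELS,
) -> pd.DataFrame:
    """Fold-change series of each labeled gene set over the amendment series.

    The per-timepoint value is the mean TPM of the label's genes divided by
    the mean TPM of all constitutive genes in the community (a pooled
    constitutive normalization, robust to sparse per-bin baselines); when no
    constitutive gene is detected the raw mean TPM is used and the ``basis``
    column records the choice.  Fold changes are relative to the first
    (pre-amendment) timepoint.
    """
    order = sorted(sample_times, key=lambda s: sample_times[s])
    if labels is None:
        labels = sorted({l for l in gene_labels.values() if l not in constitutive_labels})
    const_genes = [g for g in tpm.values.index if gene_labels.get(g) in constitutive_labels]
    rows = []
    for label in labels:
        members = [g for g in tpm.values.index if gene_labels.get(g) == label]
        if not members:
            continue
        values = []
        basis = "community_constitutive" if const_genes else "TPM"
        for s in order:
            num = float(tpm.values.loc[members, s].mean())
            if const_genes:
                den = float(tpm.values.loc[const_genes, s].mean())
                values.append(num / den if den > 0 else float("nan"))
            else:
                values.append(num)
        fc = expression.fold_change_series(values, reference_index=0)
        for s, v, f in zip(order, values, fc.folds):
            rows.append(
                {
                    "label": label,
                    "sample_id": s,
                    "time_min": sample_times[s],
                    "value": v,
                    "fold": f,
                    "max_fold": fc.max_fold,
                    "basis": basis,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["label", "sample_id", "time_min", "value", "fold", "max_fold", "basis"],
    )


def stage_compare(cfg: RunConfig) -> StageRecord:
    rec = StageRecord("compare")
    indir = cfg.outdir / "inputs"
    outdir = cfg.outdir / "comparative"
    outdir.mkdir(parents=True, exist_ok=True)
    bins = read_bins(
        _require("compare", indir / "bins.tsv"),
        _require("compare", indir / "gene_labels.tsv"),
    )
    kept = counting.filter_bins(bins, cfg.opts.min_completeness, cfg.opts.max_redundancy)
    catalog = comparative.GenomeCatalog(bins=kept)
    occ = comparative.occupancy_by_zotu(catalog)
    write_tsv(occ, outdir / "occupancy.tsv")
    _emit(rec, outdir / "occupancy.tsv", occ)
    modules = comparative.module_completeness_table(catalog)
    write_tsv(modules, outdir / "modules.tsv")
    _emit(rec, outdir / "modules.tsv", modules)
    return rec


def stage_kinetics(cfg: RunConfig) -> StageRecord:
    rec = StageRecord("kinetics")
    outdir = cfg.outdir / "kinetics"
    outdir.mkdir(parents=True, exist_ok=True)
    decay = read_tsv(
        _require("kinetics", cfg.outdir / "inputs" / "kinetics.tsv"),
        required_columns=("site", "condition", "replicate", "time_min", "fe2_um"),
    )
    fits_rows = []
    ratio_rows = []
    for site, site_df in decay.groupby("site", sort=True):
        per_condition: dict[str, list[kinetics_geochem.KineticsFit]] = {}
        pooled_fit: dict[str, kinetics_geochem.KineticsFit] = {}
        for condition, cond_df in site_df.groupby("condition", sort=True):
            series_list = []
            for rep, rep_df in cond_df.groupby("replicate", sort=True):
                rep_df = rep_df.sort_values("time_min")
                series = kinetics_geochem.DecaySeries(
                    rep_df["time_min"].to_numpy(),
                    rep_df["fe2_um"].to_numpy(),
                    condition=condition,
                    replicate=str(rep),
                )
                fit = kinetics_geochem.fit_first_order(series)
                series_list.append(series)
                per_condition.setdefault(condition, []).append(fit)
                fits_rows.append(
                    {
                        "site": site,
                        "condition": condition,
                        "replicate": str(rep),
                        "k1_per_min": fit.k1,
                        "ln_c0": fit.ln_c0,
                        "r_squared": fit.r_squared,
                        "n_points": fit.n_points,
                        "n_excluded": fit.n_excluded,
                    }
                )
            pooled_fit[condition] = kinetics_geochem.fit_pooled(series_list)
        if "live" in per_condition and "killed" in per_condition:
            mean_live = float(np.mean([f.k1 for f in per_condition["live"]]))
            mean_killed = float(np.mean([f.k1 for f in per_condition["killed"]]))
            ratio_rows.append(
                {
                    "site": site,
                    "k_live_pooled": pooled_fit["live"].k1,
                    "k_killed_pooled": pooled_fit["killed"].k1,
                    "ratio_pooled": kinetics_geochem.rate_ratio(
                        pooled_fit["live"], pooled_fit["killed"]
                    ),
                    "ratio_mean_replicates": (
                        mean_live / mean_killed if mean_killed > 0 else float("nan")
                    ),
                }
            )
    fits = pd.DataFrame(
        fits_rows,
        columns=[
            "site", "condition", "replicate", "k1_per_min", "ln_c0",
            "r_squared", "n_points", "n_excluded",
        ],
    )
    write_tsv(fits, outdir / "kinetics_fits.tsv")
    _emit(rec, outdir / "kinetics_fits.tsv", fits)
    ratios = pd.DataFrame(
        ratio_rows,
        columns=[
            "site", "k_live_pooled", "k_killed_pooled",
            "ratio_pooled", "ratio_mean_replicates",
        ],
    )
    write_tsv(ratios, outdir / "kinetics_ratios.tsv")
    _emit(rec, outdir / "kinetics_ratios.tsv", ratios)
    return rec


def stage_mixing(cfg: RunConfig) -> StageRecord:
    rec = StageRecord("mixing")
    outdir = cfg.outdir / "mixing"
    outdir.mkdir(parents=True, exist_ok=True)
    mix = cfg.sim.mixing
    model = kinetics_geochem.MixingModel(
        endmember=dict(mix.endmember),
        seawater=dict(mix.seawater),
        conservative_tracers=frozenset(mix.conservative_tracers),
        reactive_species=mix.species,
    )
    geochem = read_tsv(
        _require("mixing", cfg.outdir / "inputs" / "geochem.tsv"),
        required_columns=("sample_id", "Mg", mix.species),
    )
    rows = []
    for row in geochem.itertuples(index=False):
        frac = kinetics_geochem.mixing_fraction(getattr(row, "Mg"), model, "Mg")
        predicted = kinetics_geochem.conservative_prediction(frac.f, model, mix.species)
        observed = float(getattr(row, mix.species))
        rows.append(
            {
                "sample_id": row.sample_id,
                "f_mg": frac.f,
                "f_clamped": frac.clamped,
                "predicted_fe_um": predicted,
                "observed_fe_um": observed,
                "depletion_pct": kinetics_geochem.depletion_percent(observed, predicted),
            }
        )
    depl = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "f_mg", "f_clamped",
            "predicted_fe_um", "observed_fe_um", "depletion_pct",
        ],
    )
    write_tsv(depl, outdir / "depletion.tsv")
    _emit(rec, outdir / "depletion.tsv", depl)
    return rec


def stage_report(cfg: RunConfig) -> StageRecord:
    rec = StageRecord("report")
    outdir = cfg.outdir / "report"
    outdir.mkdir(parents=True, exist_ok=True)

    expr_dir = cfg.outdir / "expression"
    tpm = pd.read_csv(_require("report", expr_dir / "tpm.tsv"), sep="\t").set_index("entity_id")
    const = pd.read_csv(
        _require("report", expr_dir / "const_norm.tsv"), sep="\t"
    ).set_index("entity_id")
    pct = read_tsv(_require("report", expr_dir / "percentiles.tsv"))
    genes, gene_bins, gene_labels = _gene_maps(cfg)

    rows = []
    cyc2_genes = [g for g in tpm.index if gene_labels.get(g) in CYC2_LABELS]
    pct_idx = (
        pct.set_index(["gene_id", "sample_id"]) if len(pct) else None
    )
    samples = read_tsv(cfg.outdir / "inputs" / "samples.tsv")
    insitu = [s for s, r in zip(samples["sample_id"], samples["role"]) if r == "insitu"]
    for g in cyc2_genes:
        for s in insitu:
            p = np.nan
            high = False
            if pct_idx is not None and (g, s) in pct_idx.index:
                p = float(pct_idx.loc[(g, s), "percentile"])
                high = bool(pct_idx.loc[(g, s), "high_expression"])
            rows.append(
                {
                    "bin_id": gene_bins.get(g),
                    "gene_id": g,
                    "label": gene_labels.get(g),
                    "sample_id": s,
                    "tpm": float(tpm.loc[g, s]),
                    "const_norm_tpm": float(const.loc[g, s]),
                    "percentile": p,
                    "high_expression": high,
                }
            )
    table2 = pd.DataFrame(
        rows,
        columns=[
            "bin_id", "gene_id", "label", "sample_id",
            "tpm", "const_norm_tpm", "percentile", "high_expression",
        ],
    )
    write_tsv(table2, outdir / "table2_like.tsv")
    _emit(rec, outdir / "table2_like.tsv", table2)

    copies = [
        (cfg.outdir / "comparative" / "occupancy.tsv", "occupancy.tsv"),
        (expr_dir / "timeseries_folds.tsv", "timeseries_folds.tsv"),
        (cfg.outdir / "kinetics" / "kinetics_fits.tsv", "kinetics.tsv"),
        (cfg.outdir / "kinetics" / "kinetics_ratios.tsv", "kinetics_ratios.tsv"),
        (cfg.outdir / "mixing" / "depletion.tsv", "depletion.tsv"),
    ]
    for src, name in copies:
        df = read_tsv(_require("report", src))
        write_tsv(df, outdir / name)
        _emit(rec, outdir / name, df)
    return rec


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "count": stage_count,
    "express": stage_express,
    "compare": stage_compare,
    "kinetics": stage_kinetics,
    "mixing": stage_mixing,
    "report": stage_report,
}


def run(
    config_path,
    stages: Sequence[str] | None = None,
    outdir_override=None,
    seed_override=None,
) -> RunManifest:
    """Run the requested stages (all of them by default) in dependency order."""
    cfg = load_run_config(config_path, outdir_override, seed_override)
    requested = list(STAGES) if stages is None else list(stages)
    unknown = [s for s in requested if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stages {unknown}; valid stages are {list(STAGES)}")
    ordered = [s for s in STAGES if s in requested]
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_digest=_digest(cfg), seed=cfg.seed)
    for stage in ordered:
        logger.info("running stage %s", stage)
        manifest.stages.append(_STAGE_FUNCS[stage](cfg))
    (cfg.outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
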