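"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator is a pure function of its configuration (including the
seed): the same config yields byte-identical files.  The generators emulate

* a catalog of genome bins grouped into ZOTUs, with per-ZOTU Bernoulli
  gene presence/absence and non-overlapping gene coordinates (one contig
  per genome by default);
* negative-binomial read counts with a constitutive-gene baseline, a
  configurable expression fold per functional label (cyc2 elevated by
  default), and lognormal gene-to-gene variation for unlabeled background
  genes;
* amendment time series in which labeled genes follow a lognormal-shaped
  pulse (fold 1 pre-amendment, a programmed peak fold at a programmed
  time);
* pseudo-first-order Fe(II) decay with distinct live/killed rate constants
  and multiplicative lognormal measurement noise, sampled 2 min after
  amendment and every 10 min thereafter;
* two-endmember conservative mixing in which tracers sit on the mixing
  line (+/- noise) while dissolved Fe is depleted by a programmed fraction.

Counts can be materialized as aligned-read intervals (BED) fully contained
in their gene, so the counting stage recovers the simulated counts exactly.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .comparative import DEFAULT_PATHWAY_MODEL, GenomeCatalog
from .io_formats import AlignmentInterval, GeneModel, GenomeBin, SampleTable

#: Labels of the six constitutively expressed baseline genes.
CONSTITUTIVE_LABELS = ("adk", "gyrA", "recA", "rpoB", "rpoC", "secA")

#: Per-genome probability of carrying each pathway gene, loosely following
#: the occupancy structure seen across Zetaproteobacteria lineages
#: (cyc2 Cluster 1 near-universal, Cluster 3 and alternative complex III rare).
DEFAULT_OCCUPANCY: dict[str, float] = {
    "cyc2_cluster1": 0.9,
    "cyc2_cluster3": 0.3,
    "cyc1": 0.85,
    "PC12": 0.4,
    "bc1": 0.9,
    "ACIII": 0.2,
    "cbb3_proximal": 0.45,
    "cbb3_distal": 0.55,
    "aa3": 0.3,
    "bd1": 0.35,
}

#: Mean expression fold of each labeled gene relative to the constitutive
#: baseline in the in-situ samples.
DEFAULT_FOLD_MAP: dict[str, float] = {
    "cyc2_cluster1": 10.0,
    "cyc2_cluster3": 3.0,
    "cyc1": 3.0,
    "PC12": 2.0,
    "bc1": 6.6,
    "ACIII": 0.6,
    "cbb3_proximal": 5.0,
    "cbb3_distal": 5.0,
    "aa3": 1.0,
    "bd1": 1.0,
}


@dataclass(frozen=True)
class ResponseCurve:
    """Lognormal-shaped expression pulse after Fe(II) amendment.

    fold(t) = 1 + (peak_fold - 1) * exp(-(ln(t / peak_time))^2 / (2 w^2))
    for t > 0; fold 1 at and before the amendment.
    """

    peak_fold: float
    peak_time_min: float
    log_width: float = 0.6

    def fold(self, t: float) -> float:
        if t <= 0:
            return 1.0
        z = np.log(t / self.peak_time_min)
        return 1.0 + (self.peak_fold - 1.0) * float(
            np.exp(-(z**2) / (2.0 * self.log_width**2))
        )


DEFAULT_RESPONSE_CURVES: dict[str, ResponseCurve] = {
    "cyc2_cluster1": ResponseCurve(peak_fold=3.6, peak_time_min=30.0),
    "cyc1": ResponseCurve(peak_fold=2.0, peak_time_min=40.0),
    "cbb3_distal": ResponseCurve(peak_fold=2.0, peak_time_min=40.0),
}


@dataclass(frozen=True)
class KineticsConfig:
    """One paired live/killed Fe(II) amendment experiment."""

    k_live: float = 0.074  # per minute
    k_killed: float = 0.020
    c0: float = 100.0  # uM FeCl2 added
    noise_cv: float = 0.05  # multiplicative lognormal noise
    t_first: float = 2.0  # first sample 2 min after amendment ...
    t_step: float = 10.0  # ... then at 10-min intervals
    n_points: int = 7
    n_live_replicates: int = 1
    n_killed_replicates: int = 1

    @property
    def times(self) -> np.ndarray:
        return self.t_first + self.t_step * np.arange(self.n_points)


#: Site presets: rate-constant ratios of 3.7 (100 uM amendment) and 5.3
#: (333 uM amendment, duplicate live vessels).
DEFAULT_KINETICS: dict[str, KineticsConfig] = {
    "loihi": KineticsConfig(k_live=0.074, k_killed=0.020, c0=100.0),
    "mariana": KineticsConfig(
        k_live=0.106, k_killed=0.020, c0=333.0, n_live_replicates=2
    ),
}


@dataclass(frozen=True)
class MixingConfig:
    """Two-endmember mixing with reactive-Fe depletion.

    Compositions are in uM; the hydrothermal endmember is the zero-Mg
    extrapolation.  ``depletion_fraction`` may be a scalar applied to every
    sample or a per-sample sequence matching ``f_grid``.
    """

    endmember: Mapping[str, float] = field(
        default_factory=lambda: {"Mg": 0.0, "Mn": 680.0, "Si": 14000.0, "Fe": 250.0}
    )
    seawater: Mapping[str, float] = field(
        default_factory=lambda: {"Mg": 52900.0, "Mn": 0.0, "Si": 100.0, "Fe": 0.0}
    )
    conservative_tracers: tuple[str, ...] = ("Mg", "Mn", "Si")
    species: str = "Fe"
    f_grid: tuple[float, ...] = (0.02, 0.05, 0.1, 0.2, 0.4, 0.7, 1.0)
    depletion_fraction: float | tuple[float, ...] = 0.6
    tracer_noise_cv: float = 0.0

    def depletions(self) -> np.ndarray:
        d = np.asarray(self.depletion_fraction, dtype=float)
        if d.ndim == 0:
            return np.full(len(self.f_grid), float(d))
        if d.size != len(self.f_grid):
            raise ValueError("per-sample depletion_fraction must match f_grid")
        return d


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generators need; defaults give a small but complete study."""

    seed: int = 0
    n_zotus: int = 6
    genomes_per_zotu: int = 6
    occupancy_probs: Mapping = field(default_factory=lambda: dict(DEFAULT_OCCUPANCY))
    n_background_genes: int = 12  # per genome
    gene_length_range: tuple[int, int] = (300, 3000)
    gene_gap: int = 100
    baseline_mu: float = 50.0  # mean reads per kb for a fold-1 gene
    dispersion: float = 0.1  # negative-binomial dispersion (var = mu + d*mu^2)
    background_log_sigma: float = 1.0  # lognormal fold spread of background genes
    fold_map: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FOLD_MAP))
    timepoints: tuple[float, ...] = (0.0, 2.0, 12.0, 22.0, 32.0, 42.0, 52.0)
    response_curves: Mapping[str, ResponseCurve] = field(
        default_factory=lambda: dict(DEFAULT_RESPONSE_CURVES)
    )
    kinetics: Mapping[str, KineticsConfig] = field(
        default_factory=lambda: dict(DEFAULT_KINETICS)
    )
    mixing: MixingConfig = field(default_factory=MixingConfig)

    def occupancy_prob(self, zotu: str, label: str) -> float:
        probs = self.occupancy_probs
        if label in probs and isinstance(probs[label], (int, float)):
            return float(probs[label])
        if zotu in probs and isinstance(probs[zotu], Mapping):
            return float(probs[zotu].get(label, 0.0))
        return 0.0

    def labels(self) -> list[str]:
        out = []
        for key, value in self.occupancy_probs.items():
            if isinstance(value, Mapping):
                out.extend(value)
            else:
                out.append(key)
        return sorted(set(out))


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed)] + [int(s) for s in stream])


# stream ids for independent substreams of one seed
_STREAM_CATALOG = 1
_STREAM_COUNTS = 2
_STREAM_TIMESERIES = 3
_STREAM_ALIGNMENTS = 4
_STREAM_KINETICS = 5
_STREAM_MIXING = 6


@dataclass
class CatalogSimulation:
    """A simulated catalog plus the ground truth behind it."""

    catalog: GenomeCatalog
    genes: list[GeneModel]
    contig_lengths: dict[str, int]
    gene_fold: dict[str, float]  # true mean expression fold vs baseline
    config: SimulationConfig

    @property
    def gene_lengths(self) -> pd.Series:
        return pd.Series(
            {g.gene_id: g.length for g in self.genes}, name="length", dtype=float
        )

    @property
    def gene_bins(self) -> dict[str, str]:
        return {g.gene_id: g.bin_id for g in self.genes}

    @property
    def gene_labels(self) -> dict[str, str]:
        return {g.gene_id: g.label for g in self.genes if g.label is not None}


def simulate_catalog(config: SimulationConfig) -> CatalogSimulation:
    """Draw a genome catalog: ZOTUs, bins, labeled genes, coordinates.

    Each genome is one contig.  Per-genome label presence is Bernoulli with
    the configured per-ZOTU occupancy probability; every genome carries the
    six constitutive genes plus ``n_background_genes`` unlabeled genes whose
    true expression folds are lognormal around the baseline.
    """
    rng = _rng(config, _STREAM_CATALOG)
    lo, hi = config.gene_length_range
    bins: list[GenomeBin] = []
    genes: list[GeneModel] = []
    contig_lengths: dict[str, int] = {}
    gene_fold: dict[str, float] = {}
    for z in range(1, config.n_zotus + 1):
        zotu = f"ZOTU{z}"
        for g in range(1, config.genomes_per_zotu + 1):
            bin_id = f"Z{z:02d}G{g:02d}"
            contig_id = f"ctg_{bin_id}"
            labels = list(CONSTITUTIVE_LABELS)
            for label in config.labels():
                if rng.random() < config.occupancy_prob(zotu, label):
                    labels.append(label)
            n_bg = config.n_background_genes
            completeness = float(rng.uniform(75.0, 99.5))
            redundancy = float(rng.uniform(0.0, 8.0))
            pos = config.gene_gap
            k = 0
            for label in labels + [None] * n_bg:
                k += 1
                gene_id = f"{bin_id}_g{k:03d}"
                length = int(rng.integers(lo, hi + 1))
                gene = GeneModel(
                    gene_id=gene_id,
                    contig_id=contig_id,
                    start=pos,
                    end=pos + length,
                    strand="+" if rng.random() < 0.5 else "-",
                    bin_id=bin_id,
                    label=label,
                )
                genes.append(gene)
                pos = gene.end + config.gene_gap
                if label is None:
                    gene_fold[gene_id] = float(
                        rng.lognormal(0.0, config.background_log_sigma)
                    )
                else:
                    gene_fold[gene_id] = float(config.fold_map.get(label, 1.0))
            contig_lengths[contig_id] = pos
            bins.append(
                GenomeBin(
                    bin_id=bin_id,
                    zotu=zotu,
                    completeness=completeness,
                    redundancy=redundancy,
                    gene_labels=Counter(labels),
                )
            )
    catalog = GenomeCatalog(bins=bins, pathway_model=dict(DEFAULT_PATHWAY_MODEL))
    return CatalogSimulation(catalog, genes, contig_lengths, gene_fold, config)


def _negbin(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson; var = mu + dispersion * mu^2.

    ``dispersion == 0`` is the degenerate limit: counts are the rounded
    means (deterministic), which keeps the limit exactly testable.
    """
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return np.rint(mu).astype(np.int64)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam).astype(np.int64)


def _mean_counts(sim: CatalogSimulation) -> np.ndarray:
    cfg = sim.config
    return np.array(
        [
            cfg.baseline_mu * sim.gene_fold[g.gene_id] * g.length / 1000.0
            for g in sim.genes
        ]
    )


def simulate_expression_counts(
    sim: CatalogSimulation, sample_ids: Sequence[str] = ("S1", "S2")
) -> SampleTable:
    """In-situ style negative-binomial counts, one column per sample."""
    cfg = sim.config
    mu = _mean_counts(sim)
    columns = {}
    for j, sample_id in enumerate(sample_ids):
        rng = _rng(cfg, _STREAM_COUNTS, j)
        columns[sample_id] = _negbin(rng, mu, cfg.dispersion)
    df = pd.DataFrame(
        columns, index=pd.Index([g.gene_id for g in sim.genes], name="entity_id")
    )
    return SampleTable(df, kind="count")


def response_fold(config: SimulationConfig, label: str | None, t: float) -> float:
    """Programmed amendment response for one label at time t (1 = baseline)."""
    if label is None:
        return 1.0
    curve = config.response_curves.get(label)
    return 1.0 if curve is None else curve.fold(t)


def timeseries_sample_ids(config: SimulationConfig) -> dict[str, float]:
    """Ordered sample ids for the amendment series, mapped to minutes."""
    return {f"T{int(round(t)):03d}": float(t) for t in config.timepoints}


def simulate_timeseries(sim: CatalogSimulation) -> SampleTable:
    """Amendment-series counts: one sample per timepoint, folds applied.

    The first timepoint is the pre-amendment reference (all folds 1).
    """
    cfg = sim.config
    mu0 = _mean_counts(sim)
    columns = {}
    for i, (sample_id, t) in enumerate(timeseries_sample_ids(cfg).items()):
        rng = _rng(cfg, _STREAM_TIMESERIES, i)
        folds = np.array([response_fold(cfg, g.label, t) for g in sim.genes])
        columns[sample_id] = _negbin(rng, mu0 * folds, cfg.dispersion)
    df = pd.DataFrame(
        columns, index=pd.Index([g.gene_id for g in sim.genes], name="entity_id")
    )
    return SampleTable(df, kind="count")


def simulate_alignments(
    sim: CatalogSimulation,
    counts: SampleTable,
    sample_id: str,
    read_length: int = 150,
    stream: int = 0,
) -> list[AlignmentInterval]:
    """Materialize one sample's counts as read placements inside each gene.

    Reads are fully contained in their gene, so per-gene interval counting
    recovers the simulated counts exactly.
    """
    rng = _rng(sim.config, _STREAM_ALIGNMENTS, stream)
    col = counts.values[sample_id]
    intervals: list[AlignmentInterval] = []
    for g in sim.genes:
        n = int(col.get(g.gene_id, 0))
        if n == 0:
            continue
        rl = min(read_length, g.length)
        starts = rng.integers(g.start, g.end - rl + 1, size=n)
        for i, s in enumerate(np.sort(starts)):
            intervals.append(
                AlignmentInterval(
                    g.contig_id, int(s), int(s) + rl, f"{sample_id}:{g.gene_id}:r{i}"
                )
            )
    return intervals


def simulate_fe_decay(config: SimulationConfig) -> pd.DataFrame:
    """Fe(II)-vs-time tables for every configured site and condition.

    Columns: site, condition, replicate, time_min, fe2_um.  Noise is
    multiplicative lognormal with the configured coefficient of variation
    (mean-one, so the expected concentration sits on the true exponential).
    """
    rows = []
    for si, (site, kin) in enumerate(sorted(config.kinetics.items())):
        sigma = np.sqrt(np.log1p(kin.noise_cv**2))
        for ci, (condition, k, n_reps) in enumerate(
            [
                ("live", kin.k_live, kin.n_live_replicates),
                ("killed", kin.k_killed, kin.n_killed_replicates),
            ]
        ):
            for rep in range(1, n_reps + 1):
                rng = _rng(config, _STREAM_KINETICS, si, ci, rep)
                t = kin.times
                c = kin.c0 * np.exp(-k * t)
                if kin.noise_cv > 0:
                    c = c * rng.lognormal(-0.5 * sigma**2, sigma, size=t.size)
                for ti, conc in zip(t, c):
                    rows.append(
                        {
                            "site": site,
                            "condition": condition,
                            "replicate": str(rep),
                            "time_min": float(ti),
                            "fe2_um": float(conc),
                        }
                    )
    return pd.DataFrame(rows, columns=["site", "condition", "replicate", "time_min", "fe2_um"])


def simulate_mixing(config: SimulationConfig) -> pd.DataFrame:
    """Geochemistry table: tracers on the mixing line, Fe depleted below it.

    Columns: sample_id, f_true, depletion_true, one column per tracer, and
    the reactive species.  Conservative tracers sit exactly on the line when
    ``tracer_noise_cv`` is zero.
    """
    mix = config.mixing
    rng = _rng(config, _STREAM_MIXING)
    depletions = mix.depletions()
    rows = []
    for i, (f, d) in enumerate(zip(mix.f_grid, depletions), start=1):
        row = {"sample_id": f"GC{i:02d}", "f_true": float(f), "depletion_true": float(d)}
        for tracer in mix.conservative_tracers:
            value = f * mix.endmember[tracer] + (1 - f) * mix.seawater[tracer]
            if mix.tracer_noise_cv > 0:
                sigma = np.sqrt(np.log1p(mix.tracer_noise_cv**2))
                value *= rng.lognormal(-0.5 * sigma**2, sigma)
            row[tracer] = float(value)
        line = f * mix.endmember[mix.species] + (1 - f) * mix.seawater[mix.species]
        row[mix.species] = float((1.0 - d) * line)
        rows.append(row)
    return pd.DataFrame(rows)


def config_digest(config: SimulationConfig) -> str:
    """Stable digest of the semantic configuration (for run manifests)."""
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=int(seed))
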