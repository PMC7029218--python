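# Methods

## Scope and data model

`ironmats` operates downstream of assembly, binning, annotation, and read
mapping: its inputs are gene models (GFF3) on community contigs, mapped-read
intervals (BED), bin membership and quality tables, functional labels per
gene, Fe(II)-vs-time tables, and geochemistry tables.  Internally all
genomic coordinates are 0-based half-open; conversion to the 1-based
inclusive GFF3 convention happens only in `io_formats`, and the conversion
is an exact bijection (property-tested).

## Counting and filters

A read interval is counted once for every gene it overlaps by at least one
base pair.  This is the plain region-count convention: no fractional
assignment, no strand awareness (library strandedness is treated as
unknown), and a read spanning a gene boundary increments both genes.  Gene
lookup uses an interval tree per contig; the test suite checks it against
an all-pairs brute-force count and against `bedtools intersect -c`.

Contig coverage is computed exactly with a difference array.  Contigs need
breadth ≥ 0.9 at depth ≥ 1 (inclusive thresholds) to be retained; genome
bins need completeness > 70% and redundancy < 10% (strict inequalities).
These thresholds are exposed as configuration with those defaults.

## Expression normalization

TPM uses the whole-community denominator, not a per-bin one, so per-bin
statistics remain comparable across bins within a sample.  Constitutive
normalization divides TPM by the arithmetic mean TPM of the six
housekeeping genes (*adk*, *gyrA*, *recA*, *rpoB*, *rpoC*, *secA*)
*detected* (TPM > 0) in the same bin and sample.  The baseline is
undefined — and every value in that (bin, sample) is NA — when fewer than
`min_genes` (default 3) are detected or the baseline is not positive; a
`min_baseline_tpm` knob additionally lets users require a minimum baseline
depth.  NA is a value, not an error: sparsely recruited bins are expected.

Percentiles are mid-rank: a gene with `l` strictly-lower and `t` tied
competitors among `n` genes scores `100·(l + t/2)/(n − 1)`, so a unique
maximum scores 100 and a complete tie scores 50; a single-gene group is NA.
Ranks are computed within (bin, sample) by default; a `scope` switch ranks
against all genes in the sample instead, since either reading of
"percentile in community expression" is defensible.  "High expression" is
strictly above the 90th percentile.  Percentiles are invariant under any
strictly monotone transform of the expression values (tested).

Fold changes are taken against the pre-amendment timepoint, with the
maximum over later points.  The pipeline's amendment summary normalizes the
pooled TPM of a gene set by the pooled constitutive TPM of the whole
community ("community constitutive" basis, recorded in the output); this is
deliberately more robust than per-bin baselines when time-series read depth
is low, and falls back to raw TPM (also recorded) if no housekeeping gene is
detected.

## Comparative genomics

Occupancy is presence/absence (≥1 copy; copy number reported separately).
The pathway model maps each functional label to exactly one of four
modules: Fe oxidase {cyc2 Cluster 1, cyc2 Cluster 3}, electron carrier
{cyc1, periplasmic cytochromes PC*}, complex III {bc1, alternative complex
III}, terminal oxidase {cbb3 proximal, cbb3 distal, aa3, bd-I}.  A module
is present in a genome when any alternative is present.  At the ZOTU level
a module is called present when at least half the ZOTU's genomes carry it —
a deliberate middle ground, since incomplete MAGs produce false-negative
per-genome calls; both views are emitted.

## Kinetics

Pseudo-first-order rate constants come from the ordinary least-squares
log-linear fit of ln[Fe(II)] vs time: k₁ = −slope, exact (tolerance 1e−10
in tests) on noiseless exponentials.  Points at or below the 0.12 µM
ferrozine detection limit are excluded (count logged); fewer than 3 usable
points is an error.  A constant series yields k₁ = 0 with r² reported as 0
(the correlation is undefined).  Points are unweighted; replicates are
fitted independently and also pooled into a single fit, and both ratios
(pooled, mean-of-replicates) are reported because it is ambiguous which
pooling a given study used.  k₁ is invariant under rescaling all
concentrations (only the intercept shifts).

## Conservative mixing

The mixing model stores endmember and seawater compositions with a declared
set of conservative tracers (Mg, Mn, Si).  The hydrothermal fraction from a
tracer is clamped to [0, 1] with a flag when measurement error pushes it
outside.  Mg anchors the model (the endmember is the zero-Mg
extrapolation), but for low-temperature samples the Mg-derived fraction is
numerically ill-conditioned — Mg sits within a few percent of seawater, so
a relative tracer error ε inflates the fractional error of f by
(1 − f)/f — which is why Mn (or Si) is the appropriate fraction tracer for
depletion estimates in near-seawater fluids, and what the depletion
recovery experiment uses.  Depletion is 100·(predicted − observed)/predicted;
negative values (enrichment) are allowed and logged.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (config, seed) — byte-identical
outputs per seed, independent substreams per stage.

* **Catalog**: ZOTUs × genomes with Bernoulli gene presence per label
  (defaults loosely follow the observed occupancy structure: Cluster 1
  *cyc2* near-universal at 0.9, Cluster 3 at 0.3, alternative complex III
  rare at 0.2).  One contig per genome, non-overlapping genes with uniform
  lengths in 300–3000 bp, always including the six housekeeping genes.
* **Counts**: negative-binomial via gamma–Poisson with mean
  `baseline_mu · fold(label) · length/1 kb` and dispersion 0.1 (typical
  overdispersion for metatranscriptome counts); `baseline_mu` defaults to
  50 reads/kb.  Labeled folds default to the in-situ contrasts of interest
  (cyc2 Cluster 1 at 10×, bc1 at 6.6×, alternative complex III at 0.6×);
  unlabeled background genes get lognormal(σ = 1) folds.  Dispersion 0 is
  the degenerate deterministic limit (counts = rounded means), kept exactly
  testable.
* **Amendment series**: labeled genes follow a lognormal-shaped pulse
  `fold(t) = 1 + (peak − 1)·exp(−ln²(t/t_peak)/2w²)` — an empirical pulse
  shape, not mechanistic kinetics — with the cyc2 default peaking at 3.6×
  at 30 min; the first timepoint is the pre-amendment reference.
* **Fe(II) decay**: exponential with multiplicative mean-one lognormal
  noise (cv 5%), sampled at 2 min and then every 10 min.  Defaults use
  k_killed = 0.02 min⁻¹ (half-life ≈ 35 min, keeping all samples above the
  detection limit at both amendment levels of 100 and 333 µM) and live
  rates 3.7× and 5.3× higher at the two preset sites.
* **Mixing**: conservative tracers exactly on the two-endmember line
  (± optional lognormal tracer noise); Fe is the line value times
  (1 − depletion).

Counts can be materialized as fixed-length reads placed entirely within
their gene, so the counting stage recovers the simulated counts exactly —
a strong end-to-end identity, but note real read placement crosses gene
boundaries and intergenic space, which is exercised separately by the
randomized counting fixtures.

What passing tests on these data do **not** show: robustness to assembly
or binning error, multi-mapping reads, strand-specific protocols, rRNA
carry-over, compositional shifts between samples beyond a global scale
factor, or mechanistic expression dynamics.  The generator emulates the
statistical shape of the inputs, not their biology.

## Recovery experiments and problem sizes

`ironmats.experiments` defines the end-to-end recovery checks used by both
the test suite and `scripts/acceptance.py`:

* constitutive-normalized cyc2 at programmed 10×: 25 genomes × 8 genes
  (200 genes), lengths ≥ 1 kb so each gene averages ≥ 50 reads; the
  estimate is the mean per-genome value.  With NB dispersion 0.1 a single
  gene's value has ≈34% noise, so averaging over 25 genomes is what makes
  a [8, 12] recovery band achievable.
* peak fold change 3.6× at 30 min: 12 genomes pooled (as one pools all
  cyc2 copies in a community series); the max-over-timepoints estimator is
  slightly upward-biased under noise (~5–8%), so recovery is judged on the
  mean across seeds within 15%.
* rate ratios 3.7 and 5.3: one paired live/killed fit per seed at 5%
  noise, 7 timepoints.
* depletion 49% and 74%: exact at zero tracer noise; Mn-based fractions at
  2% tracer noise.

These sizes were chosen so every estimator's sampling error is small
relative to its acceptance band while the whole suite stays quick to run.

## Known limitations

* The percentile of a gene in a bin with many NA values is computed over
  the non-NA genes only.
* The pipeline's coverage filter pools all samples' alignments before
  computing breadth (one retained-contig set per run), rather than
  filtering per sample.
* `SampleTable` holds dense matrices; the intended scale is tens of
  thousands of genes, not millions.
* Mixing assumes exactly two endmembers; multi-endmember systems need the
  fraction computed upstream.
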