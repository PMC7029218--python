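# ironmats

Analysis pipeline for meta-omics of marine iron microbial mats dominated by
*Zetaproteobacteria* — chemolithotrophic Fe(II) oxidizers whose proposed
pathway runs from the outer-membrane cytochrome-porin Cyc2 through a
periplasmic electron carrier and complex III to a terminal oxidase.
`ironmats` quantifies (i) gene expression of that pathway in
metagenome-assembled genomes (MAGs), (ii) gene distribution across
*Zetaproteobacteria* operational taxonomic units (ZOTUs), and (iii) the
accompanying geochemistry: pseudo-first-order Fe(II) oxidation kinetics and
Fe depletion relative to conservative hydrothermal–seawater mixing.  A
synthetic-data module generates every input with the statistical structure
the analysis assumes, so the whole pipeline runs and is tested without any
sequencing data.

It is intended for microbial ecologists and biogeochemists who want these
estimators as reusable, tested building blocks rather than one-off scripts.

## What it computes

**Expression.** Reads mapped to community contigs are counted per gene
region (≥1 bp overlap; a read spanning two genes increments both), after
discarding contigs without ≥1× coverage over 90% of their length and MAGs
that are not >70% complete and <10% redundant.  Counts are normalized
three ways:

- **TPM**: `rate_g = count_g / length_g(kb)`, `TPM_g = 10⁶ · rate_g / Σ_h rate_h`
  per sample (denominator over the whole community mapping);
- **constitutive-normalized**: TPM divided by the mean TPM of six
  housekeeping genes (*adk*, *gyrA*, *recA*, *rpoB*, *rpoC*, *secA*)
  detected in the same MAG and sample — a value of 1 is baseline
  expression, and the value is NA when fewer than 3 of the 6 are detected;
- **max-normalized**: each time series divided by its maximum, for
  visualization.

Percentile ranks are mid-rank percentiles within (MAG, sample); "high
expression" means strictly above the 90th percentile.  Amendment time
series are summarized as fold changes against the pre-amendment point.

**Comparative genomics.** Per-ZOTU gene occupancy (fraction of a ZOTU's
genomes possessing each gene), co-occurrence fractions between gene
variants (e.g. Cluster 3 vs Cluster 1 *cyc2*), and completeness of the
four-module Fe oxidation pathway (Fe oxidase / electron carrier / complex
III / terminal oxidase), reported per genome and as a ≥50% majority vote
per ZOTU.

**Kinetics & geochemistry.** `k₁ = −slope` of the ordinary least-squares
fit of ln[Fe(II)] vs time (points at or below the 0.12 µM detection limit
excluded); the live/killed ratio `k_live/k_killed` separates biotic from
abiotic oxidation.  For mixing, the hydrothermal fraction
`f = (sample − seawater)/(endmember − seawater)` from a conservative
tracer (Mg, Mn, or Si) gives the conservative prediction
`f·endmember + (1−f)·seawater`, and Fe depletion is
`100·(predicted − observed)/predicted`.

## Worked example

Run the packaged default study (6 ZOTUs × 6 genomes, two in-situ samples,
a 7-point Fe(II) amendment series, two kinetics experiments, a 7-sample
mixing transect):

```bash
ironmats run-all --outdir demo
head -3 demo/report/table2_like.tsv
cat demo/report/kinetics_ratios.tsv
```

```
bin_id  gene_id      label          sample_id  tpm                const_norm_tpm      percentile  high_expression
Z01G02  Z01G02_g012  cyc2_cluster1  S1         6075.632735624893  10.090617982701632  100.0       True
Z01G02  Z01G02_g012  cyc2_cluster1  S2         5105.627594251303  8.66757359746182    100.0       True

site     k_live_pooled       k_killed_pooled     ratio_pooled        ratio_mean_replicates
loihi    0.0742202475384609  0.0213799718806838  3.4714848060916634  3.4714848060916634
mariana  0.1062137755935374  0.0193088545062097  5.500780771815285   5.500780771815285
```

Reading this: the *cyc2* gene in MAG `Z01G02` recruits ~6,000 TPM, about
10× that MAG's housekeeping baseline (the generator programs a 10× fold),
and is the highest-expressed gene in its MAG (100th percentile, flagged
high).  The fitted rate-constant ratios recover the programmed live/killed
contrasts (3.7 and 5.3) to within fitting noise on a single simulated
experiment.  `demo/report/` also contains the occupancy dot-plot table,
time-series fold changes, and the Fe-depletion table
(`depletion_pct` ≈ 60% for the default programmed depletion).

Every stage is also callable as a library function; see
`ironmats.expression`, `ironmats.comparative`, `ironmats.kinetics_geochem`,
and `ironmats.synthetic_data`.

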