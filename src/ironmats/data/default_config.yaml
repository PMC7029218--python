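# Default end-to-end run: a small synthetic iron-mat study.
seed: 1
outdir: ironmats_run
n_zotus: 6
genomes_per_zotu: 6
n_background_genes: 12
baseline_mu: 50.0
dispersion: 0.1
# analysis thresholds (published defaults)
min_depth: 1
min_breadth: 0.9
min_completeness: 70.0
max_redundancy: 10.0
percentile_high: 90.0
min_constitutive_genes: 3
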