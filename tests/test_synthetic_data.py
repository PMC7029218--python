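"""Determinism and statistical structure of the synthetic-data generators."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from ironmats.counting import count_reads_per_gene
from ironmats.io_formats import read_bed, read_gff3, write_bed, write_gff3
from ironmats.synthetic_data import (
    KineticsConfig,
    MixingConfig,
    ResponseCurve,
    SimulationConfig,
    simulate_alignments,
    simulate_catalog,
    simulate_expression_counts,
    simulate_fe_decay,
    simulate_mixing,
    simulate_timeseries,
    with_seed,
)


def tiny_config(**overrides):
    defaults = dict(seed=11, n_zotus=2, genomes_per_zotu=3, n_background_genes=5)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestCatalog:
    def test_certain_label_present_everywhere(self):
        cfg = tiny_config(occupancy_probs={"cyc2_cluster1": 1.0})
        sim = simulate_catalog(cfg)
        assert all(b.has_label("cyc2_cluster1") for b in sim.catalog.bins)

    def test_impossible_label_absent_everywhere(self):
        cfg = tiny_config(occupancy_probs={"cyc2_cluster1": 0.0})
        sim = simulate_catalog(cfg)
        assert not any(b.has_label("cyc2_cluster1") for b in sim.catalog.bins)

    def test_occupancy_within_binomial_ci(self):
        cfg = SimulationConfig(seed=3, n_zotus=1, genomes_per_zotu=200,
                               n_background_genes=0,
                               occupancy_probs={"cyc2_cluster1": 0.3})
        sim = simulate_catalog(cfg)
        p_hat = np.mean([b.has_label("cyc2_cluster1") for b in sim.catalog.bins])
        half = 1.96 * np.sqrt(0.3 * 0.7 / 200)
        assert 0.3 - half <= p_hat <= 0.3 + half

    def test_genes_non_overlapping_within_contig(self):
        sim = simulate_catalog(tiny_config())
        by_contig = {}
        for g in sim.genes:
            by_contig.setdefault(g.contig_id, []).append(g)
        for genes in by_contig.values():
            genes = sorted(genes, key=lambda g: g.start)
            for a, b in zip(genes, genes[1:]):
                assert a.end <= b.start

    def test_deterministic_under_seed(self):
        a = simulate_catalog(tiny_config())
        b = simulate_catalog(tiny_config())
        assert a.genes == b.genes
        assert a.contig_lengths == b.contig_lengths
        assert [x.gene_labels for x in a.catalog.bins] == [
            x.gene_labels for x in b.catalog.bins
        ]


class TestCounts:
    def test_zero_dispersion_counts_are_rounded_means(self):
        cfg = tiny_config(dispersion=0.0)
        sim = simulate_catalog(cfg)
        counts = simulate_expression_counts(sim, ["S1"])
        mu = {
            g.gene_id: cfg.baseline_mu * sim.gene_fold[g.gene_id] * g.length / 1000.0
            for g in sim.genes
        }
        for gene_id, expected in mu.items():
            assert counts.values.loc[gene_id, "S1"] == round(expected)

    def test_cyc2_mean_ratio_near_fold(self):
        """With cyc2 at fold 10 the mean count-per-kb ratio converges to ~10."""
        cfg = SimulationConfig(
            seed=4, n_zotus=1, genomes_per_zotu=500, n_background_genes=0,
            occupancy_probs={"cyc2_cluster1": 1.0},
            fold_map={"cyc2_cluster1": 10.0},
        )
        sim = simulate_catalog(cfg)
        counts = simulate_expression_counts(sim, ["S1"])
        per_kb = counts.values["S1"] / (sim.gene_lengths / 1000.0)
        labels = pd.Series(sim.gene_labels)
        cyc2 = per_kb[labels.index[labels == "cyc2_cluster1"]].mean()
        const = per_kb[labels.index[labels != "cyc2_cluster1"]].mean()
        assert cyc2 / const == pytest.approx(10.0, rel=0.1)

    def test_seed_contract(self):
        sim = simulate_catalog(tiny_config())
        a = simulate_expression_counts(sim, ["S1"])
        b = simulate_expression_counts(sim, ["S1"])
        c = simulate_expression_counts(simulate_catalog(tiny_config(seed=12)), ["S1"])
        assert a.values.equals(b.values)
        assert not a.values.equals(c.values)

    def test_alignments_reproduce_counts_exactly(self):
        sim = simulate_catalog(tiny_config())
        counts = simulate_expression_counts(sim, ["S1"])
        intervals = simulate_alignments(sim, counts, "S1")
        table = count_reads_per_gene(intervals, sim.genes, sample_id="S1")
        assert table.values["S1"].equals(counts.values["S1"])


class TestTimeseries:
    def test_flat_curve_all_folds_one(self):
        cfg = tiny_config(dispersion=0.0, response_curves={})
        sim = simulate_catalog(cfg)
        counts = simulate_timeseries(sim)
        first = counts.values.iloc[:, 0]
        for col in counts.values.columns[1:]:
            assert counts.values[col].equals(first)

    def test_pulse_peaks_near_programmed_time(self):
        curve = ResponseCurve(peak_fold=5.0, peak_time_min=30.0)
        assert curve.fold(30.0) == pytest.approx(5.0)
        assert curve.fold(0.0) == 1.0
        assert curve.fold(30.0) > curve.fold(10.0) > curve.fold(2.0)

    def test_programmed_peak_recovered_noiselessly(self):
        """With dispersion 0 the const-norm fold series equals the pulse."""
        from ironmats.expression import constitutive_normalize, fold_change_series, tpm

        cfg = SimulationConfig(
            seed=9, n_zotus=1, genomes_per_zotu=1, n_background_genes=0,
            dispersion=0.0, gene_length_range=(1500, 1501),
            occupancy_probs={"cyc2_cluster1": 1.0},
            response_curves={"cyc2_cluster1": ResponseCurve(5.0, 30.0)},
            timepoints=(0.0, 10.0, 30.0, 50.0),
        )
        sim = simulate_catalog(cfg)
        counts = simulate_timeseries(sim)
        expr = tpm(counts, sim.gene_lengths)
        norm, _ = constitutive_normalize(expr, sim.gene_bins, sim.gene_labels)
        (cyc2,) = [g for g, l in sim.gene_labels.items() if l == "cyc2_cluster1"]
        fc = fold_change_series(norm.values.loc[cyc2].to_numpy())
        assert fc.max_fold == pytest.approx(5.0, rel=0.02)  # rounding of means only


class TestKineticsAndMixing:
    def test_noiseless_decay_is_exact_exponential(self):
        cfg = tiny_config(kinetics={"loihi": KineticsConfig(noise_cv=0.0)})
        decay = simulate_fe_decay(cfg)
        live = decay[decay["condition"] == "live"]
        kin = cfg.kinetics["loihi"]
        np.testing.assert_allclose(
            live["fe2_um"], kin.c0 * np.exp(-kin.k_live * live["time_min"])
        )

    def test_sampling_grid(self):
        cfg = tiny_config(kinetics={"loihi": KineticsConfig(n_points=5)})
        decay = simulate_fe_decay(cfg)
        times = sorted(decay["time_min"].unique())
        assert times == [2.0, 12.0, 22.0, 32.0, 42.0]

    def test_mixing_zero_depletion_on_line(self):
        cfg = tiny_config(mixing=MixingConfig(depletion_fraction=0.0))
        geo = simulate_mixing(cfg)
        mix = cfg.mixing
        expected = [
            f * mix.endmember["Fe"] + (1 - f) * mix.seawater["Fe"]
            for f in mix.f_grid
        ]
        np.testing.assert_allclose(geo["Fe"], expected)

    def test_determinism_under_seed(self):
        cfg = tiny_config()
        assert simulate_fe_decay(cfg).equals(simulate_fe_decay(cfg))
        assert simulate_mixing(cfg).equals(simulate_mixing(cfg))
        other = with_seed(cfg, 99)
        assert not simulate_fe_decay(other).equals(simulate_fe_decay(cfg))


class TestFileRoundTrip:
    def test_generated_files_readable(self, tmp_path, small_sim):
        write_gff3(small_sim.genes, tmp_path / "genes.gff3")
        assert read_gff3(tmp_path / "genes.gff3") == small_sim.genes
        counts = simulate_expression_counts(small_sim, ["S1"])
        intervals = simulate_alignments(small_sim, counts, "S1")
        write_bed(intervals, tmp_path / "s1.bed")
        assert read_bed(tmp_path / "s1.bed") == intervals
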