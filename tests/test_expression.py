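"""TPM, constitutive normalization, percentiles, fold changes, gene-set means."""

import numpy as np
import pandas as pd
import pytest

from ironmats.expression import (
    CONSTITUTIVE_LABELS,
    ExpressionMatrix,
    constitutive_normalize,
    fold_change_series,
    geneset_mean_expression,
    geneset_ratio_per_bin,
    max_normalize_series,
    percentile_rank,
    tpm,
)
from ironmats.io_formats import SampleTable


def counts_table(data, samples=("S1",)):
    df = pd.DataFrame(data, columns=list(samples))
    df.index = [f"g{i}" for i in range(len(df))] if df.index.dtype != object else df.index
    df.index.name = "entity_id"
    return SampleTable(df, kind="count")


def make_counts(mapping, sample="S1"):
    df = pd.DataFrame({sample: mapping})
    df.index.name = "entity_id"
    return SampleTable(df, kind="count")


class TestTPM:
    def test_equal_rates_split_evenly(self):
        counts = make_counts({"a": 10, "b": 30})
        expr = tpm(counts, {"a": 1000, "b": 3000})
        assert expr.values["S1"].tolist() == [500000.0, 500000.0]

    def test_single_expressed_gene_takes_all(self):
        counts = make_counts({"a": 5, "b": 0})
        expr = tpm(counts, {"a": 700, "b": 1400})
        assert expr.values.loc["a", "S1"] == 1e6
        assert expr.values.loc["b", "S1"] == 0.0

    def test_hand_oracle(self):
        """rate/sum(rate) * 1e6 computed by hand for three genes."""
        counts = make_counts({"A": 10, "B": 20, "C": 90})
        expr = tpm(counts, {"A": 500, "B": 1000, "C": 1500})
        assert expr.values["S1"].tolist() == [200000.0, 200000.0, 600000.0]

    def test_columns_sum_to_one_million(self, rng):
        n = 200
        df = pd.DataFrame(
            rng.integers(0, 500, size=(n, 4)),
            index=[f"g{i}" for i in range(n)],
            columns=["S1", "S2", "S3", "S4"],
        )
        df.index.name = "entity_id"
        lengths = pd.Series(rng.integers(200, 3000, size=n), index=df.index)
        expr = tpm(SampleTable(df), lengths)
        np.testing.assert_allclose(expr.values.sum(axis=0), 1e6, rtol=1e-9)

    def test_all_zero_sample_flagged(self):
        counts = counts_table({"S1": [0, 0], "S2": [1, 1]}, samples=("S1", "S2"))
        expr = tpm(counts, {"g0": 100, "g1": 100})
        assert expr.all_zero_samples == ("S1",)
        assert (expr.values["S1"] == 0).all()

    def test_counted_gene_without_length_is_error(self):
        counts = make_counts({"a": 10})
        with pytest.raises(ValueError, match="no length"):
            tpm(counts, {})


def _const_setup(target_tpm, const_tpm=100.0, n_const=6):
    """One bin: six constitutive genes at const_tpm, one target gene."""
    labels = dict(zip([f"c{i}" for i in range(n_const)], sorted(CONSTITUTIVE_LABELS)))
    labels["t"] = "cyc2_cluster1"
    values = {f"c{i}": const_tpm for i in range(n_const)}
    values["t"] = target_tpm
    df = pd.DataFrame({"S1": values})
    expr = ExpressionMatrix(df, "TPM")
    bins = {g: "b1" for g in df.index}
    return expr, bins, labels


class TestConstitutiveNormalize:
    def test_gene_at_baseline_is_one(self):
        expr, bins, labels = _const_setup(100.0)
        norm, baselines = constitutive_normalize(expr, bins, labels)
        assert norm.values.loc["t", "S1"] == 1.0
        assert baselines[0].baseline == 100.0 and baselines[0].n_used == 6

    def test_tenfold_gene(self):
        expr, bins, labels = _const_setup(1000.0)
        norm, _ = constitutive_normalize(expr, bins, labels)
        assert norm.values.loc["t", "S1"] == 10.0

    def test_insufficient_constitutive_genes_gives_na(self):
        """Below min_genes detected housekeeping genes the bin is NA, not an error."""
        expr, bins, labels = _const_setup(1000.0, n_const=2)
        norm, baselines = constitutive_normalize(expr, bins, labels)
        assert norm.values["S1"].isna().all()
        assert np.isnan(baselines[0].baseline) and baselines[0].n_used == 2

    def test_undetected_genes_do_not_count(self):
        expr, bins, labels = _const_setup(1000.0)
        expr.values.loc[["c0", "c1", "c2", "c3"], "S1"] = 0.0
        norm, baselines = constitutive_normalize(expr, bins, labels)
        assert baselines[0].n_used == 2
        assert norm.values["S1"].isna().all()

    def test_scaling_invariance(self, rng):
        """Multiplying all counts in a sample by c > 0 leaves values unchanged."""
        n = 50
        base = rng.integers(1, 300, size=n)
        lengths = pd.Series(rng.integers(200, 2000, size=n),
                            index=[f"g{i}" for i in range(n)]).astype(float)
        labels = {f"g{i}": lab for i, lab in enumerate(sorted(CONSTITUTIVE_LABELS))}
        bins = {f"g{i}": "b1" for i in range(n)}
        reference = None
        for c in [1, 0.1, 3, 1000]:
            df = pd.DataFrame({"S1": base * c}, index=lengths.index)
            df.index.name = "entity_id"
            norm, _ = constitutive_normalize(
                tpm(SampleTable(df, kind="abundance"), lengths), bins, labels
            )
            if reference is None:
                reference = norm.values
            else:
                np.testing.assert_allclose(norm.values, reference, rtol=1e-9)


def percentile_oracle(values):
    """O(n^2) pairwise-comparison mid-rank percentile."""
    n = len(values)
    out = []
    for i, v in enumerate(values):
        lower = sum(1 for j, w in enumerate(values) if w < v)
        ties = sum(1 for j, w in enumerate(values) if j != i and w == v)
        out.append(100.0 * (lower + 0.5 * ties) / (n - 1))
    return out


class TestPercentileRank:
    def _rank(self, values, scope="bin"):
        df = pd.DataFrame({"S1": values}, index=[f"g{i}" for i in range(len(values))])
        expr = ExpressionMatrix(df, "TPM")
        bins = {g: "b1" for g in df.index}
        return percentile_rank(expr, bins, scope=scope)

    def test_unique_maximum_is_100(self):
        out = self._rank([1.0, 2.0, 3.0, 10.0]).set_index("gene_id")
        assert out.loc["g3", "percentile"] == 100.0
        assert out.loc["g3", "high_expression"]

    def test_all_tied_is_50(self):
        out = self._rank([5.0, 5.0, 5.0])
        assert (out["percentile"] == 50.0).all()
        assert not out["high_expression"].any()

    def test_matches_pairwise_oracle(self, rng):
        values = list(rng.lognormal(0, 2, size=25).round(1))  # rounding forces ties
        out = self._rank(values)
        np.testing.assert_allclose(out["percentile"], percentile_oracle(values))

    def test_single_gene_bin_flagged_na(self):
        out = self._rank([3.0])
        assert np.isnan(out["percentile"].iloc[0])
        assert not out["high_expression"].iloc[0]

    def test_invariant_under_monotone_transform(self, rng):
        values = rng.lognormal(0, 1, size=30)
        a = self._rank(list(values))["percentile"]
        b = self._rank(list(np.exp(values) + 7))["percentile"]
        np.testing.assert_allclose(a, b)

    def test_high_call_is_strictly_above_threshold(self):
        # with n=11 distinct values the ranks are exactly 0,10,...,100
        out = self._rank(list(range(11))).set_index("gene_id")
        assert not out.loc["g9", "high_expression"]  # exactly 90
        assert out.loc["g10", "high_expression"]


class TestSeries:
    def test_max_normalize(self):
        np.testing.assert_allclose(max_normalize_series([2, 4, 8]), [0.25, 0.5, 1.0])

    def test_constant_series(self):
        np.testing.assert_allclose(max_normalize_series([3.0, 3.0, 3.0]), [1, 1, 1])

    def test_preserves_order(self, rng):
        values = rng.lognormal(0, 1, size=20)
        out = max_normalize_series(values)
        assert out.max() == 1.0
        assert (np.argsort(out) == np.argsort(values)).all()

    def test_all_zero_series_is_error(self):
        with pytest.raises(ValueError, match="positive"):
            max_normalize_series([0.0, 0.0])

    def test_fold_change_reference_is_one(self):
        fc = fold_change_series([2.0, 7.0, 4.0])
        assert fc.folds[0] == 1.0
        assert fc.folds[1] == 3.5
        assert fc.max_fold == 3.5

    def test_constant_series_fold_one(self):
        fc = fold_change_series([4.0, 4.0, 4.0])
        assert fc.max_fold == 1.0 and fc.defined

    def test_zero_reference_flagged_undefined(self):
        fc = fold_change_series([0.0, 5.0])
        assert not fc.defined
        assert np.isnan(fc.max_fold)


class TestGenesetMeans:
    def test_single_gene(self):
        df = pd.DataFrame({"S1": [4.0]}, index=["g0"])
        expr = ExpressionMatrix(df, "constitutive_normalized")
        means = geneset_mean_expression(expr, {"bc1": ["bc1"]}, {"g0": "bc1"})
        assert means == {"bc1": 4.0}

    def test_ratio_between_sets(self):
        df = pd.DataFrame({"S1": [2.0, 4.0, 1.0]}, index=["a1", "a2", "b1"])
        expr = ExpressionMatrix(df, "constitutive_normalized")
        labels = {"a1": "bc1", "a2": "bc1", "b1": "ACIII"}
        bins = {g: "bin1" for g in df.index}
        ratios = geneset_ratio_per_bin(expr, ["bc1"], ["ACIII"], labels, bins)
        assert ratios["bin1"] == 3.0

    def test_mean_matches_bruteforce(self, rng):
        values = rng.lognormal(0, 1, size=10)
        df = pd.DataFrame({"S1": values}, index=[f"g{i}" for i in range(10)])
        expr = ExpressionMatrix(df, "constitutive_normalized")
        labels = {f"g{i}": "cyc1" for i in range(10)}
        means = geneset_mean_expression(expr, {"cyc1": ["cyc1"]}, labels)
        assert means["cyc1"] == pytest.approx(values.sum() / 10)

    def test_empty_set_is_nan(self):
        df = pd.DataFrame({"S1": [1.0]}, index=["g0"])
        expr = ExpressionMatrix(df, "constitutive_normalized")
        means = geneset_mean_expression(expr, {"x": ["missing"]}, {})
        assert np.isnan(means["x"])
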