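"""Partition-null variance, enrichment, KS and Fisher lengthening tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from batseq.nulltests import (enrichment_binomial_test,
                              fisher_lengthening_test, ks_partition_test,
                              partition_null_variance_test)


class TestPartitionNullVariance:
    def test_extreme_alternating_ratios(self):
        """Cells at ratio 0 or 1 with K = 50 vastly exceed the null."""
        K = np.full(20, 50)
        k1 = np.where(np.arange(20) % 2 == 0, 50, 0)
        res = partition_null_variance_test(k1, K, n_sim=1000, seed=0)
        assert res.p_hat == pytest.approx(0.5)
        assert res.observed_variance == pytest.approx(0.25)
        assert res.exceeds
        assert res.p_value == pytest.approx(1 / 1001)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        K = rng.poisson(10, 15) + 1
        k1 = rng.binomial(K, 0.4)
        a = partition_null_variance_test(k1, K, n_sim=500, seed=42)
        b = partition_null_variance_test(k1, K, n_sim=500, seed=42)
        assert a.observed_variance == b.observed_variance
        assert np.array_equal(a.null_variances, b.null_variances)
        assert a.p_value == b.p_value

    def test_too_few_informative_cells(self):
        with pytest.raises(ValueError, match="3 cells"):
            partition_null_variance_test([1, 0], [2, 0], n_sim=10)

    def test_null_data_exceeds_about_half_the_time(self):
        """Data generated from the shared-preference conditional null
        exceeds its null median in about half the replicates."""
        rng = np.random.default_rng(3)
        flags = []
        for _ in range(300):
            K = rng.poisson(8, 20) + 1
            k1 = rng.binomial(K, 0.3)
            res = partition_null_variance_test(k1, K, n_sim=200,
                                               seed=int(rng.integers(2**31)))
            flags.append(res.exceeds)
        rate = np.mean(flags)
        assert 0.40 < rate < 0.60


class TestEnrichmentBinomial:
    def test_all_exceed_closed_form(self):
        assert enrichment_binomial_test([True] * 10) == pytest.approx(2**-10)

    def test_half_exceed_not_significant(self):
        p = enrichment_binomial_test([True] * 5 + [False] * 5)
        assert p > 0.5

    def test_matches_exact_binomial_tail(self):
        """P for 300/493 equals the exact integer-arithmetic tail."""
        flags = [True] * 300 + [False] * 193
        want = sum(math.comb(493, k) for k in range(300, 494)) / 2 ** 493
        assert enrichment_binomial_test(flags) == pytest.approx(
            want, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            enrichment_binomial_test([])


class TestKsPartition:
    def test_degenerate_identical_distributions(self):
        """All cells purely long isoform: measured and simulated ratios
        are identical, KS statistic 0."""
        totals = np.full(12, 10)
        res = ks_partition_test(totals.copy(), totals, n_sim=50, seed=0,
                                n_null_reps=49)
        assert res.statistic == 0.0
        assert res.p_value > 0.9

    def test_bimodal_ratios_strongly_rejected(self):
        totals = np.full(30, 40)
        long_counts = np.where(np.arange(30) % 2 == 0, 40, 0)
        res = ks_partition_test(long_counts, totals, n_sim=200, seed=1,
                                n_null_reps=1999)
        assert res.p_value < 1e-3

    def test_all_zero_totals_error(self):
        with pytest.raises(ValueError):
            ks_partition_test(np.zeros(5), np.zeros(5))

    def test_null_pvalues_roughly_uniform(self):
        """Monte-Carlo calibrated P is approximately uniform when the
        measured ratios themselves come from the null."""
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(100)          :
            totals = rng.poisson(40, 25) + 1
            long_counts = rng.binomial(totals, 0.4)
            res = ks_partition_test(long_counts, totals, n_sim=100,
                                    seed=int(rng.integers(2**31)),
                                    n_null_reps=99)
            pvals.append(res.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestFisherLengthening:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "long_a", "short_a",
                                           "long_b", "short_b"])

    def test_balanced_table_ns(self):
        res = fisher_lengthening_test(self._table([("g", 10, 10, 10, 10)]))
        assert res.loc[0, "class"] == "ns"
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_extreme_table_matches_hypergeometric(self):
        res = fisher_lengthening_test(self._table([("g", 0, 20, 20, 0)]))
        # two-sided P of [[20, 0], [0, 20]] from hypergeometric enumeration
        want = 2 * stats.hypergeom.pmf(20, 40, 20, 20)
        assert res.loc[0, "p_value"] == pytest.approx(want, rel=1e-10)
        assert res.loc[0, "class"] == "long_up"

    def test_population_swap_flips_class(self):
        base = self._table([("g", 5, 40, 40, 5)])
        swapped = self._table([("g", 40, 5, 5, 40)])
        a = fisher_lengthening_test(base).loc[0, "class"]
        b = fisher_lengthening_test(swapped).loc[0, "class"]
        assert {a, b} == {"long_up", "short_up"}

    def test_zero_margin_ns(self):
        res = fisher_lengthening_test(self._table([("g", 0, 0, 3, 4)]))
        assert res.loc[0, "class"] == "ns"
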