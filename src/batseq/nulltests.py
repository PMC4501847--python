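"""Frequentist companions to the Bayesian isoform-preference models.

All null simulations condition on the observed per-cell totals K_gc: given
the totals, the isoform split under "random partitioning + technical noise
only" is exactly Binomial(K_gc, p) with a shared preference p (the
multinomial collapse of per-molecule choice and capture).  Conditioning
removes the nuisance parameters mu, cv and beta from the conditional null.

Provided tests:

* :func:`partition_null_variance_test` - per-gene comparison of the
  observed across-cell variance of isoform ratios with its simulated
  shared-preference null;
* :func:`enrichment_binomial_test` - population-level binomial test of how
  many genes exceed their null median (null proportion 0.5);
* :func:`ks_partition_test` - smFISH-style comparison of a measured ratio
  distribution against the partition-only null (Monte-Carlo calibrated KS);
* :func:`fisher_lengthening_test` - Fisher's exact test for 3' UTR
  lengthening/shortening between two pooled populations.

Every test is a pure function of its inputs and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GeneVarianceTestResult", "partition_null_variance_test",
           "enrichment_binomial_test", "ks_partition_test",
           "fisher_lengthening_test", "KsTestResult"]


@dataclass
class GeneVarianceTestResult:
    observed_variance: float
    null_variances: np.ndarray
    exceeds: bool                 # observed > null median (one-sided)
    p_value: float                # add-one empirical tail probability
    p_hat: float
    n_cells: int
    n_sim: int


def partition_null_variance_test(k1: np.ndarray, K: np.ndarray,
                                 n_sim: int = 1000, seed: int = 0,
                                 p_hat: float | None = None,
                                 exceed_ref: str = "median"
                                 ) -> GeneVarianceTestResult:
    """Per-gene variance test against the shared-preference null.

    ``k1``/``K`` are one gene's per-cell isoform-1 and total counts; cells
    with K == 0 are uninformative and dropped (at least 3 must remain).
    The shared preference defaults to the pooled fraction sum(k1)/sum(K).
    Each of ``n_sim`` simulations redraws k1* ~ Binomial(K_c, p_hat) per
    cell, conditioning on the observed totals, and records the across-cell
    variance of k1*/K.  The gene "exceeds" when the observed variance is
    above the null median; the one-sided empirical P uses the add-one rule.
    """
    k1 = np.asarray(k1, dtype=np.int64)
    K = np.asarray(K, dtype=np.int64)
    informative = K >= 1
    k1, K = k1[informative], K[informative]
    if len(K) < 3:
        raise ValueError("need at least 3 cells with observed molecules")
    if p_hat is None:
        p_hat = float(k1.sum()) / float(K.sum())
    rng = np.random.default_rng(seed)
    obs_var = float(np.var(k1 / K, ddof=0))
    sims = rng.binomial(K[None, :], p_hat, size=(n_sim, len(K)))
    null_vars = np.var(sims / K[None, :], axis=1, ddof=0)
    ref = np.median(null_vars) if exceed_ref == "median" \
        else np.mean(null_vars)
    r = int(np.sum(null_vars >= obs_var))
    return GeneVarianceTestResult(
        observed_variance=obs_var, null_variances=null_vars,
        exceeds=bool(obs_var > ref), p_value=(r + 1) / (n_sim + 1),
        p_hat=p_hat, n_cells=len(K), n_sim=n_sim)


def enrichment_binomial_test(exceeds: np.ndarray | list[bool],
                             null_prop: float = 0.5) -> float:
    """One-sided binomial P for enrichment of genes exceeding their null.

    Under the shared-preference model the observed variance falls above
    its null median with probability 1/2, so the number of exceeding genes
    is Binomial(n_genes, 0.5); the alternative is an excess.
    """
    flags = np.asarray(exceeds, dtype=bool)
    if flags.size == 0:
        raise ValueError("need at least one gene")
    return float(stats.binomtest(int(flags.sum()), flags.size, null_prop,
                                 alternative="greater").pvalue)


@dataclass
class KsTestResult:
    statistic: float
    p_value: float                # Monte-Carlo calibrated
    p_value_asymptotic: float     # scipy two-sample KS (conservative w/ ties)
    p_hat: float
    n_cells: int


def ks_partition_test(long_counts: np.ndarray, totals: np.ndarray,
                      n_sim: int = 1000, seed: int = 0,
                      n_null_reps: int = 199) -> KsTestResult:
    """Kolmogorov-Smirnov comparison against the partition-only null.

    For full molecule counts (smFISH regime, no capture thinning) the null
    of no preference variability says each cell's long-isoform count is
    Binomial(total_c, p_hat) with the pooled p_hat.  A reference null
    sample of per-cell ratios is built from ``n_sim`` conditional
    simulations, and the measured-vs-reference two-sample KS statistic is
    calibrated against ``n_null_reps`` same-sized null datasets, yielding
    an add-one Monte-Carlo P that stays exact under the heavy ties of
    discrete ratios (the asymptotic KS P is also reported).
    """
    long_counts = np.asarray(long_counts, dtype=np.int64)
    totals = np.asarray(totals, dtype=np.int64)
    if np.all(totals == 0):
        raise ValueError("all totals are zero")
    keep = totals > 0
    long_counts, totals = long_counts[keep], totals[keep]
    p_hat = float(long_counts.sum()) / float(totals.sum())
    rng = np.random.default_rng(seed)
    measured = long_counts / totals

    def reference(p):
        sims = rng.binomial(totals[None, :], p, size=(n_sim, len(totals)))
        return (sims / totals[None, :]).ravel()

    ref = reference(p_hat)
    ks = stats.ks_2samp(measured, ref)

    # parametric bootstrap of the whole procedure: each null replicate
    # re-estimates its own pooled preference, mirroring the plug-in step
    null_stats = np.empty(n_null_reps)
    for b in range(n_null_reps):
        fake = rng.binomial(totals, p_hat)
        p_b = float(fake.sum()) / float(totals.sum())
        null_stats[b] = stats.ks_2samp(fake / totals,
                                       reference(p_b)).statistic
    p_mc = (1 + int(np.sum(null_stats >= ks.statistic))) / (n_null_reps + 1)
    return KsTestResult(statistic=float(ks.statistic), p_value=float(p_mc),
                        p_value_asymptotic=float(ks.pvalue), p_hat=p_hat,
                        n_cells=len(totals))


def fisher_lengthening_test(counts: pd.DataFrame, alpha: float = 0.05
                            ) -> pd.DataFrame:
    """Per-gene Fisher's exact test for 3' UTR length shifts between two
    pooled populations.

    ``counts`` needs columns ``gene_id, long_a, short_a, long_b, short_b``
    (molecule counts summed over the cells of populations A and B).  Each
    gene's 2x2 table [[long_b, long_a], [short_b, short_a]] is tested
    two-sided; when P < ``alpha`` the gene is classed "long_up" (longer
    isoform relatively more used in B) or "short_up" by the direction of
    the odds ratio, otherwise "ns".  Zero-margin tables are "ns".
    """
    out = []
    for row in counts.itertuples(index=False):
        table = np.array([[row.long_b, row.long_a],
                          [row.short_b, row.short_a]], dtype=np.int64)
        if np.any(table < 0):
            raise ValueError("counts must be non-negative")
        if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
            out.append((row.gene_id, np.nan, 1.0, "ns"))
            continue
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        if p < alpha:
            frac_b = row.long_b / (row.long_b + row.short_b)
            frac_a = row.long_a / (row.long_a + row.short_a)
            cls = "long_up" if frac_b > frac_a else "short_up"
        else:
            cls = "ns"
        out.append((row.gene_id, odds, p, cls))
    return pd.DataFrame(out, columns=["gene_id", "odds_ratio", "p_value",
                                      "class"])
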