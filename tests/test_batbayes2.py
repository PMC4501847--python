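"""Factor-model clustering and preference-PCA tests."""

import warnings

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from batseq.batbayes import McmcConfig, ObservedIsoforms
from batseq.batbayes2 import (detect_correlated_component, fit_factor_model,
                              project_preferences_pca)
from batseq.synth import simulate_two_population_counts

CFG = McmcConfig(chains=2, iters=1200, warmup=600, seed=77)


def _fit(data, beta, cfg=CFG):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_factor_model(data, beta, cfg)


class TestProjectPreferencesPca:
    def test_identical_columns_at_origin(self):
        prefs = np.tile(np.random.default_rng(0).normal(size=(8, 1)), (1, 6))
        coords, _ = project_preferences_pca(prefs)
        assert np.allclose(coords, 0.0)

    def test_two_blocks_separated_on_pc1(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(10, 1))
        shift = rng.normal(size=(10, 1))
        prefs = np.hstack([np.tile(base, (1, 4)),
                           np.tile(base + shift, (1, 4))])
        coords, evr = project_preferences_pca(prefs)
        pc1 = coords[:, 0]
        assert max(pc1[:4]) < min(pc1[4:]) or min(pc1[:4]) > max(pc1[4:])
        assert evr[0] > 0.99

    def test_matches_eigendecomposition_oracle(self):
        """PCA coordinates equal scores from an explicit eigendecomposition
        of the cell-cell covariance, up to sign."""
        rng = np.random.default_rng(2)
        prefs = rng.normal(size=(20, 9))
        coords, _ = project_preferences_pca(prefs)
        X = prefs - prefs.mean(axis=1, keepdims=True)
        Xc = X.T - X.T.mean(axis=0)
        vals, vecs = np.linalg.eigh(Xc @ Xc.T)
        order = np.argsort(vals)[::-1]
        for j in range(2):
            v = vecs[:, order[j]] * np.sqrt(vals[order[j]])
            match = min(np.max(np.abs(coords[:, j] - v)),
                        np.max(np.abs(coords[:, j] + v)))
            assert match < 1e-8

    def test_rank_deficient_returns_fewer_components(self):
        prefs = np.ones((5, 3))
        prefs[0] = [1.0, 2.0, 3.0]
        coords, evr = project_preferences_pca(prefs, n_components=2)
        assert coords.shape[1] == 1


class TestFitFactorModel:
    def test_coordinated_shift_separates_populations(self):
        data, beta, labels = simulate_two_population_counts(
            n_genes=40, n_cells=40, shift=1.2, seed=10)
        ff = _fit(data, beta)
        s = ff.scores
        assert mannwhitneyu(s[labels == 0], s[labels == 1]).pvalue < 1e-5
        # scores are standardised
        assert s.std() == pytest.approx(1.0, abs=1e-6)

    def test_sign_anchor_positive(self):
        data, beta, _ = simulate_two_population_counts(seed=11)
        ff = _fit(data, beta)
        anchored = ff.loading_draws[..., ff.anchor_gene]
        assert np.all(anchored >= 0)

    def test_null_loadings_cover_zero(self):
        """Without a correlated component the loading posteriors
        concentrate around zero for most genes."""
        data, beta, _ = simulate_two_population_counts(
            n_genes=30, n_cells=30, preference_shift=False, seed=12)
        ff = _fit(data, beta)
        lam = ff.loading_draws.reshape(-1, 30)
        lo, hi = np.percentile(lam, [5, 95], axis=0)
        assert np.mean((lo <= 0) & (0 <= hi)) > 0.7

    def test_single_cell_rejected(self):
        data = ObservedIsoforms(np.array([[3]]), np.array([[1]]))
        with pytest.raises(ValueError, match="2 cells"):
            fit_factor_model(data, np.array([0.5]))


class TestDetectCorrelatedComponent:
    def test_no_evidence_on_uncorrelated_data(self):
        hits = 0
        for seed in (0, 1, 2):
            data, beta, _ = simulate_two_population_counts(
                n_genes=30, n_cells=30, preference_shift=False,
                seed=40 + seed)
            cfg = McmcConfig(chains=2, iters=1000, warmup=500,
                             seed=500 + seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = detect_correlated_component(data, beta, cfg)
            hits += res.evidence
        assert hits <= 1

    def test_evidence_on_strong_half_gene_shift(self):
        """Coordinated strong shifts on half the genes are detectable."""
        rng = np.random.default_rng(3)
        data, beta, labels = simulate_two_population_counts(
            n_genes=30, n_cells=30, shift=2.0, seed=44)
        # silence loadings of half the genes by regenerating them as
        # preference-shift-free: overwrite with a null dataset's counts
        null, _, _ = simulate_two_population_counts(
            n_genes=30, n_cells=30, preference_shift=False, seed=44)
        k1 = np.vstack([data.k1[:15], null.k1[15:]])
        k2 = np.vstack([data.k2[:15], null.k2[15:]])
        mixed = ObservedIsoforms(k1, k2)
        cfg = McmcConfig(chains=2, iters=1000, warmup=500, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = detect_correlated_component(mixed, beta, cfg)
        assert res.evidence
        assert res.share_observed[0] > res.share_null[0]

    def test_power_caveat_attached(self):
        data, beta, _ = simulate_two_population_counts(
            n_genes=20, n_cells=20, preference_shift=False, seed=60)
        cfg = McmcConfig(chains=2, iters=600, warmup=300, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = detect_correlated_component(data, beta, cfg)
        assert "half of the genes" in res.caveat
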