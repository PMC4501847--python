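"""Correlated-preference factor model and preference-based cell clustering.

The extension adds one latent factor to the preference layer:

    logit p_gc = eta_g + lambda_g * s_c + eps_gc,   eps ~ N(0, sigma_g)

Per-cell scores s_c order cells along the dominant axis of coordinated
3'-isoform-preference change (e.g. global UTR lengthening); per-gene
loadings lambda_g say how strongly, and in which direction, each gene
follows that axis.  Expression levels enter the likelihood only through
the totals K_gc, which carry no information about the factor, so the
clustering depends on isoform usage alone.

The likelihood is invariant under (lambda, s) -> (-lambda, -s) and
(c * lambda, s / c); draws are standardised to SD(s) = 1 and the sign is
anchored so the gene with the largest |loading| posterior mean is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._gibbs import McmcConfig, PriorConfig, run_chain
from .batbayes import (BatBayesParams, ObservedIsoforms, PosteriorFit,
                       fit_model, simulate_dataset)

__all__ = ["FactorFit", "fit_factor_model", "detect_correlated_component",
           "project_preferences_pca"]


@dataclass
class FactorFit:
    scores: np.ndarray            # posterior mean s_c, SD standardised to 1
    loadings: np.ndarray          # posterior mean lambda_g (logit units)
    score_draws: np.ndarray       # (chains, draws, cells)
    loading_draws: np.ndarray     # (chains, draws, genes)
    sigma_resid: np.ndarray       # posterior mean residual SD per gene
    anchor_gene: int              # index whose loading is held positive
    cell_ids: list[str] | None = None
    gene_ids: list[str] | None = None
    fit: PosteriorFit | None = None

    def scores_frame(self) -> pd.DataFrame:
        idx = self.cell_ids or list(range(len(self.scores)))
        return pd.DataFrame({"cell_id": idx, "score": self.scores})

    def loadings_frame(self) -> pd.DataFrame:
        idx = self.gene_ids or list(range(len(self.loadings)))
        return pd.DataFrame({"gene_id": idx, "loading": self.loadings,
                             "sigma_resid": self.sigma_resid})

    def variance_share_draws(self) -> np.ndarray:
        """Posterior draws of the mean share of preference variance that
        the factor explains: mean_g lambda_g^2 / (lambda_g^2 + sigma_g^2)
        (scores standardised to unit variance)."""
        lam2 = self.loading_draws ** 2
        sig2 = self.fit.draws["sigma_g"] ** 2
        return (lam2 / (lam2 + sig2)).mean(axis=-1)


def fit_factor_model(data: ObservedIsoforms, beta: np.ndarray,
                     config: McmcConfig | None = None,
                     priors: PriorConfig | None = None) -> FactorFit:
    """Fit the one-factor correlated-preference model by MCMC.

    Requires at least two cells (the factor is unidentifiable from one);
    ten or more genes are recommended for a stable loading direction.
    """
    config = config or McmcConfig()
    priors = priors or PriorConfig()
    if data.shape[1] < 2:
        raise ValueError("factor model needs at least 2 cells")
    if data.shape[0] < 10:
        warnings.warn("fewer than 10 genes; factor direction may be "
                      "poorly identified", stacklevel=2)
    beta = np.resize(np.asarray(beta, float), data.shape[1])
    nonzero = data.K.sum(axis=1) > 0
    k1, k2 = data.k1[nonzero], data.k2[nonzero]

    chains = []
    ss = np.random.SeedSequence(config.seed)
    for child in ss.spawn(config.chains):
        rng = np.random.default_rng(child)
        chains.append(run_chain("factor", k1, k2, beta, priors, config, rng,
                                sigma_mode="hierarchical"))

    lam = np.stack([c.lam for c in chains])     # (chains, draws, G)
    s = np.stack([c.s for c in chains])         # (chains, draws, C)
    # sign anchor: gene with the largest mean absolute loading
    anchor = int(np.argmax(np.abs(lam).mean(axis=(0, 1))))
    flip = np.sign(lam[..., anchor])[..., None]
    flip[flip == 0] = 1.0
    lam = lam * flip
    s = s * flip

    draws = {"mu": np.stack([c.mu for c in chains]),
             "cv": np.stack([c.cv for c in chains]),
             "eta": np.stack([c.eta for c in chains]),
             "sigma": np.stack([c.sigma for c in chains]),
             "tau": np.stack([c.tau for c in chains]),
             "sigma_g": np.stack([c.sigma_g for c in chains]),
             "lambda": lam, "s": s}
    n_total = sum(c.n_saved for c in chains)
    p_mean = sum(c.p_sum for c in chains) / n_total
    p_sq = sum(c.p_sq_sum for c in chains) / n_total
    fit = PosteriorFit(
        model="factor", draws=draws, p_mean=p_mean,
        p_sd=np.sqrt(np.maximum(p_sq - p_mean ** 2, 0.0)),
        deviance=np.stack([c.deviance for c in chains]),
        beta=beta, cell_ids=data.cell_ids, config=config)

    scores = s.reshape(-1, s.shape[-1]).mean(axis=0)
    loadings = lam.reshape(-1, lam.shape[-1]).mean(axis=0)
    # final standardisation of the posterior-mean score vector
    sd = scores.std()
    if sd > 0:
        scores = scores / sd
        loadings = loadings * sd
    gene_ids = [g for g, keep in zip(data.gene_ids or [], nonzero) if keep] \
        or None
    return FactorFit(scores=scores, loadings=loadings, score_draws=s,
                     loading_draws=lam,
                     sigma_resid=fit.posterior_mean("sigma_g"),
                     anchor_gene=anchor, cell_ids=data.cell_ids,
                     gene_ids=gene_ids, fit=fit)


@dataclass
class DetectionResult:
    evidence: bool
    prob_exceeds_null: float
    share_observed: tuple[float, float]   # posterior mean and 90% upper
    share_null: tuple[float, float]
    caveat: str

    def to_dict(self) -> dict:
        return {"evidence": self.evidence,
                "prob_exceeds_null": self.prob_exceeds_null,
                "share_observed_mean": self.share_observed[0],
                "share_null_mean": self.share_null[0],
                "caveat": self.caveat}


_POWER_CAVEAT = ("detection requires relatively strong coordinated "
                 "preference changes across at least half of the genes; "
                 "absence of evidence does not exclude weaker or sparser "
                 "correlated variation")


def detect_correlated_component(data: ObservedIsoforms, beta: np.ndarray,
                                config: McmcConfig | None = None,
                                priors: PriorConfig | None = None,
                                prob_threshold: float = 0.95
                                ) -> DetectionResult:
    """Decide whether a correlated preference component is present.

    The factor model is fitted to the data and, as a null reference, to one
    parametric-bootstrap replicate simulated from the uncorrelated
    variable-preference model fitted to the same data.  Evidence is called
    when the posterior of the factor's mean variance share exceeds the null
    replicate's with probability >= ``prob_threshold`` (independent draw
    pairing).
    """
    config = config or McmcConfig()
    priors = priors or PriorConfig()
    beta = np.resize(np.asarray(beta, float), data.shape[1])

    obs_fit = fit_factor_model(data, beta, config, priors)
    base = fit_model(data, beta, model="variable_pref", config=config,
                     priors=priors)
    params = BatBayesParams(
        mu=base.posterior_mean("mu"), cv=base.posterior_mean("cv"),
        eta=base.posterior_mean("eta"), beta=beta,
        sigma_g=base.posterior_mean("sigma_g"))
    null_data, _ = simulate_dataset(params, data.shape[0], data.shape[1],
                                    seed=config.seed + 101)
    null_fit = fit_factor_model(null_data, beta, config, priors)

    share_obs = obs_fit.variance_share_draws().ravel()
    share_null = null_fit.variance_share_draws().ravel()
    n = min(len(share_obs), len(share_null))
    rng = np.random.default_rng(config.seed + 7)
    prob = float(np.mean(rng.permutation(share_obs)[:n]
                         > rng.permutation(share_null)[:n]))
    return DetectionResult(
        evidence=prob >= prob_threshold,
        prob_exceeds_null=prob,
        share_observed=(float(share_obs.mean()),
                        float(np.percentile(share_obs, 90))),
        share_null=(float(share_null.mean()),
                    float(np.percentile(share_null, 90))),
        caveat=_POWER_CAVEAT)


def project_preferences_pca(preferences: np.ndarray, n_components: int = 2
                            ) -> tuple[np.ndarray, np.ndarray]:
    """PCA projection of cells from posterior-mean logit preferences.

    ``preferences`` is a genes x cells matrix (logit scale); rows are
    centred and cells are scored on the leading principal components.
    Returns (cell coordinates, explained variance ratios).  Deterministic
    up to sign; the sign is fixed so each component's largest-magnitude
    coordinate is positive.  Rank-deficient input yields fewer components.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(preferences, float)
    X = X - X.mean(axis=1, keepdims=True)
    if not X.size or np.allclose(X, 0.0):
        return np.zeros((X.shape[1], n_components)), np.zeros(n_components)
    rank = int(np.linalg.matrix_rank(X))
    k = max(min(n_components, rank, X.shape[1]), 0)
    if k == 0:
        return np.zeros((X.shape[1], n_components)), np.zeros(n_components)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X.T)
    for j in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords, pca.explained_variance_ratio_
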