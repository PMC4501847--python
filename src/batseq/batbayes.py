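"""Hierarchical Bayesian models of single-cell 3' isoform preference.

The generative model per gene g and cell c has three stochastic layers:

1. expression: the true molecule count Q_gc ~ NegBin(mean mu_g,
   variance (cv_g * mu_g)^2);
2. random partitioning: each molecule independently picks isoform 1 with
   probability p_gc, the cell's isoform preference (logit p_gc ~
   Normal(eta_g, sigma_g); the shared-preference model forces sigma = 0 so
   p_gc = logistic(eta_g) in every cell);
3. technical noise: each molecule is observed with the cell's capture
   efficiency beta_c.

Because a multinomial split of a negative binomial collapses exactly, the
observed totals K_gc = k1 + k2 are NegBin(mean mu_g beta_c, same
dispersion r_g) and k1 | K is Binomial(K, p_gc); inference never needs the
latent Q.  The variable-preference model shares information across genes
through a hierarchy log sigma_g ~ Normal(log sigma, tau): sigma is the
preference-variability scale of the typical gene, the quantity whose
variance sigma^2 the analyses report.

Model comparison uses the deviance information criterion
DIC = Dbar + pD with pD = Dbar - D(posterior means), the plug-in deviance
evaluated at the posterior means of the continuous parameters (including
the per-cell preferences p_gc).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from ._gibbs import (McmcConfig, PriorConfig, dispersion_r, nb_loglik,
                     run_chain, softplus)
from .counts import IsoformCountMatrix, two_isoform_arrays

__all__ = [
    "BatBayesParams", "ObservedIsoforms", "PosteriorFit", "DicResult",
    "simulate_dataset", "observed_loglik", "fit_model", "compute_dic",
    "McmcConfig", "PriorConfig",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class BatBayesParams:
    """Generative-model parameters; arrays broadcast to (genes, cells)."""

    mu: np.ndarray                # mean molecules per cell, per gene
    cv: np.ndarray                # coefficient of variation of Q_gc
    eta: np.ndarray               # population-mean preference, logit scale
    beta: np.ndarray              # per-cell capture efficiency
    sigma: float = 0.0            # SD of cell-level logit preference
    sigma_g: np.ndarray | None = None   # gene-wise SDs (override sigma)
    p: np.ndarray | None = None   # explicit (G, C) preferences if known
    beta_iso: tuple[float, float] | None = None  # isoform-specific capture

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, float))
        self.cv = np.atleast_1d(np.asarray(self.cv, float))
        self.eta = np.atleast_1d(np.asarray(self.eta, float))
        self.beta = np.atleast_1d(np.asarray(self.beta, float))
        if np.any(self.mu <= 0) or np.any(self.cv <= 0):
            raise ValueError("mu and cv must be positive")
        if np.any((self.beta <= 0) | (self.beta > 1)):
            raise ValueError("beta must lie in (0, 1]")
        dispersion_r(self.mu, self.cv)  # validates cv^2 > 1/mu

    @property
    def n_genes(self) -> int:
        return len(self.mu)

    @property
    def n_cells(self) -> int:
        return len(self.beta)


@dataclass
class ObservedIsoforms:
    """Observed molecule counts of the two isoforms, gene x cell."""

    k1: np.ndarray
    k2: np.ndarray
    gene_ids: list[str] | None = None
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.k1 = np.asarray(self.k1)
        self.k2 = np.asarray(self.k2)
        for arr in (self.k1, self.k2):
            if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
                raise ValueError("isoform counts must be non-negative "
                                 "integers")
        if self.k1.shape != self.k2.shape:
            raise ValueError("k1 and k2 must have the same shape")
        self.k1 = self.k1.astype(np.int64)
        self.k2 = self.k2.astype(np.int64)

    @property
    def K(self) -> np.ndarray:
        return self.k1 + self.k2

    @property
    def shape(self) -> tuple[int, int]:
        return self.k1.shape

    @classmethod
    def from_matrix(cls, matrix: IsoformCountMatrix,
                    genes: list[str] | None = None) -> "ObservedIsoforms":
        genes = genes or matrix.gene_ids
        k1, k2, kept = two_isoform_arrays(matrix, genes)
        return cls(k1, k2, gene_ids=kept, cell_ids=matrix.cell_ids)


# ---------------------------------------------------------------------------
# simulation


def simulate_dataset(params: BatBayesParams, n_genes: int, n_cells: int,
                     seed: int) -> tuple[ObservedIsoforms, dict]:
    """Draw one dataset from the three-layer generative model.

    Scalar parameter entries broadcast to ``n_genes`` / ``n_cells``.
    Returns the observed counts and a truth dict with the latent molecule
    counts ``Q``, preferences ``p`` and their logits ``x``.
    """
    rng = np.random.default_rng(seed)
    mu = np.resize(params.mu, n_genes)
    cv = np.resize(params.cv, n_genes)
    eta = np.resize(params.eta, n_genes)
    beta = np.resize(params.beta, n_cells)
    r = dispersion_r(mu, cv)

    Q = rng.negative_binomial(r[:, None],
                              (r / (r + mu))[:, None],
                              size=(n_genes, n_cells))
    if params.p is not None:
        p = np.broadcast_to(params.p, (n_genes, n_cells)).copy()
        x = logit(np.clip(p, 1e-12, 1 - 1e-12))
    else:
        if params.sigma_g is not None:
            sd = np.resize(params.sigma_g, n_genes)[:, None]
        else:
            sd = params.sigma
        x = eta[:, None] + rng.normal(size=(n_genes, n_cells)) * sd
        p = expit(x)

    if params.beta_iso is not None:
        b1, b2 = params.beta_iso
        pr1 = p * b1
        k1 = rng.binomial(Q, pr1)
        rest = Q - k1
        pr2 = np.divide((1 - p) * b2, 1 - pr1, out=np.zeros_like(p),
                        where=(1 - pr1) > 0)
        k2 = rng.binomial(rest, np.clip(pr2, 0, 1))
    else:
        pr1 = p * beta[None, :]
        k1 = rng.binomial(Q, pr1)
        rest = Q - k1
        pr2 = np.divide((1 - p) * beta[None, :], 1 - pr1,
                        out=np.zeros_like(p), where=(1 - pr1) > 0)
        k2 = rng.binomial(rest, np.clip(pr2, 0, 1))

    data = ObservedIsoforms(k1, k2,
                            gene_ids=[f"g{i:04d}" for i in range(n_genes)],
                            cell_ids=[f"c{j:03d}" for j in range(n_cells)])
    return data, {"Q": Q, "p": p, "x": x}


# ---------------------------------------------------------------------------
# likelihood


def observed_loglik(data: ObservedIsoforms, params: BatBayesParams) -> float:
    """Exact collapsed log-likelihood of the observed isoform counts.

    K_gc ~ NegBin(mean mu_g beta_c, dispersion r_g) and
    k1 | K ~ Binomial(K, p_gc); equals the sum over the latent molecule
    count Q and all latent partitions (multinomial collapse identity).
    """
    k1, k2 = data.k1, data.k2
    K = data.K
    G, C = K.shape
    mu = np.resize(params.mu, G)
    cv = np.resize(params.cv, G)
    beta = np.resize(params.beta, C)
    if params.p is not None:
        p = np.broadcast_to(params.p, (G, C))
    else:
        if params.sigma != 0 or params.sigma_g is not None:
            raise ValueError("observed_loglik needs explicit p when "
                             "preferences vary (sigma > 0)")
        p = np.broadcast_to(expit(np.resize(params.eta, G))[:, None], (G, C))
    r = dispersion_r(mu, cv)
    nb = nb_loglik(K, mu[:, None] * beta[None, :], r[:, None])
    x = logit(np.clip(p, 1e-300, 1 - 1e-16))
    binom = (gammaln(K + 1) - gammaln(k1 + 1) - gammaln(k2 + 1)
             + k1 * x - K * softplus(x))
    return float(np.sum(nb) + np.sum(binom))


# ---------------------------------------------------------------------------
# fitting


@dataclass
class PosteriorFit:
    """MCMC draws and summaries for one fitted model."""

    model: str
    draws: dict[str, np.ndarray]      # name -> (chains, draws[, genes])
    p_mean: np.ndarray                # posterior mean preference (G, C)
    p_sd: np.ndarray
    deviance: np.ndarray              # (chains, draws)
    beta: np.ndarray
    gene_ids: list[str] | None = None
    cell_ids: list[str] | None = None
    sigma_mode: str = "hierarchical"
    config: McmcConfig | None = None

    def posterior_mean(self, name: str) -> np.ndarray | float:
        d = self.draws[name]
        out = d.reshape(-1, *d.shape[2:]).mean(axis=0)
        return float(out) if np.ndim(out) == 0 else out

    @property
    def preference_variance_draws(self) -> np.ndarray:
        """Draws of the preference variance sigma^2 of the typical gene."""
        if "sigma" not in self.draws:
            raise ValueError("shared-preference model has no sigma")
        return self.draws["sigma"] ** 2

    def rhat(self, name: str) -> np.ndarray | float:
        import arviz as az

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = az.rhat(az.convert_to_dataset(self.draws[name]))
        vals = np.asarray(r.to_array()).squeeze()
        return float(vals) if vals.ndim == 0 else vals

    def ess(self, name: str) -> np.ndarray | float:
        import arviz as az

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = az.ess(az.convert_to_dataset(self.draws[name]))
        vals = np.asarray(r.to_array()).squeeze()
        return float(vals) if vals.ndim == 0 else vals

    def summary(self, names: tuple[str, ...] = ("mu", "cv", "eta", "sigma")
                ) -> pd.DataFrame:
        rows = []
        qs = (2.5, 16.5, 83.5, 97.5)
        for name in names:
            if name not in self.draws:
                continue
            d = self.draws[name]
            flat = d.reshape(-1, *d.shape[2:])
            if flat.ndim == 1:
                flat = flat[:, None]
            rh = np.atleast_1d(self.rhat(name))
            es = np.atleast_1d(self.ess(name))
            for j in range(flat.shape[1]):
                label = name if flat.shape[1] == 1 else f"{name}[{j}]"
                q = np.percentile(flat[:, j], qs)
                rows.append((label, flat[:, j].mean(), flat[:, j].std(),
                             *q, rh[j] if j < len(rh) else np.nan,
                             es[j] if j < len(es) else np.nan))
        return pd.DataFrame(rows, columns=[
            "parameter", "mean", "sd", "q2.5", "q16.5", "q83.5", "q97.5",
            "rhat", "ess"])

    def to_tsv(self, path: str,
               names: tuple[str, ...] = ("mu", "cv", "eta", "sigma", "tau")
               ) -> None:
        self.summary(names).to_csv(path, sep="\t", index=False)


def fit_model(data: ObservedIsoforms, beta: np.ndarray,
              model: str = "variable_pref",
              config: McmcConfig | None = None,
              priors: PriorConfig | None = None,
              sigma_mode: str = "hierarchical",
              fix_sigma: float | None = None) -> PosteriorFit:
    """Fit the shared- or variable-preference model by MCMC.

    Parameters
    ----------
    data : observed two-isoform counts (gene x cell).
    beta : per-cell capture efficiencies, treated as known constants.
    model : "shared_pref" (identical preference in all cells) or
        "variable_pref" (cell-level logit preferences with gene-wise SDs
        tied together hierarchically).
    sigma_mode : "hierarchical" (log sigma_g ~ Normal(log sigma, tau)) or
        "pooled" (a single sigma for all genes).

    All-zero genes are dropped with a warning; convergence is flagged
    (warning, not failure) when the split-Rhat of any monitored scalar
    exceeds 1.05.
    """
    if model not in ("shared_pref", "variable_pref"):
        raise ValueError(f"unknown model {model!r}")
    config = config or McmcConfig()
    priors = priors or PriorConfig()
    if fix_sigma is not None:
        sigma_mode = "pooled"
    beta = np.resize(np.asarray(beta, float), data.shape[1])
    if data.shape[1] < 2 or data.shape[0] < 1:
        raise ValueError("need at least 2 cells and 1 gene")

    nonzero = data.K.sum(axis=1) > 0
    if not nonzero.all():
        warnings.warn(f"dropping {int((~nonzero).sum())} all-zero genes",
                      stacklevel=2)
    k1, k2 = data.k1[nonzero], data.k2[nonzero]
    gene_ids = [g for g, keep in zip(data.gene_ids or [], nonzero) if keep] \
        or None

    chains = []
    ss = np.random.SeedSequence(config.seed)
    for child in ss.spawn(config.chains):
        rng = np.random.default_rng(child)
        chains.append(run_chain(model, k1, k2, beta, priors, config, rng,
                                sigma_mode, fix_sigma=fix_sigma))

    def stack(name):
        vals = [getattr(c, name) for c in chains]
        return None if vals[0] is None else np.stack(vals)

    draws = {n: stack(n) for n in ("mu", "cv", "eta", "sigma", "tau",
                                   "sigma_g")}
    draws = {n: v for n, v in draws.items() if v is not None}
    n_total = sum(c.n_saved for c in chains)
    p_mean = sum(c.p_sum for c in chains) / n_total
    p_sq = sum(c.p_sq_sum for c in chains) / n_total
    fit = PosteriorFit(
        model=model, draws=draws, p_mean=p_mean,
        p_sd=np.sqrt(np.maximum(p_sq - p_mean ** 2, 0.0)),
        deviance=np.stack([c.deviance for c in chains]),
        beta=beta, gene_ids=gene_ids, cell_ids=data.cell_ids,
        sigma_mode=sigma_mode, config=config)
    _warn_if_not_converged(fit)
    return fit


def _warn_if_not_converged(fit: PosteriorFit, limit: float = 1.05) -> None:
    if fit.draws[next(iter(fit.draws))].shape[0] < 2:
        return
    monitored = [n for n in ("sigma", "tau") if n in fit.draws]
    for name in monitored:
        r = np.max(np.atleast_1d(fit.rhat(name)))
        if r > limit:
            warnings.warn(
                f"split-Rhat of {name} is {r:.3f} (> {limit}); consider "
                "longer chains", stacklevel=3)


# ---------------------------------------------------------------------------
# DIC


@dataclass
class DicResult:
    dic: float
    pd: float
    dbar: float
    dhat: float

    def to_dict(self) -> dict:
        return {"DIC": self.dic, "pD": self.pd, "Dbar": self.dbar,
                "Dhat": self.dhat}


def compute_dic(fit: PosteriorFit, data: ObservedIsoforms) -> DicResult:
    """Deviance information criterion with a plug-in at posterior means.

    Dbar is the posterior mean deviance; the plug-in deviance D(theta-hat)
    evaluates the collapsed likelihood at the posterior means of mu, cv and
    the per-cell preferences p_gc.  pD = Dbar - D(theta-hat); lower DIC is
    better.
    """
    n_draws = fit.deviance.size
    if n_draws < 10:
        raise ValueError("need at least 10 posterior draws for DIC")
    G = fit.p_mean.shape[0]
    if data.shape[0] != G:
        # the fit may have dropped all-zero genes
        keep = data.K.sum(axis=1) > 0
        data = ObservedIsoforms(data.k1[keep], data.k2[keep])
    params = BatBayesParams(
        mu=fit.posterior_mean("mu"), cv=fit.posterior_mean("cv"),
        eta=fit.posterior_mean("eta"), beta=fit.beta, p=fit.p_mean)
    dbar = float(fit.deviance.mean())
    dhat = -2.0 * observed_loglik(data, params)
    p_d = dbar - dhat
    return DicResult(dic=dbar + p_d, pd=p_d, dbar=dbar, dhat=dhat)
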