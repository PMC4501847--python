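"""Metropolis-within-Gibbs machinery for the isoform-preference models.

All samplers work on the collapsed observation model: the observed total
K_gc = k1 + k2 for gene g in cell c is negative-binomial with mean
mu_g * beta_c and the gene's dispersion (binomial thinning of a negative
binomial keeps the dispersion parameter r), and k1 | K is binomial with the
cell's isoform-1 preference p_gc.  Latent logit preferences x_gc are
updated element-wise by adaptive random-walk Metropolis; location/scale
parameters use conjugate draws where the conditional is Gaussian and
adaptive Metropolis elsewhere.  Step sizes adapt only during warmup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def nb_loglik(K: np.ndarray, mean: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Elementwise log pmf of NB with given mean and dispersion r."""
    return (gammaln(K + r) - gammaln(r) - gammaln(K + 1)
            + r * np.log(r / (r + mean)) + K * np.log(mean / (r + mean)))


def dispersion_r(mu: np.ndarray, cv: np.ndarray) -> np.ndarray:
    """NB dispersion r for mean mu and coefficient of variation cv.

    Var = (cv * mu)^2 = mu + mu^2 / r  requires cv^2 > 1/mu.
    """
    denom = cv ** 2 * mu - 1.0
    if np.any(denom <= 0):
        raise ValueError(
            "cv_g^2 must exceed 1/mu_g for a negative-binomial law "
            "(variance above the Poisson floor)")
    return mu / denom


@dataclass
class PriorConfig:
    eta_sd: float = 2.5           # Normal prior SD of population-mean logit
    mu_log_sd: float = 2.0        # log-normal prior SD of mu_g
    mu_log_mean: float | None = None   # None: empirical log mean of K/beta
    cv_hn_scale: float = 1.0      # half-normal prior scale of cv_g
    sigma_hn_scale: float = 1.0   # half-normal prior scale of sigma
    tau_hn_scale: float = 0.5     # half-normal prior scale of tau
    lambda_sd: float = 1.0        # Normal prior SD of factor loadings


@dataclass
class McmcConfig:
    chains: int = 4
    iters: int = 4000             # total iterations per chain
    warmup: int = 2000
    thin: int = 1
    seed: int = 0

    @property
    def n_save(self) -> int:
        return (self.iters - self.warmup) // self.thin


class _StepSize:
    """Robbins-Monro step-size adaptation toward a target acceptance."""

    def __init__(self, shape, target: float = 0.44, init: float = 0.8):
        self.log_s = np.full(shape, np.log(init))
        self.target = target
        self.t = 0

    @property
    def s(self) -> np.ndarray:
        return np.exp(self.log_s)

    def update(self, accept_prob: np.ndarray) -> None:
        self.t += 1
        gamma = min(0.25, self.t ** -0.6)
        self.log_s += gamma * (accept_prob - self.target)
        np.clip(self.log_s, -8.0, 4.0, out=self.log_s)


def _half_normal_logpdf_logscale(value: float, scale: float) -> float:
    """log density of a half-normal variate expressed in its own log.

    For v = exp(w) with v ~ HN(scale):  log p(w) = -v^2/(2 scale^2) + w
    up to a constant.
    """
    return -value ** 2 / (2.0 * scale ** 2) + np.log(value)


@dataclass
class ChainState:
    log_mu: np.ndarray
    log_cv: np.ndarray
    eta: np.ndarray
    x: np.ndarray | None = None          # logit preferences (model 2)
    log_sig_g: np.ndarray | None = None
    log_sigma: float = np.log(0.3)
    log_tau: float = np.log(0.2)
    lam: np.ndarray | None = None        # factor loadings
    s: np.ndarray | None = None          # factor scores
    nb_ll_g: np.ndarray | None = None    # cached per-gene NB loglik


def _init_state(k1, k2, beta, priors: PriorConfig, rng,
                model: str) -> ChainState:
    K = k1 + k2
    G, C = K.shape
    mu0 = np.maximum(K.mean(axis=1) / np.mean(beta), 2.0)
    log_mu = np.log(mu0) + rng.normal(0, 0.1, G)
    cv0 = np.maximum(0.7, np.sqrt(1.5 / mu0))
    log_cv = np.log(cv0) + rng.normal(0, 0.05, G)
    phat = (k1.sum(axis=1) + 1.0) / (K.sum(axis=1) + 2.0)
    eta = np.log(phat / (1 - phat)) + rng.normal(0, 0.05, G)
    st = ChainState(log_mu=log_mu, log_cv=log_cv, eta=eta)
    if model in ("variable_pref", "factor"):
        praw = (k1 + 0.5) / (K + 1.0)
        xr = np.log(praw / (1 - praw))
        st.x = eta[:, None] + 0.5 * (xr - eta[:, None]) \
            + rng.normal(0, 0.05, (G, C))
        st.log_sigma = float(np.log(0.3) + rng.normal(0, 0.1))
        st.log_tau = float(np.log(0.2) + rng.normal(0, 0.1))
        st.log_sig_g = np.full(G, st.log_sigma) + rng.normal(0, 0.05, G)
    if model == "factor":
        st.lam = rng.normal(0, 0.1, G)
        st.s = rng.normal(0, 1.0, C)
    return st


def _binom_logcoef(k1, k2):
    K = k1 + k2
    return float(np.sum(gammaln(K + 1) - gammaln(k1 + 1) - gammaln(k2 + 1)))


def _nb_ll_per_gene(K, beta, log_mu, log_cv):
    mu = np.exp(log_mu)
    cv = np.exp(log_cv)
    r = dispersion_r(mu, cv)
    return nb_loglik(K, mu[:, None] * beta[None, :], r[:, None]).sum(axis=1)


def _update_mu_cv(st: ChainState, K, beta, priors: PriorConfig, step,
                  rng, adapt: bool, mu_log_mean: float) -> None:
    G = st.log_mu.shape[0]
    s = step.s
    prop_lm = st.log_mu + s * rng.normal(size=G)
    prop_lcv = st.log_cv + s * rng.normal(size=G)
    mu_p, cv_p = np.exp(prop_lm), np.exp(prop_lcv)
    valid = cv_p ** 2 * mu_p > 1.0
    # guard invalid proposals so the vectorised NB evaluation stays finite
    safe_lcv = np.where(valid, prop_lcv,
                        np.log(np.sqrt(1.5 / mu_p)))
    ll_p = _nb_ll_per_gene(K, beta, prop_lm, safe_lcv)

    def logprior(lm, lcv):
        cv = np.exp(lcv)
        pr_mu = -(lm - mu_log_mean) ** 2 / (2 * priors.mu_log_sd ** 2)
        pr_cv = -cv ** 2 / (2 * priors.cv_hn_scale ** 2) + lcv
        return pr_mu + pr_cv

    if st.nb_ll_g is None:
        st.nb_ll_g = _nb_ll_per_gene(K, beta, st.log_mu, st.log_cv)
    log_alpha = (ll_p + logprior(prop_lm, safe_lcv)
                 - st.nb_ll_g - logprior(st.log_mu, st.log_cv))
    log_alpha = np.where(valid, log_alpha, -np.inf)
    acc = np.log(rng.random(G)) < log_alpha
    st.log_mu = np.where(acc, prop_lm, st.log_mu)
    st.log_cv = np.where(acc, safe_lcv, st.log_cv)
    st.nb_ll_g = np.where(acc, ll_p, st.nb_ll_g)
    if adapt:
        step.update(np.minimum(1.0, np.exp(log_alpha)))


def _update_x(st: ChainState, k1, K, prior_mean, prior_sd, step, rng,
              adapt: bool) -> None:
    x = st.x
    prop = x + step.s * rng.normal(size=x.shape)
    dll = (k1 * (prop - x) - K * (softplus(prop) - softplus(x))
           - ((prop - prior_mean) ** 2 - (x - prior_mean) ** 2)
           / (2 * prior_sd ** 2))
    acc = np.log(rng.random(x.shape)) < dll
    st.x = np.where(acc, prop, x)
    if adapt:
        step.update(np.minimum(1.0, np.exp(np.minimum(dll, 0.0))))


def _update_eta_model1(st: ChainState, k1, K, priors, step, rng,
                       adapt: bool) -> None:
    G = st.eta.shape[0]
    prop = st.eta + step.s * rng.normal(size=G)

    def ll(e):
        return (k1 * e[:, None] - K * softplus(e[:, None])).sum(axis=1) \
            - e ** 2 / (2 * priors.eta_sd ** 2)

    log_alpha = ll(prop) - ll(st.eta)
    acc = np.log(rng.random(G)) < log_alpha
    st.eta = np.where(acc, prop, st.eta)
    if adapt:
        step.update(np.minimum(1.0, np.exp(np.minimum(log_alpha, 0.0))))


def _update_sig_g(st: ChainState, priors, step, rng, adapt: bool,
                  resid_ss: np.ndarray, C: int) -> None:
    ls = st.log_sig_g
    prop = ls + step.s * rng.normal(size=ls.shape)

    def target(w):
        sig2 = np.exp(2 * w)
        hyper = -(w - st.log_sigma) ** 2 / (2 * np.exp(2 * st.log_tau))
        return -C * w - resid_ss / (2 * sig2) + hyper

    log_alpha = target(prop) - target(ls)
    acc = np.log(rng.random(ls.shape)) < log_alpha
    st.log_sig_g = np.where(acc, prop, ls)
    if adapt:
        step.update(np.minimum(1.0, np.exp(np.minimum(log_alpha, 0.0))))


def _update_hyper(st: ChainState, priors, steps, rng, adapt: bool) -> None:
    G = st.log_sig_g.shape[0]
    # log_sigma
    prop = st.log_sigma + steps["sigma"].s * rng.normal()

    def t_sigma(w):
        tau2 = np.exp(2 * st.log_tau)
        return (-np.sum((st.log_sig_g - w) ** 2) / (2 * tau2)
                + _half_normal_logpdf_logscale(np.exp(w),
                                               priors.sigma_hn_scale))

    la = t_sigma(prop) - t_sigma(st.log_sigma)
    if np.log(rng.random()) < la:
        st.log_sigma = float(prop)
    if adapt:
        steps["sigma"].update(np.minimum(1.0, np.exp(min(la, 0.0))))
    # log_tau
    prop = st.log_tau + steps["tau"].s * rng.normal()

    def t_tau(w):
        tau2 = np.exp(2 * w)
        return (-G * w - np.sum((st.log_sig_g - st.log_sigma) ** 2)
                / (2 * tau2)
                + _half_normal_logpdf_logscale(np.exp(w),
                                               priors.tau_hn_scale))

    la = t_tau(prop) - t_tau(st.log_tau)
    if np.log(rng.random()) < la:
        st.log_tau = float(prop)
    if adapt:
        steps["tau"].update(np.minimum(1.0, np.exp(min(la, 0.0))))


def _scale_move(st: ChainState, k1, K, priors, step, rng, adapt: bool,
                prior_mean: np.ndarray, hierarchical: bool) -> None:
    """Joint rescaling of preference residuals and their SDs.

    Proposes x' = m + c (x - m) together with log sigma(_g) + log c.  The
    Gaussian preference layer is invariant under this map (the Jacobian
    c^{G C} cancels the density rescaling), so the acceptance ratio reduces
    to the binomial-likelihood change plus the half-normal prior ratio on
    sigma.  This move decouples the mixing of sigma from the element-wise
    latent updates.
    """
    logc = float(step.s * rng.normal())
    c = np.exp(logc)
    x_new = prior_mean + c * (st.x - prior_mean)
    dll = float(np.sum(k1 * (x_new - st.x)
                       - K * (softplus(x_new) - softplus(st.x))))
    dpr = (_half_normal_logpdf_logscale(np.exp(st.log_sigma + logc),
                                        priors.sigma_hn_scale)
           - _half_normal_logpdf_logscale(np.exp(st.log_sigma),
                                          priors.sigma_hn_scale))
    la = dll + dpr
    if np.log(rng.random()) < la:
        st.x = x_new
        st.log_sigma += logc
        if hierarchical and st.log_sig_g is not None:
            st.log_sig_g = st.log_sig_g + logc
    if adapt:
        step.update(np.minimum(1.0, np.exp(min(la, 0.0))))


def _update_sigma_pooled(st: ChainState, priors, step, rng, adapt: bool,
                         resid_ss_total: float, n: int) -> None:
    prop = st.log_sigma + step.s * rng.normal()

    def target(w):
        return (-n * w - resid_ss_total / (2 * np.exp(2 * w))
                + _half_normal_logpdf_logscale(np.exp(w),
                                               priors.sigma_hn_scale))

    la = target(prop) - target(st.log_sigma)
    if np.log(rng.random()) < la:
        st.log_sigma = float(prop)
    if adapt:
        step.update(np.minimum(1.0, np.exp(min(la, 0.0))))


# ---------------------------------------------------------------------------
# chain drivers


@dataclass
class ChainDraws:
    mu: np.ndarray
    cv: np.ndarray
    eta: np.ndarray
    sigma: np.ndarray | None = None
    tau: np.ndarray | None = None
    sigma_g: np.ndarray | None = None
    lam: np.ndarray | None = None
    s: np.ndarray | None = None
    deviance: np.ndarray = None
    p_sum: np.ndarray = None
    p_sq_sum: np.ndarray = None
    n_saved: int = 0


def run_chain(model: str, k1, k2, beta, priors: PriorConfig,
              config: McmcConfig, rng, sigma_mode: str = "hierarchical",
              fix_sigma: float | None = None) -> ChainDraws:
    """One MCMC chain for 'shared_pref', 'variable_pref' or 'factor'.

    ``fix_sigma`` pins the preference SD to a constant (pooled mode, no
    sigma updates); used to check that the variable-preference model nests
    the shared one as sigma -> 0.
    """
    k1 = np.asarray(k1, float)
    k2 = np.asarray(k2, float)
    K = k1 + k2
    beta = np.asarray(beta, float)
    G, C = K.shape
    mu_log_mean = priors.mu_log_mean
    if mu_log_mean is None:
        mu_log_mean = float(np.log(np.maximum(
            K.mean() / np.mean(beta), 2.0)))
    st = _init_state(k1, k2, beta, priors, rng, model)
    if fix_sigma is not None:
        if fix_sigma <= 0:
            raise ValueError("fix_sigma must be > 0 (use shared_pref for "
                             "sigma = 0)")
        sigma_mode = "pooled"
        st.log_sigma = float(np.log(fix_sigma))
    st.nb_ll_g = _nb_ll_per_gene(K, beta, st.log_mu, st.log_cv)
    logcoef = _binom_logcoef(k1, k2)

    steps = {
        "mu_cv": _StepSize(G, target=0.3, init=0.3),
        "x": _StepSize((G, C), target=0.44, init=1.0),
        "eta1": _StepSize(G, target=0.44, init=0.3),
        "sig_g": _StepSize(G, target=0.44, init=0.4),
        "sigma": _StepSize((), target=0.44, init=0.3),
        "tau": _StepSize((), target=0.44, init=0.3),
        "scale": _StepSize((), target=0.44, init=0.1),
    }

    n_save = config.n_save
    dr = ChainDraws(
        mu=np.empty((n_save, G)), cv=np.empty((n_save, G)),
        eta=np.empty((n_save, G)),
        deviance=np.empty(n_save),
        p_sum=np.zeros((G, C)), p_sq_sum=np.zeros((G, C)))
    if model in ("variable_pref", "factor"):
        dr.sigma = np.empty(n_save)
        dr.tau = np.empty(n_save)
        dr.sigma_g = np.empty((n_save, G))
    if model == "factor":
        dr.lam = np.empty((n_save, G))
        dr.s = np.empty((n_save, C))

    save_idx = 0
    for it in range(config.iters):
        adapt = it < config.warmup
        _update_mu_cv(st, K, beta, priors, steps["mu_cv"], rng, adapt,
                      mu_log_mean)
        if model == "shared_pref":
            _update_eta_model1(st, k1, K, priors, steps["eta1"], rng, adapt)
            x_eff = np.broadcast_to(st.eta[:, None], (G, C))
        else:
            if model == "factor":
                prior_mean = st.eta[:, None] + st.lam[:, None] * st.s[None, :]
            else:
                prior_mean = np.broadcast_to(st.eta[:, None], (G, C))
            sig_g = np.exp(st.log_sig_g)[:, None] \
                if sigma_mode == "hierarchical" else np.exp(st.log_sigma)
            _update_x(st, k1, K, prior_mean, sig_g, rng=rng,
                      step=steps["x"], adapt=adapt)
            sig2_g = np.exp(2 * st.log_sig_g) \
                if sigma_mode == "hierarchical" \
                else np.full(G, np.exp(2 * st.log_sigma))
            if model == "factor":
                _update_eta_lambda(st, sig2_g, priors, rng)
                _update_scores(st, sig2_g, rng)
                resid = st.x - st.eta[:, None] - st.lam[:, None] * st.s[None, :]
            else:
                # eta_g | x conjugate
                prec = C / sig2_g + 1.0 / priors.eta_sd ** 2
                mean = (st.x.sum(axis=1) / sig2_g) / prec
                st.eta = mean + rng.normal(size=G) / np.sqrt(prec)
                resid = st.x - st.eta[:, None]
            ss_g = (resid ** 2).sum(axis=1)
            if fix_sigma is not None:
                pass  # sigma pinned; no scale updates
            elif sigma_mode == "hierarchical":
                _update_sig_g(st, priors, steps["sig_g"], rng, adapt, ss_g, C)
                _update_hyper(st, priors, steps, rng, adapt)
            else:
                _update_sigma_pooled(st, priors, steps["sigma"], rng, adapt,
                                     float(ss_g.sum()), G * C)
            if model == "factor":
                pm = st.eta[:, None] + st.lam[:, None] * st.s[None, :]
            else:
                pm = np.broadcast_to(st.eta[:, None], (G, C))
            if fix_sigma is None:
                _scale_move(st, k1, K, priors, steps["scale"], rng, adapt,
                            pm, sigma_mode == "hierarchical")
            x_eff = st.x

        if it >= config.warmup and (it - config.warmup) % config.thin == 0:
            i = save_idx
            dr.mu[i] = np.exp(st.log_mu)
            dr.cv[i] = np.exp(st.log_cv)
            dr.eta[i] = st.eta
            if model in ("variable_pref", "factor"):
                dr.sigma[i] = np.exp(st.log_sigma)
                dr.tau[i] = np.exp(st.log_tau)
                dr.sigma_g[i] = np.exp(st.log_sig_g) \
                    if sigma_mode == "hierarchical" \
                    else np.exp(st.log_sigma)
            if model == "factor":
                sd = st.s.std()
                sd = sd if sd > 0 else 1.0
                dr.lam[i] = st.lam * sd
                dr.s[i] = st.s / sd
            p = 1.0 / (1.0 + np.exp(-x_eff))
            dr.p_sum += p
            dr.p_sq_sum += p ** 2
            binom_ll = logcoef + float(
                np.sum(k1 * x_eff - K * softplus(x_eff)))
            dr.deviance[i] = -2.0 * (float(st.nb_ll_g.sum()) + binom_ll)
            save_idx += 1
            dr.n_saved = save_idx
    return dr


def _update_eta_lambda(st: ChainState, sig2_g: np.ndarray,
                       priors: PriorConfig, rng) -> None:
    """Joint conjugate draw of (eta_g, lambda_g) given x and scores."""
    s = st.s
    C = s.shape[0]
    S1, S2 = float(s.sum()), float((s ** 2).sum())
    a = C / sig2_g + 1.0 / priors.eta_sd ** 2
    b = S1 / sig2_g
    d = S2 / sig2_g + 1.0 / priors.lambda_sd ** 2
    b1 = st.x.sum(axis=1) / sig2_g
    b2 = (st.x * s[None, :]).sum(axis=1) / sig2_g
    # mean = A^{-1} b with A = [[a, b], [b, d]]
    det = a * d - b * b
    m1 = (d * b1 - b * b2) / det
    m2 = (a * b2 - b * b1) / det
    # sample via Cholesky of the precision: A = L L^T
    l11 = np.sqrt(a)
    l21 = b / l11
    l22 = np.sqrt(d - l21 ** 2)
    z1 = rng.normal(size=a.shape)
    z2 = rng.normal(size=a.shape)
    # solve L^T u = z
    u2 = z2 / l22
    u1 = (z1 - l21 * u2) / l11
    st.eta = m1 + u1
    st.lam = m2 + u2


def _update_scores(st: ChainState, sig2_g: np.ndarray, rng) -> None:
    lam = st.lam
    prec = 1.0 + np.sum(lam ** 2 / sig2_g)
    resid = st.x - st.eta[:, None]
    mean = (lam[:, None] / sig2_g[:, None] * resid).sum(axis=0) / prec
    st.s = mean + rng.normal(size=st.s.shape) / np.sqrt(prec)
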