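"""Spike-in capture-efficiency estimation and binomial-noise simulations.

Capture of an mRNA molecule by a 3'-tag library prep is modelled as
independent per-molecule thinning: each molecule of cell c is observed with
probability beta_c.  With synthetic spike-in transcripts of known input
molecule number per reaction, beta_c is the slope of a regression through
the origin of observed on known counts, clamped to [0, 1].  The companion
simulation reproduces the classic bulk-vs-summed-single-cells correlation
check: two rounds of binomial subsampling from a common pool of "true"
expression values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CaptureEfficiency:
    beta: pd.Series          # per cell, NaN when not estimable
    se: pd.Series            # slope standard error
    n_species: pd.Series
    missing: pd.Series       # True when < min_species spike species

    @property
    def mean_beta(self) -> float:
        return float(self.beta.dropna().mean())

    def to_tsv(self, path: str) -> None:
        pd.DataFrame({"cell_id": self.beta.index, "beta": self.beta.values,
                      "se": self.se.values,
                      "n_species": self.n_species.values,
                      "missing": self.missing.values}
                     ).to_csv(path, sep="\t", index=False)


def origin_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope through the origin and its standard error."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sxx = float(np.sum(x * x))
    if sxx == 0:
        return np.nan, np.nan
    slope = float(np.sum(x * y)) / sxx
    resid = y - slope * x
    dof = max(len(x) - 1, 1)
    se = float(np.sqrt(np.sum(resid ** 2) / dof / sxx))
    return slope, se


def estimate_capture_efficiency(observed: pd.DataFrame,
                                known: pd.Series,
                                min_species: int = 3,
                                weights: str = "none") -> CaptureEfficiency:
    """Per-cell capture efficiency from spike-in observations.

    Parameters
    ----------
    observed : spike_id x cell matrix of observed molecule counts.
    known : molecules spiked into each reaction, indexed by spike_id.
    weights : "none" for ordinary least squares, "poisson" for 1/known
        weighting (variance proportional to the mean under thinning).

    Capture is multiplicative thinning, so the regression is constrained
    through the origin and the slope clamped to [0, 1].  Cells observing
    fewer than ``min_species`` spike species are flagged missing.
    """
    known = known.loc[known.index.intersection(observed.index)]
    if (known <= 0).any():
        raise ValueError("known spike-in molecule numbers must be > 0")
    implaus = (observed.ge(10 * known, axis=0)).any().any()
    if implaus:
        warnings.warn("some observed spike counts exceed 10x the known "
                      "input; check the manifest", stacklevel=2)
    betas, ses, ns, miss = {}, {}, {}, {}
    for cell in observed.columns:
        y = observed.loc[known.index, cell].to_numpy(float)
        x = known.to_numpy(float)
        if weights == "poisson":
            w = 1.0 / np.sqrt(x)
            x, y = x * w, y * w
        n = len(x)
        ns[cell] = n
        if n < min_species:
            betas[cell], ses[cell], miss[cell] = np.nan, np.nan, True
            continue
        miss[cell] = False
        if np.all(y == 0):
            warnings.warn(f"cell {cell}: no spike-in molecules observed; "
                          "efficiency set to 0", stacklevel=2)
            betas[cell], ses[cell] = 0.0, 0.0
            continue
        slope, se = origin_slope(x, y)
        betas[cell] = float(np.clip(slope, 0.0, 1.0))
        ses[cell] = se
    idx = list(observed.columns)
    return CaptureEfficiency(
        beta=pd.Series(betas, index=idx, name="beta"),
        se=pd.Series(ses, index=idx, name="se"),
        n_species=pd.Series(ns, index=idx, name="n_species"),
        missing=pd.Series(miss, index=idx, name="missing"),
    )


def read_spike_manifest(path: str) -> pd.Series:
    """Spike manifest TSV: columns spike_id, molecules_per_cell_reaction."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index("spike_id")["molecules_per_cell_reaction"]


# ---------------------------------------------------------------------------
# binomial-subsampling correlation simulation


@dataclass
class ExpressionMixture:
    """Two-component log-normal mixture of true per-pool expression values.

    Defaults describe a transcriptome with a large low-expression mode and
    a smaller high-expression mode, scaled so that thinning at beta ~ 0.05
    leaves a few thousand detected genes per cell.
    """
    weights: tuple[float, float] = (0.6, 0.4)
    log_means: tuple[float, float] = (3.0, 6.0)   # natural log of molecules
    log_sds: tuple[float, float] = (1.0, 1.2)
    n_genes: int = 8_000

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        comp = rng.random(self.n_genes) < self.weights[0]
        mu = np.where(comp, self.log_means[0], self.log_means[1])
        sd = np.where(comp, self.log_sds[0], self.log_sds[1])
        return np.maximum(np.round(np.exp(rng.normal(mu, sd))), 0
                          ).astype(np.int64)


def simulate_subsampling_correlation(expr_dist: ExpressionMixture,
                                     beta_bulk: float,
                                     beta_cells: np.ndarray,
                                     n_cells: int | None = None,
                                     seed: int = 0,
                                     isoform_pref_conc: float = 5.0
                                     ) -> tuple[float, float]:
    """Correlation expected from pure binomial-loss technical noise.

    Draws true gene totals for a pool, observes them once in "bulk" at
    ``beta_bulk``, partitions them to cells and observes each cell at its
    own efficiency, and returns the Pearson correlation of log(1+count)
    between bulk and the in-silico sum of cells, at gene level and at
    isoform level (genes split into two isoforms with a fixed per-gene
    preference drawn from Beta(c, c)).
    """
    beta_cells = np.atleast_1d(np.asarray(beta_cells, float))
    if n_cells is None:
        n_cells = len(beta_cells)
    if len(beta_cells) != n_cells:
        beta_cells = np.resize(beta_cells, n_cells)
    if np.any(beta_cells <= 0) or not (0 < beta_bulk <= 1):
        raise ValueError("efficiencies must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    true = expr_dist.draw(rng)

    # split the true pool into two isoforms once, with a fixed per-gene
    # preference; bulk and single cells then observe the same pools
    pref = rng.beta(isoform_pref_conc, isoform_pref_conc, size=len(true))
    true1 = rng.binomial(true, pref)
    pools = np.stack([true1, true - true1])      # 2 x genes

    bulk = rng.binomial(pools, beta_bulk)
    cell_sum = np.zeros_like(pools)
    remaining = pools.copy()
    for c in range(n_cells):
        p_left = 1.0 / (n_cells - c)
        share = rng.binomial(remaining, p_left)
        remaining -= share
        cell_sum += rng.binomial(share, beta_cells[c])

    def _corr(a, b):
        la, lb = np.log1p(np.ravel(a)), np.log1p(np.ravel(b))
        if la.std() == 0 or lb.std() == 0:
            return 0.0
        return float(np.corrcoef(la, lb)[0, 1])

    gene_corr = _corr(bulk.sum(axis=0), cell_sum.sum(axis=0))
    isoform_corr = _corr(bulk, cell_sum)
    return gene_corr, isoform_corr
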