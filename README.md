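# batseq

Single-cell 3′-tag sequencing measures, for every gene and every cell, how
many mRNA molecules end at each polyadenylation (PA) site. Two cells from
the same homogeneous population almost never show the same isoform ratio —
but how much of that is biology? `batseq` answers this question for
researchers studying alternative polyadenylation (APA) in single cells. It
provides:

* a **read pipeline** that turns aligned 3′-tag reads into per-cell
  molecule counts over discovered PA sites (UMI deduplication at Hamming
  distance ≤ 1, internal-priming filters on downstream genomic A-content,
  greedy 12-bp PA-site merging, 20-kb downstream gene assignment);
* **capture-efficiency calibration** from RNA spike-ins (regression through
  the origin of observed on known molecule counts, per cell);
* a **hierarchical Bayesian model** that decomposes the observed variance
  of isoform ratios into three noise layers — technical loss of molecules,
  random partitioning of a finite molecule pool to isoforms, and true
  cell-to-cell variability in isoform *preference* — with DIC model
  comparison between the shared-preference and variable-preference models;
* a **one-factor extension** that discovers coordinated preference changes
  and clusters cells by 3′ isoform usage alone, independent of expression
  level, plus a PCA projection of preference estimates;
* **frequentist companions**: a per-gene partition-null variance test with
  a binomial enrichment summary, a Kolmogorov–Smirnov comparison of
  smFISH-style counts against the partition-only null, and Fisher's exact
  test for 3′ UTR lengthening between pooled populations.

## The model

For gene *g* in cell *c*, the true molecule count is

&nbsp;&nbsp;&nbsp;&nbsp;Q<sub>gc</sub> ~ NegBin(mean μ<sub>g</sub>, variance (cv<sub>g</sub> μ<sub>g</sub>)²),

each molecule independently chooses isoform 1 with the cell's preference
p<sub>gc</sub>, where

&nbsp;&nbsp;&nbsp;&nbsp;logit p<sub>gc</sub> ~ Normal(η<sub>g</sub>, σ<sub>g</sub>),&nbsp;&nbsp;&nbsp;&nbsp;log σ<sub>g</sub> ~ Normal(log σ, τ),

and each molecule is observed with the cell's capture efficiency
β<sub>c</sub> (estimated from spike-ins). The *shared-preference* model
forces σ = 0 (all cells share p<sub>g</sub> = logistic(η<sub>g</sub>)); the
*variable-preference* model lets preferences differ between cells, sharing
information across genes through the σ hierarchy. Because a multinomial
split of a negative binomial collapses exactly, the observed totals
K<sub>gc</sub> = k1 + k2 are NegBin(μ<sub>g</sub>β<sub>c</sub>, same
dispersion) and k1 | K ~ Binomial(K, p<sub>gc</sub>) — inference never
instantiates Q. The factor extension replaces the preference mean with
η<sub>g</sub> + λ<sub>g</sub>s<sub>c</sub>: per-cell scores s<sub>c</sub>
order cells along the dominant axis of coordinated 3′-choice change (e.g.
global UTR lengthening), per-gene loadings λ<sub>g</sub> give each gene's
direction and strength.

Fitting uses an adaptive Metropolis-within-Gibbs sampler (vectorised numpy;
conjugate draws for all Gaussian conditionals, a joint residual/σ scale
move for fast mixing of the variance, split-R̂ and ESS via arviz).

## Worked example

```python
import numpy as np
from batseq.synth import simulate_study_counts
from batseq.batbayes import fit_model, compute_dic, McmcConfig

# two-isoform counts for 100 genes x 40 cells at ~5% capture efficiency,
# simulated with preference variance 0.25 (sigma = 0.5)
data, beta, truth = simulate_study_counts(n_genes=100, n_cells=40,
                                          sigma=0.5, seed=7)
cfg = McmcConfig(chains=4, iters=2000, warmup=1000, seed=1)
fit2 = fit_model(data, beta, "variable_pref", cfg)
fit1 = fit_model(data, beta, "shared_pref", cfg)

v = fit2.preference_variance_draws
print(f"posterior mean preference variance: {v.mean():.3f} (true 0.250)")
print(f"95% credible interval: [{np.percentile(v, 2.5):.3f}, "
      f"{np.percentile(v, 97.5):.3f}]")
d1, d2 = compute_dic(fit1, data), compute_dic(fit2, data)
print(f"DIC shared {d1.dic:.1f} vs variable {d2.dic:.1f} "
      f"(delta {d1.dic - d2.dic:.1f})")
```

prints

```
posterior mean preference variance: 0.245 (true 0.250)
95% credible interval: [0.206, 0.283]
DIC shared 43170.8 vs variable 41240.1 (delta 1930.7)
```

The posterior recovers the generating variance, and DIC (lower is better)
correctly prefers the variable-preference model on data that truly contains
preference variability.

The same workflows are available from the shell: `batseq callpa` (reads →
counts), `batseq calibrate`, `batseq fit`, `batseq cluster`,
`batseq nulltest`, `batseq lengthening`, `batseq simulate-noise`; all
thresholds are flags with the defaults above.

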