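# Methods

## Read processing

The pipeline consumes aligned 3′-tag reads, either as SAM/BAM (cell and
molecular barcodes in `CB`/`UB` tags or read-name suffixes) or as a TSV tag
table with columns `cell_id, umi, chrom, strand, end3, mapq, read_len,
read_a_frac, read_count, unique`. Coordinates are 1-based inclusive (GTF
convention); "downstream" always means 3′ of the read's end on the read's
strand.

**Demultiplexing.** The first 7 bases of read 2 are the batch barcode, the
first 6 bases of read 1 the cell barcode and the next 8 the UMI. Terminal
A's are trimmed from read 2; pairs with fewer than 10 terminal A's are
rejected (no poly-A evidence). Unknown barcodes route to an "unassigned"
bin rather than raising.

**Alignment filters**, applied in a fixed order so every discarded read
carries exactly one machine-readable reason: non-unique alignment,
mapping quality < 30, read length < 20 bp, read A-content > 80%, excluded
contig (chrM/MT; rRNA genes are removed by annotation biotype at gene
assignment), then the internal-priming filters — > 80% A in the 15-base
or > 65% A in the 50-base genomic window downstream of the 3′ end,
evaluated on the read's strand (A on a minus-strand read is T on the
reference). Windows truncated by a contig edge are evaluated over the
available bases; fewer than 5 available bases is a conservative discard
(avoids high-variance fractions of tiny denominators).

**UMI collapsing** operates per (cell, gene): UMIs connected at Hamming
distance ≤ 1 (single-linkage over the neighbour graph, found by
enumerating the 24 single-substitution variants against a hash map) form
one molecule, anchored at the constituent with the highest read count
(ties: smaller position, then lexicographically smaller UMI). A molecule
whose constituent 3′ ends span ≥ 20 bp is discarded as a barcode
collision. The implementation is checked against an exhaustive pairwise-
distance clustering oracle on random instances.

**PA-site calling** pools molecule counts over all cells per gene
(reference sites are population-level). A pass processes positions in
ascending count order (ties: smaller coordinate first); each position
that has a surviving neighbour with a strictly higher current count
within 12 bp is eliminated and its count added to that neighbour (highest
count wins; ties merge toward the smaller coordinate). Counts are
conserved by construction. A *single* pass is not a fixed point in rare
configurations — a site can grow by absorption after a lower neighbour
was already processed, leaving a ≤ 12 bp pair — so by default passes
repeat until nothing changes, which makes the operation idempotent;
`iterate=False` gives the literal single pass. Per-cell molecule positions
are then reassigned to the nearest retained site (ties: smaller
coordinate).

**Gene assignment**: a site belongs to a gene when it overlaps the gene
span on the same strand or lies ≤ 20 kb downstream of its transcript
termination site; multiple candidates resolve to the nearest TTS (ties:
alphabetical). Otherwise the site is "antisense" (opposite-strand overlap)
or "intergenic". Cells with fewer than 1,000 total molecules are dropped
when the count matrix is built.

**Gene selection for isoform analysis** keeps genes whose two
most-expressed PA sites both have capture-corrected mean expression
(observed mean ÷ mean capture efficiency) between 8 and 1,000 molecules
per cell; the band is on the molecule scale because 8 *observed* UMIs per
cell would contradict the ~5% capture regime the protocol operates in.

## Capture-efficiency calibration

Capture is modelled as independent per-molecule thinning with a per-cell
success probability β_c. From spike-ins of known input molecule number,
β_c is the least-squares slope *through the origin* of observed on known
counts (an intercept has no physical meaning for multiplicative thinning),
clamped to [0, 1]; optional 1/√known weighting accounts for
variance-proportional-to-mean noise. Cells with fewer than 3 spike
species are flagged missing rather than estimated.

The bulk-versus-summed-single-cells simulation draws "true" per-pool gene
expression from a two-component log-normal mixture (user configuration;
the defaults give a few thousand detected genes per cell at β ≈ 0.05),
splits each gene's pool into two isoforms once with a fixed per-gene
preference, then observes the same pools twice — one binomial subsample
at the bulk efficiency, and a per-cell partition followed by per-cell
thinning, summed in silico. Splitting before either observation matters:
both measurements must share the partitioning noise of the true isoform
pools. Reported values are Pearson correlations of log(1 + count).

## The preference models

Per gene g and cell c: Q_gc ~ NegBin(mean μ_g, variance (cv_g μ_g)²) with
dispersion r_g = μ_g / (cv_g² μ_g − 1), which requires cv_g² > 1/μ_g
(variance above the Poisson floor; violations raise). Each molecule picks
isoform 1 with probability p_gc and is observed with probability β_c.
The multinomial collapse identity makes the observed likelihood exact
without latent molecule counts:

    K_gc = k1 + k2 ~ NegBin(mean μ_g β_c, dispersion r_g)
    k1 | K ~ Binomial(K_gc, p_gc)

(binomial thinning of a negative binomial preserves r). This is verified
against an exhaustive sum over Q and latent partitions to 1e-8.

Preferences are logit-normal: logit p_gc ~ Normal(η_g, σ_g) with
log σ_g ~ Normal(log σ, τ). σ is the preference-variability scale of the
typical gene; σ² is the "preference variance" the analyses report. The
shared-preference model sets σ = 0 (p_gc = logistic(η_g) for all cells).
A `pooled` mode (single σ for all genes) and a `fix_sigma` option (σ
pinned, used to verify that the variable model nests the shared one) are
available.

**Priors** (all configurable): η_g ~ Normal(0, 2.5²); log μ_g ~
Normal(empirical log mean of K/β̄, 2²); cv_g ~ HalfNormal(1) truncated to
the representability region; σ ~ HalfNormal(1); τ ~ HalfNormal(0.5);
factor loadings λ_g ~ Normal(0, 1), scores s_c ~ Normal(0, 1). Weakly
informative throughout.

**Sampler.** Adaptive Metropolis-within-Gibbs, fully vectorised:
element-wise random-walk updates of the latent logits x_gc (per-element
Robbins–Monro step adaptation toward 0.44 acceptance, frozen after
warmup); conjugate Gaussian draws for η_g (and jointly (η_g, λ_g) and
s_c in the factor model); random-walk updates of (log μ_g, log cv_g)
jointly per gene, of log σ_g, and of the hyperparameters; plus a joint
scale move that rescales all preference residuals together with σ and
σ_g (the Gaussian layer is invariant under this map, so the acceptance
ratio reduces to the binomial-likelihood change and the σ prior ratio).
The scale move exists because without it σ mixes through its coupling to
thousands of latent logits one step at a time (observed split-R̂ ≈ 1.5 in
early runs; ≈ 1.01 with the move). Chains are seeded independently via
`numpy.random.SeedSequence.spawn`; split-R̂ above 1.05 on monitored
scalars triggers a warning, not a failure. Capture efficiencies are
treated as known constants (they are estimated from spike-ins first).

**DIC.** DIC = D̄ + pD with pD = D̄ − D(θ̂): D̄ is the posterior mean of
−2 × collapsed log-likelihood along the chain; the plug-in D(θ̂)
evaluates the same likelihood at the posterior means of μ, cv and of the
per-cell preferences p_gc (continuous-parameter focus). Both D̄ and pD
are reported so alternative conventions remain recoverable. Lower DIC is
better.

**Factor model identifiability.** The likelihood is invariant under
(λ, s) → (−λ, −s) and (cλ, s/c). Saved draws are standardised to
SD(s) = 1 (loadings rescaled inversely) and the sign is anchored so the
gene with the largest mean |loading| has a positive loading; the final
posterior-mean score vector is standardised to SD exactly 1. Scores
depend on expression level only through the information content of the
counts, never through the totals themselves — the binomial layer
conditions on K_gc — which is what makes the clustering
expression-invariant.

**Detecting a correlated component.** With ~40 cells at ~5% capture the
factor's variance share has a prior-dominated posterior under the null,
so no fixed absolute threshold is meaningful. The decision instead
compares the posterior of the mean per-gene variance share
λ_g²/(λ_g² + σ_g²) on the data against the same quantity from a
parametric-bootstrap replicate simulated from the fitted *uncorrelated*
model: "evidence" requires P(share_obs > share_null) ≥ 0.95 over
independent draw pairs. Power is limited: coordinated changes must be
strong and affect roughly half the genes to be detectable at this data
size, and the result object carries that caveat.

## Frequentist null tests

All null simulations condition on the observed per-cell totals K_gc:
given the totals, the isoform split under "partitioning + technical noise
only" is exactly Binomial(K_gc, p) — the conditional null needs no
knowledge of μ, cv or β. The pooled estimate p̂ = Σk1/ΣK plugs in for p.

* **Per-gene variance test**: the across-cell variance of k1/K is
  compared with its simulated null distribution (default 1,000
  conditional simulations); "exceeds" means above the null *median*
  (one-sided; the reference and sidedness are flags), and the empirical P
  uses the add-one rule (r+1)/(n_sim+1). Genes with fewer than 3
  informative cells are excluded.
* **Enrichment**: under the null each gene exceeds its median with
  probability ½, so the number of exceeding genes is tested one-sided
  against Binomial(n_genes, 0.5).
* **KS partition test** (smFISH regime: full molecule counts, no capture
  thinning): a reference sample of null ratios is simulated at p̂ and the
  measured-vs-reference two-sample KS statistic is calibrated by a
  parametric bootstrap in which every null replicate re-estimates its own
  p̂ — the re-estimation step is what makes the P-values uniform under
  the null; the asymptotic KS P is conservative under the heavy ties of
  discrete ratios and is reported alongside.
* **Fisher lengthening test**: per gene, the 2×2 table of pooled
  (long, short) counts in two populations, two-sided, classed
  long-up/short-up by the direction of the long-isoform fraction when
  P < α = 0.05 (raw P, matching common practice for this comparison);
  zero-margin tables are "ns".

## Synthetic data

`generate_synthetic_tags` builds a random genome (balanced base
composition; downstream windows of true PA sites pinned to 25% A so the
priming filters never fire on signal; an A-run contig for decoys), an
annotation, and a tag table with known truth. Constraints that make the
zero-noise round trip exact are enforced: true PA sites of a gene are
> 12 bp apart, and the UMIs of a (cell, gene) are pairwise Hamming ≥ 3 so
single-substitution sequencing errors cannot chain-merge molecules. With
positive UMI-error rates recovery is approximate and tested against a
tolerance. The generator does not emulate alignment error, fragment-length
bias, or sequence-dependent capture; passing round-trip tests therefore
validate the bookkeeping of the pipeline, not robustness to artefacts the
generator does not produce.

`simulate_study_counts` generates two-isoform count matrices under the
study conditions the models target: per-isoform mean expression
log-uniform on the 8–1,000 molecules-per-cell band (the gene mean is the
sum of the two isoform means and the mean preference their log-ratio),
cv_g uniform on 0.4–0.8, β_c ~ Normal(0.054, 0.008) clipped to
[0.02, 0.12], and σ as requested (0.5 in the recovery experiments, i.e.
preference variance 0.25). An isoform-specific-capture option (β₁ ≠ β₂)
exists on the simulator for robustness experiments.

## Problem sizes and numerical choices

The test suite runs every workflow at reduced sizes chosen to keep the
whole suite in a few minutes while leaving each check statistically
decisive (e.g. recovery at 200 genes × 40 cells with 4 × 4,000
iterations; DIC direction over 10 seeds at 60 × 30 with 2 × 1,500;
calibration over 200 replicate datasets). `scripts/acceptance.py` runs
the recovery experiment at the full 493 × 40 study scale. At that scale
the posterior SD of the preference variance is ≈ 3% of its value — the
information limit set by ~5% capture — so single-seed deviations of a
few percent are expected; the posterior mean is unbiased within that
spread.

Degenerate inputs have defined behaviour throughout: empty UMI groups
return empty molecule lists, all-zero genes are dropped from fits with a
warning, a single cell is rejected by the factor model (unidentifiable),
rank-deficient preference matrices yield fewer PCA components, zero-margin
Fisher tables are "ns", and all-zero spike observations give β = 0 with a
warning.

## Known limitations

* At most two isoforms per gene enter the models (third and lower sites
  are rare at moderate-to-high expression and are excluded by design).
* One latent factor; multi-factor structure would require an ordering
  and rotation convention not implemented here.
* Capture efficiencies are plug-in constants; their sampling error is not
  propagated (the robustness simulations indicate the preference-variance
  inference is insensitive to moderate mis-calibration).
* DIC with latent preferences depends on the plug-in focus; the reported
  D̄/pD decomposition makes the convention explicit rather than hiding it.
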