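"""Synthetic 3'-tag data with known ground truth.

The generator emits a tag table, a matching genome and annotation, and a
truth table of molecules per (cell, gene, PA site).  It emulates the
pipeline-relevant structure of a 3'-tag experiment: distinct UMIs per
molecule, read pile-ups at the true PA positions, optional single-base UMI
sequencing errors, and optional internal-priming decoy reads planted in an
A-rich genomic region.  With all error rates at zero the pipeline's output
equals the truth table exactly; the UMI spacing and PA-site spacing
constraints that guarantee this are enforced at construction.

It does NOT emulate alignment errors, fragment-length effects, or
sequence-dependent capture bias; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Gene, GeneAnnotation, GenomeSequence

_BASES = np.array(list("ACGT"))


@dataclass
class SynthGene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    pa_sites: list[int]           # true 3'-end coordinates, inside the span

    def __post_init__(self) -> None:
        for s in self.pa_sites:
            if not (self.start <= s <= self.end):
                raise ValueError(f"PA site {s} outside {self.gene_id} span")
        sites = sorted(self.pa_sites)
        for a, b in zip(sites, sites[1:]):
            if b - a <= 12:
                raise ValueError(
                    "true PA sites must be > 12 bp apart for exact recovery")


@dataclass
class SynthConfig:
    genes: list[SynthGene]
    n_cells: int = 4
    # molecules per (cell, gene, site): mean of a Poisson draw, or use
    # `fixed_counts[(cell_idx, gene_id, site)]` for explicit truth
    mean_molecules: float = 5.0
    fixed_counts: dict | None = None
    reads_per_molecule: float = 2.0   # 1 + Poisson(mean - 1)
    umi_error_rate: float = 0.0       # per-read single-substitution prob
    n_decoys: int = 0                 # internal-priming decoy reads
    contig_length: int = 20_000
    seed_pad: int = 0                 # offsets genome sequence randomness


def _random_genome(config: SynthConfig, rng: np.random.Generator
                   ) -> GenomeSequence:
    """Balanced-composition genome with an A-run for decoy planting."""
    seqs = {}
    chroms = sorted({g.chrom for g in config.genes} | {"chrDecoy"})
    for chrom in chroms:
        seq = rng.choice(_BASES, size=config.contig_length)
        # keep PA-site neighbourhoods below the A-content thresholds
        seqs[chrom] = "".join(seq)
    if config.n_decoys:
        # A-rich stretch on chrDecoy: downstream windows exceed 80%/65% A
        s = list(seqs["chrDecoy"])
        mid = config.contig_length // 2
        s[mid:mid + 60] = "A" * 60
        seqs["chrDecoy"] = "".join(s)
    return GenomeSequence(seqs)


def _sanitise_windows(genome: GenomeSequence, config: SynthConfig) -> None:
    """Rewrite downstream windows of true PA sites to 25% A exactly.

    Random sequence occasionally exceeds the 65%-A/50-bp threshold; pinning
    the windows keeps the zero-noise round trip deterministic.
    """
    pattern = "ACGT" * 20
    for g in config.genes:
        s = list(genome.sequences[g.chrom])
        for site in g.pa_sites:
            if g.strand == "+":
                lo, hi = site, min(site + 52, len(s))
                s[lo:hi] = pattern[:hi - lo]
            else:
                lo, hi = max(site - 53, 0), site - 1
                s[lo:hi] = pattern[:hi - lo]
        genome.sequences[g.chrom] = "".join(s)


def _distinct_umis(n: int, rng: np.random.Generator, length: int = 8,
                   min_dist: int = 3) -> list[str]:
    """Random UMIs with pairwise Hamming distance >= min_dist."""
    out: list[str] = []
    guard = 0
    while len(out) < n:
        cand = "".join(rng.choice(_BASES, size=length))
        if all(sum(a != b for a, b in zip(cand, u)) >= min_dist for u in out):
            out.append(cand)
        guard += 1
        if guard > 100_000:
            raise RuntimeError("UMI space exhausted; lower molecule counts")
    return out


def _mutate_umi(umi: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(len(umi)))
    base = str(rng.choice([b for b in "ACGT" if b != umi[pos]]))
    return umi[:pos] + base + umi[pos + 1:]


@dataclass
class SynthResult:
    tags: pd.DataFrame
    truth: pd.DataFrame           # cell_id, gene_id, pa_site, molecules
    genome: GenomeSequence
    annotation: GeneAnnotation


def generate_synthetic_tags(config: SynthConfig, seed: int) -> SynthResult:
    """Generate a tag table plus ground truth; see module docstring."""
    rng = np.random.default_rng(np.random.SeedSequence(
        [seed, config.seed_pad]))
    genome = _random_genome(config, rng)
    _sanitise_windows(genome, config)
    annotation = GeneAnnotation([
        Gene(g.gene_id, g.chrom, g.strand, g.start, g.end,
             tts=(g.end if g.strand == "+" else g.start))
        for g in config.genes
    ])

    cells = [f"cell{i:02d}" for i in range(config.n_cells)]
    rows = []
    truth_rows = []
    for ci, cell in enumerate(cells):
        for g in config.genes:
            n_mols = []
            for site in sorted(g.pa_sites):
                if config.fixed_counts is not None:
                    n = int(config.fixed_counts.get((ci, g.gene_id, site), 0))
                else:
                    n = int(rng.poisson(config.mean_molecules))
                n_mols.append((site, n))
                if n:
                    truth_rows.append((cell, g.gene_id, site, n))
            total = sum(n for _, n in n_mols)
            if total == 0:
                continue
            umis = _distinct_umis(total, rng)
            k = 0
            for site, n in n_mols:
                for _ in range(n):
                    umi = umis[k]
                    k += 1
                    n_reads = 1 + int(rng.poisson(
                        max(config.reads_per_molecule - 1, 0)))
                    for _ in range(n_reads):
                        u = umi
                        if config.umi_error_rate and \
                                rng.random() < config.umi_error_rate:
                            u = _mutate_umi(umi, rng)
                        rows.append((cell, u, g.chrom, g.strand, site,
                                     60, 40, 0.25, 1, True))
    # internal-priming decoys: reads whose downstream window is the A-run
    mid = config.contig_length // 2
    for d in range(config.n_decoys):
        cell = cells[d % len(cells)]
        umi = "".join(rng.choice(_BASES, size=8))
        rows.append((cell, umi, "chrDecoy", "+", mid - 1, 60, 40, 0.25, 1,
                     True))

    tags = pd.DataFrame(rows, columns=[
        "cell_id", "umi", "chrom", "strand", "end3", "mapq", "read_len",
        "read_a_frac", "read_count", "unique"])
    # identical (cell, umi, position) reads show up as read_count
    tags = (tags.groupby(["cell_id", "umi", "chrom", "strand", "end3",
                          "mapq", "read_len", "read_a_frac", "unique"],
                         as_index=False)["read_count"].sum())
    tags = tags[["cell_id", "umi", "chrom", "strand", "end3", "mapq",
                 "read_len", "read_a_frac", "read_count", "unique"]]
    truth = pd.DataFrame(
        truth_rows, columns=["cell_id", "gene_id", "pa_site", "molecules"])
    truth = (truth.groupby(["cell_id", "gene_id", "pa_site"], as_index=False)
             ["molecules"].sum())
    return SynthResult(tags=tags.reset_index(drop=True), truth=truth,
                       genome=genome, annotation=annotation)


def simulate_study_counts(n_genes: int = 493, n_cells: int = 40,
                          sigma: float = 0.5, seed: int = 0,
                          expression_fold: float = 1.0):
    """Two-isoform count data under the study conditions of a 3'-tag
    single-cell experiment.

    Each gene's two isoform means are drawn log-uniform over the 8-1000
    molecules-per-cell-and-isoform band that defines moderate-to-high
    expression in a gene-selection step; the gene mean is their sum and
    the population-mean preference their ratio.  Coefficients of variation
    are uniform over 0.4-0.8 and capture efficiencies Normal(0.054, 0.008)
    clipped to [0.02, 0.12] — the ~5% regime of UMI-based single-cell
    protocols.  ``sigma`` is the SD of the cell-level logit preference
    (0 gives the shared-preference model).  ``expression_fold`` multiplies
    every gene mean, for expression-invariance experiments.

    Returns (data, beta, truth) where truth also carries the generating
    parameter arrays.
    """
    from .batbayes import BatBayesParams, simulate_dataset

    rng = np.random.default_rng(seed)
    m1 = np.exp(rng.uniform(np.log(8), np.log(1000), n_genes))
    m2 = np.exp(rng.uniform(np.log(8), np.log(1000), n_genes))
    mu = (m1 + m2) * expression_fold
    cv = rng.uniform(0.4, 0.8, n_genes)
    eta = np.log(m1 / m2)
    beta = np.clip(rng.normal(0.054, 0.008, n_cells), 0.02, 0.12)
    params = BatBayesParams(mu=mu, cv=cv, eta=eta, beta=beta, sigma=sigma)
    data, latent = simulate_dataset(params, n_genes, n_cells,
                                    seed=int(rng.integers(2 ** 31)))
    truth = {"mu": mu, "cv": cv, "eta": eta, "sigma": sigma, **latent}
    return data, beta, truth


def simulate_two_population_counts(n_genes: int = 40, n_cells: int = 40,
                                   shift: float = 1.2,
                                   resid_sigma: float = 0.3,
                                   expression_fold: float = 1.0,
                                   preference_shift: bool = True,
                                   seed: int = 0):
    """Counts for two equally sized cell populations.

    With ``preference_shift`` the populations sit at opposite ends of a
    coordinated preference axis: gene g's logit preference moves by
    +/- lambda_g * shift / 2 with lambda_g ~ Normal(0, 1).  Without it the
    populations share all preferences and differ only in expression level
    (population B's gene means multiplied by ``expression_fold``).

    Returns (data, beta, labels).
    """
    from scipy.special import expit

    from .batbayes import ObservedIsoforms

    rng = np.random.default_rng(seed)
    G, C = n_genes, n_cells
    mu = np.exp(rng.uniform(np.log(20), np.log(300), G))
    cv = rng.uniform(0.4, 0.8, G)
    eta = rng.normal(0, 0.8, G)
    beta = np.clip(rng.normal(0.054, 0.008, C), 0.02, 0.12)
    labels = np.repeat([0, 1], C // 2 + C % 2)[:C]
    x = eta[:, None] + rng.normal(0, resid_sigma, (G, C))
    mu_mat = np.broadcast_to(mu[:, None], (G, C)).copy()
    if preference_shift:
        lam = rng.normal(0, 1.0, G)
        x = x + lam[:, None] * np.where(labels[None, :] == 1,
                                        shift / 2, -shift / 2)
    if expression_fold != 1.0:
        mu_mat[:, labels == 1] *= expression_fold
    r = (mu / (cv ** 2 * mu - 1))[:, None]
    Q = rng.negative_binomial(r, r / (r + mu_mat), size=(G, C))
    p = expit(x)
    k1 = rng.binomial(Q, p * beta[None, :])
    pr2 = np.clip((1 - p) * beta[None, :] / (1 - p * beta[None, :]), 0, 1)
    k2 = rng.binomial(Q - k1, pr2)
    return ObservedIsoforms(k1, k2), beta, labels


def default_gene_set(n_genes: int = 3, sites_per_gene: int = 2,
                     site_spacing: int = 300) -> list[SynthGene]:
    """A small plausible gene layout on one chromosome, both strands."""
    genes = []
    cursor = 500
    for i in range(n_genes):
        strand = "+" if i % 2 == 0 else "-"
        start = cursor
        end = start + 1_200
        inner = [start + 400 + j * site_spacing for j in range(sites_per_gene)]
        genes.append(SynthGene(f"gene{i:02d}", "chr1", strand, start, end,
                               pa_sites=inner))
        cursor = end + 2_000
    return genes
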