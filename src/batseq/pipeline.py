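"""3'-tag read processing: from aligned tag reads to molecule counts.

The pipeline mirrors the processing stages of a UMI-based polyadenylation
site mapping assay:

1. demultiplex raw read pairs into (batch, cell) and extract the UMI
   (:func:`parse_read_tags`);
2. filter alignments for mapping quality, length, read A-content and
   genomic internal-priming signatures (:func:`filter_alignment`);
3. collapse UMIs within (cell, gene) at Hamming distance <= 1 into
   molecules (:func:`collapse_umis`);
4. merge per-position molecule counts pooled over all cells into reference
   polyadenylation sites with a greedy 12-bp rule (:func:`call_pa_sites`);
5. assign sites to genes via same-strand overlap or a 20-kb downstream
   window (:meth:`GeneAnnotation.assign_gene`);
6. tabulate molecules per (gene, site, cell) and drop shallow cells
   (:func:`build_count_matrix`).

The tag-table currency is a pandas DataFrame with columns
``cell_id, umi, chrom, strand, end3, mapq, read_len, read_a_frac,
read_count, unique`` (one row per unique alignment observation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import ANTISENSE, INTERGENIC, GeneAnnotation, GenomeSequence
from .counts import IsoformCountMatrix

TAG_COLUMNS = ["cell_id", "umi", "chrom", "strand", "end3", "mapq",
               "read_len", "read_a_frac", "read_count", "unique"]

#: machine-readable discard reasons, in the order the checks run
FILTER_REASONS = ("not_unique", "low_mapq", "short_read", "read_a_rich",
                  "excluded_contig", "internal_priming_15",
                  "internal_priming_50", "edge_window")

UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# demultiplexing


@dataclass
class ParsedTag:
    cell_id: str      # "<batch>:<cell>" or UNASSIGNED
    umi: str
    trimmed_read2: str
    n_terminal_a: int
    rejected: bool    # True when the poly-A evidence is insufficient


def parse_read_tags(read1_seq: str, read2_seq: str,
                    batch_table: dict[str, str],
                    cell_table: dict[str, str],
                    min_terminal_a: int = 10) -> ParsedTag:
    """Demultiplex one read pair and extract the molecular barcode.

    The first 7 bases of read 2 identify the batch; the first 6 bases of
    read 1 identify the cell within the batch and the following 8 bases are
    the UMI.  Terminal A's are trimmed off the remainder of read 2, and the
    pair is rejected unless at least ``min_terminal_a`` were present.
    Unknown barcodes route the record to the "unassigned" bin.
    """
    if len(read1_seq) < 14:
        raise ValueError("read 1 shorter than 14 bases (6 nt cell + 8 nt UMI)")
    batch_bc, rest2 = read2_seq[:7], read2_seq[7:]
    cell_bc, umi = read1_seq[:6], read1_seq[6:14]
    batch = batch_table.get(batch_bc)
    cell = cell_table.get(cell_bc)
    cell_id = f"{batch}:{cell}" if batch is not None and cell is not None \
        else UNASSIGNED
    stripped = rest2.rstrip("A")
    n_a = len(rest2) - len(stripped)
    return ParsedTag(cell_id=cell_id, umi=umi, trimmed_read2=stripped,
                     n_terminal_a=n_a, rejected=n_a < min_terminal_a)


# ---------------------------------------------------------------------------
# alignment filtering


@dataclass
class FilterParams:
    min_mapq: int = 30
    min_read_len: int = 20
    max_read_a_frac: float = 0.80
    window_short: int = 15
    max_a_short: float = 0.80
    window_long: int = 50
    max_a_long: float = 0.65
    min_window_bases: int = 5          # contig-edge guard
    excluded_chroms: frozenset[str] = frozenset({"chrM", "MT"})


def filter_alignment(tag, genome: GenomeSequence,
                     params: FilterParams | None = None
                     ) -> tuple[bool, str | None]:
    """Keep/discard decision for one aligned tag; returns (keep, reason).

    Discards non-unique alignments, mapq < 30, reads < 20 bp, reads > 80% A,
    alignments on excluded contigs (chrM), and internal-priming candidates
    whose downstream genomic window is A-rich (> 80% A over 15 bases or
    > 65% A over 50 bases, evaluated on the read's strand).  Windows
    truncated by a contig end are evaluated over the available bases and
    discarded outright when fewer than 5 bases remain.
    """
    p = params or FilterParams()
    if not bool(tag.unique):
        return False, "not_unique"
    if tag.mapq < p.min_mapq:
        return False, "low_mapq"
    if tag.read_len < p.min_read_len:
        return False, "short_read"
    if tag.read_a_frac > p.max_read_a_frac:
        return False, "read_a_rich"
    if tag.chrom in p.excluded_chroms:
        return False, "excluded_contig"
    frac15, n15 = genome.downstream_a_fraction(tag.chrom, tag.strand,
                                               int(tag.end3), p.window_short)
    if n15 < p.min_window_bases:
        return False, "edge_window"
    if frac15 > p.max_a_short:
        return False, "internal_priming_15"
    frac50, n50 = genome.downstream_a_fraction(tag.chrom, tag.strand,
                                               int(tag.end3), p.window_long)
    if n50 >= p.min_window_bases and frac50 > p.max_a_long:
        return False, "internal_priming_50"
    return True, None


def filter_tag_table(tags: pd.DataFrame, genome: GenomeSequence,
                     params: FilterParams | None = None,
                     excluded_genes: set[str] | None = None
                     ) -> tuple[pd.DataFrame, pd.Series]:
    """Apply :func:`filter_alignment` to a tag table.

    Returns the retained rows and a tally of discard reasons (indexed by
    :data:`FILTER_REASONS`).  ``excluded_genes`` is handled later, at gene
    assignment; it is accepted here only for interface symmetry.
    """
    keep = np.zeros(len(tags), dtype=bool)
    reasons: list[str | None] = []
    for i, tag in enumerate(tags.itertuples(index=False)):
        k, r = filter_alignment(tag, genome, params)
        keep[i] = k
        reasons.append(r)
    tally = pd.Series(
        {r: sum(1 for x in reasons if x == r) for r in FILTER_REASONS},
        name="discarded")
    return tags.loc[keep].reset_index(drop=True), tally


# ---------------------------------------------------------------------------
# UMI collapsing


@dataclass
class Molecule:
    cell_id: str
    gene_id: str
    umi: str          # representative (highest read count)
    chrom: str
    strand: str
    position: int     # representative 3'-end position
    read_count: int   # total reads over the component
    n_umis: int = 1


def _hamming1_components(umis: list[str]) -> list[list[int]]:
    """Connected components of the Hamming-distance-<=1 graph over UMIs.

    Uses neighbour enumeration (8 positions x 3 substitutions) against a
    hash map, so it scales linearly in the number of UMIs.
    """
    index: dict[str, int] = {u: i for i, u in enumerate(umis)}
    parent = list(range(len(umis)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    alphabet = "ACGTN"
    for u, i in index.items():
        for pos in range(len(u)):
            for b in alphabet:
                if b == u[pos]:
                    continue
                j = index.get(u[:pos] + b + u[pos + 1:])
                if j is not None:
                    union(i, j)
    comps: dict[int, list[int]] = {}
    for i in range(len(umis)):
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


def collapse_umis(group: pd.DataFrame, max_span: int = 20
                  ) -> list[Molecule]:
    """Collapse the tag observations of one (cell, gene) group into molecules.

    UMIs connected at Hamming distance <= 1 merge into a single molecule
    anchored at the constituent with the highest read count (ties: smaller
    position, then lexicographic UMI).  A molecule whose constituent 3' ends
    span >= ``max_span`` bases is discarded as a barcode collision.
    """
    if len(group) == 0:
        return []
    agg = (group.groupby(["umi", "end3"], as_index=False)["read_count"].sum())
    umis = sorted(agg["umi"].unique())
    cell = group["cell_id"].iloc[0]
    gene = group["gene_id"].iloc[0] if "gene_id" in group else ""
    chrom = group["chrom"].iloc[0]
    strand = group["strand"].iloc[0]
    by_umi = {u: sub for u, sub in agg.groupby("umi")}
    out: list[Molecule] = []
    for comp in _hamming1_components(umis):
        rows = pd.concat([by_umi[umis[i]] for i in comp])
        positions = rows["end3"].to_numpy()
        if positions.max() - positions.min() >= max_span:
            continue  # discarded: same barcode, distant 3' ends
        rows = rows.sort_values(["read_count", "end3", "umi"],
                                ascending=[False, True, True],
                                kind="stable")
        top = rows.iloc[0]
        out.append(Molecule(cell_id=cell, gene_id=gene, umi=str(top["umi"]),
                            chrom=chrom, strand=strand,
                            position=int(top["end3"]),
                            read_count=int(rows["read_count"].sum()),
                            n_umis=len(comp)))
    return out


# ---------------------------------------------------------------------------
# PA-site calling


def call_pa_sites(position_counts: dict[int, int], window: int = 12,
                  iterate: bool = True) -> dict[int, int]:
    """Greedy merge of per-position molecule counts into PA sites.

    One pass processes positions in ascending count order (ties: ascending
    coordinate).  Each position looks for a surviving position with a
    strictly higher current count within ``window`` bases; if one exists it
    is eliminated and its count added to that neighbour (the highest-count
    neighbour; ties broken toward the smaller coordinate).  Counts are
    conserved.

    A single pass can leave a pair of sites within the window when one of
    them grew (by absorbing others) only after its neighbour had already
    been processed; with ``iterate`` (the default) passes repeat until the
    result is a fixed point, making the operation idempotent.
    """
    current = {int(p): int(c) for p, c in position_counts.items()}
    while True:
        before = dict(current)
        order = sorted(current, key=lambda p: (before[p], p))
        for pos in order:
            if pos not in current:
                continue
            mine = current[pos]
            best: tuple[int, int] | None = None  # (-count, coordinate)
            for q, c in current.items():
                if q != pos and abs(q - pos) <= window and c > mine:
                    key = (-c, q)
                    if best is None or key < best:
                        best = key
            if best is not None:
                current[best[1]] += current.pop(pos)
        if not iterate or current == before:
            return current


def nearest_site(position: int, sites: list[int]) -> int:
    """Nearest retained PA site to a position (ties: smaller coordinate)."""
    if not sites:
        raise ValueError("no sites to assign to")
    return min(sites, key=lambda s: (abs(s - position), s))


# ---------------------------------------------------------------------------
# matrix building and gene selection


def build_count_matrix(molecules: pd.DataFrame, cell_min: int = 1000,
                       spike_genes: set[str] | None = None
                       ) -> IsoformCountMatrix:
    """Tabulate molecules (columns cell_id, gene_id, pa_site) per cell.

    Cells with fewer than ``cell_min`` total molecules are dropped; raises
    if no cell survives.
    """
    mat = molecules.pivot_table(index=["gene_id", "pa_site"],
                                columns="cell_id", values="umi"
                                if "umi" in molecules else "pa_site",
                                aggfunc="count", fill_value=0)
    mat = mat.astype(np.int64)
    mat.columns.name = None
    matrix = IsoformCountMatrix(mat, set(spike_genes or ()))
    return matrix.drop_small_cells(cell_min)


def select_isoform_genes(matrix: IsoformCountMatrix,
                         beta: pd.Series | float,
                         low: float = 8.0, high: float = 1000.0
                         ) -> tuple[list[str], IsoformCountMatrix]:
    """Select genes whose two top isoforms are moderately-to-highly expressed.

    Observed per-cell mean counts are converted to the molecule scale by
    dividing by the mean capture efficiency; a gene is kept when the
    corrected means of its two most-expressed PA sites both fall in
    [``low``, ``high``] molecules per cell.  Returns the gene list and the
    2-isoform submatrix with sites ordered (major, minor) per gene.
    """
    mean_beta = float(np.mean(beta))
    if not (0 < mean_beta <= 1):
        raise ValueError("mean capture efficiency must be in (0, 1]")
    selected: list[str] = []
    blocks = []
    for gene in matrix.gene_ids:
        if matrix.is_spike(gene) or gene in (ANTISENSE, INTERGENIC):
            continue
        block = matrix.gene(gene)
        if block.shape[0] < 2:
            continue
        totals = block.sum(axis=1).sort_values(ascending=False, kind="stable")
        top2 = totals.index[:2]
        corrected = block.loc[top2].mean(axis=1) / mean_beta
        if (corrected >= low).all() and (corrected <= high).all():
            selected.append(gene)
            sub = block.loc[top2].copy()
            sub.index = pd.MultiIndex.from_tuples(
                [(gene, s) for s in top2], names=["gene_id", "pa_site"])
            blocks.append(sub)
    if not selected:
        raise ValueError("no gene passes the expression band")
    return selected, IsoformCountMatrix(pd.concat(blocks), set())


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class PipelineResult:
    matrix: IsoformCountMatrix
    pa_sites: pd.DataFrame        # gene_id, chrom, strand, position, molecules
    molecules: pd.DataFrame       # one row per surviving molecule
    filter_tally: pd.Series
    qc: pd.DataFrame              # per-cell totals before/after thresholds
    discarded_spans: int = 0


@dataclass
class PipelineParams:
    filter: FilterParams = field(default_factory=FilterParams)
    merge_window: int = 12
    gene_window: int = 20_000
    umi_span: int = 20
    cell_min: int = 1000
    excluded_biotypes: frozenset[str] = frozenset({"rRNA"})


def run_pipeline(tags: pd.DataFrame, annotation: GeneAnnotation,
                 genome: GenomeSequence,
                 params: PipelineParams | None = None,
                 spike_genes: set[str] | None = None) -> PipelineResult:
    """Full tag-table -> count-matrix pipeline (stages 2-6 of the module)."""
    p = params or PipelineParams()
    spike_genes = set(spike_genes or ())
    kept, tally = filter_tag_table(tags, genome, p.filter)

    # gene assignment per unique 3'-end position
    pos = kept[["chrom", "strand", "end3"]].drop_duplicates()
    gene_of = {
        (r.chrom, r.strand, r.end3):
            annotation.assign_gene(r.chrom, r.strand, int(r.end3),
                                   p.gene_window)
        for r in pos.itertuples(index=False)
    }
    kept = kept.assign(gene_id=[
        gene_of[(c, s, e)] for c, s, e in
        zip(kept["chrom"], kept["strand"], kept["end3"])])

    # drop excluded biotypes (rRNA etc.); chrM went with the contig filter
    excluded = annotation.excluded_gene_ids(p.excluded_biotypes)
    kept = kept[~kept["gene_id"].isin(excluded)]
    real = kept[~kept["gene_id"].isin((ANTISENSE, INTERGENIC))]

    molecules: list[Molecule] = []
    discarded_spans = 0
    for _, group in real.groupby(["cell_id", "gene_id"], sort=True):
        mols = collapse_umis(group, p.umi_span)
        n_comp = len(_hamming1_components(sorted(group["umi"].unique())))
        discarded_spans += n_comp - len(mols)
        molecules.extend(mols)
    mol_df = pd.DataFrame(
        [(m.cell_id, m.gene_id, m.chrom, m.strand, m.position, m.umi,
          m.read_count) for m in molecules],
        columns=["cell_id", "gene_id", "chrom", "strand", "position", "umi",
                 "read_count"])

    # reference PA sites over the pooled population, per gene
    site_rows = []
    assigned = []
    for gene, grp in mol_df.groupby("gene_id", sort=True):
        counts = grp.groupby("position").size().to_dict()
        merged = call_pa_sites(counts, p.merge_window)
        sites = sorted(merged)
        chrom = grp["chrom"].iloc[0]
        strand = grp["strand"].iloc[0]
        for s in sites:
            site_rows.append((gene, chrom, strand, s, merged[s]))
        assigned.append(grp.assign(
            pa_site=[nearest_site(int(x), sites) for x in grp["position"]]))
    if not assigned:
        raise ValueError("no molecules survived filtering")
    mol_df = pd.concat(assigned, ignore_index=True)
    pa_sites = pd.DataFrame(
        site_rows,
        columns=["gene_id", "chrom", "strand", "position", "molecules"])

    totals_before = mol_df.groupby("cell_id").size().rename("molecules")
    matrix = build_count_matrix(mol_df, p.cell_min, spike_genes)
    qc = totals_before.to_frame()
    qc["retained"] = qc.index.isin(matrix.cell_ids)
    return PipelineResult(matrix=matrix, pa_sites=pa_sites, molecules=mol_df,
                          filter_tally=tally, qc=qc.reset_index(),
                          discarded_spans=discarded_spans)


# ---------------------------------------------------------------------------
# tag-table I/O


def read_tag_table(path: str) -> pd.DataFrame:
    tags = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "umi": str,
                                              "chrom": str, "strand": str})
    missing = [c for c in TAG_COLUMNS if c not in tags.columns]
    if missing:
        raise ValueError(f"tag table misses columns: {missing}")
    return tags[TAG_COLUMNS]


def read_sam_tags(path: str, mode: str = "r") -> pd.DataFrame:
    """Build a tag table from an aligned SAM/BAM file.

    Cell and molecular barcodes are taken from the ``CB``/``UB`` tags
    (falling back to ``<name>:<cell>:<umi>`` read-name suffixes).  The 3'
    end is the rightmost aligned base on '+' and the leftmost on '-';
    ``unique`` is true for primary alignments with NH absent or NH == 1.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(path, mode) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.has_tag("CB") and read.has_tag("UB"):
                cell, umi = read.get_tag("CB"), read.get_tag("UB")
            else:
                parts = read.query_name.split(":")
                if len(parts) < 3:
                    continue
                cell, umi = parts[-2], parts[-1]
            strand = "-" if read.is_reverse else "+"
            end3 = read.reference_end if strand == "+" \
                else read.reference_start + 1
            seq = read.query_sequence or ""
            a_frac = seq.upper().count("A") / len(seq) if seq else 0.0
            nh = read.get_tag("NH") if read.has_tag("NH") else 1
            rows.append((cell, umi, read.reference_name, strand, int(end3),
                         int(read.mapping_quality), len(seq), a_frac, 1,
                         nh == 1))
    df = pd.DataFrame(rows, columns=TAG_COLUMNS)
    # identical observations collapse into one row with a read count
    grouped = (df.groupby(TAG_COLUMNS[:8], as_index=False)
               .agg(read_count=("read_count", "sum"),
                    unique=("unique", "all")))
    return grouped[TAG_COLUMNS]
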