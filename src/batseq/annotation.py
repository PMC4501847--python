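"""Gene annotation and genome-sequence access for 3'-tag processing.

A :class:`GeneAnnotation` holds gene spans and transcript termination sites
(TTS) indexed by (chromosome, strand); it answers the question every tag
position asks: which gene (if any) does this putative polyadenylation site
belong to?  A :class:`GenomeSequence` answers the A-content queries used by
the internal-priming filters.

Coordinates are 1-based inclusive throughout (GTF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# sentinels used when a position cannot be assigned to a gene
ANTISENSE = "antisense"
INTERGENIC = "intergenic"


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int   # 1-based inclusive
    end: int
    tts: int     # transcript termination site (3' end of the gene)
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (self.start <= self.tts <= self.end):
            raise ValueError(
                f"TTS {self.tts} outside gene span [{self.start}, {self.end}] "
                f"for {self.gene_id}"
            )


class GeneAnnotation:
    """Indexed collection of genes supporting strand-aware position queries."""

    def __init__(self, genes: list[Gene]):
        self.genes = list(genes)
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValueError("duplicate gene_id in annotation")
        # per (chrom, strand): parallel arrays for vector-ish lookups
        self._index: dict[tuple[str, str], dict[str, np.ndarray]] = {}
        groups: dict[tuple[str, str], list[Gene]] = {}
        for g in self.genes:
            groups.setdefault((g.chrom, g.strand), []).append(g)
        for key, gs in groups.items():
            gs = sorted(gs, key=lambda g: (g.start, g.gene_id))
            self._index[key] = {
                "start": np.array([g.start for g in gs]),
                "end": np.array([g.end for g in gs]),
                "tts": np.array([g.tts for g in gs]),
                "ids": np.array([g.gene_id for g in gs], dtype=object),
            }

    def __len__(self) -> int:
        return len(self.genes)

    def get(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    # -- queries ---------------------------------------------------------

    def _candidates(self, chrom: str, strand: str, pos: int,
                    downstream_window: int) -> list[tuple[int, str]]:
        """(|pos - TTS|, gene_id) for genes that could own this position."""
        idx = self._index.get((chrom, strand))
        if idx is None:
            return []
        inside = (idx["start"] <= pos) & (pos <= idx["end"])
        if strand == "+":
            d = pos - idx["tts"]
        else:
            d = idx["tts"] - pos
        downstream = (d > 0) & (d <= downstream_window)
        hit = inside | downstream
        return [(abs(int(pos - t)), str(i))
                for t, i in zip(idx["tts"][hit], idx["ids"][hit])]

    def assign_gene(self, chrom: str, strand: str, pos: int,
                    downstream_window: int = 20_000) -> str:
        """Assign a 3'-end position to a gene.

        A position belongs to a gene when it overlaps the gene span on the
        same strand or lies at most ``downstream_window`` bases 3' of its
        TTS.  Among multiple candidates the gene with the nearest TTS wins
        (ties broken alphabetically).  Failing that, overlap with a gene on
        the opposite strand yields :data:`ANTISENSE`; otherwise
        :data:`INTERGENIC`.
        """
        cands = self._candidates(chrom, strand, pos, downstream_window)
        if cands:
            return min(cands)[1]
        other = "-" if strand == "+" else "+"
        idx = self._index.get((chrom, other))
        if idx is not None:
            if np.any((idx["start"] <= pos) & (pos <= idx["end"])):
                return ANTISENSE
        return INTERGENIC

    def excluded_gene_ids(self, biotypes: frozenset[str] = frozenset({"rRNA"})
                          ) -> set[str]:
        return {g.gene_id for g in self.genes if g.biotype in biotypes}

    # -- construction ----------------------------------------------------

    @classmethod
    def from_gtf(cls, path: str) -> "GeneAnnotation":
        """Load gene records from a GTF file (uses pyranges)."""
        import pyranges

        df = pyranges.read_gtf(path).df
        genes = df[df["Feature"] == "gene"]
        out = []
        for _, row in genes.iterrows():
            # pyranges converts to 0-based half-open; back to GTF 1-based
            start, end = int(row["Start"]) + 1, int(row["End"])
            strand = str(row["Strand"])
            tts = end if strand == "+" else start
            out.append(Gene(
                gene_id=str(row["gene_id"]),
                chrom=str(row["Chromosome"]),
                strand=strand,
                start=start,
                end=end,
                tts=tts,
                biotype=str(row.get("gene_biotype", "protein_coding")),
            ))
        return cls(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g.gene_id, g.chrom, g.strand, g.start, g.end, g.tts, g.biotype)
             for g in self.genes],
            columns=["gene_id", "chrom", "strand", "start", "end", "tts",
                     "biotype"],
        )


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class GenomeSequence:
    """Genome sequence access backed by an in-memory dict or a FASTA file.

    ``sequences`` maps chromosome name to an upper-case sequence string.
    Use :meth:`from_fasta` for on-disk genomes (pyfaidx handles indexing).
    """

    sequences: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeSequence":
        import pyfaidx

        fa = pyfaidx.Fasta(path, sequence_always_upper=True)
        obj = cls({})
        obj._fasta = fa  # lazy access; dict stays empty
        return obj

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice of the reference (plus strand)."""
        if start > end:
            return ""
        fa = getattr(self, "_fasta", None)
        if fa is not None:
            return str(fa[chrom][start - 1:end]).upper()
        seq = self.sequences[chrom]
        return seq[max(start - 1, 0):end]

    def contig_length(self, chrom: str) -> int:
        fa = getattr(self, "_fasta", None)
        if fa is not None:
            return len(fa[chrom])
        return len(self.sequences[chrom])

    def downstream_a_fraction(self, chrom: str, strand: str, end3: int,
                              window: int) -> tuple[float, int]:
        """A-fraction (on the read's strand) of the genomic window just 3'
        of ``end3``; returns (fraction, bases available).

        On the minus strand "downstream" runs toward smaller coordinates and
        an A on the read corresponds to a T on the reference.
        """
        n = self.contig_length(chrom)
        if strand == "+":
            start, end = end3 + 1, min(end3 + window, n)
            seq = self.fetch(chrom, start, end)
            base = "A"
        else:
            start, end = max(end3 - window, 1), end3 - 1
            seq = self.fetch(chrom, start, end)
            base = "T"
        if not seq:
            return 0.0, 0
        return seq.count(base) / len(seq), len(seq)
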