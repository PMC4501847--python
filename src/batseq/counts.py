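"""Per-cell molecule-count matrices over (gene, polyadenylation site).

The :class:`IsoformCountMatrix` is the hand-off point between the read
pipeline and the statistical models: rows are (gene_id, pa_site) pairs,
columns are cells, entries are UMI-deduplicated molecule counts.  Spike-in
"genes" are carried in the same matrix and flagged.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class IsoformCountMatrix:
    counts: pd.DataFrame          # MultiIndex rows (gene_id, pa_site) x cells
    spike_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not isinstance(self.counts.index, pd.MultiIndex):
            raise ValueError("counts must be indexed by (gene_id, pa_site)")
        arr = self.counts.to_numpy()
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)) or np.any(arr < 0):
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(np.int64)

    # -- basic views -----------------------------------------------------

    @property
    def cell_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index.get_level_values(0).unique())

    def cell_totals(self, include_spikes: bool = True) -> pd.Series:
        df = self.counts if include_spikes else self.counts.loc[
            [g for g in self.gene_ids if g not in self.spike_genes]]
        return df.sum(axis=0)

    def total_molecules(self) -> int:
        return int(self.counts.to_numpy().sum())

    def is_spike(self, gene_id: str) -> bool:
        return gene_id in self.spike_genes

    def gene(self, gene_id: str) -> pd.DataFrame:
        """Site x cell count block for one gene."""
        return self.counts.xs(gene_id, level=0, drop_level=True)

    def drop_small_cells(self, cell_min: int = 1000) -> "IsoformCountMatrix":
        totals = self.cell_totals()
        keep = totals[totals >= cell_min].index
        if len(keep) == 0:
            raise ValueError(
                f"no cell reaches {cell_min} molecules; nothing to analyse")
        return IsoformCountMatrix(self.counts[keep], set(self.spike_genes))

    def spike_counts(self) -> pd.DataFrame:
        """Spike-in rows summed over PA sites (spike_id x cell)."""
        rows = self.counts.loc[self.counts.index.get_level_values(0).isin(
            self.spike_genes)]
        return rows.groupby(level=0).sum()

    # -- I/O ---------------------------------------------------------------

    def to_long_tsv(self, path: str) -> None:
        long = (self.counts.stack().rename("molecules").reset_index())
        long.columns = ["gene_id", "pa_site", "cell_id", "molecules"]
        long = long[long["molecules"] > 0]
        long["spike"] = long["gene_id"].isin(self.spike_genes)
        long.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_long_tsv(cls, path: str) -> "IsoformCountMatrix":
        long = pd.read_csv(path, sep="\t")
        mat = long.pivot_table(index=["gene_id", "pa_site"],
                               columns="cell_id", values="molecules",
                               aggfunc="sum", fill_value=0).astype(np.int64)
        mat.columns.name = None
        if "spike" in long.columns:
            spikes = set(long.loc[long["spike"].astype(bool), "gene_id"])
        else:
            spikes = set()
        return cls(mat, spikes)

    def to_mtx(self, prefix: str) -> None:
        """Write an MTX triplet plus row/column index files."""
        from scipy import io as sio
        from scipy import sparse

        sio.mmwrite(prefix + ".mtx", sparse.csr_matrix(self.counts.to_numpy()))
        with open(prefix + ".rows.tsv", "w") as fh:
            fh.write("gene_id\tpa_site\tspike\n")
            for g, s in self.counts.index:
                fh.write(f"{g}\t{s}\t{int(g in self.spike_genes)}\n")
        with open(prefix + ".cols.tsv", "w") as fh:
            fh.write("cell_id\n")
            for c in self.counts.columns:
                fh.write(f"{c}\n")

    @classmethod
    def from_mtx(cls, prefix: str) -> "IsoformCountMatrix":
        from scipy import io as sio

        mat = np.asarray(sio.mmread(prefix + ".mtx").todense()).astype(np.int64)
        rows = pd.read_csv(prefix + ".rows.tsv", sep="\t")
        cols = pd.read_csv(prefix + ".cols.tsv", sep="\t")
        index = pd.MultiIndex.from_frame(rows[["gene_id", "pa_site"]])
        counts = pd.DataFrame(mat, index=index, columns=cols["cell_id"])
        counts.columns.name = None
        return cls(counts, set(rows.loc[rows["spike"] == 1, "gene_id"]))


def two_isoform_arrays(matrix: IsoformCountMatrix, genes: list[str]
                       ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(k1, k2) arrays (gene x cell) of the two most-expressed isoforms.

    Isoform 1 is the major (higher total) site of each gene; ties broken by
    coordinate.  Genes with a single site are skipped.
    """
    k1, k2, kept = [], [], []
    for g in genes:
        block = matrix.gene(g)
        if block.shape[0] < 2:
            continue
        order = block.sum(axis=1).sort_values(ascending=False,
                                              kind="stable").index
        k1.append(block.loc[order[0]].to_numpy())
        k2.append(block.loc[order[1]].to_numpy())
        kept.append(g)
    if not kept:
        raise ValueError("no gene with two isoforms")
    return np.array(k1), np.array(k2), kept
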