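import itertools

import numpy as np
import pandas as pd
import pytest

from batseq.annotation import Gene, GeneAnnotation, GenomeSequence


@pytest.fixture()
def flat_genome():
    """Two contigs with known composition for window-filter tests.

    chrA is all C (0% A downstream everywhere); chrB carries an A-rich
    stretch at positions 501-600.
    """
    chrA = "C" * 1000
    chrB = "C" * 500 + "A" * 100 + "C" * 400
    return GenomeSequence({"chrA": chrA, "chrB": chrB})


@pytest.fixture()
def simple_annotation():
    return GeneAnnotation([
        Gene("geneX", "chr1", "+", 1000, 3000, tts=3000),
        Gene("geneY", "chr1", "-", 30_000, 31_500, tts=30_000),
    ])


def make_tag(**kw):
    """One tag-table record with clean defaults, overridable per test.

    Returned as a namespace (not a pandas row) so the ``unique`` field is
    a plain attribute.
    """
    from types import SimpleNamespace

    row = dict(cell_id="c0", umi="ACGTACGT", chrom="chrA", strand="+",
               end3=100, mapq=60, read_len=50, read_a_frac=0.3,
               read_count=1, unique=True)
    row.update(kw)
    return SimpleNamespace(**row)


def brute_force_umi_components(umis):
    """Single-linkage components of the Hamming-<=1 graph, by exhaustive
    pairwise distances (the independent oracle for collapse_umis)."""
    n = len(umis)
    adj = [[] for _ in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        if sum(a != b for a, b in zip(umis[i], umis[j])) <= 1:
            adj[i].append(j)
            adj[j].append(i)
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            k = stack.pop()
            comp.append(k)
            for m in adj[k]:
                if not seen[m]:
                    seen[m] = True
                    stack.append(m)
        comps.append(sorted(comp))
    return sorted(comps)


def greedy_pa_oracle(position_counts, window=12):
    """Literal transcription of the merge procedure: sort sites by count,
    walk from the bottom of the list, eliminate any site with a
    higher-count site within the window, adding its count to that site."""
    counts = dict(position_counts)
    order = sorted(counts, key=lambda p: (position_counts[p], p))
    for pos in order:
        if pos not in counts:
            continue
        higher = [(c, -q) for q, c in counts.items()
                  if q != pos and abs(q - pos) <= window and c > counts[pos]]
        if higher:
            c, negq = max(higher)
            counts[-negq] += counts.pop(pos)
    return counts
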