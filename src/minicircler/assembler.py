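"""Greedy overlap-layout-consensus assembly for small read pools.

Replaces de-Bruijn assembly for the desk-scale pools this pipeline
produces (hundreds to thousands of reads per bait or junction).  Reads
must be pre-oriented (recruitment and junction harvesting both know the
strand); merging requires an exact suffix-prefix overlap of at least k
(default 31), taken greedily from the longest overlap down, which cannot
chimerize pools whose reads end in circle-specific sequence.  The
consensus is a column-wise majority vote over the layout, so isolated
sequencing errors are corrected wherever coverage allows.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .containers import Contig

DEFAULT_OVERLAP_K = 31


class AssemblyError(ValueError):
    pass


def assemble_greedy(seqs: list[str], k: int = DEFAULT_OVERLAP_K,
                    provenance: str = "", id_prefix: str = "contig",
                    ) -> list[Contig]:
    """Assemble pre-oriented sequences into contigs.

    Returns contigs sorted by (length, mean coverage) descending; reads
    that overlap nothing are returned as singleton contigs.
    """
    seqs = [s for s in seqs if len(s) >= k]
    if not seqs:
        return []
    counts = Counter(seqs)
    uniq = sorted(counts)                       # canonical processing order

    prefix_index: dict[str, list[int]] = {}
    for i, s in enumerate(uniq):
        prefix_index.setdefault(s[:k], []).append(i)

    # largest exact suffix-prefix overlap for each ordered pair
    edges: dict[tuple[int, int], int] = {}
    for i, s in enumerate(uniq):
        for pos in range(1, len(s) - k + 1):
            for j in prefix_index.get(s[pos : pos + k], ()):
                if j == i:
                    continue
                ov = len(s) - pos
                if ov <= len(uniq[j]) and uniq[j][:ov] == s[pos:]:
                    if edges.get((i, j), 0) < ov:
                        edges[(i, j)] = ov

    order = sorted(edges.items(), key=lambda kv: (-kv[1], uniq[kv[0][0]], uniq[kv[0][1]]))
    succ: dict[int, tuple[int, int]] = {}
    pred: dict[int, int] = {}
    root = list(range(len(uniq)))

    def find(x: int) -> int:
        while root[x] != x:
            root[x] = root[root[x]]
            x = root[x]
        return x

    for (i, j), ov in order:
        if i in succ or j in pred or find(i) == find(j):
            continue
        succ[i] = (j, ov)
        pred[j] = i
        root[find(i)] = find(j)

    contigs: list[Contig] = []
    heads = [i for i in range(len(uniq)) if i not in pred]
    for head in heads:
        members: list[tuple[int, int]] = []     # (uniq idx, offset)
        offset, node = 0, head
        members.append((node, 0))
        while node in succ:
            nxt, ov = succ[node]
            offset += len(uniq[node]) - ov
            node = nxt
            members.append((node, offset))
        length = members[-1][1] + len(uniq[members[-1][0]])
        seq, cov = _consensus(uniq, counts, members, length)
        reads_total = sum(counts[uniq[m]] for m, _ in members)
        contigs.append(Contig(
            id="", seq=seq, coverage=cov,
            read_ids=[f"n={reads_total}"], provenance=provenance,
        ))
    contigs.sort(key=lambda c: (-len(c), -c.mean_coverage, c.seq))
    for n, c in enumerate(contigs):
        c.id = f"{id_prefix}_{n:04d}"
    return contigs


def _consensus(uniq: list[str], counts: Counter, members, length: int,
               ) -> tuple[str, np.ndarray]:
    tally = np.zeros((5, length), dtype=np.int64)   # A C G T other
    lane = {"A": 0, "C": 1, "G": 2, "T": 3}
    for idx, offset in members:
        s, w = uniq[idx], counts[uniq[idx]]
        for p, base in enumerate(s):
            tally[lane.get(base, 4), offset + p] += w
    best = np.argmax(tally[:4], axis=0)
    seq = "".join("ACGT"[b] for b in best)
    coverage = tally.sum(axis=0)
    return seq, coverage.astype(float)


def trim_low_coverage(contig: Contig, min_cov: float = 3.0) -> Contig:
    """Clip contig ends whose consensus rests on fewer than ``min_cov``
    reads; fringe columns inherit single-read sequencing errors that break
    exact-overlap logic downstream."""
    idx = np.nonzero(contig.coverage >= min_cov)[0]
    if len(idx) == 0:
        return contig
    s, e = int(idx[0]), int(idx[-1]) + 1
    if (s, e) == (0, len(contig.seq)):
        return contig
    return Contig(contig.id, contig.seq[s:e], contig.coverage[s:e],
                  contig.read_ids, contig.provenance)


def assemble_recruited(seqs: list[str], k: int = DEFAULT_OVERLAP_K,
                       provenance: str = "") -> list[Contig]:
    """Assembly entry point for recruited read pools (>=2 reads)."""
    if len(seqs) < 2:
        raise AssemblyError("need at least two reads to assemble")
    return assemble_greedy(seqs, k=k, provenance=provenance)


def select_best_contig(contigs: list[Contig]) -> Contig:
    """Deterministic best contig: longest, then highest mean coverage,
    then lexicographically smallest sequence."""
    if not contigs:
        raise AssemblyError("cannot select from an empty contig list")
    return min(contigs, key=lambda c: (-len(c), -c.mean_coverage, c.seq))
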