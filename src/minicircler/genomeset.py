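"""Minicircle typing: conserved CR blocks, duplicate removal, genome stats.

The assembly process can emit several contigs whose coding regions are
identical but whose control regions differ in the circle-specific spacer
sequence; those are assembly artefacts of the shared CR and are collapsed
to the best-covered representative.
"""

from __future__ import annotations

import math

import edlib
import numpy as np
import pandas as pd

from .align import Mapper
from .config import PipelineConfig
from .containers import GenomeSet, Minicircle

_MIN_BLOCK_NT = 50
_MIN_PRESENCE = 0.80
# blastn-like ungapped Karlin-Altschul parameterization (+1 match / -2 mismatch)
_NT_LAMBDA = 1.33
_NT_K = 0.621


def alignment_evalue(n_match: int, n_mismatch: int, m: int, n: int) -> float:
    """Significance proxy for an ungapped nucleotide alignment."""
    score = n_match - 2 * n_mismatch
    return _NT_K * m * n * math.exp(-_NT_LAMBDA * score)


def find_conserved_blocks(contigs: list[Minicircle], cfg: PipelineConfig,
                          ) -> tuple[list[str], dict[str, list[tuple[int, int]]]]:
    """Maximal blocks >=50 nt shared by >=80% of contigs.

    The first contig (by id) anchors the search: every other contig is
    mapped onto it (both strands, wrap-aware via doubling) and reference
    positions covered by a qualifying alignment are tallied; runs of
    sufficient presence are the conserved blocks.  Hits of each block are
    then located in every contig.
    """
    if len(contigs) < 2:
        raise ValueError("need >=2 contigs to find shared blocks")
    ordered = sorted(contigs, key=lambda c: c.id)
    ref = ordered[0]
    mapper = Mapper(ref.seq, min_identity=cfg.min_cr_identity, min_anchor=_MIN_BLOCK_NT)
    presence = np.zeros(len(ref.seq), dtype=int)
    for other in ordered[1:]:
        mask = np.zeros(len(ref.seq), dtype=bool)
        query = other.seq + other.seq if other.circular else other.seq
        for p in mapper.map_sequence(query):
            mismatch = p.anchor - p.n_match
            ev = alignment_evalue(p.n_match, mismatch, len(ref.seq), len(query))
            if p.anchor >= _MIN_BLOCK_NT and ev <= cfg.max_cr_evalue:
                mask[p.t_start : p.t_end] = True
        presence += mask
    needed = math.ceil(_MIN_PRESENCE * len(ordered)) - 1
    blocks: list[str] = []
    run_start = None
    covered = presence >= max(1, needed)
    for i in range(len(covered) + 1):
        if i < len(covered) and covered[i]:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            if i - run_start >= _MIN_BLOCK_NT:
                blocks.append(ref.seq[run_start:i])
            run_start = None

    hits: dict[str, list[tuple[int, int]]] = {c.id: [] for c in ordered}
    for block in blocks:
        max_dist = int((1.0 - cfg.min_cr_identity) * len(block))
        for c in ordered:
            target = c.seq + c.seq if c.circular else c.seq
            res = edlib.align(block, target, mode="HW", task="locations",
                              k=max_dist)
            if res["editDistance"] < 0:
                continue
            for s, e in sorted(set(res["locations"])):
                start = s % len(c.seq)
                span = (start, start + (e + 1 - s))
                if span not in hits[c.id]:
                    hits[c.id].append(span)
    return blocks, hits


def coding_region_key(circle: Minicircle) -> tuple:
    """Rotation/strand-normalized key of the coding region.

    Circles are expected in canonical form (longest gene at the origin on
    the plus strand), under which the ordered concatenation of gene
    sequences identifies the coding region exactly.
    """
    if not circle.genes:
        return ("__naked__", circle.seq)
    n = len(circle.seq)
    doubled = circle.seq + circle.seq
    parts = []
    for g in sorted(circle.genes, key=lambda g: g.start):
        parts.append((g.label, g.strand, doubled[g.start : g.start + len(g)]))
    return tuple(parts)


def dedupe_contigs(circles: list[Minicircle],
                   ) -> tuple[list[Minicircle], list[str]]:
    """Collapse circles with identical coding regions, keeping the
    best-covered (then longest, then lexicographically smallest) one."""
    groups: dict[tuple, list[Minicircle]] = {}
    for c in circles:
        groups.setdefault(coding_region_key(c), []).append(c)
    kept: list[Minicircle] = []
    removed: list[str] = []
    for _key, members in sorted(groups.items(), key=lambda kv: str(kv[0])):
        members = sorted(
            members, key=lambda c: (-c.mean_coverage, -len(c), c.seq, c.id)
        )
        kept.append(members[0])
        removed.extend(m.id for m in members[1:])
    kept.sort(key=lambda c: c.id)
    return kept, sorted(removed)


def _at_percent(seq: str) -> float:
    s = seq.upper()
    return 100.0 * (s.count("A") + s.count("T")) / len(s) if seq else 0.0


def genome_stats(gs: GenomeSet) -> pd.DataFrame:
    """Per-genome summary mirroring the published assembly tables."""
    circles = gs.circles
    complete = [c for c in circles if c.circular]
    total_seq = "".join(c.seq for c in circles)
    coding_parts = []
    for c in circles:
        doubled = c.seq + c.seq
        for g in c.genes:
            coding_parts.append(doubled[g.start : g.start + len(g)])
    coding_seq = "".join(coding_parts)
    n_genes = sum(len(c.genes) for c in circles)
    row = {
        "species": gs.species,
        "minicircles": len(circles),
        "complete_circles": len(complete),
        "min_len": min((len(c) for c in complete), default=0),
        "max_len": max((len(c) for c in complete), default=0),
        "total_at_pct": round(_at_percent(total_seq), 1),
        "coding_at_pct": round(_at_percent(coding_seq), 1),
        "genes_per_circle": round(n_genes / len(circles), 2) if circles else 0.0,
    }
    return pd.DataFrame([row])
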