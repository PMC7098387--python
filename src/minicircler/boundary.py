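"""The "bioinformatic PCR primer" stage.

The conserved control-region core immediately upstream of a coding region
is shared by every minicircle of a genome, so reads that align to a window
ending at the CR/coding boundary and run past its 3' terminus carry
circle-specific sequence from *all* circles.  Harvest those reads,
assemble them, keep well-covered contigs, strip the shared conserved
prefix, and the remaining variable tails are one extension seed per
minicircle.
"""

from __future__ import annotations

import numpy as np

from .align import Mapper, ReadStore, _encode
from .assembler import AssemblyError, assemble_greedy, trim_low_coverage
from .config import PipelineConfig
from .containers import Contig, EdgeSeed, SequenceRecord

_MIN_OVERHANG = 15
_WINDOW_ANCHOR = 30
_MIN_TAIL = 20
#: a read's alignment may stop this far short of the window terminus (the
#: detected boundary can sit a base or two outside the conserved core, and
#: foreign-circle reads can only align up to the core's edge)
_TERMINUS_SLACK = 8


class TrimError(ValueError):
    pass


def extract_upstream_window(contig: Contig | str, boundary: int,
                            window: int = 250, circular: bool = False,
                            ) -> tuple[SequenceRecord, bool]:
    """``window`` nt ending at ``boundary`` on the coding strand.

    Wraps across the origin on circular contigs; on linear contigs with
    fewer than ``window`` nt upstream the shorter prefix is returned with
    the truncation flag set.
    """
    seq = contig.seq if isinstance(contig, Contig) else contig
    cid = contig.id if isinstance(contig, Contig) else "window"
    if boundary < 0 or boundary > len(seq):
        raise ValueError(f"boundary {boundary} outside contig")
    if circular:
        start = (boundary - window) % len(seq)
        if start < boundary:
            out = seq[start:boundary]
        else:
            out = seq[start:] + seq[:boundary]
        return SequenceRecord(f"{cid}|upstream{window}", out), False
    start = max(0, boundary - window)
    out = seq[start:boundary]
    return SequenceRecord(f"{cid}|upstream{window}", out), start == 0 and boundary < window


def collect_overhang_reads(store: ReadStore, window: SequenceRecord,
                           cfg: PipelineConfig,
                           min_overhang: int = _MIN_OVERHANG,
                           ) -> list[SequenceRecord]:
    """Mates whose alignment reaches the window's 3' terminus and continues
    beyond it.  The whole pool is scanned; reads are returned oriented
    along the window."""
    if len(window.seq) < 100:
        raise ValueError("boundary window shorter than 100 nt")
    mapper = Mapper(window.seq, min_identity=cfg.map_min_identity,
                    min_anchor=_WINDOW_ANCHOR)
    out: list[SequenceRecord] = []
    for idx in range(len(store)):
        for strand, seq, arr in (
            ("+", store.seqs[idx], store.fwd[idx]),
            ("-", store.rev_seqs[idx], store.rev[idx]),
        ):
            hit = False
            for p in mapper.place(idx, strand, seq, arr):
                gap = len(window.seq) - p.t_end
                overhang = (len(seq) - p.q_end) - gap
                if gap <= _TERMINUS_SLACK and overhang >= min_overhang:
                    hit = True
                    break
            if hit:
                out.append(SequenceRecord(store.ids[idx], seq))
                break
    return out


def assemble_overhangs(reads: list[SequenceRecord], cfg: PipelineConfig,
                       ) -> list[Contig]:
    """Assemble harvested junction reads; keep contigs whose supported-core
    mean coverage meets the configured floor (>= threshold, so a contig at
    exactly the floor survives)."""
    if len(reads) < 10:
        raise AssemblyError(
            f"only {len(reads)} junction reads; need at least 10"
        )
    contigs = assemble_greedy([r.seq for r in reads], provenance="edge",
                              id_prefix="edge")
    # unmerged single reads are not assembly products; keeping them as
    # remap candidates would siphon every error-bearing read onto its own
    # perfect-match singleton
    max_read = max(len(r.seq) for r in reads)
    contigs = [c for c in contigs if len(c) > max_read]
    if not contigs:
        return []
    contigs = _remap_pool_coverage(contigs, [r.seq for r in reads])
    kept = []
    for c in contigs:
        c = trim_low_coverage(c)
        # junction-anchored contigs taper linearly away from the shared
        # boundary; their read support is judged on the junction-supported
        # core, not the single-read tapers
        peak = float(c.coverage.max()) if len(c.coverage) else 0.0
        core = c.coverage[c.coverage >= max(3.0, 0.25 * peak)]
        mean_cov = float(core.mean()) if len(core) else c.mean_coverage
        if mean_cov >= cfg.min_edge_contig_cov:
            kept.append(c)
    return kept


def _remap_pool_coverage(contigs: list[Contig], seqs: list[str],
                         ) -> list[Contig]:
    """Recompute contig coverage by assigning every pool read to its best
    contig; suffix-prefix-only merging cannot place same-start or
    contained reads, which would otherwise go uncounted."""
    mappers = [Mapper(c.seq, min_identity=0.90,
                      min_anchor=min(30, len(c.seq) - 2)) for c in contigs]
    coverage = [np.zeros(len(c.seq)) for c in contigs]
    for seq in seqs:
        arr = _encode(seq)
        best = None
        for ci, mapper in enumerate(mappers):
            for p in mapper.place(-1, "+", seq, arr):
                if best is None or p.n_match > best[1].n_match:
                    best = (ci, p)
        if best is not None:
            ci, p = best
            coverage[ci][p.t_start : p.t_end] += 1
    return [
        Contig(c.id, c.seq, cov, c.read_ids, c.provenance)
        for c, cov in zip(contigs, coverage)
    ]


def trim_conserved_prefix(contigs: list[Contig]) -> list[EdgeSeed]:
    """Strip the 5' prefix shared (>=90% column identity) across contigs.

    Contigs are anchored to the longest contig by exact-diagonal mapping
    (progressive pairwise anchoring rather than a full MSA); the first
    reference column where the covering contigs disagree marks the end of
    the conserved region, and everything 3' of it is the circle-specific
    tail.  Tails shorter than 20 nt are dropped.
    """
    if len(contigs) < 2:
        raise TrimError("need at least two contigs to identify a shared prefix")
    ref = max(contigs, key=lambda c: (len(c), c.seq))
    mapper = Mapper(ref.seq, min_identity=0.85,
                    min_anchor=min(40, len(ref.seq) - 2))
    offsets: dict[str, int | None] = {}
    for c in contigs:
        if c.id == ref.id and c.seq == ref.seq:
            offsets[c.id] = 0
            continue
        placements = mapper.place(-1, "+", c.seq, _encode(c.seq))
        if placements:
            best = max(placements, key=lambda p: (p.n_match, p.identity))
            offsets[c.id] = best.t_start - best.q_start
        else:
            offsets[c.id] = None

    anchored = [c for c in contigs if offsets[c.id] is not None]
    cut_col = None
    max_col = max(offsets[c.id] + len(c) for c in anchored)
    for col in range(max_col):
        bases = [
            c.seq[col - offsets[c.id]]
            for c in anchored
            if 0 <= col - offsets[c.id] < len(c)
        ]
        if len(bases) < 2:
            continue
        top = max(bases.count(b) for b in set(bases))
        if top / len(bases) < 0.90:
            cut_col = col
            break
    if cut_col is None:
        raise TrimError(
            "contigs share their entire alignable span; no variable tails "
            f"(contigs: {sorted(c.id for c in contigs)})"
        )

    seeds: list[EdgeSeed] = []
    for c in contigs:
        off = offsets[c.id]
        local_cut = max(0, cut_col - off) if off is not None else 0
        tail = c.seq[local_cut:]
        if len(tail) < _MIN_TAIL:
            continue
        seeds.append(EdgeSeed(
            id=f"seed_{c.id}", seq=tail,
            source_contig_id=c.id, source_mean_coverage=c.mean_coverage,
        ))
    return seeds
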