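"""Homology-based gene annotation and region delimitation.

Protein-coding genes are called by six-frame translated local alignment
against a reference protein set (>=50% aa identity over >=70% of the
reference); rRNA and tRNA genes by nucleotide alignment (>=80% identity
over the reference length).  Searches run on the doubled sequence so
calls may wrap the circular origin, and both strands are examined.  PCG
calls are nudged onto the nearest in-frame start/stop codons of the
invertebrate mitochondrial code.
"""

from __future__ import annotations

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

from .align import Mapper, Placement, ReadStore, best_per_read
from .containers import GeneAnnotation, Minicircle, SequenceRecord
from .genetics import (
    IUPAC_FROM_BASES,
    START_CODONS_5,
    STOP_CODONS_5,
    revcomp,
    translate_mito,
)

_PCG_MIN_AA_IDENTITY = 0.50
_PCG_MIN_REF_COVER = 0.70
_NT_MIN_IDENTITY = 0.80
_SEED_AA = 5


class AnnotationError(ValueError):
    pass


def _aa_aligner() -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aln.open_gap_score = -11.0
    aln.extend_gap_score = -1.0
    return aln


def annotate_genes(circle: Minicircle | str,
                   protein_refs: list[SequenceRecord],
                   nt_refs: list[SequenceRecord]) -> list[GeneAnnotation]:
    seq = circle.seq if isinstance(circle, Minicircle) else circle
    if not protein_refs and not nt_refs:
        raise AnnotationError("empty reference set")
    calls = _annotate_pcgs(seq, protein_refs) + _annotate_nt(seq, nt_refs)
    return _merge_same_label(calls, len(seq))


def _annotate_pcgs(seq: str, refs: list[SequenceRecord]) -> list[GeneAnnotation]:
    if not refs:
        return []
    n = len(seq)
    doubled = seq + seq
    aligner = _aa_aligner()
    seed_index: dict[str, set[int]] = {}
    for ri, ref in enumerate(refs):
        for i in range(len(ref.seq) - _SEED_AA + 1):
            seed_index.setdefault(ref.seq[i : i + _SEED_AA], set()).add(ri)

    calls: list[tuple[float, GeneAnnotation]] = []
    for strand in "+-":
        template = doubled if strand == "+" else revcomp(doubled)
        for frame in range(3):
            pep = translate_mito(template, frame)
            if len(pep) < _SEED_AA:
                continue
            candidates: set[int] = set()
            for i in range(len(pep) - _SEED_AA + 1):
                candidates |= seed_index.get(pep[i : i + _SEED_AA], set())
            for ri in sorted(candidates):
                ref = refs[ri]
                alns = aligner.align(ref.seq, pep)
                if len(alns) == 0:
                    continue
                aln = alns[0]
                ident, ref_cover, q_span = _aa_alignment_stats(aln, ref.seq, pep)
                if ident < _PCG_MIN_AA_IDENTITY or ref_cover < _PCG_MIN_REF_COVER:
                    continue
                nt_start = frame + 3 * q_span[0]
                nt_end = frame + 3 * q_span[1]
                nt_start, nt_end = _tune_orf(template, nt_start, nt_end)
                if strand == "-":
                    nt_start, nt_end = (
                        len(template) - nt_end, len(template) - nt_start
                    )
                start = nt_start % n
                calls.append((
                    aln.score,
                    GeneAnnotation(ref.id, start, start + (nt_end - nt_start),
                                   strand, ident),
                ))
    return [c for _s, c in sorted(calls, key=lambda sc: -sc[0])]


def _aa_alignment_stats(aln, ref: str, pep: str):
    ref_blocks, q_blocks = aln.aligned
    ident_n = 0
    aligned_ref = 0
    for (rs, re_), (qs, qe) in zip(ref_blocks, q_blocks):
        aligned_ref += re_ - rs
        ident_n += sum(ref[rs + i] == pep[qs + i] for i in range(re_ - rs))
    ref_cover = aligned_ref / len(ref)
    ident = ident_n / aligned_ref if aligned_ref else 0.0
    q_span = (int(q_blocks[0][0]), int(q_blocks[-1][-1]))
    return ident, ref_cover, q_span


def _tune_orf(template: str, start: int, end: int,
              max_shift: int = 15) -> tuple[int, int]:
    """Snap a translated hit onto in-frame start/stop codons nearby."""
    for shift in range(0, max_shift + 1, 3):
        if start - shift >= 0 and template[start - shift : start - shift + 3] in START_CODONS_5:
            start = start - shift
            break
    else:
        for shift in range(3, max_shift + 1, 3):
            if template[start + shift : start + shift + 3] in START_CODONS_5:
                start = start + shift
                break
    for shift in range(0, max_shift + 1, 3):
        codon = template[end + shift : end + shift + 3]
        if codon in STOP_CODONS_5:
            end = end + shift + 3
            break
    return start, end


def _annotate_nt(seq: str, refs: list[SequenceRecord]) -> list[GeneAnnotation]:
    n = len(seq)
    doubled = seq + seq
    calls: list[tuple[float, GeneAnnotation]] = []
    for ref in refs:
        max_dist = int((1.0 - _NT_MIN_IDENTITY) * len(ref.seq))
        for strand in "+-":
            template = doubled if strand == "+" else revcomp(doubled)
            res = edlib.align(ref.seq, template, mode="HW", task="locations",
                              k=max_dist)
            if res["editDistance"] < 0:
                continue
            ident = 1.0 - res["editDistance"] / len(ref.seq)
            for loc_start, loc_end in _distinct_locations(res["locations"]):
                s, e = loc_start, loc_end + 1
                if strand == "-":
                    s, e = len(template) - e, len(template) - s
                start = s % n
                calls.append((
                    ident,
                    GeneAnnotation(ref.id, start, start + (e - s), strand, ident),
                ))
    return [c for _s, c in sorted(calls, key=lambda sc: -sc[0])]


def _distinct_locations(locations) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(set(locations)):
        if out and s <= out[-1][1]:
            continue
        out.append((s, e))
    return out


def _merge_same_label(calls: list[GeneAnnotation], n: int,
                      ) -> list[GeneAnnotation]:
    """Greedy non-overlap selection; overlapping same-label calls merge."""
    kept: list[GeneAnnotation] = []
    for call in calls:
        overlap = next(
            (k for k in kept if _spans_overlap(call, k, n)), None
        )
        if overlap is None:
            kept.append(call)
        elif overlap.label == call.label:
            continue                      # duplicate image of the same call
    return sorted(kept, key=lambda g: (g.start, g.label))


def _spans_overlap(a: GeneAnnotation, b: GeneAnnotation, n: int) -> bool:
    cols_a = {(a.start + i) % n for i in range(len(a))}
    cols_b = {(b.start + i) % n for i in range(len(b))}
    shared = len(cols_a & cols_b)
    return shared > 0.3 * min(len(a), len(b))


def delimit_regions(circle: Minicircle,
                    annotations: list[GeneAnnotation],
                    conserved_blocks: list[str] | None = None,
                    ) -> tuple[tuple[int, int] | None, list[tuple[int, int]], bool]:
    """CR span, intergenic arcs and a CR-not-found warning flag.

    The CR is the largest annotation-free arc containing a match to the
    conserved blocks (or simply the largest arc when no blocks are given).
    """
    n = len(circle.seq)
    if not annotations:
        raise AnnotationError("region delimitation needs >=1 annotation")
    occupied = sorted(
        ((g.start % n, (g.start % n) + len(g)) for g in annotations)
    )
    arcs: list[tuple[int, int]] = []
    for (s1, e1), (s2, _e2) in zip(occupied, occupied[1:]):
        if s2 > e1:
            arcs.append((e1, s2))
    tail_gap = occupied[0][0] + n - occupied[-1][1]
    if tail_gap > 0:
        arcs.append((occupied[-1][1], occupied[0][0] + n))
    arcs = [a for a in arcs if a[1] - a[0] >= 100]
    if not arcs:
        return None, [], True

    doubled = circle.seq + circle.seq
    def has_block(arc: tuple[int, int]) -> bool:
        if not conserved_blocks:
            return True
        segment = doubled[arc[0] : arc[1]]
        for block in conserved_blocks:
            k = int(0.2 * len(block))
            res = edlib.align(block, segment, mode="HW", k=k)
            if res["editDistance"] >= 0:
                return True
        return False

    matching = [a for a in arcs if has_block(a)]
    pool = matching if matching else arcs
    cr = max(pool, key=lambda a: (a[1] - a[0], -a[0]))
    intergenic = [a for a in arcs if a != cr]
    return cr, intergenic, False


def mask_cr_ambiguities(circle: Minicircle, placements: list[Placement],
                        store: ReadStore,
                        max_minor_frac: float = 0.2) -> Minicircle:
    """Rewrite CR columns with substantial minor alleles as IUPAC codes.

    ``placements`` must be computed against ``circle.seq`` doubled (or a
    doubled prefix); target positions fold modulo the circle length.
    Coding columns are never touched.
    """
    if circle.cr_span is None:
        return circle
    n = len(circle.seq)
    counts: dict[int, dict[str, int]] = {}
    for p in best_per_read(placements).values():
        seq = store.oriented(p.read_idx, p.strand)
        for t in range(p.t_start, p.t_end):
            base = seq[p.q_start + (t - p.t_start)]
            col = t % n
            counts.setdefault(col, {}).setdefault(base, 0)
            counts[col][base] += 1
    cr_cols = {(circle.cr_span[0] + i) % n
               for i in range(circle.cr_span[1] - circle.cr_span[0])}
    out = list(circle.seq)
    for col in cr_cols:
        tally = counts.get(col)
        if not tally:
            continue
        total = sum(tally.values())
        alleles = frozenset(
            b for b, c in tally.items() if b in "ACGT" and c / total > max_minor_frac
        )
        if len(alleles) > 1:
            out[col] = IUPAC_FROM_BASES[alleles]
    masked = Minicircle(
        id=circle.id, seq="".join(out), circular=circle.circular,
        cr_span=circle.cr_span, genes=list(circle.genes),
        species=circle.species, mean_coverage=circle.mean_coverage,
    )
    return masked
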