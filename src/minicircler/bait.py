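"""Read recruitment by homology to bait sequences.

Protein baits recruit reads through a translated search: a 5-aa exact seed
shared with any six-frame translation of a mate proposes the bait, and a
local Smith-Waterman (BLOSUM62, gap open -11 / extend -1) confirms it.
Scores are converted to bits with the standard gapped BLOSUM62
Karlin-Altschul parameters so the recruitment threshold behaves like a
familiar bit score (default 40 bits).  Recruitment is pair-level: both
mates of a recruited pair enter the assembly pool, oriented along the bait.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .align import Mapper, ReadStore
from .containers import SequenceRecord
from .genetics import six_frame_translations

_SEED_AA = 5
_LAMBDA = 0.267          # gapped BLOSUM62 (open 11 / extend 1)
_LN_K = math.log(0.041)


class BaitError(ValueError):
    pass


@dataclass
class BaitHit:
    read_id: str
    frame: int               # +1..+3 forward, -1..-3 reverse strand
    score: float             # bit score
    bait_id: str


def raw_to_bits(raw: float) -> float:
    return (_LAMBDA * raw - _LN_K) / math.log(2.0)


def _aligner() -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aln.open_gap_score = -11.0
    aln.extend_gap_score = -1.0
    return aln


class ProteinBaitSet:
    """Seeded translated search against a set of protein baits."""

    def __init__(self, baits: list[SequenceRecord], min_score: float = 40.0):
        for bait in baits:
            if len(bait.seq) < 20:
                raise BaitError(f"bait {bait.id!r} shorter than 20 aa")
        self.baits = {b.id: b.seq for b in baits}
        self.min_score = min_score
        self.seed_index: dict[str, set[str]] = {}
        for bid, seq in self.baits.items():
            for i in range(len(seq) - _SEED_AA + 1):
                self.seed_index.setdefault(seq[i : i + _SEED_AA], set()).add(bid)
        self.aligner = _aligner()

    def best_hits(self, read: SequenceRecord) -> list[BaitHit]:
        """Best-scoring hit per bait for one mate (all six frames)."""
        per_bait: dict[str, BaitHit] = {}
        for frame, pep in six_frame_translations(read.seq):
            if len(pep) < _SEED_AA:
                continue
            candidates: set[str] = set()
            for i in range(len(pep) - _SEED_AA + 1):
                candidates |= self.seed_index.get(pep[i : i + _SEED_AA], set())
            for bid in sorted(candidates):
                raw = self.aligner.score(self.baits[bid], pep)
                bits = raw_to_bits(raw)
                if bits < self.min_score:
                    continue
                cur = per_bait.get(bid)
                if cur is None or bits > cur.score:
                    per_bait[bid] = BaitHit(read.id, frame, bits, bid)
        return list(per_bait.values())


def recruit_reads(store: ReadStore, bait: SequenceRecord,
                  min_score: float = 40.0) -> list[BaitHit]:
    """Hits of every mate against one protein bait."""
    baitset = ProteinBaitSet([bait], min_score)
    hits: list[BaitHit] = []
    for idx in range(len(store)):
        rec = SequenceRecord(store.ids[idx], store.seqs[idx])
        hits.extend(baitset.best_hits(rec))
    return hits


def recruit_pairs(store: ReadStore, baits: list[SequenceRecord],
                  min_score: float = 40.0) -> dict[str, list[str]]:
    """Pair-level recruitment pools, one oriented read pool per bait.

    A single pass translates every mate once; a pair joins a bait's pool
    when either mate scores.  Reads are oriented along the bait (reverse
    frames are reverse-complemented; a hit-less mate of a recruited pair
    takes the orientation opposite to its mate's).
    """
    baitset = ProteinBaitSet(baits, min_score)
    mate_hits: list[dict[str, BaitHit]] = []
    for idx in range(len(store)):
        rec = SequenceRecord(store.ids[idx], store.seqs[idx])
        mate_hits.append({h.bait_id: h for h in baitset.best_hits(rec)})

    pools: dict[str, list[str]] = {b.id: [] for b in baits}
    for pair_idx in range(len(store) // 2):
        i, j = 2 * pair_idx, 2 * pair_idx + 1
        for bid in sorted(set(mate_hits[i]) | set(mate_hits[j])):
            hi, hj = mate_hits[i].get(bid), mate_hits[j].get(bid)
            ori_i = _orientation(hi) or _flip(_orientation(hj))
            ori_j = _orientation(hj) or _flip(_orientation(hi))
            pools[bid].append(store.oriented(i, ori_i))
            pools[bid].append(store.oriented(j, ori_j))
    return pools


def _orientation(hit: BaitHit | None) -> str | None:
    if hit is None:
        return None
    return "+" if hit.frame > 0 else "-"


def _flip(strand: str | None) -> str:
    return {"+": "-", "-": "+"}.get(strand, "+")


def recruit_pairs_nt(store: ReadStore, ref: SequenceRecord,
                     min_identity: float = 0.90,
                     min_anchor: int = 40) -> list[str]:
    """Nucleotide recruitment pool for one rRNA/tRNA reference.

    Used by the pipeline's reference-rescue seeding stage; anchors shrink
    automatically for references shorter than the requested anchor.
    """
    anchor = min(min_anchor, max(20, len(ref.seq) - 10))
    mapper = Mapper(ref.seq, min_identity=min_identity, min_anchor=anchor)
    pool: list[str] = []
    seen_pairs: set[int] = set()
    for idx in range(len(store)):
        placements = mapper.place(idx, "+", store.seqs[idx], store.fwd[idx])
        placements += mapper.place(idx, "-", store.rev_seqs[idx], store.rev[idx])
        if not placements:
            continue
        pair = idx // 2
        if pair in seen_pairs:
            continue
        seen_pairs.add(pair)
        best = max(placements, key=lambda p: (p.n_match, p.identity))
        mate = idx ^ 1
        pool.append(store.oriented(idx, best.strand))
        pool.append(store.oriented(mate, _flip(best.strand)))
    return pool
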