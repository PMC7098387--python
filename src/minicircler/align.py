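"""Fast read-to-contig mapping.

A k-mer (default 21-mer) shared between read and target proposes a
diagonal; the best locally matching segment on that diagonal is found by a
maximal-subarray scan (+1 match / -3 mismatch), which clips mismatching
tails the way a local aligner soft-clips.  Substitution-dominated Illumina
data needs no gapped extension here; gapped identity checks elsewhere go
through edlib.

Placements record the aligned target span and, when the aligned segment
reaches a target end, the read sequence overhanging that end — the raw
material of iterative extension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ReadPair
from .genetics import revcomp

KMER = 21
_STRIDE = 8


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class ReadStore:
    """Mates of cleaned read pairs with cached numpy encodings.

    Mate ``2*i`` and ``2*i + 1`` are the two mates of pair ``i``; the mate
    of read ``j`` is ``j ^ 1``.
    """

    def __init__(self, pairs: list[ReadPair]):
        self.ids: list[str] = []
        self.seqs: list[str] = []
        for pair in pairs:
            for mate in (pair.mate1, pair.mate2):
                self.ids.append(mate.id)
                self.seqs.append(mate.seq)
        self.fwd = [_encode(s) for s in self.seqs]
        self.rev_seqs = [revcomp(s) for s in self.seqs]
        self.rev = [_encode(s) for s in self.rev_seqs]

    def __len__(self) -> int:
        return len(self.seqs)

    def oriented(self, idx: int, strand: str) -> str:
        return self.seqs[idx] if strand == "+" else self.rev_seqs[idx]


@dataclass
class Placement:
    """One clipped alignment of an oriented read against a target."""

    read_idx: int
    strand: str          # orientation of the read relative to the target
    q_start: int         # aligned span in oriented-read coordinates
    q_end: int
    t_start: int         # aligned span on the target
    t_end: int
    identity: float
    n_match: int
    left_overhang: str = ""   # read bases hanging off target position 0
    right_overhang: str = ""  # read bases hanging off the target 3' end

    @property
    def anchor(self) -> int:
        return self.q_end - self.q_start


def _best_segment(match: np.ndarray) -> tuple[int, int, int]:
    """Maximal-scoring run (+1 match / -3 mismatch) of a boolean array."""
    score = np.where(match, 1.0, -3.0)
    cum = np.empty(len(score) + 1)
    cum[0] = 0.0
    np.cumsum(score, out=cum[1:])
    prefix_min = np.minimum.accumulate(cum[:-1])
    gains = cum[1:] - prefix_min
    e = int(np.argmax(gains)) + 1
    s = int(np.argmin(cum[:e]))
    return s, e, int(match[s:e].sum())


class Mapper:
    """K-mer diagonal mapper against one target sequence."""

    def __init__(self, target: str, k: int = KMER,
                 min_identity: float = 0.90, min_anchor: int = 40):
        self.target = target
        self.t_arr = _encode(target)
        self.k = k
        self.min_identity = min_identity
        self.min_anchor = min(min_anchor, max(1, len(target) - 2))
        index: dict[str, list[int]] = {}
        for pos in range(0, len(target) - k + 1):
            index.setdefault(target[pos : pos + k], []).append(pos)
        self.index = index

    # -- single-orientation placement ------------------------------------

    def _diagonals(self, seq: str) -> list[int]:
        n, k = len(seq), self.k
        if n < k:
            return []
        qpos_list = list(range(0, n - k + 1, _STRIDE))
        if qpos_list[-1] != n - k:
            qpos_list.append(n - k)
        diags: dict[int, int] = {}
        for qpos in qpos_list:
            for tpos in self.index.get(seq[qpos : qpos + k], ())[:4]:
                d = tpos - qpos
                diags[d] = diags.get(d, 0) + 1
        ranked = sorted(diags, key=lambda d: (-diags[d], d))
        return ranked[:8]

    def _place_on_diagonal(self, read_idx: int, strand: str, seq: str,
                           arr: np.ndarray, diag: int) -> Placement | None:
        n, t_len = len(arr), len(self.t_arr)
        q0 = max(0, -diag)
        q1 = min(n, t_len - diag)
        if q1 - q0 < self.min_anchor:
            return None
        match = self.t_arr[diag + q0 : diag + q1] == arr[q0:q1]
        s, e, n_match = _best_segment(match)
        s, e = s + q0, e + q0
        anchor = e - s
        if anchor < self.min_anchor:
            return None
        identity = n_match / anchor
        if identity < self.min_identity:
            return None
        t_start, t_end = s + diag, e + diag
        left = seq[:s] if (t_start == 0 and s > 0) else ""
        right = seq[e:] if (t_end == t_len and e < n) else ""
        return Placement(read_idx, strand, s, e, t_start, t_end,
                         identity, n_match, left, right)

    def place(self, read_idx: int, strand: str, seq: str,
              arr: np.ndarray) -> list[Placement]:
        out = []
        for diag in self._diagonals(seq):
            p = self._place_on_diagonal(read_idx, strand, seq, arr, diag)
            if p is not None:
                out.append(p)
        return out

    # -- read-store mapping ----------------------------------------------

    def map_store(self, store: ReadStore) -> list[Placement]:
        """All acceptable placements of every mate, both orientations."""
        out: list[Placement] = []
        for idx in range(len(store)):
            out.extend(self.place(idx, "+", store.seqs[idx], store.fwd[idx]))
            out.extend(self.place(idx, "-", store.rev_seqs[idx], store.rev[idx]))
        return out

    def map_sequence(self, seq: str, seq_id: int = -1) -> list[Placement]:
        placements = self.place(seq_id, "+", seq, _encode(seq))
        rc = revcomp(seq)
        placements += self.place(seq_id, "-", rc, _encode(rc))
        return placements


def best_per_read(placements: list[Placement]) -> dict[int, Placement]:
    """Single best placement per mate (matches, identity, leftmost)."""
    best: dict[int, Placement] = {}
    for p in placements:
        cur = best.get(p.read_idx)
        if cur is None or (p.n_match, p.identity, -p.t_start) > (
            cur.n_match, cur.identity, -cur.t_start
        ):
            best[p.read_idx] = p
    return best


def confirmed_reads(best: dict[int, Placement], store: ReadStore,
                    insert_mean: float, insert_sd: float) -> set[int]:
    """Mates whose pair placed in proper orientation at plausible distance.

    A pair is proper when mates map on opposite strands, the plus-strand
    mate is leftmost, and the implied fragment length sits within 4 sd of
    the library insert size.
    """
    ok: set[int] = set()
    lo = insert_mean - 4.0 * insert_sd
    hi = insert_mean + 4.0 * insert_sd
    for idx, p in best.items():
        mate = best.get(idx ^ 1)
        if mate is None or mate.strand == p.strand:
            continue
        fwd, rev = (p, mate) if p.strand == "+" else (mate, p)
        # project to full-read extents on the target
        n_f = len(store.seqs[fwd.read_idx])
        n_r = len(store.seqs[rev.read_idx])
        f_start = fwd.t_start - fwd.q_start
        r_end = rev.t_end + (n_r - rev.q_end)
        frag = r_end - f_start
        if f_start <= rev.t_start and lo <= frag <= hi:
            ok.add(idx)
    return ok
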