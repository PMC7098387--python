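"""Iterative mapping extension of a seed contig.

Each iteration maps the read pool against the current contig and appends,
at each end, a consensus of the overhanging read bases: a column is called
when at least three reads support it and the winning base carries a clear
majority; on a split vote the call falls back to pair-confirmed reads
(mates whose partner placed on the contig at proper orientation and
insert distance), which is what lets extension cross the conserved
control-region core where reads from every circle pile up and disagree
only about what follows it.  Extension stops at no-growth, at detected
circularity (terminal repeat above the configured minimum), or at the
iteration cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import Mapper, Placement, ReadStore, best_per_read, confirmed_reads
from .circularity import find_wrap_repeat
from .config import PipelineConfig
from .containers import Contig

_MIN_SUPPORT = 3
_CLEAR_FRAC = 0.7
# a large vote pile can only be a mixed, multi-circle pile-up (it exceeds
# what one circle's junction coverage provides), so raw majorities there
# must be near-unanimous — a dominant-copy-number circle can otherwise
# drag extension across the conserved core into its own spacer
_BIG_PILE = 15
_UNANIMOUS_FRAC = 0.9


@dataclass
class ExtensionState:
    contig: Contig
    iteration: int = 0
    grew_last_iter: bool = False
    circularized: bool = False
    repeat_len: int | None = None
    stop_reason: str = ""
    iteration_log: list[str] = field(default_factory=list)


def map_reads(store: ReadStore, ref: Contig | str,
              min_ident: float = 0.90, min_anchor: int = 40,
              ) -> list[Placement]:
    """All acceptable placements of the pool against a reference."""
    seq = ref.seq if isinstance(ref, Contig) else ref
    return Mapper(seq, min_identity=min_ident, min_anchor=min_anchor).map_store(store)


def _consensus_tail(votes: list[tuple[str, bool]], cap: int) -> str:
    """Column-by-column consensus over overhang strings.

    ``votes`` pairs each overhang with its pair-confirmation flag.  Reads
    disagreeing with an accepted column stop voting at later columns.
    """
    out: list[str] = []
    active = list(range(len(votes)))
    for col in range(cap):
        live = [i for i in active if len(votes[i][0]) > col]
        if len(live) < _MIN_SUPPORT:
            break
        counts: dict[str, int] = {}
        conf_counts: dict[str, int] = {}
        for i in live:
            base = votes[i][0][col]
            counts[base] = counts.get(base, 0) + 1
            if votes[i][1]:
                conf_counts[base] = conf_counts.get(base, 0) + 1
        # pair-confirmed reads outrank the raw pile-up: inside the conserved
        # CR core every circle's reads agree, but only the contig's own
        # circle has mates anchored in unique sequence nearby
        if sum(conf_counts.values()) >= _MIN_SUPPORT:
            base = _call(conf_counts) or _call(counts, strict_when_big=True)
        else:
            base = _call(counts, strict_when_big=True)
        if base is None:
            break
        out.append(base)
        active = [
            i for i in active
            if len(votes[i][0]) <= col or votes[i][0][col] == base
        ]
    return "".join(out)


def _call(counts: dict[str, int], strict_when_big: bool = False) -> str | None:
    total = sum(counts.values())
    if total < _MIN_SUPPORT:
        return None
    frac = _CLEAR_FRAC
    if strict_when_big and total >= _BIG_PILE:
        frac = _UNANIMOUS_FRAC
    top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top[0][1] >= _MIN_SUPPORT and top[0][1] >= frac * total:
        return top[0][0]
    return None


def extend_iteratively(seed: Contig | str, store: ReadStore,
                       cfg: PipelineConfig) -> ExtensionState:
    seq = seed.seq if isinstance(seed, Contig) else seed
    seed_id = seed.id if isinstance(seed, Contig) else "seed"
    state = ExtensionState(contig=Contig(seed_id, seq, np.zeros(len(seq))))
    per_end_cap = max(1, cfg.read_len_nt - cfg.map_min_anchor_nt)

    placements: list[Placement] = []
    while state.iteration < cfg.max_extend_iters:
        state.iteration += 1
        hit = find_wrap_repeat(seq, cfg.min_terminal_repeat_nt)
        if hit is not None:
            rep, t5, t3 = hit
            seq = seq[t5 : len(seq) - t3]
            state.circularized, state.repeat_len = True, rep
            state.stop_reason = "circularized"
            break
        placements = map_reads(store, seq, cfg.map_min_identity,
                               cfg.map_min_anchor_nt)
        best = best_per_read(placements)
        confirmed = confirmed_reads(best, store, cfg.insert_mean_nt,
                                    cfg.insert_sd_nt)
        right_votes = [
            (p.right_overhang, p.read_idx in confirmed)
            for p in placements if p.right_overhang
        ]
        left_votes = [
            (p.left_overhang[::-1], p.read_idx in confirmed)
            for p in placements if p.left_overhang
        ]
        right = _consensus_tail(right_votes, per_end_cap)
        left = _consensus_tail(left_votes, per_end_cap)[::-1]
        grew = bool(left or right)
        state.iteration_log.append(
            f"iter={state.iteration} len={len(seq)} +5'={len(left)} +3'={len(right)}"
        )
        if not grew:
            state.grew_last_iter = False
            state.stop_reason = "no_growth"
            break
        seq = left + seq + right
        state.grew_last_iter = True
        hit = find_wrap_repeat(seq, cfg.min_terminal_repeat_nt)
        if hit is not None:
            rep, t5, t3 = hit
            seq = seq[t5 : len(seq) - t3]
            state.circularized, state.repeat_len = True, rep
            state.stop_reason = "circularized"
            break
        if len(seq) > cfg.max_contig_nt:
            state.stop_reason = "length_cap"
            break
    else:
        state.stop_reason = "iteration_cap"

    coverage = np.zeros(len(seq))
    final_placements = map_reads(store, seq, cfg.map_min_identity,
                                 cfg.map_min_anchor_nt)
    supporting: list[str] = []
    for p in best_per_read(final_placements).values():
        coverage[p.t_start : p.t_end] += 1
        supporting.append(store.ids[p.read_idx])
    state.contig = Contig(seed_id, seq, coverage,
                          read_ids=sorted(supporting), provenance=seed_id)
    return state
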