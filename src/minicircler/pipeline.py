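"""End-to-end minicircle discovery pipeline.

Stages: read preparation -> protein-baited seed assembly (A) -> iterative
extension of the anchor seed -> coverage segmentation and CR/coding
boundary -> junction-read harvest and edge seeds (B) -> extension of every
seed -> circularization -> annotation -> CR delimitation and ambiguity
masking -> duplicate removal -> genome statistics.  A reference-rescue
stage seeds extension directly from the supplied rRNA/tRNA nucleotide
references so chromosomes without protein baits (rRNA and tRNA-only
circles) do not depend solely on the edge-contig coverage filter.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import edlib
import numpy as np

from .align import Mapper, ReadStore, best_per_read
from .annotate import annotate_genes, delimit_regions, mask_cr_ambiguities
from .assembler import (
    AssemblyError,
    assemble_greedy,
    select_best_contig,
    trim_low_coverage,
)
from .bait import recruit_pairs, recruit_pairs_nt
from .boundary import (
    assemble_overhangs,
    collect_overhang_reads,
    extract_upstream_window,
    trim_conserved_prefix,
)
from .circularity import (
    canonical_rotation,
    collapse_terminal_repeat,
    find_terminal_repeat,
)
from .config import PipelineConfig
from .containers import Contig, GenomeSet, Minicircle, ReadPair, SequenceRecord
from .coverage import (
    BoundaryError,
    locate_cr_coding_boundary,
    profile_coverage,
    segment_profile,
)
from .extend import extend_iteratively, map_reads
from .genetics import revcomp
from .genomeset import dedupe_contigs, find_conserved_blocks, genome_stats
from .read_prep import prepare_pairs


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunManifest:
    config: dict = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, **info})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "stages": self.stages}, fh,
                      indent=2, sort_keys=True)
            fh.write("\n")


def _sha(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _redundant(seed_seq: str, circles: list[Minicircle],
               max_div: float = 0.05) -> bool:
    """Does this seed already live inside a finished circle?"""
    k = max(2, int(max_div * len(seed_seq)))
    for c in circles:
        target = c.seq + c.seq if c.circular else c.seq
        for q in (seed_seq, revcomp(seed_seq)):
            if len(q) > len(target):
                continue
            if edlib.align(q, target, mode="HW", k=k)["editDistance"] >= 0:
                return True
    return False


def _covered_fraction(seq: str, circles: list[Minicircle]) -> float:
    """Fraction of ``seq`` covered by alignments to any finished circle."""
    if not circles:
        return 0.0
    covered = np.zeros(len(seq), dtype=bool)
    for c in circles:
        target = c.seq + c.seq if c.circular else c.seq
        mapper = Mapper(target, min_identity=0.90, min_anchor=40)
        for p in mapper.map_sequence(seq):
            if p.strand == "+":
                covered[p.q_start : p.q_end] = True
            else:
                covered[len(seq) - p.q_end : len(seq) - p.q_start] = True
    return float(covered.mean())


def _circular_profile(circle_seq: str, store: ReadStore, cfg: PipelineConfig):
    """Wrap-aware coverage: map against the circle extended by one read
    length and fold the tail back onto the origin."""
    pad = min(len(circle_seq), 2 * cfg.read_len_nt)
    target = circle_seq + circle_seq[:pad]
    placements = map_reads(store, target, cfg.map_min_identity,
                           cfg.map_min_anchor_nt)
    prof = profile_coverage(placements, len(target), "circular")
    folded = prof.depth[: len(circle_seq)].copy()
    folded[:pad] += prof.depth[len(circle_seq):]
    prof.depth = folded
    return prof, placements


def _polish_circle(seq: str, store: ReadStore, cfg: PipelineConfig,
                   ) -> tuple[str, float]:
    """One majority-vote polishing pass over a collapsed circle.

    Seed contigs inherit occasional greedy-consensus errors; a column
    majority over all mapped reads removes them so that independently
    seeded assemblies of the same chromosome converge byte-identically.
    Returns the polished sequence and its mean coverage.
    """
    prof, placements = _circular_profile(seq, store, cfg)
    n = len(seq)
    counts: dict[int, dict[str, int]] = {}
    for p in best_per_read(placements).values():
        rseq = store.oriented(p.read_idx, p.strand)
        for t in range(p.t_start, p.t_end):
            base = rseq[p.q_start + (t - p.t_start)]
            col = t % n
            col_counts = counts.setdefault(col, {})
            col_counts[base] = col_counts.get(base, 0) + 1
    out = list(seq)
    for col, tally in counts.items():
        total = sum(tally.values())
        base, top = max(sorted(tally.items()), key=lambda kv: kv[1])
        if top >= 3 and top >= 0.7 * total and base in "ACGT":
            out[col] = base
    return "".join(out), float(prof.depth.mean())


def _finish_circle(state, store: ReadStore, cfg: PipelineConfig,
                   baits: list[SequenceRecord], nt_refs: list[SequenceRecord],
                   species: str, name: str) -> Minicircle | None:
    """Collapse/annotate/canonicalize one extension product."""
    contig = state.contig
    if state.stop_reason == "length_cap":
        return None                      # runaway product, never a chromosome
    if state.circularized and state.repeat_len:
        seq = collapse_terminal_repeat(contig.seq, state.repeat_len)
        seq, mean_cov = _polish_circle(seq, store, cfg)
        genes = annotate_genes(seq, baits, nt_refs)
        seq, genes = canonical_rotation(seq, genes)
        return Minicircle(
            id=name, seq=seq, circular=True, genes=genes, species=species,
            mean_coverage=mean_cov,
        )
    if len(contig.seq) < 300:
        return None
    genes = annotate_genes(contig.seq, baits, nt_refs)
    genes = [g for g in genes if g.end <= len(contig.seq)]
    return Minicircle(
        id=name, seq=contig.seq, circular=False, genes=genes,
        species=species, mean_coverage=contig.mean_coverage,
    )


def run_pipeline(cfg: PipelineConfig, pairs: list[ReadPair],
                 baits: list[SequenceRecord],
                 nt_refs: list[SequenceRecord] | None = None,
                 species: str = "sample",
                 ) -> tuple[GenomeSet, RunManifest]:
    nt_refs = nt_refs or []
    manifest = RunManifest(config=vars(cfg).copy())

    # -- read preparation -------------------------------------------------
    survivors, log = prepare_pairs(pairs, cfg)
    if not survivors:
        raise PipelineError("read_prep", "no read pairs survived cleaning")
    store = ReadStore(survivors)
    manifest.record("read_prep", pairs_in=log.pairs_in,
                    survivors=len(survivors),
                    discarded_short=log.discarded_short,
                    discarded_duplicate=log.discarded_duplicate)

    # -- stage A: protein-baited seeds ------------------------------------
    seeds: list[tuple[str, str]] = []       # (name, seq) in extension order
    pools = recruit_pairs(store, baits) if baits else {}
    for bid in sorted(pools, key=lambda b: (-len(pools[b]), b)):
        pool = pools[bid]
        if len(pool) < 4:
            continue
        best = trim_low_coverage(
            select_best_contig(assemble_greedy(pool, provenance=bid))
        )
        if len(best) >= 100:
            seeds.append((f"bait_{bid}", best.seq))
    manifest.record("bait_assembly", baits=len(baits), seeds=len(seeds),
                    recruited={b: len(p) for b, p in sorted(pools.items())})

    if not seeds:
        raise PipelineError("bait_assembly", "no bait produced a seed contig")

    # -- anchor extension and CR/coding boundary --------------------------
    anchor_name, anchor_seq = max(seeds, key=lambda s: len(s[1]))
    anchor_state = extend_iteratively(anchor_seq, store, cfg)
    window, boundary, anchor_sp = _boundary_window(anchor_state, store, cfg,
                                                   baits, nt_refs)
    manifest.record("anchor_extension", anchor=anchor_name,
                    iterations=anchor_state.iteration,
                    circularized=anchor_state.circularized,
                    contig_len=len(anchor_state.contig.seq),
                    boundary=boundary,
                    cr_coding_ratio=(anchor_sp.ratio if anchor_sp else None),
                    contig_sha=_sha(anchor_state.contig.seq))

    # -- stage B: junction harvest ----------------------------------------
    edge_seeds = []
    n_junction = 0
    if window is not None:
        junction_reads = collect_overhang_reads(store, window, cfg)
        n_junction = len(junction_reads)
        if n_junction >= 10:
            try:
                edge_contigs = assemble_overhangs(junction_reads, cfg)
                if len(edge_contigs) >= 2:
                    edge_seeds = trim_conserved_prefix(edge_contigs)
            except (AssemblyError, ValueError):
                edge_seeds = []
    manifest.record("boundary_primers", junction_reads=n_junction,
                    edge_seeds=len(edge_seeds))

    # -- reference rescue seeds -------------------------------------------
    rescue: list[tuple[str, str]] = []
    for ref in sorted(nt_refs, key=lambda r: (-len(r.seq), r.id)):
        pool = recruit_pairs_nt(store, ref, cfg.map_min_identity,
                                cfg.map_min_anchor_nt)
        if len(pool) < 4:
            continue
        best = trim_low_coverage(
            select_best_contig(assemble_greedy(pool, provenance=ref.id))
        )
        if len(best) >= 50:
            rescue.append((f"ref_{ref.id}", best.seq))
    manifest.record("reference_rescue", seeds=len(rescue))

    # -- extend every seed, circularize, annotate -------------------------
    queue: list[tuple[str, str]] = []
    queue.extend(sorted((s for s in seeds if s[0] != anchor_name),
                        key=lambda s: -len(s[1])))
    queue.extend((f"edge_{e.id}", e.seq)
                 for e in sorted(edge_seeds,
                                 key=lambda e: -e.source_mean_coverage))
    queue.extend(rescue)

    circles: list[Minicircle] = []
    stop_reasons: dict[str, str] = {anchor_name: anchor_state.stop_reason}
    anchor_circle = _finish_circle(anchor_state, store, cfg, baits, nt_refs,
                                   species, anchor_name)
    if anchor_circle is not None:
        circles.append(anchor_circle)
    for name, seq in queue:
        closed = [c for c in circles if c.circular]
        if len(seq) < 31 or _redundant(seq, closed):
            stop_reasons[name] = "redundant_seed"
            continue
        state = extend_iteratively(seq, store, cfg)
        stop_reasons[name] = state.stop_reason
        circle = _finish_circle(state, store, cfg, baits, nt_refs,
                                species, name)
        if circle is None:
            continue
        if _redundant(circle.seq[: min(len(circle.seq), 500)], closed):
            stop_reasons[name] = "redundant_contig"
            continue
        circles.append(circle)

    # a linear leftover largely contained in a finished circle is an
    # assembly shadow of that circle, not a chromosome of its own
    closed = [c for c in circles if c.circular]
    circles = closed + [
        c for c in circles
        if not c.circular and _covered_fraction(c.seq, closed) < 0.6
    ]
    manifest.record("extension", candidates=len(queue),
                    circles=len(circles), stop_reasons=stop_reasons)

    if not circles:
        raise PipelineError("extension", "no contig could be assembled")

    # -- conserved blocks, CR delimitation, masking -----------------------
    blocks: list[str] = []
    if len(circles) >= 2:
        blocks, _hits = find_conserved_blocks(circles, cfg)
    for circle in circles:
        cr, _inter, warn = delimit_regions(circle, circle.genes,
                                           blocks or None) \
            if circle.genes else (None, [], True)
        circle.cr_span = cr
    masked: list[Minicircle] = []
    for circle in circles:
        if circle.circular and circle.cr_span is not None:
            _prof, placements = _circular_profile(circle.seq, store, cfg)
            masked.append(mask_cr_ambiguities(circle, placements, store))
        else:
            masked.append(circle)
    manifest.record("typing", conserved_blocks=len(blocks))

    # -- dedupe + stats ----------------------------------------------------
    kept, removed = dedupe_contigs(masked)
    for i, c in enumerate(sorted(kept, key=lambda c: c.id)):
        c.id = f"{species}_mc{i + 1:02d}"
    genome = GenomeSet(species=species, circles=sorted(kept, key=lambda c: c.id))
    stats = genome_stats(genome)
    manifest.record(
        "genome", circles=len(genome.circles), removed_duplicates=removed,
        stats=stats.iloc[0].to_dict(),
        fasta_sha=_sha("".join(c.seq for c in genome.circles)),
    )
    return genome, manifest


def measure_cr_ratio(cfg: PipelineConfig, pairs: list[ReadPair],
                     baits: list[SequenceRecord],
                     nt_refs: list[SequenceRecord] | None = None,
                     ) -> float:
    """CR/coding depth ratio of the anchor contig.

    Runs read prep, protein-baited seeding, extension of the largest seed
    and coverage segmentation, then returns mean(high)/mean(low) — the
    coverage-multiplication signal that counts the circles sharing the
    conserved control-region core.
    """
    nt_refs = nt_refs or []
    survivors, _log = prepare_pairs(pairs, cfg)
    store = ReadStore(survivors)
    pools = recruit_pairs(store, baits)
    bid = max(pools, key=lambda b: (len(pools[b]), b))
    seed = trim_low_coverage(
        select_best_contig(assemble_greedy(pools[bid], provenance=bid))
    )
    state = extend_iteratively(seed.seq, store, cfg)
    _window, _boundary, sp = _boundary_window(state, store, cfg, baits,
                                              nt_refs)
    if sp is None:
        raise PipelineError("coverage_boundary",
                            "anchor contig could not be segmented")
    return sp.ratio


def _boundary_window(anchor_state, store: ReadStore, cfg: PipelineConfig,
                     baits, nt_refs):
    """Profile the anchor contig, segment it, and cut the 250 bp window
    ending at the CR->coding boundary."""
    contig = anchor_state.contig
    if anchor_state.circularized and anchor_state.repeat_len:
        seq = collapse_terminal_repeat(contig.seq, anchor_state.repeat_len)
        genes = annotate_genes(seq, baits, nt_refs)
        if genes:
            # rotate the circle so the origin sits 150 nt before the
            # largest annotation-free arc (the control region): the whole
            # CR and its high-coverage conserved core are then contiguous
            # near the front, no coverage segment wraps the linearized
            # ends, and the leading low-coverage stretch stays wide enough
            # to survive segment merging
            n = len(seq)
            occ = sorted((g.start % n, g.start % n + len(g)) for g in genes)
            gaps = [(s2 - e1, e1, s2)
                    for (s1, e1), (s2, e2) in zip(occ, occ[1:]) if s2 > e1]
            gaps.append((occ[0][0] + n - occ[-1][1], occ[-1][1], occ[0][0] + n))
            _glen, gs, _ge = max(gaps)
            shift = (gs - 150) % n
            seq = seq[shift:] + seq[:shift]
            genes = annotate_genes(seq, baits, nt_refs)
        circular = True
    else:
        seq = contig.seq
        genes = annotate_genes(seq, baits, nt_refs)
        genes = [g for g in genes if g.end <= len(seq)]
        circular = False
    if not genes:
        return None, None, None
    prof, _pl = (_circular_profile(seq, store, cfg) if circular
                 else (profile_coverage(
                     map_reads(store, seq, cfg.map_min_identity,
                               cfg.map_min_anchor_nt), len(seq), "anchor"),
                     None))
    try:
        sp = segment_profile(prof)
        spans = [(g.start % len(seq), (g.start % len(seq)) + len(g))
                 for g in genes]
        boundary = locate_cr_coding_boundary(sp, spans)
    except (BoundaryError, ValueError):
        return None, None, None
    window, _trunc = extract_upstream_window(seq, boundary,
                                             cfg.upstream_window_nt,
                                             circular=circular)
    if len(window.seq) < 100:
        return None, None, sp
    return window, boundary, sp
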