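"""Read cleaning, deduplication and subsampling.

The cleaning rules operate per mate: a fixed 5 nt clip from the 5' end,
then repeated removal of the 3'-terminal base while its phred quality is
below the cutoff (a 1 nt sliding window), and finally the whole pair is
discarded if either mate dropped below the minimum length.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field

import numpy as np

from .config import ConfigError, PipelineConfig
from .containers import ReadPair, SequenceRecord


@dataclass
class DiscardLog:
    """Counts of pairs surviving / discarded per reason."""

    pairs_in: int = 0
    survivors: int = 0
    discarded_short: int = 0
    discarded_duplicate: int = 0
    extra: dict[str, int] = field(default_factory=dict)

    def as_rows(self) -> list[tuple[str, int]]:
        rows = [
            ("pairs_in", self.pairs_in),
            ("survivors", self.survivors),
            ("discarded_short", self.discarded_short),
            ("discarded_duplicate", self.discarded_duplicate),
        ]
        rows.extend(sorted(self.extra.items()))
        return rows

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("reason\tcount\n")
            for reason, count in self.as_rows():
                fh.write(f"{reason}\t{count}\n")


def dedupe_pairs(pairs: Iterable[ReadPair],
                 log: DiscardLog | None = None) -> Iterator[ReadPair]:
    """Keep the first occurrence of each exact (mate1.seq, mate2.seq) pair."""
    seen: set[tuple[str, str]] = set()
    for pair in pairs:
        key = (pair.mate1.seq, pair.mate2.seq)
        if key in seen:
            if log is not None:
                log.discarded_duplicate += 1
            continue
        seen.add(key)
        yield pair


def _clean_mate(mate: SequenceRecord, cfg: PipelineConfig) -> SequenceRecord:
    if mate.qual is None:
        raise ConfigError(f"read {mate.id!r} has no qualities; cleaning needs them")
    seq = mate.seq[cfg.clip5_nt :]
    qual = mate.qual[cfg.clip5_nt :]
    end = len(seq)
    while end > 0 and qual[end - 1] < cfg.qual_cutoff:
        end -= 1
    if end == 0:
        return SequenceRecord(mate.id, "N", [0])  # sentinel; always sub-length
    return SequenceRecord(mate.id, seq[:end], qual[:end])


def clean_reads(pairs: Iterable[ReadPair], cfg: PipelineConfig,
                log: DiscardLog | None = None) -> Iterator[ReadPair]:
    """Apply clip / 3'-quality-trim / length rules; drop failing pairs whole."""
    own_log = log if log is not None else DiscardLog()
    for pair in pairs:
        own_log.pairs_in += 1
        m1 = _clean_mate(pair.mate1, cfg)
        m2 = _clean_mate(pair.mate2, cfg)
        if len(m1) < cfg.min_read_len or len(m2) < cfg.min_read_len:
            own_log.discarded_short += 1
            continue
        own_log.survivors += 1
        yield ReadPair(m1, m2)


def subsample_pairs(pairs: Iterable[ReadPair], frac: float,
                    seed: int) -> Iterator[ReadPair]:
    """Retain each pair independently with probability ``frac`` (seeded)."""
    if not 0.0 < frac <= 1.0:
        raise ValueError(f"subsample fraction {frac} outside (0, 1]")
    if frac == 1.0:
        yield from pairs
        return
    rng = np.random.default_rng(seed)
    for pair in pairs:
        if rng.random() < frac:
            yield pair


def prepare_pairs(pairs: Iterable[ReadPair], cfg: PipelineConfig,
                  ) -> tuple[list[ReadPair], DiscardLog]:
    """dedupe -> clean -> subsample, returning survivors and the log."""
    log = DiscardLog()
    cleaned = clean_reads(dedupe_pairs(pairs, log), cfg, log)
    survivors = list(subsample_pairs(cleaned, cfg.subsample_frac, cfg.rng_seed))
    log.extra["after_subsample"] = len(survivors)
    return survivors, log
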