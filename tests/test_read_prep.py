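"""Read cleaning, deduplication and subsampling rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from minicircler.config import ConfigError, PipelineConfig
from minicircler.containers import ReadPair, SequenceRecord
from minicircler.read_prep import (
    DiscardLog,
    clean_reads,
    dedupe_pairs,
    subsample_pairs,
)


def make_pair(i, seq1, seq2, q1=None, q2=None):
    q1 = q1 if q1 is not None else [40] * len(seq1)
    q2 = q2 if q2 is not None else [40] * len(seq2)
    return ReadPair(
        SequenceRecord(f"r{i}/1", seq1, q1),
        SequenceRecord(f"r{i}/2", seq2, q2),
    )


def random_pair(rng, i, n=150):
    s1 = "".join(rng.choice(list("ACGT"), size=n))
    s2 = "".join(rng.choice(list("ACGT"), size=n))
    return make_pair(i, s1, s2)


class TestDedupe:
    def test_distinct_pairs_pass_through(self):
        rng = np.random.default_rng(0)
        pairs = [random_pair(rng, i) for i in range(3)]
        assert list(dedupe_pairs(pairs)) == pairs

    def test_exact_duplicates_removed(self):
        rng = np.random.default_rng(0)
        a, b = random_pair(rng, 0), random_pair(rng, 1)
        dup = make_pair(9, a.mate1.seq, a.mate2.seq)
        assert [p.mate1.id for p in dedupe_pairs([a, dup, b])] == ["r0/1", "r1/1"]

    def test_injected_duplicates_match_set_oracle(self):
        rng = np.random.default_rng(7)
        base = [random_pair(rng, i) for i in range(900)]
        dups = [make_pair(1000 + i, p.mate1.seq, p.mate2.seq)
                for i, p in enumerate(rng.choice(base, size=100))]
        pool = base + dups
        order = rng.permutation(len(pool))
        pool = [pool[i] for i in order]
        survivors = list(dedupe_pairs(pool))
        oracle = {(p.mate1.seq, p.mate2.seq) for p in pool}
        assert len(survivors) == len(oracle)


class TestClean:
    def test_high_quality_mate_loses_only_the_5prime_clip(self, cfg):
        pair = make_pair(0, "A" * 150, "C" * 150)
        out = list(clean_reads([pair], cfg))
        assert len(out[0].mate1.seq) == 145
        assert len(out[0].mate2.seq) == 145

    def test_long_low_quality_tail_discards_the_pair(self, cfg):
        q = [40] * 70 + [27] * 80          # 65 nt survive after clip+trim
        pair = make_pair(0, "A" * 150, "C" * 150, q1=q)
        log = DiscardLog()
        out = list(clean_reads([pair], cfg, log))
        assert out == []
        assert log.discarded_short == 1

    def test_mixed_tails_match_hand_applied_rule(self, cfg):
        rng = np.random.default_rng(3)
        pairs, expected = [], []
        for i in range(10):
            s1 = "".join(rng.choice(list("ACGT"), size=150))
            s2 = "".join(rng.choice(list("ACGT"), size=150))
            tail1, tail2 = int(rng.integers(0, 80)), int(rng.integers(0, 80))
            q1 = [40] * (150 - tail1) + [20] * tail1
            q2 = [40] * (150 - tail2) + [20] * tail2
            pairs.append(make_pair(i, s1, s2, q1, q2))
            m1, m2 = s1[5:150 - tail1], s2[5:150 - tail2]
            if len(m1) >= 75 and len(m2) >= 75:
                expected.append((m1, m2))
        got = [(p.mate1.seq, p.mate2.seq) for p in clean_reads(pairs, cfg)]
        assert got == expected

    def test_internal_low_quality_bases_survive(self, cfg):
        # trimming is strictly 3'-terminal: an interior Q20 base stays
        q = [40] * 50 + [20] + [40] * 99
        pair = make_pair(0, "A" * 150, "C" * 150, q1=q)
        out = list(clean_reads([pair], cfg))
        assert len(out[0].mate1.seq) == 145

    def test_missing_qualities_is_a_configuration_error(self, cfg):
        pair = ReadPair(
            SequenceRecord("x/1", "ACGT" * 40),
            SequenceRecord("x/2", "ACGT" * 40),
        )
        with pytest.raises(ConfigError):
            list(clean_reads([pair], cfg))

    def test_pair_accounting_is_conserved(self, cfg):
        rng = np.random.default_rng(11)
        pairs = []
        for i in range(60):
            tail = int(rng.integers(0, 120))
            q = [40] * (150 - tail) + [10] * tail
            pairs.append(make_pair(i, "".join(rng.choice(list("ACGT"), 150)),
                                   "".join(rng.choice(list("ACGT"), 150)),
                                   q1=q))
        log = DiscardLog()
        survivors = list(clean_reads(pairs, cfg, log))
        assert log.pairs_in == len(survivors) + log.discarded_short

    @given(tail=st.integers(0, 150), n=st.integers(75, 150))
    @settings(max_examples=30, derandomize=True)
    def test_cleaning_never_lengthens_a_mate(self, tail, n):
        cfg = PipelineConfig(subsample_frac=1.0)
        tail = min(tail, n)
        q = [40] * (n - tail) + [20] * tail
        pair = make_pair(0, "A" * n, "C" * n, q1=q)
        for out in clean_reads([pair], cfg):
            assert len(out.mate1.seq) <= n
            assert len(out.mate1.seq) >= cfg.min_read_len
            assert len(out.mate2.seq) >= cfg.min_read_len


class TestSubsample:
    def test_full_fraction_is_identity(self):
        rng = np.random.default_rng(0)
        pairs = [random_pair(rng, i, 20) for i in range(50)]
        assert list(subsample_pairs(pairs, 1.0, seed=0)) == pairs

    def test_retained_count_within_binomial_bound(self):
        n, frac = 100_000, 0.10
        pairs = [make_pair(i, "ACGTACGTAC", "ACGTACGTAC") for i in range(n)]
        kept = sum(1 for _ in subsample_pairs(pairs, frac, seed=5))
        sigma = (n * frac * (1 - frac)) ** 0.5
        assert abs(kept - n * frac) < 4 * sigma

    def test_same_seed_reproduces_the_survivor_set(self):
        rng = np.random.default_rng(1)
        pairs = [random_pair(rng, i, 20) for i in range(500)]
        a = [p.mate1.id for p in subsample_pairs(pairs, 0.3, seed=9)]
        b = [p.mate1.id for p in subsample_pairs(pairs, 0.3, seed=9)]
        assert a == b

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            list(subsample_pairs([], 0.0, seed=0))


def test_dedupe_then_clean_equals_clean_then_dedupe_on_unique_input(cfg):
    rng = np.random.default_rng(2)
    pairs = [random_pair(rng, i) for i in range(40)]
    a = [(p.mate1.seq, p.mate2.seq)
         for p in clean_reads(dedupe_pairs(pairs), cfg)]
    b = [(p.mate1.seq, p.mate2.seq)
         for p in dedupe_pairs(clean_reads(pairs, cfg))]
    assert a == b
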