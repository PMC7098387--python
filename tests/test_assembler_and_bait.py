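"""Greedy overlap assembly, contig selection, and read recruitment."""

import itertools

import numpy as np
import pytest

from minicircler.align import Mapper, ReadStore
from minicircler.assembler import (
    AssemblyError,
    assemble_greedy,
    assemble_recruited,
    select_best_contig,
)
from minicircler.bait import BaitError, ProteinBaitSet, recruit_pairs
from minicircler.containers import Contig, ReadPair, SequenceRecord
from minicircler.genetics import revcomp, translate_mito
from tests.conftest import random_dna


def tile(seq, read_len=100, step=10):
    return [seq[i : i + read_len]
            for i in range(0, len(seq) - read_len + 1, step)]


class TestAssembler:
    def test_tiling_reads_reassemble_the_full_gene(self):
        rng = np.random.default_rng(0)
        gene = random_dna(rng, 1530)
        reads = tile(gene) * 3                    # ~30x, error-free
        contigs = assemble_greedy(reads)
        assert gene in contigs[0].seq
        assert len(contigs[0].seq) == 1530

    def test_disjoint_reads_stay_singletons(self):
        rng = np.random.default_rng(1)
        a, b = random_dna(rng, 100), random_dna(rng, 100)
        contigs = assemble_greedy([a, b])
        assert sorted(c.seq for c in contigs) == sorted([a, b])

    def test_two_gene_pool_assembles_without_chimeras(self):
        rng = np.random.default_rng(2)
        g1, g2 = random_dna(rng, 800), random_dna(rng, 800)
        contigs = assemble_greedy(tile(g1) * 2 + tile(g2) * 2)
        big = [c for c in contigs if len(c) >= 700]
        assert len(big) == 2
        for c in big:
            assert (c.seq in g1) or (c.seq in g2)

    def test_assembly_is_input_order_invariant(self):
        rng = np.random.default_rng(3)
        gene = random_dna(rng, 500)
        reads = tile(gene, 90, 17) * 2
        ref = [c.seq for c in assemble_greedy(reads)]
        for perm_seed in range(3):
            prng = np.random.default_rng(perm_seed)
            shuffled = [reads[i] for i in prng.permutation(len(reads))]
            assert [c.seq for c in assemble_greedy(shuffled)] == ref

    def test_every_contig_base_has_read_support(self):
        rng = np.random.default_rng(4)
        gene = random_dna(rng, 600)
        for contig in assemble_greedy(tile(gene) * 2):
            assert (contig.coverage >= 1).all()

    def test_needs_two_reads(self):
        with pytest.raises(AssemblyError):
            assemble_recruited(["ACGT" * 20])


class TestSelectBestContig:
    def _contig(self, seq, cov):
        return Contig("x", seq, np.full(len(seq), cov))

    def test_single_contig_returned(self):
        c = self._contig("ACGT" * 30, 5)
        assert select_best_contig([c]) is c

    def test_longest_wins(self):
        short = self._contig("A" * 800, 50)
        long = self._contig("C" * 900, 10)
        assert select_best_contig([short, long]) is long

    def test_coverage_breaks_length_ties_order_independently(self):
        a = self._contig("A" * 500, 40)
        b = self._contig("C" * 500, 20)
        for perm in itertools.permutations([a, b]):
            assert select_best_contig(list(perm)) is a

    def test_empty_selection_is_an_error(self):
        with pytest.raises(AssemblyError):
            select_best_contig([])


def _pairs_from(seqs):
    return [
        ReadPair(
            SequenceRecord(f"p{i}/1", s),
            SequenceRecord(f"p{i}/2", revcomp(s)),
        )
        for i, s in enumerate(seqs)
    ]


class TestRecruitment:
    def test_reads_overlapping_the_gene_are_recruited(self, sim_k5, store_k5):
        params, truth, _pairs, table = sim_k5
        bait = next(b for b in truth.baits if b.id == "cox1")
        pools = recruit_pairs(store_k5, [bait])
        circle = truth.circle("circle_cox1")
        gene = next(g for g in circle.genes if g.label == "cox1")
        eligible = []
        for _i, row in table[table.circle_id == "circle_cox1"].iterrows():
            # overlap of either mate with the gene by >= 60 nt
            m1 = (row.start, row.start + params.read_len)
            m2 = (row.start + row.frag_len - params.read_len,
                  row.start + row.frag_len)
            def ov(span):
                s, e = span
                return max(0, min(e, gene.end) - max(s, gene.start))
            if max(ov(m1), ov(m2)) >= 60:
                eligible.append(row.read_id)
        assert len(eligible) > 20
        # recruited pool stores oriented sequences; count matching pairs
        pool_seqs = set(pools["cox1"])
        hit = 0
        id_to_idx = {rid: i for i, rid in enumerate(store_k5.ids)}
        for rid in eligible:
            idxs = [id_to_idx.get(rid + "/1"), id_to_idx.get(rid + "/2")]
            variants = set()
            for idx in idxs:
                if idx is not None:
                    variants.add(store_k5.seqs[idx])
                    variants.add(store_k5.rev_seqs[idx])
            if variants & pool_seqs:
                hit += 1
        assert hit / len(eligible) >= 0.95

    def test_control_region_reads_match_no_protein_bait(self, sim_k5):
        params, truth, _pairs, _table = sim_k5
        rng = np.random.default_rng(5)
        circle = truth.circle("circle_cox1")
        cr = circle.seq[circle.cr_span[0]:]
        reads = [cr[i : i + 145] for i in
                 rng.integers(0, len(cr) - 145, size=60)]
        store = ReadStore(_pairs_from(reads))
        pools = recruit_pairs(store, truth.baits)
        assert all(len(pool) == 0 for pool in pools.values())

    def test_exact_back_translation_hits_in_frame_plus_one(self):
        rng = np.random.default_rng(6)
        from minicircler.simulate import _random_orf

        orf = _random_orf(rng, 300, 0.65)
        bait = SequenceRecord("cox3", translate_mito(orf)[:-1])
        baitset = ProteinBaitSet([bait])
        hits = baitset.best_hits(SequenceRecord("read", orf[:150]))
        assert len(hits) == 1
        assert hits[0].frame == 1
        # the same residues in any other frame cannot score higher
        assert hits[0].score >= 40

    def test_short_bait_rejected(self):
        with pytest.raises(BaitError):
            ProteinBaitSet([SequenceRecord("tiny", "MKL")])


class TestMapper:
    def test_read_matching_contig_end_records_the_overhang(self):
        rng = np.random.default_rng(7)
        contig = random_dna(rng, 400)
        read = contig[-60:] + random_dna(rng, 90)
        mapper = Mapper(contig, min_anchor=40)
        placements = mapper.map_sequence(read)
        assert any(
            len(p.right_overhang) == 90 and p.t_end == 400
            for p in placements
        )

    def test_unrelated_sequence_is_not_placed(self):
        rng = np.random.default_rng(8)
        mapper = Mapper(random_dna(rng, 500))
        assert mapper.map_sequence(random_dna(rng, 150)) == []

    def test_most_own_reads_place_on_their_reference(self, sim_k5, store_k5, cfg):
        _params, truth, _pairs, table = sim_k5
        circle = truth.circle("circle_cob")
        mapper = Mapper(circle.seq + circle.seq[:300])
        placed = {
            p.read_idx for p in mapper.map_store(store_k5)
        }
        own = table[table.circle_id == "circle_cob"]
        id_to_idx = {rid: i for i, rid in enumerate(store_k5.ids)}
        total, hit = 0, 0
        for rid in own.read_id:
            for suffix in ("/1", "/2"):
                idx = id_to_idx.get(rid + suffix)
                if idx is not None:
                    total += 1
                    hit += idx in placed
        assert total > 100
        assert hit / total >= 0.99
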