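"""Homology annotation, region delimitation, ambiguity masking."""

import numpy as np
import pytest

from minicircler.align import Placement, ReadStore
from minicircler.annotate import (
    AnnotationError,
    annotate_genes,
    delimit_regions,
    mask_cr_ambiguities,
)
from minicircler.containers import (
    GeneAnnotation,
    Minicircle,
    ReadPair,
    SequenceRecord,
)
from minicircler.genetics import revcomp, translate_mito
from minicircler.simulate import SimParams, simulate_genome
from tests.conftest import random_dna


@pytest.fixture(scope="module")
def annotated_truth(sim_k5):
    """Annotations recomputed on every simulated K=5 circle."""
    _params, truth, _pairs, _table = sim_k5
    out = []
    for circle in truth.circles:
        calls = annotate_genes(circle.seq, truth.baits, truth.nt_refs)
        out.append((circle, calls))
    return out


def test_pcg_annotation_recovers_span_and_strand(annotated_truth):
    for circle, calls in annotated_truth:
        for gene in circle.genes:
            if gene.label.startswith(("trn", "rrn")):
                continue
            hit = next(c for c in calls if c.label == gene.label)
            assert hit.strand == gene.strand
            assert abs(hit.start - gene.start) <= 3
            assert abs(hit.end - gene.end) <= 3


def test_annotation_recall_and_label_accuracy(annotated_truth):
    pcg_total = pcg_hit = trna_total = trna_hit = 0
    for circle, calls in annotated_truth:
        truth_labels = {g.label for g in circle.genes}
        call_labels = {c.label for c in calls}
        assert call_labels <= truth_labels          # no spurious labels
        for g in circle.genes:
            if g.label.startswith("trn"):
                trna_total += 1
                trna_hit += g.label in call_labels
            else:
                pcg_total += 1
                pcg_hit += g.label in call_labels
    assert pcg_hit / pcg_total >= 0.95
    assert trna_hit / trna_total >= 0.80


def test_annotated_pcg_translations_are_stop_free(annotated_truth):
    for circle, calls in annotated_truth:
        doubled = circle.seq + circle.seq
        for c in calls:
            if c.label.startswith(("trn", "rrn")):
                continue
            seq = doubled[c.start : c.end]
            if c.strand == "-":
                seq = revcomp(seq)
            pep = translate_mito(seq)
            assert "*" not in pep[:-1]


def test_trna_only_circle_gets_only_trna_calls(annotated_truth):
    saw_trna_only = False
    for circle, calls in annotated_truth:
        if all(g.label.startswith("trn") for g in circle.genes):
            saw_trna_only = True
            assert calls
            assert all(c.label.startswith("trn") for c in calls)
    assert saw_trna_only


def test_unrelated_sequence_annotates_empty(sim_k5):
    _params, truth, _pairs, _table = sim_k5
    rng = np.random.default_rng(0)
    assert annotate_genes(random_dna(rng, 1200), truth.baits,
                          truth.nt_refs) == []


def test_empty_reference_set_is_an_error():
    with pytest.raises(AnnotationError):
        annotate_genes("ACGT" * 300, [], [])


class TestDelimit:
    def test_single_gene_circle_cr_is_the_complementary_arc(self):
        rng = np.random.default_rng(1)
        circle = Minicircle(id="c", seq=random_dna(rng, 1500))
        genes = [GeneAnnotation("cox1", 0, 900, "+")]
        cr, intergenic, warn = delimit_regions(circle, genes)
        assert not warn
        assert cr == (900, 1500)

    def test_simulated_cr_span_overlaps_truth(self, sim_k5, annotated_truth):
        _params, truth, _pairs, _table = sim_k5
        for circle, calls in annotated_truth:
            mc = Minicircle(id=circle.id, seq=circle.seq)
            cr, _inter, warn = delimit_regions(mc, calls,
                                               truth.conserved_blocks)
            assert not warn
            n = len(circle.seq)
            got = {(cr[0] + i) % n for i in range(cr[1] - cr[0])}
            want = {(circle.cr_span[0] + i) % n
                    for i in range(circle.cr_span[1] - circle.cr_span[0])}
            jaccard = len(got & want) / len(got | want)
            assert jaccard >= 0.9

    def test_fully_coding_circle_warns(self):
        rng = np.random.default_rng(2)
        circle = Minicircle(id="c", seq=random_dna(rng, 600))
        genes = [GeneAnnotation("cox1", 0, 550, "+")]
        _cr, _inter, warn = delimit_regions(circle, genes)
        assert warn


class TestMasking:
    def _setup(self, bases_at_150):
        rng = np.random.default_rng(3)
        seq = random_dna(rng, 300)
        circle = Minicircle(id="c", seq=seq, cr_span=(100, 200),
                            genes=[GeneAnnotation("trnI", 0, 70, "+")])
        pairs, placements = [], []
        for i, base in enumerate(bases_at_150):
            read = seq[120:150] + base + seq[151:181]
            pairs.append(ReadPair(SequenceRecord(f"m{i}/1", read),
                                  SequenceRecord(f"m{i}/2", revcomp(read))))
            placements.append(Placement(2 * i, "+", 0, 61, 120, 181, 1.0, 61))
        return circle, placements, ReadStore(pairs)

    def test_unanimous_columns_unchanged(self):
        probe, _p, _s = self._setup(["A"])
        true_base = probe.seq[150]
        circle, placements, store = self._setup([true_base] * 5)
        masked = mask_cr_ambiguities(circle, placements, store)
        assert masked.seq == circle.seq

    def test_strong_minor_allele_becomes_iupac_code(self):
        circle, placements, store = self._setup(list("AAAGG"))
        masked = mask_cr_ambiguities(circle, placements, store)
        assert masked.seq[150] == "R"          # A/G
        assert masked.seq[:150] == circle.seq[:150]

    def test_coding_columns_are_never_masked(self):
        rng = np.random.default_rng(4)
        seq = random_dna(rng, 300)
        circle = Minicircle(id="c", seq=seq, cr_span=(200, 290),
                            genes=[GeneAnnotation("trnI", 100, 170, "+")])
        pairs, placements = [], []
        for i, base in enumerate("AAAGG"):
            read = seq[120:150] + base + seq[151:181]
            pairs.append(ReadPair(SequenceRecord(f"m{i}/1", read),
                                  SequenceRecord(f"m{i}/2", revcomp(read))))
            placements.append(Placement(2 * i, "+", 0, 61, 120, 181, 1.0, 61))
        masked = mask_cr_ambiguities(circle, placements, ReadStore(pairs))
        assert masked.seq == seq               # position 150 is coding-side
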