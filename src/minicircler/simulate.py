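"""Synthetic fragmented-mitogenome generator.

Emulates the minicircle architecture the pipeline targets: K small circular
chromosomes (~1.1-3.1 kb), each carrying one protein-coding or rRNA gene
plus 0-3 tRNAs (two circles carry only tRNAs), and a control region built
from motif blocks shared verbatim across circles flanked by circle-specific
spacers.  Coding sequence is AT-biased (~65%) and protein genes are valid
ORFs under the invertebrate mitochondrial code; per-circle copy number
varies log-uniformly.  Paired-end reads wrap the circular origin and carry
substitution errors plus occasional low-quality 3' tails.

Circle layout (plus strand, position 0 = first gene):

    genes+intergenic | spacer1 | conserved core (block1+block2) | spacer2 | ->wrap

so the conserved core sits immediately upstream of the coding start across
the origin, the geometry the boundary-harvesting stage exploits.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    GeneAnnotation,
    Minicircle,
    PCG_NAMES,
    ReadPair,
    SequenceRecord,
)
from .genetics import STOP_CODONS_5, revcomp, translate_mito

#: Nucleotide lengths (incl. stop codon) used for the simulated PCGs;
#: typical insect mitochondrial values.
PCG_LENGTHS: dict[str, int] = {
    "cox1": 1530, "cob": 1134, "nad5": 1716, "cox2": 684, "cox3": 789,
    "nad1": 936, "nad2": 1020, "nad4": 1338, "nad3": 351, "nad6": 522,
    "atp6": 678, "nad4l": 291, "atp8": 159,
}

#: Order in which protein/rRNA carrier circles are created when K < 17.
CARRIER_ORDER: tuple[str, ...] = (
    "cox1", "cob", "nad5", "rrnL", "rrnS", "cox2", "cox3", "nad1",
    "nad2", "nad4", "nad3", "nad6", "atp6", "nad4l", "atp8",
)


class SimulationParameterError(ValueError):
    """Requested architecture cannot be generated."""


@dataclass
class SimParams:
    n_circles: int = 17
    circle_len_range: tuple[int, int] = (1100, 3100)
    genes_per_circle: tuple[int, int] = (1, 4)
    cr_conserved_blocks: tuple[int, ...] = (120, 80)
    cr_variable_len_range: tuple[int, int] = (100, 600)
    coding_at_frac: float = 0.65
    copy_number_range: tuple[float, float] = (0.5, 2.0)
    read_len: int = 150
    insert_mean: int = 400
    insert_sd: int = 40
    depth: float = 50.0
    subst_error: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.subst_error < 0.25:
            raise SimulationParameterError("subst_error must be in [0, 0.25)")
        if self.circle_len_range[0] <= 0:
            raise SimulationParameterError("circle lengths must be positive")
        gmin, gmax = self.genes_per_circle
        if gmin < 1 or gmax > 4 or gmin > gmax:
            raise SimulationParameterError("genes_per_circle must sit in [1, 4]")
        if self.n_circles < 1:
            raise SimulationParameterError("need at least one circle")
        if self.n_circles > len(CARRIER_ORDER) + 2:
            raise SimulationParameterError(
                f"at most {len(CARRIER_ORDER) + 2} circles supported "
                "(one per PCG/rRNA plus two tRNA-only circles)"
            )


@dataclass
class CircleTruth:
    id: str
    seq: str
    cr_span: tuple[int, int]
    genes: list[GeneAnnotation]
    copy_number: float

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class SimTruth:
    circles: list[CircleTruth]
    conserved_blocks: list[str]
    baits: list[SequenceRecord] = field(default_factory=list)
    nt_refs: list[SequenceRecord] = field(default_factory=list)

    def circle(self, circle_id: str) -> CircleTruth:
        return next(c for c in self.circles if c.id == circle_id)

    def as_minicircles(self, species: str = "sim") -> list[Minicircle]:
        return [
            Minicircle(
                id=c.id, seq=c.seq, circular=True, cr_span=c.cr_span,
                genes=list(c.genes), species=species,
            )
            for c in self.circles
        ]


def load_reference_set() -> list[SequenceRecord]:
    """The bundled synthetic tRNA/rRNA placeholder sequences."""
    path = importlib.resources.files("minicircler.data").joinpath(
        "synthetic_mito_refs.fasta"
    )
    records: list[SequenceRecord] = []
    name, chunks = None, []
    for line in path.read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                records.append(SequenceRecord(name, "".join(chunks)))
            name, chunks = line[1:].strip(), []
        elif line:
            chunks.append(line.strip())
    if name is not None:
        records.append(SequenceRecord(name, "".join(chunks)))
    return records


def _random_seq(rng: np.random.Generator, n: int, at: float) -> str:
    probs = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs)) if n else ""


def _random_orf(rng: np.random.Generator, n_nt: int, at: float) -> str:
    """Start codon, stop-free interior, TAA terminator (table 5)."""
    assert n_nt % 3 == 0 and n_nt >= 9
    codons = [rng.choice(["ATA", "ATG"])]
    while len(codons) < n_nt // 3 - 1:
        codon = _random_seq(rng, 3, at)
        if codon not in STOP_CODONS_5:
            codons.append(codon)
    codons.append("TAA")
    return "".join(codons)


def simulate_genome(p: SimParams) -> SimTruth:
    rng = np.random.default_rng(p.seed)
    refs = {r.id: r.seq for r in load_reference_set()}
    trna_names = [n for n in refs if n.startswith("trn")]
    gmin, gmax = p.genes_per_circle

    blocks = [_random_seq(rng, n, 0.70) for n in p.cr_conserved_blocks]
    core = "".join(blocks)

    k = p.n_circles
    n_only = 2 if (k >= 4 and gmax >= 2) else 0
    carriers = list(CARRIER_ORDER[: k - n_only])
    if len(carriers) < k - n_only:
        raise SimulationParameterError("not enough distinct main genes")

    # distribute tRNA isotypes: tRNA-only circles first, then carriers
    pool = [str(x) for x in rng.permutation(trna_names)]
    circle_plans: list[tuple[str, list[str]]] = []
    for i in range(n_only):
        take = int(rng.integers(max(1, gmin), min(gmax, 4) + 1))
        take = min(take, max(1, len(pool) - (n_only - 1 - i)))
        mine, pool = pool[:take], pool[take:]
        circle_plans.append((f"circle_trn{i + 1}", mine))
    for name in carriers:
        cap = min(3, gmax - 1)
        take = int(rng.integers(0, cap + 1)) if cap > 0 else 0
        mine, pool = pool[:take], pool[take:]
        circle_plans.append((f"circle_{name}", [name] + mine))
    # spread any remaining isotypes over carriers with spare capacity
    for plan_id, genes in circle_plans:
        while pool and len(genes) < gmax and not plan_id.startswith("circle_trn"):
            genes.append(pool.pop(0))

    lo_len, hi_len = p.circle_len_range
    var_lo, var_hi = p.cr_variable_len_range
    circles: list[CircleTruth] = []
    baits: list[SequenceRecord] = []
    used_refs: dict[str, str] = {}

    for circle_id, gene_names in circle_plans:
        gene_names = [str(x) for x in rng.permutation(gene_names)]
        gene_seqs: dict[str, str] = {}
        for g in gene_names:
            if g in PCG_LENGTHS:
                orf = _random_orf(rng, PCG_LENGTHS[g], p.coding_at_frac)
                gene_seqs[g] = orf
                baits.append(SequenceRecord(g, translate_mito(orf)[:-1]))
            else:
                gene_seqs[g] = refs[g]
                used_refs[g] = refs[g]
        main = max(gene_names, key=lambda g: (len(gene_seqs[g]), g))

        spacer2 = int(rng.integers(60, 141))
        spacer1 = int(rng.integers(max(40, var_lo - spacer2),
                                   max(41, var_hi - spacer2 + 1)))
        coding, genes = "", []
        for g in gene_names:
            strand = "+" if (g == main or rng.random() < 0.5) else "-"
            seq = gene_seqs[g] if strand == "+" else revcomp(gene_seqs[g])
            start = len(coding)
            coding += seq
            genes.append(GeneAnnotation(g, start, len(coding), strand))
            coding += _random_seq(rng, int(rng.integers(0, 11)), p.coding_at_frac)
        baseline = len(coding) + spacer1 + len(core) + spacer2
        if baseline < lo_len:
            spacer1 += lo_len - baseline        # pad to the minimum circle size
        seq = (coding + _random_seq(rng, spacer1, 0.70) + core
               + _random_seq(rng, spacer2, 0.70))
        if len(seq) > hi_len:
            raise SimulationParameterError(
                f"{circle_id}: genes cannot fit the circle length range"
            )
        copy = float(np.exp(rng.uniform(*np.log(p.copy_number_range))))
        circles.append(CircleTruth(
            id=circle_id, seq=seq,
            cr_span=(len(coding), len(seq)),
            genes=genes, copy_number=copy,
        ))

    nt_refs = [SequenceRecord(n, refs[n]) for n in sorted(used_refs)]
    # keep one bait per PCG (first occurrence)
    seen: set[str] = set()
    baits = [b for b in baits if not (b.id in seen or seen.add(b.id))]
    return SimTruth(circles=circles, conserved_blocks=blocks,
                    baits=baits, nt_refs=nt_refs)


def simulate_reads(truth: SimTruth, p: SimParams,
                   ) -> tuple[list[ReadPair], pd.DataFrame]:
    """Paired reads plus the ground-truth placement table."""
    rng = np.random.default_rng(p.seed + 1)
    pairs: list[ReadPair] = []
    rows: list[tuple[str, str, int, int, str]] = []
    idx = 0
    for circle in truth.circles:
        n = len(circle)
        expected = n * p.depth * circle.copy_number / (2.0 * p.read_len)
        n_pairs = int(rng.poisson(expected)) if expected > 0 else 0
        if n_pairs == 0:
            continue
        doubled = circle.seq + circle.seq
        starts = rng.integers(0, n, size=n_pairs)
        flens = np.clip(
            np.rint(rng.normal(p.insert_mean, p.insert_sd, size=n_pairs)),
            p.read_len + 10, min(700, n),
        ).astype(int)
        strands = rng.random(n_pairs) < 0.5
        for s, fl, plus in zip(starts, flens, strands):
            frag = doubled[s : s + fl]
            if not plus:
                frag = revcomp(frag)
            m1 = frag[: p.read_len]
            m2 = revcomp(frag[-p.read_len :])
            rid = f"sim{idx:07d}"
            pair = ReadPair(
                _noisy_mate(rng, f"{rid}/1", m1, p),
                _noisy_mate(rng, f"{rid}/2", m2, p),
            )
            pairs.append(pair)
            rows.append((rid, circle.id, int(s), int(fl), "+" if plus else "-"))
            idx += 1
    table = pd.DataFrame(
        rows, columns=["read_id", "circle_id", "start", "frag_len", "strand"]
    )
    return pairs, table


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _noisy_mate(rng: np.random.Generator, rid: str, seq: str,
                p: SimParams) -> SequenceRecord:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < p.subst_error)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    qual = np.full(len(arr), 38, dtype=int)
    if rng.random() < 0.10:                      # low-quality 3' tail
        tail = int(rng.integers(5, 31))
        qual[-tail:] = 20
    return SequenceRecord(rid, arr.tobytes().decode(), qual.tolist())


def fragment_spans_origin(row: pd.Series, circle_len: int) -> bool:
    """True when a truth placement wraps the circle origin."""
    return row["start"] + row["frag_len"] > circle_len
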