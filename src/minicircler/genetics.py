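"""Nucleotide and protein sequence primitives.

Reverse complement, the invertebrate mitochondrial genetic code (NCBI
translation table 5), IUPAC ambiguity handling and base-composition
statistics used throughout the pipeline.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_COMPLEMENT = str.maketrans(
    "ACGTUacgtuRYSWKMBDHVNryswkmbdhvn",
    "TGCAAtgcaaYRSWMKVHDBNyrswmkvhdbn",
)

#: Codon -> amino acid for the invertebrate mitochondrial code (table 5).
_T5 = CodonTable.unambiguous_dna_by_id[5]
CODON_TABLE_5: dict[str, str] = dict(_T5.forward_table)
for _stop in _T5.stop_codons:
    CODON_TABLE_5[_stop] = "*"
START_CODONS_5: frozenset[str] = frozenset(_T5.start_codons)
STOP_CODONS_5: frozenset[str] = frozenset(_T5.stop_codons)

#: Base set -> IUPAC ambiguity code.
IUPAC_FROM_BASES: dict[frozenset[str], str] = {
    frozenset(b): c
    for c, b in {
        "A": "A", "C": "C", "G": "G", "T": "T",
        "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
        "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
        "H": "ACT", "V": "ACG", "N": "ACGT",
    }.items()
}

#: IUPAC code -> set of compatible unambiguous bases.
BASES_FROM_IUPAC: dict[str, frozenset[str]] = {
    c: b for b, c in IUPAC_FROM_BASES.items()
}

#: Pairs of IUPAC-compatible symbols, in the form edlib's additionalEqualities wants.
IUPAC_EQUALITIES: list[tuple[str, str]] = [
    (code, base)
    for code, bases in BASES_FROM_IUPAC.items()
    if len(bases) > 1
    for base in sorted(bases)
]


def revcomp(seq: str) -> str:
    """Reverse complement; IUPAC ambiguity codes are complemented too."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_mito(seq: str, frame: int = 0) -> str:
    """Translate ``seq`` from ``frame`` (0..2) with the invertebrate mito code.

    Trailing partial codons are dropped; codons containing non-ACGT symbols
    translate to ``X``; stops translate to ``*``.
    """
    table = CODON_TABLE_5
    end = len(seq) - (len(seq) - frame) % 3
    return "".join(
        table.get(seq[i : i + 3], "X") for i in range(frame, end, 3)
    )


def six_frame_translations(seq: str) -> list[tuple[int, str]]:
    """All six translated frames as ``(frame, peptide)``.

    Frames +1..+3 are 1,2,3; frames on the reverse strand are -1,-2,-3
    (frame -1 starts at the last base).
    """
    rc = revcomp(seq)
    out = []
    for f in range(3):
        out.append((f + 1, translate_mito(seq, f)))
    for f in range(3):
        out.append((-(f + 1), translate_mito(rc, f)))
    return out


def at_percent(seq: str) -> float:
    """A+T percentage.  Ambiguity codes count in the denominator only."""
    if not seq:
        return 0.0
    s = seq.upper()
    return 100.0 * (s.count("A") + s.count("T")) / len(s)
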