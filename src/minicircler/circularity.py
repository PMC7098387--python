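"""Circularity detection and canonical circular form.

A linear assembly of a circular chromosome ends in an exact duplicated
stretch (here: strictly >50 bp, so the 51 nt minimum).  The longest exact
prefix==suffix border is found with a KMP failure function, the suffix
copy is collapsed, and the circle is rotated (and strand-flipped) into a
deterministic canonical form: position 0 at the first base of the longest
annotated gene on the plus strand, or the lexicographically minimal
rotation of the lexicographically smaller strand when unannotated.
"""

from __future__ import annotations

from collections.abc import Sequence

from .containers import Contig, GeneAnnotation, Minicircle
from .genetics import revcomp


class MalformedContigError(ValueError):
    pass


def find_terminal_repeat(contig: Contig | str, min_len: int = 51) -> int | None:
    """Longest L >= min_len with seq[:L] == seq[-L:] exactly, else None.

    Ambiguity codes compare as ordinary (mismatching) characters.
    """
    seq = contig.seq if isinstance(contig, Contig) else contig
    n = len(seq)
    if n < 2 * min_len:
        return None
    # KMP failure function: fail[i] = longest proper border of seq[:i+1]
    fail = [0] * n
    k = 0
    for i in range(1, n):
        while k > 0 and seq[i] != seq[k]:
            k = fail[k - 1]
        if seq[i] == seq[k]:
            k += 1
        fail[i] = k
    border = fail[-1]
    return border if border >= min_len else None


def find_wrap_repeat(seq: str, min_len: int = 51, max_trim: int = 5,
                     ) -> tuple[int, int, int] | None:
    """Terminal-repeat search tolerating a few unsupported tip bases.

    Extension consensus can leave one or two contested bases at a contig
    tip; an exact prefix==suffix border then never forms even though the
    contig has wrapped.  This probes whether trimming up to ``max_trim``
    bases from either end exposes an exact terminal repeat, returning
    ``(repeat_len, trim5, trim3)`` for the first (smallest-trim) success.
    """
    n = len(seq)
    for trim5 in range(max_trim + 1):
        probe = seq[trim5 : trim5 + 30]
        if len(probe) < 30:
            return None
        idx = seq.rfind(probe, trim5 + 1)
        if idx <= trim5:
            continue
        # extend the match rightwards from the reoccurrence
        m = 30
        while idx + m < n and trim5 + m < idx and seq[trim5 + m] == seq[idx + m]:
            m += 1
        trim3 = n - (idx + m)
        if m >= min_len and 0 <= trim3 <= max_trim and idx + m <= n:
            inner = seq[trim5 : n - trim3]
            rep = find_terminal_repeat(inner, min_len)
            if rep is not None:
                return rep, trim5, trim3
    return None


def least_rotation(s: Sequence) -> int:
    """Booth's algorithm: index of the lexicographically minimal rotation."""
    n = len(s)
    doubled = list(s) + list(s)
    fail = [-1] * (2 * n)
    k = 0
    for j in range(1, 2 * n):
        i = fail[j - k - 1]
        while i != -1 and doubled[j] != doubled[k + i + 1]:
            if doubled[j] < doubled[k + i + 1]:
                k = j - i - 1
            i = fail[i]
        if doubled[j] != doubled[k + i + 1]:
            if doubled[j] < doubled[k]:
                k = j
            fail[j - k] = -1
        else:
            fail[j - k] = i + 1
    return k


def collapse_terminal_repeat(seq: str, repeat_len: int) -> str:
    if repeat_len >= len(seq):
        raise MalformedContigError(
            f"repeat length {repeat_len} >= contig length {len(seq)}"
        )
    return seq[: len(seq) - repeat_len]


def _shift_gene(gene: GeneAnnotation, shift: int, n: int) -> GeneAnnotation:
    start = (gene.start - shift) % n
    return GeneAnnotation(gene.label, start, start + len(gene),
                          gene.strand, gene.identity)


def _revcomp_gene(gene: GeneAnnotation, n: int) -> GeneAnnotation:
    start = (n - gene.end) % n
    strand = "-" if gene.strand == "+" else "+"
    return GeneAnnotation(gene.label, start, start + len(gene),
                          strand, gene.identity)


def canonical_rotation(seq: str, genes: list[GeneAnnotation],
                       ) -> tuple[str, list[GeneAnnotation]]:
    """Rotate/flip a circle into its deterministic canonical form."""
    n = len(seq)
    if genes:
        anchor = max(genes, key=lambda g: (len(g), g.label, -g.start))
        if anchor.strand == "-":
            seq = revcomp(seq)
            genes = [_revcomp_gene(g, n) for g in genes]
            anchor = next(
                g for g in genes
                if (g.label, len(g)) == (anchor.label, len(anchor))
            )
        shift = anchor.start % n
        seq = seq[shift:] + seq[:shift]
        genes = sorted(
            (_shift_gene(g, shift, n) for g in genes), key=lambda g: g.start
        )
        return seq, genes
    rc = revcomp(seq)
    cands = sorted(
        (s[least_rotation(s):] + s[: least_rotation(s)] for s in (seq, rc))
    )
    return cands[0], []


def canonicalize_circle(contig: Contig, repeat_len: int,
                        annotations: list[GeneAnnotation] | None = None,
                        species: str = "") -> Minicircle:
    """Collapse the terminal repeat and emit the canonical Minicircle."""
    collapsed = collapse_terminal_repeat(contig.seq, repeat_len)
    seq, genes = canonical_rotation(collapsed, list(annotations or []))
    mean_cov = float(contig.coverage.mean()) if len(contig.coverage) else 0.0
    return Minicircle(
        id=contig.id, seq=seq, circular=True, genes=genes,
        species=species, mean_coverage=mean_cov,
    )
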