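"""Readers and writers for the formats the pipeline touches.

FASTQ is phred+33 only.  GFF3 is emitted with 1-based inclusive
coordinates; circular chromosomes carry ``Is_circular=true`` on their
``region`` feature and origin-wrapping genes are split into two parts
joined by a shared ``ID``.
"""

from __future__ import annotations

import contextlib
import gzip
import itertools
from collections.abc import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .containers import GeneAnnotation, Minicircle, ReadPair, SequenceRecord


class FastqParseError(ValueError):
    """Malformed or truncated FASTQ input."""


class PairingError(ValueError):
    """Desynchronized mate files."""


def _open_text(path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[SequenceRecord]:
    """Iterate phred+33 FASTQ records, validating record structure."""
    with _open_text(path) as fh:
        for idx, (title, seq, qual) in enumerate(FastqGeneralIterator(fh)):
            if len(qual) != len(seq):
                raise FastqParseError(
                    f"{path}: record {idx} ({title.split()[0]!r}) quality "
                    f"length {len(qual)} != sequence length {len(seq)}"
                )
            yield SequenceRecord(
                id=title.split()[0],
                seq=seq.upper(),
                qual=[ord(c) - 33 for c in qual],
            )


def read_fastq_pairs(path1, path2) -> Iterator[ReadPair]:
    """Iterate synchronized paired FASTQ files in input order."""
    it1, it2 = read_fastq(path1), read_fastq(path2)
    for idx, (r1, r2) in enumerate(itertools.zip_longest(it1, it2)):
        if r1 is None or r2 is None:
            orphan = (r1 or r2).id
            raise PairingError(
                f"unequal record counts; first orphan is {orphan!r}"
            )
        try:
            yield ReadPair(r1, r2)
        except ValueError as exc:
            raise PairingError(f"record {idx}: {exc}") from exc


def write_fastq(records: Iterable[SequenceRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            if rec.qual is None:
                raise ValueError(f"record {rec.id!r} has no qualities")
            qual = "".join(chr(q + 33) for q in rec.qual)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


def write_fastq_pairs(pairs: Iterable[ReadPair], path1, path2) -> None:
    pairs = list(pairs)
    write_fastq((p.mate1 for p in pairs), path1)
    write_fastq((p.mate2 for p in pairs), path2)


def read_fasta(path) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    name, chunks = None, []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    records.append(SequenceRecord(name, "".join(chunks)))
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        records.append(SequenceRecord(name, "".join(chunks)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 with circular topology
# ---------------------------------------------------------------------------

class Gff3ValidationError(ValueError):
    """Feature coordinates incompatible with the declared sequence region."""


def write_gff3(circles: Iterable[Minicircle], path) -> None:
    """Emit one ``##sequence-region`` + region feature per circle.

    Gene features wrapping the circular origin are split into two parts
    that share an ``ID`` attribute.
    """
    lines = ["##gff-version 3"]
    for circle in circles:
        n = len(circle)
        lines.append(f"##sequence-region {circle.id} 1 {n}")
        circ = "true" if circle.circular else "false"
        attrs = f"ID=region-{circle.id};Is_circular={circ}"
        lines.append(
            f"{circle.id}\tminicircler\tregion\t1\t{n}\t.\t+\t.\t{attrs}"
        )
        if circle.cr_span is not None:
            for i, (s, e) in enumerate(_split_span(circle.cr_span, n, circle.circular)):
                cr_attrs = f"ID=cr-{circle.id};Name=control_region;part={i + 1}"
                lines.append(
                    f"{circle.id}\tminicircler\tD_loop\t{s + 1}\t{e}\t.\t+\t.\t{cr_attrs}"
                )
        for gi, gene in enumerate(sorted(circle.genes, key=lambda g: g.start)):
            if gene.start < 0 or gene.start >= n or gene.end > 2 * n:
                raise Gff3ValidationError(
                    f"{circle.id}: {gene.label} span {gene.start}..{gene.end} "
                    f"outside circle of length {n}"
                )
            if not circle.circular and gene.end > n:
                raise Gff3ValidationError(
                    f"{circle.id}: {gene.label} wraps a linear contig"
                )
            gid = f"gene-{circle.id}-{gi}-{gene.label}"
            for i, (s, e) in enumerate(_split_span((gene.start, gene.end), n, circle.circular)):
                attrs = (
                    f"ID={gid};Name={gene.label};part={i + 1};"
                    f"identity={gene.identity:.4f}"
                )
                lines.append(
                    f"{circle.id}\tminicircler\tgene\t{s + 1}\t{e}\t.\t"
                    f"{gene.strand}\t.\t{attrs}"
                )
    with _open_text(path, "wt") as fh:
        fh.write("\n".join(lines) + "\n")


def _split_span(span: tuple[int, int], n: int, circular: bool) -> list[tuple[int, int]]:
    start, end = span
    if end <= n:
        return [(start, end)]
    if not circular:
        raise Gff3ValidationError(f"span {span} wraps a linear sequence")
    return [(start, n), (0, end - n)]


def read_gff3(path) -> list[Minicircle]:
    """Parse back GFF3 written by :func:`write_gff3` (that subset only)."""
    circles: dict[str, Minicircle] = {}
    parts: dict[str, list[tuple[str, int, int, str, float]]] = {}
    order: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = (
                line.split("\t")
            )
            a = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            s, e = int(start) - 1, int(end)
            if ftype == "region":
                circles[seqid] = Minicircle(
                    id=seqid, seq="N" * e,
                    circular=a.get("Is_circular") == "true",
                )
                order.append(seqid)
            elif ftype == "D_loop":
                parts.setdefault(a["ID"], []).append(("__cr__", s, e, "+", 1.0))
            elif ftype == "gene":
                parts.setdefault(a["ID"], []).append(
                    (a["Name"], s, e, strand, float(a.get("identity", 1.0)))
                )
    for fid, chunks in parts.items():
        seqid = fid.split("-", 1)[1].rsplit("-", 2)[0] if fid.startswith("gene-") else fid[3:]
        circle = circles[seqid]
        n = len(circle)
        chunks = sorted(chunks, key=lambda c: c[1])
        if len(chunks) == 2 and chunks[0][1] == 0 and chunks[-1][2] == n:
            # wrapped feature: rejoin across the origin
            label, _s, e1, strand, ident = chunks[0]
            _, s2, _e2, _, _ = chunks[1]
            span = (s2, n + e1)
        else:
            label, s1, e1, strand, ident = chunks[0]
            span = (s1, e1)
        if label == "__cr__":
            circle.cr_span = span
        else:
            circle.genes.append(
                GeneAnnotation(label, span[0], span[1], strand, ident)
            )
    for circle in circles.values():
        circle.genes.sort(key=lambda g: g.start)
    return [circles[name] for name in order]


@contextlib.contextmanager
def stage_log(path):
    """Plain-text log with per-stage timestamps, used by the CLI."""
    import datetime

    with _open_text(path, "at") as fh:
        def log(stage: str, message: str) -> None:
            stamp = datetime.datetime.now().isoformat(timespec="seconds")
            fh.write(f"{stamp}\t{stage}\t{message}\n")
        yield log
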