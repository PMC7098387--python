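"""Core in-memory containers shared across pipeline stages.

Internal coordinates are 0-based half-open throughout.  On a circular
sequence of length L a feature may wrap the origin, in which case its span
is stored as ``(start, end)`` with ``start < L <= end`` and all positions
are understood modulo L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The canonical 37-gene mitochondrial vocabulary.
PCG_NAMES: tuple[str, ...] = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
)
RRNA_NAMES: tuple[str, ...] = ("rrnL", "rrnS")
TRNA_NAMES: tuple[str, ...] = tuple(
    f"trn{a}" for a in (
        "A", "C", "D", "E", "F", "G", "H", "I", "K", "L1", "L2",
        "M", "N", "P", "Q", "R", "S1", "S2", "T", "V", "W", "Y",
    )
)
GENE_VOCABULARY: frozenset[str] = frozenset(PCG_NAMES + RRNA_NAMES + TRNA_NAMES)


@dataclass
class SequenceRecord:
    """A named sequence with optional per-base phred qualities."""

    id: str
    seq: str
    qual: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r} has empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadPair:
    """Two synchronized mates of a paired-end fragment."""

    mate1: SequenceRecord
    mate2: SequenceRecord

    def __post_init__(self) -> None:
        if _pair_key(self.mate1.id) != _pair_key(self.mate2.id):
            raise ValueError(
                f"mates {self.mate1.id!r} / {self.mate2.id!r} are not a pair"
            )


def _pair_key(read_id: str) -> str:
    """Read id with a trailing /1, /2, .1, .2 mate suffix removed."""
    if len(read_id) > 1 and read_id[-2] in "/." and read_id[-1] in "12":
        return read_id[:-2]
    return read_id


@dataclass
class Contig:
    """Assembled sequence with per-base coverage and read provenance."""

    id: str
    seq: str
    coverage: np.ndarray
    read_ids: list[str] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage, dtype=float)
        if len(self.coverage) != len(self.seq):
            raise ValueError(
                f"contig {self.id!r}: coverage length {len(self.coverage)} "
                f"!= sequence length {len(self.seq)}"
            )
        if np.any(self.coverage < 0):
            raise ValueError(f"contig {self.id!r}: negative coverage")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def mean_coverage(self) -> float:
        return float(self.coverage.mean()) if len(self.coverage) else 0.0


@dataclass
class GeneAnnotation:
    """A gene call on a (possibly circular) chromosome."""

    label: str
    start: int
    end: int            # exclusive; may exceed circle length when wrapping
    strand: str         # '+' or '-'
    identity: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in GENE_VOCABULARY:
            raise ValueError(f"unknown gene label {self.label!r}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(f"{self.label}: empty span {self.start}..{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Minicircle:
    """A canonicalized minicircle chromosome."""

    id: str
    seq: str
    circular: bool = True
    cr_span: tuple[int, int] | None = None
    genes: list[GeneAnnotation] = field(default_factory=list)
    species: str = ""
    mean_coverage: float = 0.0

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def gene_labels(self) -> list[str]:
        return [g.label for g in sorted(self.genes, key=lambda g: g.start)]


@dataclass
class EdgeSeed:
    """Circle-specific variable tail harvested at the CR/coding junction."""

    id: str
    seq: str
    source_contig_id: str
    source_mean_coverage: float

    def __post_init__(self) -> None:
        if len(self.seq) < 20:
            raise ValueError(f"edge seed {self.id!r} shorter than 20 nt")


@dataclass
class GenomeSet:
    """One species' collection of minicircles."""

    species: str
    circles: list[Minicircle] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.circles)
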