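"""Cross-species comparison of minicircle gene arrangements.

Two circles share an arrangement when their gene orders agree up to
rotation and whole-circle strand flip (reflection), read as a circular
word of (label, strand) symbols.  The canonical key is the
lexicographically minimal rotation (Booth's algorithm) of the word or of
its reflected reading, whichever is smaller.
"""

from __future__ import annotations

from collections import Counter

import pandas as pd

from .circularity import least_rotation
from .containers import GenomeSet, Minicircle

ArrangementKey = tuple[tuple[str, str], ...]


class KeyError_(ValueError):
    """A circle without annotations has no arrangement."""


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def arrangement_key(circle: Minicircle,
                    content_only: bool = False) -> ArrangementKey:
    genes = sorted(circle.genes, key=lambda g: (g.start, g.label))
    if not genes:
        raise KeyError_(f"circle {circle.id!r} has no annotations")
    word = tuple((g.label, g.strand) for g in genes)
    if content_only:
        return tuple(sorted((g.label, "+") for g in genes))
    reflected = tuple((lab, _flip(st)) for lab, st in reversed(word))
    best = []
    for w in (word, reflected):
        r = least_rotation(w)
        best.append(w[r:] + w[:r])
    return min(best)


def arrangement_key_bruteforce(circle: Minicircle) -> ArrangementKey:
    """Explicit minimum over every rotation and the reflected rotations.

    Exists as the independent oracle for the fast canonical form.
    """
    genes = sorted(circle.genes, key=lambda g: (g.start, g.label))
    if not genes:
        raise KeyError_(f"circle {circle.id!r} has no annotations")
    word = tuple((g.label, g.strand) for g in genes)
    reflected = tuple((lab, _flip(st)) for lab, st in reversed(word))
    n = len(word)
    variants = [w[i:] + w[:i] for w in (word, reflected) for i in range(n)]
    return min(variants)


def shared_minicircles(a: GenomeSet, b: GenomeSet,
                       content_only: bool = False,
                       ) -> tuple[int, list[tuple[str, str]]]:
    """Multiset intersection of arrangement keys, with matched id pairs."""
    keys_a: dict[ArrangementKey, list[str]] = {}
    for c in a.circles:
        keys_a.setdefault(arrangement_key(c, content_only), []).append(c.id)
    pairs: list[tuple[str, str]] = []
    used = Counter()
    for c in sorted(b.circles, key=lambda c: c.id):
        key = arrangement_key(c, content_only)
        avail = keys_a.get(key, [])
        if used[key] < len(avail):
            pairs.append((avail[used[key]], c.id))
            used[key] += 1
    return len(pairs), pairs


def arrangement_table(sets: list[GenomeSet], content_only: bool = False,
                      ) -> tuple[pd.DataFrame, pd.DataFrame, list[ArrangementKey]]:
    """Pairwise shared-count matrix, key x species presence table, and the
    keys present in every species."""
    if len(sets) < 2:
        raise ValueError("need >=2 genome sets to compare")
    names = [g.species for g in sets]
    matrix = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i, a in enumerate(sets):
        for j, b in enumerate(sets):
            matrix.iloc[i, j] = shared_minicircles(a, b, content_only)[0]

    all_keys: dict[ArrangementKey, dict[str, int]] = {}
    for g in sets:
        for c in g.circles:
            key = arrangement_key(c, content_only)
            all_keys.setdefault(key, {n: 0 for n in names})
            all_keys[key][g.species] += 1
    presence = pd.DataFrame(
        [
            {"arrangement": _format_key(k), **counts}
            for k, counts in sorted(all_keys.items())
        ]
    )
    universal = [
        k for k, counts in sorted(all_keys.items())
        if all(counts[n] > 0 for n in names)
    ]
    return matrix, presence, universal


def _format_key(key: ArrangementKey) -> str:
    return " ".join(f"{st}{lab}" for lab, st in key)
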