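"""Motif equivalence classes under rotation and reverse complement.

Two SSR motifs describe the same repeat if one is a circular permutation of
the other or of its reverse complement: an (AG)n array read on the opposite
strand is (CT)n, and shifting the reading frame by one base turns it into
(GA)n / (TC)n.  Each equivalence class is named by its lexicographically
smallest member (A < C < G < T) and labelled by the full member list joined
with "/", e.g. ``AG/GA/CT/TC``.

Only primitive motifs participate — a motif that is an integer power of a
shorter motif (``ATAT`` = ``(AT)^2``) describes a shorter-period repeat and
is rejected rather than silently reduced (reduction is the repeat scanner's
job).  Non-power motifs whose smallest period does not divide their length
(e.g. ``AABA``, smallest period 3) are genuine period-4 motifs and are kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import List, TYPE_CHECKING

from ._util import revcomp
from .repeat_finder import primitive_period

if TYPE_CHECKING:  # pragma: no cover
    from .repeat_finder import RepeatHit


@dataclass(frozen=True)
class MotifClass:
    """An equivalence class of k-mer motifs.

    ``members`` is ordered: left-rotations of the representative first, then
    the reverse complement of each of those in the same order (duplicates
    removed, first occurrence kept).  ``label`` joins members with "/".
    """

    k: int
    representative: str
    members: tuple

    @property
    def label(self) -> str:
        return "/".join(self.members)

    def __contains__(self, motif: str) -> bool:
        return motif in self.members


def is_power(motif: str) -> bool:
    """True iff the motif is an integer power of a strictly shorter string."""
    p = primitive_period(motif)
    return p < len(motif) and len(motif) % p == 0


def _rotations(motif: str) -> List[str]:
    return [motif[i:] + motif[:i] for i in range(len(motif))]


def _orbit(motif: str) -> frozenset:
    return frozenset(_rotations(motif)) | frozenset(_rotations(revcomp(motif)))


@lru_cache(maxsize=None)
def _class_from_orbit(orbit: frozenset) -> MotifClass:
    rep = min(orbit)
    ordered: List[str] = []
    for m in _rotations(rep) + [revcomp(r) for r in _rotations(rep)]:
        if m not in ordered:
            ordered.append(m)
    assert set(ordered) == set(orbit)
    return MotifClass(k=len(rep), representative=rep, members=tuple(ordered))


def canonical_motif(motif: str) -> MotifClass:
    """Return the equivalence class of ``motif``.

    Raises ``ValueError`` for non-ACGT input, length outside 2–6, or a
    non-primitive motif (one whose primitive period is shorter than itself).
    """
    if not motif or any(c not in "ACGT" for c in motif):
        raise ValueError(f"motif must be a non-empty ACGT string: {motif!r}")
    if not 2 <= len(motif) <= 6:
        raise ValueError(f"motif length must be 2-6, got {len(motif)}")
    if is_power(motif):
        raise ValueError(
            f"motif {motif!r} is not primitive; reduce it to its primitive "
            "period before classification")
    return _class_from_orbit(_orbit(motif))


def enumerate_classes(k: int) -> List[MotifClass]:
    """All motif classes of length ``k``, sorted by representative.

    Partitions the primitive k-mers: 4 dinucleotide and 10 trinucleotide
    classes (33, 102 and 350 for k = 4, 5, 6).
    """
    if not 2 <= k <= 6:
        raise ValueError(f"k must be 2-6, got {k}")
    from itertools import product

    seen = set()
    classes: List[MotifClass] = []
    for tup in product("ACGT", repeat=k):
        m = "".join(tup)
        if is_power(m) or m in seen:
            continue
        cls = canonical_motif(m)
        seen.update(cls.members)
        classes.append(cls)
    return sorted(classes, key=lambda c: c.representative)


def class_of_hit(hit: "RepeatHit") -> MotifClass:
    """Equivalence class of a repeat hit's observed motif."""
    return canonical_motif(hit.motif)
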