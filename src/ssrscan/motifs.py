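"""Canonical motif classes under rotation and reverse complement.

Two motifs describe the same repeat if one is a circular permutation of the
other or of its reverse complement (AC = CA = GT = TG).  Each equivalence
class is named by its lexicographically smallest member under A < C < G < T,
which coincides with the first-named motif of conventional pair labels such
as AGG/CCT.  Richness (AT versus GC content) and per-copy nucleotide counts
are properties of the class: both are invariant under rotation and reverse
complement.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

AT_RICH = "AT_RICH"
GC_RICH = "GC_RICH"
BALANCED = "BALANCED"

RICHNESS_CATEGORIES = (AT_RICH, GC_RICH, BALANCED)


def _check_acgt(motif: str) -> None:
    if not motif:
        raise ValueError("empty motif")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")


def smallest_period(s: str) -> int:
    """Smallest p such that ``s`` is a whole-number repetition of ``s[:p]``.

    Returns ``len(s)`` for primitive strings; the result always divides
    ``len(s)``.
    """
    _check_acgt(s)
    n = len(s)
    for p in range(1, n // 2 + 1):
        if n % p == 0 and s == s[:p] * (n // p):
            return p
    return n


def is_primitive(motif: str) -> bool:
    """True if the motif is not a repetition of a shorter unit."""
    return smallest_period(motif) == len(motif)


def reverse_complement(motif: str) -> str:
    _check_acgt(motif)
    return motif.translate(_COMPLEMENT)[::-1]


def rotations(motif: str) -> list[str]:
    """All circular permutations of the motif, in rotation order."""
    return [motif[i:] + motif[:i] for i in range(len(motif))]


@lru_cache(maxsize=1 << 16)
def canonical_motif(motif: str) -> str:
    """Lexicographic minimum over all rotations of the motif and of its
    reverse complement (A < C < G < T).  Idempotent, and equal for any two
    members of one class."""
    _check_acgt(motif)
    rc = reverse_complement(motif)
    return min(min(rotations(motif)), min(rotations(rc)))


@dataclass(frozen=True)
class MotifClass:
    """A canonical motif equivalence class."""

    canonical: str
    members: frozenset[str]
    period: int


def motif_class(motif: str) -> MotifClass:
    """The full equivalence class (rotations plus reverse-complement
    rotations) containing ``motif``."""
    _check_acgt(motif)
    members = frozenset(rotations(motif)) | frozenset(
        rotations(reverse_complement(motif))
    )
    return MotifClass(canonical_motif(motif), members, len(motif))


def canonical_classes(period: int, primitive_only: bool = True) -> list[str]:
    """Enumerate every canonical class representative of a given period.

    With ``primitive_only`` (the default) motifs that are repetitions of a
    shorter unit are excluded; there are 2 classes for period 1, 4 for
    period 2 and 10 for period 3.
    """
    if period < 1:
        raise ValueError("period must be >= 1")
    out = set()
    for letters in product("ACGT", repeat=period):
        m = "".join(letters)
        if primitive_only and not is_primitive(m):
            continue
        out.add(canonical_motif(m))
    return sorted(out)


@lru_cache(maxsize=1 << 16)
def richness(motif: str) -> str:
    """AT_RICH if A+T exceeds G+C within one motif copy, GC_RICH if the
    reverse, BALANCED on ties."""
    _check_acgt(motif)
    at = motif.count("A") + motif.count("T")
    gc = len(motif) - at
    if at > gc:
        return AT_RICH
    if gc > at:
        return GC_RICH
    return BALANCED


def motif_nucleotide_counts(motif: str) -> dict[str, int]:
    """Letter counts of one motif copy; values sum to the period."""
    _check_acgt(motif)
    return {base: motif.count(base) for base in "ACGT"}
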