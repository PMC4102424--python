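"""Motif primitives: validation, rotation classes, canonical forms.

A microsatellite motif is a 1-4 bp DNA word that is *primitive*: it is not
itself a tandem repeat of a shorter word ("ATAT" is two copies of "AT" and is
therefore a dinucleotide, not a tetranucleotide, motif).

Two canonical forms are used throughout the package:

* the *rotation canonical* form (minimum over cyclic rotations) identifies
  phase-shifted runs of the same strand motif, e.g. ``CA`` and ``AC``;
* the *strand canonical* form (minimum over rotations of the motif and of its
  reverse complement) additionally folds the two strands together, grouping
  e.g. ``[A/T]_n`` mononucleotide repeats into one class for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

DNA_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(word: str) -> bool:
    """True if ``word`` is not a tandem repeat of any shorter word."""
    n = len(word)
    for d in range(1, n):
        if n % d == 0 and word == word[:d] * (n // d):
            return False
    return True


def rotations(word: str) -> list[str]:
    return [word[i:] + word[:i] for i in range(len(word))]


def rotation_canonical(word: str) -> str:
    """Lexicographic minimum over cyclic rotations (same-strand class)."""
    return min(rotations(word))


def canonical_motif(word: str) -> str:
    """Lexicographic minimum over rotations of ``word`` and of its reverse
    complement. Idempotent; unique per strand-symmetric motif class."""
    return min(min(rotations(word)), min(rotations(reverse_complement(word))))


@dataclass(frozen=True)
class Motif:
    """A primitive 1-4 bp repeat motif, stored as the leading unit observed."""

    sequence: str

    def __post_init__(self) -> None:
        if not 1 <= len(self.sequence) <= 4:
            raise ValueError(f"motif length must be 1-4, got {self.sequence!r}")
        if not set(self.sequence) <= DNA_ALPHABET:
            raise ValueError(f"motif must be over ACGT, got {self.sequence!r}")
        if not is_primitive(self.sequence):
            raise ValueError(
                f"{self.sequence!r} is a tandem repeat of a shorter motif"
            )

    @property
    def size(self) -> int:
        return len(self.sequence)

    @property
    def rotation_class(self) -> str:
        return rotation_canonical(self.sequence)

    @property
    def canonical(self) -> "Motif":
        return Motif(canonical_motif(self.sequence))

    def same_class(self, other: "Motif") -> bool:
        """Same-strand (rotation) motif class equality."""
        return self.rotation_class == other.rotation_class
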