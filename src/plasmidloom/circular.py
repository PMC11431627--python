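"""Circular DNA sequences with canonical rotation and strand rules.

Small plasmids are circular replicons: any rotation of the sequence, on
either strand, denotes the same molecule.  This module provides the
container used throughout the package plus the canonicalization used to
compare reconstructed plasmids with their ground truth (lexicographically
minimal rotation over both strands, computed with Booth's algorithm).

Coordinates are 0-based half-open internally; intervals on the circle may
"wrap" past the origin, in which case ``end > length`` and positions are
taken modulo the length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _booth_least_rotation(s: str) -> int:
    """Index of the lexicographically least rotation of ``s`` (Booth, 1980)."""
    s2 = s + s
    n = len(s2)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = s2[j]
        i = f[j - k - 1]
        while i != -1 and sj != s2[k + i + 1]:
            if sj < s2[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s2[k + i + 1]:
            if sj < s2[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


@dataclass(frozen=True)
class CircularSequence:
    """A circular DNA replicon."""

    seq: str
    name: str = "plasmid"

    def __post_init__(self):
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)

    def __str__(self) -> str:
        return self.seq

    @property
    def doubled(self) -> str:
        """Sequence concatenated with itself; every wrapped word is a substring."""
        return self.seq + self.seq

    def fetch(self, start: int, length: int) -> str:
        """Subsequence of given length starting at ``start`` (wraps the origin)."""
        if length > len(self.seq):
            raise ValueError("fetch longer than the circle")
        start %= len(self.seq)
        return self.doubled[start : start + length]

    def rotate(self, offset: int) -> "CircularSequence":
        """Same circle re-written to start at position ``offset``."""
        offset %= len(self.seq)
        return CircularSequence(self.seq[offset:] + self.seq[:offset], self.name)

    def reverse_complement(self) -> "CircularSequence":
        return CircularSequence(revcomp(self.seq), self.name)

    def canonical(self) -> "CircularSequence":
        """Canonical form: lexicographically minimal rotation over both strands.

        Idempotent and strand-invariant, so two reconstructions of the same
        circular molecule compare equal regardless of start base or strand.
        """
        fwd = self.seq
        rev = revcomp(self.seq)
        fc = fwd[_booth_least_rotation(fwd):] + fwd[:_booth_least_rotation(fwd)]
        rc = rev[_booth_least_rotation(rev):] + rev[:_booth_least_rotation(rev)]
        return CircularSequence(min(fc, rc), self.name)

    def gc_fraction(self) -> float:
        if not self.seq:
            return 0.0
        return (self.seq.count("G") + self.seq.count("C")) / len(self.seq)


@dataclass
class GeneAnnotation:
    """A gene feature on a circular sequence.

    ``start``/``end`` are 0-based half-open on the forward strand; features
    spanning the origin have ``end > seqlen`` (positions mod seqlen).
    """

    seqid: str
    label: str
    start: int
    end: int
    strand: str  # '+' or '-'
    feature_type: str = "CDS"
    attributes: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval_on(self, seqlen: int) -> tuple[int, int]:
        """(start mod L, end) with end possibly > L for wrapped features."""
        s = self.start % seqlen
        return s, s + self.length

    def overlaps(self, start: int, end: int, seqlen: int) -> bool:
        """Wrap-aware interval overlap test on a circle of length ``seqlen``."""
        s1, e1 = self.interval_on(seqlen)
        s2 = start % seqlen
        e2 = s2 + (end - start)
        for shift1 in (0, seqlen):
            for shift2 in (0, seqlen):
                if s1 + shift1 < e2 + shift2 and s2 + shift2 < e1 + shift1:
                    return True
        return False
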