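"""k-mer avoidance statistics under maximal-order Markov expectations.

Small mobile genetic elements of halophilic archaea systematically deplete
short palindromic words (classically GGCC and CTAG) that are targets of
host restriction-modification systems.  Depletion is quantified as the
ratio of the observed circular count of a word to its maximal-order Markov
expectation computed from the word's own sub-word counts:

    expected(b1..bk) = N(b1..b(k-1)) * N(b2..bk) / N(b2..b(k-1))

For tetramers this is the second-order Markov estimate
N(b1b2b3)*N(b2b3b4)/N(b2b3); 6-mers use the order-4 analogue.

Counting is circular by default (counts over all L wrapped start positions,
so the counts of all words of length k sum to exactly L); a linear mode is
available for contigs.  Classification: a word absent from the sequence is
``absent``; a word with ratio below the threshold (default 0.70) *and* an
expectation large enough to support the call (default >= 5) is
``under_represented``; anything else is ``expected_level``.  The minimum
expectation guards against calling depletion for words too rare to assess
(for a 6-mer on a 6 kb plasmid the expectation is ~1.5, where a single
occurrence would otherwise masquerade as "under-represented").
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .circular import CircularSequence

DEFAULT_MOTIFS = ("GGCC", "CTAG", "TTAA", "GGATCC")
UNDER_REPRESENTATION_THRESHOLD = 0.70
MIN_EXPECTED_FOR_CALL = 5.0

_VALID = re.compile(r"^[ACGT]*$")


@dataclass
class MotifReport:
    motif: str
    observed: int
    expected: Optional[float]
    ratio: Optional[float]
    classification: str  # absent | under_represented | expected_level | absent_context
    region_mask: list = field(default_factory=list)


def _check_alphabet(seq: str):
    bad = [i for i, c in enumerate(seq) if c not in "ACGT"]
    if bad:
        head = ", ".join(map(str, bad[:10]))
        raise ValueError(f"non-ACGT characters at positions {head}" + ("…" if len(bad) > 10 else ""))


def _as_str(seq) -> str:
    return seq.seq if isinstance(seq, CircularSequence) else str(seq).upper()


def count_overlapping(text: str, word: str) -> int:
    """Occurrences of ``word`` in ``text`` counting overlaps."""
    count = start = 0
    while True:
        start = text.find(word, start)
        if start == -1:
            return count
        count += 1
        start += 1


def _count_word(segments: Sequence[str], word: str, circular: bool) -> int:
    """Count a word over linear segments, or circularly when one segment."""
    if circular:
        (seg,) = segments
        if len(seg) < len(word):
            return 0
        text = seg + seg[: len(word) - 1]
        return count_overlapping(text, word)
    return sum(count_overlapping(seg, word) for seg in segments)


def kmer_counts_circular(seq, k: int, circular: bool = True) -> Counter:
    """Counts of all k-words; circular counting covers all L wrapped positions."""
    s = _as_str(seq)
    if not 1 <= k <= 8:
        raise ValueError("k must be in [1, 8]")
    if len(s) < k:
        raise ValueError("sequence shorter than k")
    _check_alphabet(s)
    text = s + s[: k - 1] if circular else s
    counts: Counter = Counter()
    for i in range(len(text) - k + 1):
        counts[text[i : i + k]] += 1
    return counts


def _classify(observed: int, expected: Optional[float], ratio: Optional[float],
              threshold: float, min_expected: float) -> str:
    if observed == 0:
        return "absent"
    if expected is None:
        return "absent_context"
    if ratio is not None and ratio < threshold and expected >= min_expected:
        return "under_represented"
    return "expected_level"


def markov_expected_ratio(
    seq,
    motif: str,
    circular: bool = True,
    threshold: float = UNDER_REPRESENTATION_THRESHOLD,
    min_expected: float = MIN_EXPECTED_FOR_CALL,
) -> MotifReport:
    """Observed/expected report for one word under its maximal-order Markov model."""
    s = _as_str(seq)
    motif = motif.upper()
    if len(motif) < 3:
        raise ValueError("motif must be at least 3 nt for a Markov expectation")
    _check_alphabet(s)
    _check_alphabet(motif)
    return _report_on_segments([s], motif, circular, threshold, min_expected)


def _report_on_segments(segments, motif, circular, threshold, min_expected) -> MotifReport:
    observed = _count_word(segments, motif, circular)
    prefix, suffix, core = motif[:-1], motif[1:], motif[1:-1]
    n_core = _count_word(segments, core, circular)
    if n_core == 0:
        return MotifReport(motif, observed, None, None,
                           _classify(observed, None, None, threshold, min_expected))
    expected = _count_word(segments, prefix, circular) * _count_word(segments, suffix, circular) / n_core
    ratio = observed / expected if expected > 0 else None
    return MotifReport(motif, observed, expected, ratio,
                       _classify(observed, expected, ratio, threshold, min_expected))


def motif_report(
    seq,
    motifs: Sequence[str] = DEFAULT_MOTIFS,
    mask: Optional[Sequence[tuple[int, int]]] = None,
    circular: bool = True,
    threshold: float = UNDER_REPRESENTATION_THRESHOLD,
    min_expected: float = MIN_EXPECTED_FOR_CALL,
) -> list[MotifReport]:
    """Reports for a list of words, optionally excluding masked regions.

    ``mask`` is a list of 0-based half-open intervals to exclude (e.g., an
    acquired region whose motif content should not count against the host
    backbone).  The retained segments are analysed linearly — no artificial
    junction words are formed across excised regions.
    """
    s = _as_str(seq)
    _check_alphabet(s)
    if mask:
        L = len(s)
        for a, b in mask:
            if not (0 <= a < b <= L):
                raise ValueError(f"mask interval ({a}, {b}) outside sequence bounds [0, {L}]")
        keep = []
        pos = 0
        for a, b in sorted(mask):
            if a > pos:
                keep.append(s[pos:a])
            pos = max(pos, b)
        if pos < L:
            keep.append(s[pos:L])
        segments, circ = keep, False
    else:
        segments, circ = [s], circular
    reports = []
    for motif in motifs:
        rep = _report_on_segments(segments, motif.upper(), circ, threshold, min_expected)
        rep.region_mask = sorted(mask) if mask else []
        reports.append(rep)
    return reports
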