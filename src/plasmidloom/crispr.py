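"""CRISPR array detection, spacer-to-plasmid matching, and host-genus calls.

CRISPR arrays record past invasions: each spacer is a fragment of an
invading element, and the flanking direct repeat (DR) is characteristic of
the host taxon carrying the array.  Matching metagenomic spacers to a
plasmid therefore maps which host lineages the plasmid has invaded, and the
DR assigns each event to a genus.

Array detection follows CRT/MinCED-style constraints: repeats of 23–47 nt
in at least 3 near-identical copies (<=2 mismatches to the column-majority
consensus) separated by 26–50 nt spacers, discovered from exact 8-mer seeds
recurring at array-compatible periods.  Spacer matching is an exhaustive
mismatch-only scan of each spacer and its reverse complement against the
circular (origin-unrolled) plasmid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import edlib
import numpy as np

from .circular import revcomp

REPEAT_LEN = (23, 47)
SPACER_LEN = (26, 50)
MIN_REPEATS = 3
SEED_K = 8


@dataclass
class CrisprArray:
    contig_id: str
    repeat_consensus: str
    repeat_intervals: list[tuple[int, int]]
    spacers: list[str]
    spacer_intervals: list[tuple[int, int]]


@dataclass
class DrReference:
    """Rows of (genus, direct-repeat sequence)."""

    rows: list[tuple[str, str]]

    def __post_init__(self):
        if not self.rows:
            raise ValueError("direct-repeat reference is empty")
        for genus, dr in self.rows:
            if not genus:
                raise ValueError("empty genus name in DR reference")
            if set(dr.upper()) - set("ACGT"):
                raise ValueError(f"DR for {genus} contains non-ACGT characters")


@dataclass
class SpacerMatch:
    spacer_id: str
    plasmid_id: str
    position: int  # 1-based first matching base, plasmid forward strand
    strand: str
    mismatches: int
    genus: Optional[str] = None
    genus_identity: Optional[float] = None


# ---------------------------------------------------------------- detection


def _seed_chains(seq: str) -> list[list[int]]:
    """Chains of >=MIN_REPEATS exact 8-mer positions at array-like periods."""
    positions: dict[str, list[int]] = {}
    for i in range(len(seq) - SEED_K + 1):
        positions.setdefault(seq[i : i + SEED_K], []).append(i)
    lo = REPEAT_LEN[0] + SPACER_LEN[0]
    hi = REPEAT_LEN[1] + SPACER_LEN[1]
    chains = []
    for pos in positions.values():
        if len(pos) < MIN_REPEATS:
            continue
        chain = [pos[0]]
        for p in pos[1:]:
            if lo <= p - chain[-1] <= hi:
                chain.append(p)
            else:
                if len(chain) >= MIN_REPEATS:
                    chains.append(chain)
                chain = [p]
        if len(chain) >= MIN_REPEATS:
            chains.append(chain)
    return chains


def _column(seq: str, anchors: Sequence[int], off: int) -> list[str]:
    return [seq[a + off] for a in anchors if 0 <= a + off < len(seq)]


def _majority(col: list[str]) -> tuple[str, float]:
    counts: dict[str, int] = {}
    for b in col:
        counts[b] = counts.get(b, 0) + 1
    base, n = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    return base, n / len(col)


def _expand_repeat(seq: str, anchors: list[int],
                   window: tuple[int, int] = (0, SEED_K)) -> Optional[tuple[int, int, str]]:
    """Grow a seed window into the maximal near-identical repeat window.

    Columns join the window on a 75% majority (so a mutated repeat instance
    does not truncate it), then non-unanimous boundary columns are trimmed
    back: a by-chance majority column just outside a repeat is almost never
    unanimous, so trimming restores exact boundaries on clean arrays.
    Returns (left_offset, right_offset, consensus) relative to the anchors,
    or None when the window cannot satisfy the repeat-length constraints.
    """
    left, right = window  # window [anchor+left, anchor+right)
    while right - left < REPEAT_LEN[1]:
        grew = False
        for side in ("left", "right"):
            off = left - 1 if side == "left" else right
            col = _column(seq, anchors, off)
            if len(col) < len(anchors):
                continue
            _base, frac = _majority(col)
            if frac >= 0.75:
                if side == "left":
                    left -= 1
                else:
                    right += 1
                grew = True
                if right - left >= REPEAT_LEN[1]:
                    break
        if not grew:
            break
    def unanimous(off):
        col = _column(seq, anchors, off)
        return len(col) == len(anchors) and len(set(col)) == 1
    while right - left > SEED_K and not unanimous(left):
        left += 1
    while right - left > SEED_K and not unanimous(right - 1):
        right -= 1
    length = right - left
    if not REPEAT_LEN[0] <= length <= REPEAT_LEN[1]:
        return None
    consensus = "".join(
        _majority(_column(seq, anchors, off))[0] for off in range(left, right)
    )
    return left, right, consensus


def _relocate_anchors(seq: str, draft: str) -> list[list[int]]:
    """Runs of draft-repeat occurrences (<=2 mismatches) at array periods.

    A chance extra seed occurrence can corrupt a raw seed chain; re-locating
    every occurrence of the drafted consensus recovers missed instances and
    drops false anchors.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    word = np.frombuffer(draft.encode(), dtype=np.uint8)
    hits = [off for off, _mm in _hamming_scan(arr, word, 2)]
    # collapse near-duplicate offsets (shifted partial self-matches)
    merged: list[int] = []
    for h in hits:
        if not merged or h - merged[-1] >= len(draft):
            merged.append(h)
    lo = len(draft) + SPACER_LEN[0]
    hi = len(draft) + SPACER_LEN[1]
    runs, run = [], []
    for p in merged:
        if run and not lo <= p - run[-1] <= hi:
            runs.append(run)
            run = []
        run.append(p)
    if run:
        runs.append(run)
    return [r for r in runs if len(r) >= MIN_REPEATS]


def detect_arrays(contigs: dict[str, str], min_contig_len: int = 150) -> list[CrisprArray]:
    """Find CRISPR repeat/spacer arrays in a contig set (either strand)."""
    arrays: list[CrisprArray] = []
    for name, seq in sorted(contigs.items()):
        seq = seq.upper()
        if len(seq) < min_contig_len:
            continue
        claimed: set[int] = set()
        for chain in sorted(_seed_chains(seq), key=lambda c: (c[0], -len(c))):
            if any(p in claimed for p in chain):
                continue
            exp = _expand_repeat(seq, chain)
            if exp is None:
                continue
            _left, _right, draft = exp
            for anchors in _relocate_anchors(seq, draft):
                if any(p in claimed for p in anchors):
                    continue
                exp2 = _expand_repeat(seq, anchors, window=(0, len(draft)))
                if exp2 is None:
                    continue
                left, right, consensus = exp2
                rep_iv = [(a + left, a + right) for a in anchors]
                if rep_iv[0][0] < 0 or rep_iv[-1][1] > len(seq):
                    continue
                spacer_iv = [(rep_iv[i][1], rep_iv[i + 1][0])
                             for i in range(len(rep_iv) - 1)]
                if not all(SPACER_LEN[0] <= b - a <= SPACER_LEN[1] for a, b in spacer_iv):
                    continue
                if any(sum(x != y for x, y in zip(seq[a:b], consensus)) > 2
                       for a, b in rep_iv):
                    continue
                arrays.append(
                    CrisprArray(
                        name,
                        consensus,
                        rep_iv,
                        [seq[a:b] for a, b in spacer_iv],
                        spacer_iv,
                    )
                )
                claimed.update(range(rep_iv[0][0], rep_iv[-1][1]))
    return arrays


# ---------------------------------------------------------------- matching


def _hamming_scan(text: np.ndarray, word: np.ndarray, max_mm: int) -> list[tuple[int, int]]:
    """(offset, mismatches) for every window of ``text`` within ``max_mm``."""
    n, m = text.size, word.size
    if n < m:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(text, m)
    mism = (windows != word).sum(axis=1)
    return [(int(i), int(mism[i])) for i in np.nonzero(mism <= max_mm)[0]]


def match_spacers(
    spacers: dict[str, str],
    plasmids: dict[str, str],
    max_mismatches: int = 2,
) -> list[SpacerMatch]:
    """All placements of each spacer on each circular plasmid.

    Both the spacer and its reverse complement are scanned across the
    origin-unrolled plasmid; every position within ``max_mismatches`` is
    reported with its 1-based first matching base on the forward strand.
    Spacers shorter than 20 nt are skipped.
    """
    import warnings

    matches: list[SpacerMatch] = []
    for pname, pseq in sorted(plasmids.items()):
        pseq = pseq.upper()
        L = len(pseq)
        arr = np.frombuffer((pseq + pseq[:-1]).encode(), dtype=np.uint8)
        for sid, sp in sorted(spacers.items()):
            sp = sp.upper()
            if len(sp) < 20:
                warnings.warn(f"spacer {sid} shorter than 20 nt: skipped")
                continue
            if len(sp) > L:
                continue
            for strand, s in (("+", sp), ("-", revcomp(sp))):
                word = np.frombuffer(s.encode(), dtype=np.uint8)
                for off, mm in _hamming_scan(arr[: L + len(sp) - 1], word, max_mismatches):
                    matches.append(SpacerMatch(sid, pname, off + 1, strand, mm))
    return matches


# ---------------------------------------------------------------- genus call


def assign_host_genus(
    dr: str,
    dr_ref: DrReference,
    min_identity: float = 0.90,
    min_len_frac: float = 0.90,
) -> tuple[Optional[str], Optional[float]]:
    """Genus of the best-matching reference DR, or (None, best identity).

    Both orientations of the query DR are compared by global alignment;
    a call requires identity >= ``min_identity`` over a reference whose
    length is within ``min_len_frac`` of the query.  A tie between genera
    is reported as no call (ambiguous).
    """
    dr = dr.upper()
    best: dict[str, float] = {}
    for genus, ref in dr_ref.rows:
        ref = ref.upper()
        if min(len(ref), len(dr)) < min_len_frac * max(len(ref), len(dr)):
            continue
        ident = 0.0
        for query in (dr, revcomp(dr)):
            res = edlib.align(query, ref, mode="NW")
            ident = max(ident, 1 - res["editDistance"] / max(len(ref), len(query)))
        best[genus] = max(best.get(genus, 0.0), ident)
    if not best:
        return None, None
    top = max(best.values())
    if top < min_identity:
        return None, top
    winners = [g for g, v in best.items() if v == top]
    if len(winners) > 1:
        return None, top  # ambiguous across genera
    return winners[0], top


def annotate_matches_with_genus(
    matches: Sequence[SpacerMatch],
    arrays: Sequence[CrisprArray],
    dr_ref: DrReference,
    **kwargs,
) -> list[SpacerMatch]:
    """Fill each match's genus call from its source array's DR consensus."""
    by_spacer: dict[str, CrisprArray] = {}
    for arr in arrays:
        for i in range(len(arr.spacers)):
            by_spacer[f"{arr.contig_id}.sp{i}"] = arr
    for m in matches:
        arr = by_spacer.get(m.spacer_id)
        if arr is not None:
            m.genus, m.genus_identity = assign_host_genus(arr.repeat_consensus, dr_ref, **kwargs)
    return matches


def array_spacer_dict(arrays: Sequence[CrisprArray]) -> dict[str, str]:
    """Spacer id -> sequence for all detected arrays (ids ``<contig>.sp<i>``)."""
    return {
        f"{arr.contig_id}.sp{i}": sp
        for arr in arrays
        for i, sp in enumerate(arr.spacers)
    }
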