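"""Deterministic read-to-reference mapper with three named stringency presets.

The whole pipeline shares one mapper, configured by three presets that
reproduce the stringencies used at different stages of plasmid recovery:

* ``relaxed``   — 35% mismatches, ambiguity 5, gaps allowed (2%, max 6 nt);
                  used to bait reads from divergent relatives of a reference.
* ``stringent`` — 2% mismatches, ambiguity 2; used for seed assembly and
                  contig extension so co-circulating divergent strains are
                  excluded.
* ``quant``     — 1% mismatches, ambiguity 1, no gaps; used for abundance
                  and transcription quantification.

Mapping is k-mer seeded: every read k-mer is looked up in a reference
index, candidate diagonals are evaluated as gapless alignments by direct
mismatch counting, and (when the preset allows gaps) failed candidates are
re-scored with a banded edit-distance alignment (edlib).  A read whose
number of tied best placements exceeds ``max_ambiguity`` is discarded as
ambiguous.  Output is deterministic and independent of read input order.

The mapper targets references of at most tens of kb; there is deliberately
no FM-index machinery.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Optional

import edlib
import numpy as np

from .circular import revcomp

_ENCODE = np.zeros(256, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENCODE[b] = i


def _as_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class MappingParams:
    max_mismatch_frac: float
    max_ambiguity: int
    allow_gaps: bool = False
    gap_frac: float = 0.0
    max_gap_size: int = 0
    seed_kmer: int = 21

    def __post_init__(self):
        if not 0 <= self.max_mismatch_frac <= 0.5:
            raise ValueError("max_mismatch_frac must be in [0, 0.5]")
        if self.max_ambiguity < 1:
            raise ValueError("max_ambiguity must be >= 1")

    def mismatch_budget(self, read_len: int) -> int:
        return math.ceil(self.max_mismatch_frac * read_len)

    def gap_budget(self, read_len: int) -> int:
        return math.ceil(self.gap_frac * read_len) if self.allow_gaps else 0


# 35% tolerance needs short seeds: at 25% divergence the chance that a
# 150 nt read contains any clean 13-mer is only ~0.6 (run statistics), so
# the relaxed preset seeds with 9-mers; stringent modes afford long seeds.
PRESETS = {
    "relaxed": MappingParams(0.35, 5, allow_gaps=True, gap_frac=0.02, max_gap_size=6, seed_kmer=9),
    "stringent": MappingParams(0.02, 2, allow_gaps=True, gap_frac=0.02, max_gap_size=6, seed_kmer=21),
    "quant": MappingParams(0.01, 1, allow_gaps=False, seed_kmer=21),
}


def preset_params(name: str) -> MappingParams:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(sorted(PRESETS))}"
        ) from None


@dataclass
class ReadPlacement:
    read_id: str
    reference_id: str
    start: int  # 0-based on the circle; end may exceed reference length (wrap)
    end: int
    strand: str
    mismatches: int
    gaps: int = 0
    cigar: str = ""
    read_seq: str = ""
    mate_link: Optional["ReadPlacement"] = None

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass
class MappingStats:
    mapped: int = 0
    unmapped: int = 0
    ambiguous: int = 0
    too_short: int = 0


class ReferenceIndex:
    """Exact k-mer index over a (possibly circularly unrolled) reference set."""

    def __init__(self, references: dict[str, str], k: int, circular: bool, unroll: int):
        if not references:
            raise ValueError("reference set is empty")
        self.k = k
        self.circular = circular
        self.refs = {}
        self.index: dict[str, dict[str, list[int]]] = {}
        for name, seq in references.items():
            seq = seq.upper()
            ext = seq + seq[: min(unroll, len(seq))] if circular else seq
            self.refs[name] = (seq, ext, _as_array(ext))
            idx: dict[str, list[int]] = {}
            for i in range(len(ext) - k + 1):
                idx.setdefault(ext[i : i + k], []).append(i)
            self.index[name] = idx


def _candidate_diagonals(index: ReferenceIndex, name: str, read: str, stride: int):
    k = index.k
    idx = index.index[name]
    ext_len = len(index.refs[name][1])
    n = len(read)
    diags = set()
    for i in range(0, n - k + 1, stride):
        for p in idx.get(read[i : i + k], ()):
            d = p - i
            if 0 <= d <= ext_len - n:
                diags.add(d)
    return diags


def _gapless_mismatches(ext_arr: np.ndarray, read_arr: np.ndarray, d: int) -> int:
    return int(np.count_nonzero(ext_arr[d : d + read_arr.size] != read_arr))


_CIG_RE = re.compile(r"(\d+)([=XIDM])")


def _gapped_eval(ext: str, read: str, d: int, params: MappingParams):
    """Banded alignment of read against the window around diagonal d.

    Returns (mismatches, gapped_bases, max_gap, cigar, ref_start, ref_end)
    or None when alignment fails the gap constraints.
    """
    band = params.max_gap_size
    w0 = max(0, d - band)
    w1 = min(len(ext), d + len(read) + band)
    res = edlib.align(read, ext[w0:w1], mode="HW", task="path")
    if res["editDistance"] < 0 or not res["cigar"]:
        return None
    mism = gapped = max_gap = 0
    for num, op in _CIG_RE.findall(res["cigar"]):
        num = int(num)
        if op == "X":
            mism += num
        elif op in "ID":
            gapped += num
            max_gap = max(max_gap, num)
    loc = res["locations"][0]
    return mism, gapped, max_gap, res["cigar"], w0 + loc[0], w0 + loc[1] + 1


def map_read(
    read_id: str,
    read_seq: str,
    index: ReferenceIndex,
    params: MappingParams,
) -> tuple[Optional[ReadPlacement], str]:
    """Best placement of one read, or (None, reason) among
    {'too_short','unmapped','ambiguous'}."""
    read_seq = read_seq.upper()
    n = len(read_seq)
    if n < params.seed_kmer:
        return None, "too_short"
    budget = params.mismatch_budget(n)
    gap_budget = params.gap_budget(n)
    # Disjoint-block probing carries a pigeonhole guarantee: with fewer
    # mismatches than full k-blocks, at least one probe is error-free, so a
    # placement within budget is never missed.  Otherwise probe densely.
    stride = params.seed_kmer if budget < n // params.seed_kmer else 1

    candidates: list[tuple[int, int, str, int, int, int, str]] = []
    # (mismatches, ref_order, strand_order, start_mod, gaps, end, cigar) per placement
    for ref_order, (name, (seq, ext, ext_arr)) in enumerate(index.refs.items()):
        L = len(seq)
        for strand, rseq in (("+", read_seq), ("-", revcomp(read_seq))):
            rarr = _as_array(rseq)
            seen_starts = set()
            for d in sorted(_candidate_diagonals(index, name, rseq, stride)):
                mm = _gapless_mismatches(ext_arr, rarr, d)
                gaps = 0
                end = d + n
                cigar = f"{n}M"
                if mm > budget and params.allow_gaps and gap_budget:
                    ev = _gapped_eval(ext, rseq, d, params)
                    if ev is None:
                        continue
                    mm, gapped, max_gap, cigar, gstart, gend = ev
                    if gapped > gap_budget or max_gap > params.max_gap_size:
                        continue
                    gaps, d, end = gapped, gstart, gend
                if mm > budget:
                    continue
                start_mod = d % L
                key = (name, strand, start_mod)
                if key in seen_starts:
                    continue
                seen_starts.add(key)
                candidates.append(
                    (mm, ref_order, 0 if strand == "+" else 1, start_mod, gaps, start_mod + (end - d), cigar)
                )
    if not candidates:
        return None, "unmapped"
    best_mm = min(c[0] for c in candidates)
    ties = [c for c in candidates if c[0] == best_mm]
    if len(ties) > params.max_ambiguity:
        return None, "ambiguous"
    # tie-break: fewest mismatches, then reference order, leftmost start, + strand
    mm, ref_order, strand_o, start, gaps, end, cigar = min(ties)
    name = list(index.refs)[ref_order]
    strand = "+" if strand_o == 0 else "-"
    return (
        ReadPlacement(read_id, name, start, end, strand, mm, gaps, cigar, read_seq),
        "mapped",
    )


def map_reads(
    reads: Iterable,
    references: dict[str, str],
    params: MappingParams,
    circular: bool = False,
    unroll: int | None = None,
) -> tuple[list[ReadPlacement], MappingStats]:
    """Map single-end reads (FastqRead or (id, seq) tuples) to a reference set.

    When ``circular`` the reference is unrolled by one read length plus a
    maximum insert allowance so origin-spanning reads place correctly.
    """
    reads = [(r.read_id, r.seq) if hasattr(r, "read_id") else tuple(r) for r in reads]
    if unroll is None:
        max_len = max((len(s) for _, s in reads), default=0)
        unroll = max_len + 600
    index = ReferenceIndex(references, params.seed_kmer, circular, unroll)
    stats = MappingStats()
    placements = []
    for read_id, seq in sorted(reads):
        placement, status = map_read(read_id, seq, index, params)
        if placement is not None:
            placements.append(placement)
            stats.mapped += 1
        else:
            setattr(stats, status, getattr(stats, status) + 1)
    return placements, stats


def map_pairs(pairs, references, params, circular=False):
    """Map both mates of each pair independently; link placements by pair.

    Returns ({pair_index: (placement1 | None, placement2 | None)}, stats).
    """
    flat = []
    for i, (r1, r2) in enumerate(pairs):
        flat.append((f"{i:09d}/1", r1.seq))
        flat.append((f"{i:09d}/2", r2.seq))
    placements, stats = map_reads(flat, references, params, circular=circular)
    by_id = {p.read_id: p for p in placements}
    out = {}
    for i in range(len(pairs)):
        p1 = by_id.get(f"{i:09d}/1")
        p2 = by_id.get(f"{i:09d}/2")
        if p1 is not None:
            p1.mate_link = p2
        if p2 is not None:
            p2.mate_link = p1
        out[i] = (p1, p2)
    return out, stats
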