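"""Circular plasmid reconstruction by iterative seed-and-extend assembly.

The strategy mirrors manual plasmid recovery from metagenomic reads:

1. **harvest** — map all reads at relaxed stringency (35% mismatches) to
   known related plasmids and pull out the reads (plus mates) hitting a
   conserved target gene (default F3, the replicase);
2. **seed** — de-novo assemble the harvested reads under stringent
   parameters (<=2% mismatch within overlaps) and select a 400–1200 nt
   window of >=10x coverage;
3. **extend** — repeated rounds of mapping the full read set back to the
   growing contig; reads anchored to a terminus by an overlap of at least
   100 nt (<=2% mismatches within the overlap) donate their overhang, and
   each terminus grows by the majority consensus of overhangs with support
   >= 3 (a tie halts that terminus for the round).  One round performs a
   bounded batch of such consensus steps per terminus, so a round advances
   each end by up to a few hundred nt, in line with how interactive
   mapping rounds behave;
4. **closure** — when the contig's termini repeat exactly over >= 100 nt
   the circle has been traversed; the terminal duplication is trimmed to
   yield the monomer.  Exact identity is required: a closure carrying even
   one mismatch is rejected in favour of further extension rounds, so a
   closed sequence is never chimeric;
5. **polish & rotate** — the monomer consensus is re-called from a full
   stringent re-mapping at final coverage, then rotated to start at the
   point most similar to a chosen reference (or put into canonical
   rotation when no reference is given).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .circular import CircularSequence, GeneAnnotation, revcomp
from .mapping import map_reads, preset_params

STRINGENT_MM_FRAC = 0.02


class InsufficientCoverageError(RuntimeError):
    """Raised when the seed stage cannot reach the required coverage."""

    def __init__(self, message, contig=""):
        super().__init__(message)
        self.contig = contig


class ClosureAmbiguityError(RuntimeError):
    """Raised when equally plausible terminal duplications exist (tandem repeat)."""


@dataclass
class SeedContig:
    sequence: str
    coverage: np.ndarray
    window: tuple[int, int]  # interval selected on the assembled contig


@dataclass
class ReconstructionResult:
    monomer: Optional[CircularSequence]
    contig: str
    closed: bool
    rounds: int
    terminal_repeat_len: int = 0
    coverage: Optional[np.ndarray] = None
    log: list = field(default_factory=list)


@dataclass
class ReconstructionConfig:
    target_gene: str = "F3"
    min_anchor: int = 100       # minimum terminal overlap for extension
    mismatch_frac: float = STRINGENT_MM_FRAC
    min_support: int = 3        # overhang consensus support
    inner_steps: int = 8        # consensus steps batched into one round
    closure_min: int = 100      # exact terminal identity required for closure
    window_bounds: tuple[int, int] = (400, 1200)
    min_window_coverage: int = 10
    min_seed_reads: int = 20
    seed_anchor: int = 60       # assembly-phase overlap requirement
    max_rounds: int = 50
    stall_rounds: int = 3
    polish: bool = True


# ---------------------------------------------------------------- read pool


class ReadPool:
    """All read sequences of a paired set, in both orientations.

    Each oriented entry remembers its pair and mate so terminal extension
    can use pairing evidence (a fully anchored mate vouches for its
    partner's shorter overlap).
    """

    def __init__(self, pairs):
        seqs = []
        self.entries = []  # (pair_idx, mate_idx, seq, array)
        for i, (r1, r2) in enumerate(pairs):
            for mate_idx, r in enumerate((r1, r2)):
                seqs.append(r.seq)
                for s in (r.seq, revcomp(r.seq)):
                    self.entries.append(
                        (i, mate_idx, s, np.frombuffer(s.encode(), dtype=np.uint8))
                    )
        self.reads = seqs
        self.oriented = [e[2] for e in self.entries]
        self.arrays = [e[3] for e in self.entries]
        self.max_len = max((len(s) for s in seqs), default=0)


# ---------------------------------------------------------------- harvest


def harvest_seed_reads(
    pairs,
    references: Sequence[tuple[CircularSequence, Sequence[GeneAnnotation]]],
    target_gene: str = "F3",
):
    """Reads (with mates) whose relaxed-stringency placement hits the target gene."""
    targets = {}
    for ref, annotations in references:
        ivs = [a for a in annotations if a.label == target_gene]
        if ivs:
            targets[ref.name] = (len(ref), ivs)
    if not targets:
        raise ValueError(f"no reference carries an annotated {target_gene} gene")
    refdict = {ref.name: ref.seq for ref, _ in references}
    flat = []
    for i, (r1, r2) in enumerate(pairs):
        flat.append((f"{i:09d}/1", r1.seq))
        flat.append((f"{i:09d}/2", r2.seq))
    placements, _stats = map_reads(flat, refdict, preset_params("relaxed"), circular=True)
    keep = set()
    for p in placements:
        if p.reference_id not in targets:
            continue
        L, ivs = targets[p.reference_id]
        for ann in ivs:
            if ann.overlaps(p.start, p.end, L):
                keep.add(int(p.read_id.split("/")[0]))
                break
    return [pairs[i] for i in sorted(keep)]


# ---------------------------------------------------------------- tip extension


def _consensus_overhang(overhangs: list[str], min_support: int) -> str:
    out = []
    j = 0
    while True:
        counts: dict[str, int] = {}
        for o in overhangs:
            if j < len(o):
                counts[o[j]] = counts.get(o[j], 0) + 1
        if not counts:
            break
        top = max(counts.values())
        winners = [b for b, c in counts.items() if c == top]
        if top < min_support or len(winners) != 1:
            break
        out.append(winners[0])
        j += 1
    return "".join(out)


MATE_ANCHOR_MIN = 30  # own-overlap needed by a mate-rescued read
MAX_PAIR_SPAN = 700   # sanity bound on implied fragment span


def _right_overhangs(contig: str, pool: ReadPool, min_anchor: int, mm_frac: float,
                     k: int = 21) -> list[str]:
    """Overhangs of read pairs anchored to the right terminus.

    A read contributes its overhang when the pair is anchored by at least
    ``min_anchor`` nt of terminal overlap — either the read's own overlap
    reaches ``min_anchor``, or its mate is placed fully on the contig near
    the terminus (overlap >= its whole length) and the read itself still
    aligns over >= MATE_ANCHOR_MIN nt.  The mate route lets extension step
    across local coverage troughs, using the fragment span as the bridge.
    """
    L = len(contig)
    tail_off = max(0, L - (pool.max_len + MAX_PAIR_SPAN))
    T = contig[tail_off:]
    index: dict[str, list[int]] = {}
    for i in range(len(T) - k + 1):
        index.setdefault(T[i : i + k], []).append(i)
    contig_arr = np.frombuffer(contig.encode(), dtype=np.uint8)
    direct: list[str] = []
    short: list[tuple[int, int, str]] = []  # (pair_idx, g, overhang) needing a mate
    inside: dict[int, int] = {}  # pair_idx -> leftmost full placement position
    for pair_idx, _mate_idx, s, arr in pool.entries:
        n = len(s)
        if n < k:
            continue
        stride = max(1, (n - k) // 6)
        diags = set()
        for i in range(0, n - k + 1, stride):
            for p in index.get(s[i : i + k], ()):
                diags.add(p - i)
        best = None
        for d in diags:
            g = tail_off + d
            if g < 0:
                continue
            overlap = min(L - g, n)
            if overlap < MATE_ANCHOR_MIN:
                continue
            mism = int(np.count_nonzero(contig_arr[g : g + overlap] != arr[:overlap]))
            if mism <= math.ceil(mm_frac * overlap):
                cand = (mism, -overlap, g)
                if best is None or cand < best:
                    best = cand
        if best is None:
            continue
        _mism, neg_overlap, g = best
        overlap = -neg_overlap
        if overlap >= n:  # fully contained: can vouch for its mate
            prev = inside.get(pair_idx)
            if prev is None or g < prev:
                inside[pair_idx] = g
            continue
        if overlap >= min_anchor:
            direct.append(s[overlap:])
        else:
            short.append((pair_idx, g, s[overlap:]))
    rescued = [
        oh for pair_idx, g, oh in short
        if pair_idx in inside
        and inside[pair_idx] < g
        and g - inside[pair_idx] <= MAX_PAIR_SPAN
        and L - inside[pair_idx] >= min_anchor
    ]
    return direct + rescued


def _extend_right(contig: str, pool: ReadPool, cfg: ReconstructionConfig,
                  steps: int, anchor: int) -> tuple[str, int]:
    added = 0
    for _ in range(steps):
        overhangs = _right_overhangs(contig, pool, anchor, cfg.mismatch_frac)
        ext = _consensus_overhang(overhangs, cfg.min_support)
        if not ext:
            break
        contig += ext
        added += len(ext)
    return contig, added


def extend_round(contig: str, pool: ReadPool, cfg: ReconstructionConfig = None,
                 ) -> tuple[str, dict]:
    """One extension round: both termini grown by overhang consensus."""
    cfg = cfg or ReconstructionConfig()
    if len(contig) < 400:
        raise ValueError("contig must be at least 400 nt before extension")
    contig, right_added = _extend_right(contig, pool, cfg, cfg.inner_steps, cfg.min_anchor)
    rc, left_added = _extend_right(revcomp(contig), pool, cfg, cfg.inner_steps, cfg.min_anchor)
    return revcomp(rc), {"left": left_added, "right": right_added}


# ---------------------------------------------------------------- seed


def build_seed_contig(pairs, cfg: ReconstructionConfig = None) -> SeedContig:
    """Stringent de-novo assembly of harvested reads plus window selection."""
    cfg = cfg or ReconstructionConfig()
    pool = ReadPool(pairs)
    if len(pool.reads) < cfg.min_seed_reads:
        raise InsufficientCoverageError(
            f"only {len(pool.reads)} harvested reads (< {cfg.min_seed_reads}); "
            "more data needed"
        )
    # start from the read sitting in the most k-mer-dense (best covered) spot
    k = 21
    kmer_mult: dict[str, int] = {}
    for s in pool.oriented:
        for i in range(0, len(s) - k + 1, 4):
            w = s[i : i + k]
            kmer_mult[w] = kmer_mult.get(w, 0) + 1
    def read_score(s):
        probes = [s[i : i + k] for i in range(0, len(s) - k + 1, 8)]
        vals = sorted(kmer_mult.get(w, 0) + kmer_mult.get(revcomp(w), 0) for w in probes)
        return vals[len(vals) // 2] if vals else 0
    start_read = max(sorted(set(pool.reads)), key=read_score)
    contig = start_read
    for _ in range(40):
        contig, r = _extend_right(contig, pool, cfg, 4, cfg.seed_anchor)
        rc, l = _extend_right(revcomp(contig), pool, cfg, 4, cfg.seed_anchor)
        contig = revcomp(rc)
        if l + r == 0 or len(contig) > 3000:
            break
    coverage, consensus = _coverage_and_consensus(contig, pool, cfg, circular=False)
    contig = consensus
    lo, hi = cfg.window_bounds
    window = _select_window(coverage, lo, hi, cfg.min_window_coverage)
    if window is None:
        raise InsufficientCoverageError(
            f"no {lo}-{hi} nt window reaches {cfg.min_window_coverage}x coverage; "
            "more data needed",
            contig=contig,
        )
    a, b = window
    return SeedContig(contig[a:b], coverage[a:b], window)


def _window_minima(coverage: np.ndarray, length: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(coverage, length).min(axis=1)


def _select_window(coverage: np.ndarray, lo: int, hi: int, min_cov: float):
    """Min-coverage-maximizing window of length in [lo, hi]; ties -> longest.

    The achievable max-min coverage is non-increasing in window length, so
    the optimum score is found at the shortest length and the longest
    window attaining it is located by bisection.
    """
    n = coverage.size
    if n < lo:
        return None
    hi = min(hi, n)
    best_score = _window_minima(coverage, lo).max()
    if best_score < min_cov:
        return None
    low, high = lo, hi
    while low < high:  # largest length whose max-min equals best_score
        mid = (low + high + 1) // 2
        if _window_minima(coverage, mid).max() >= best_score:
            low = mid
        else:
            high = mid - 1
    mins = _window_minima(coverage, low)
    start = int(np.argmax(mins))
    return start, start + low


def _coverage_and_consensus(contig: str, pool: ReadPool, cfg: ReconstructionConfig,
                            circular: bool) -> tuple[np.ndarray, str]:
    """Stringent re-mapping of the pool: per-base coverage and majority consensus."""
    reads = [(f"r{i:07d}", s) for i, s in enumerate(pool.reads)]
    placements, _ = map_reads(reads, {"contig": contig}, preset_params("stringent"),
                              circular=circular)
    L = len(contig)
    counts = np.zeros((L, 4), dtype=np.int32)
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    for p in placements:
        seq = p.read_seq if p.strand == "+" else revcomp(p.read_seq)
        if p.gaps:
            continue
        arr = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
        pos = (np.arange(p.start, p.start + arr.size)) % L
        ok = arr >= 0
        np.add.at(counts, (pos[ok], arr[ok]), 1)
    coverage = counts.sum(axis=1)
    bases = np.frombuffer(contig.encode(), dtype=np.uint8).copy()
    covered = coverage > 0
    maj = counts.argmax(axis=1)
    top = counts.max(axis=1)
    unique = (counts == top[:, None]).sum(axis=1) == 1
    upd = covered & unique
    bases[upd] = np.frombuffer(b"ACGT", dtype=np.uint8)[maj[upd]]
    return coverage, bases.tobytes().decode()


# ---------------------------------------------------------------- closure


def _terminal_repeat_length(contig: str, closure_min: int) -> int:
    """Longest exact prefix/suffix identity, or 0 when below closure_min."""
    for k in range(len(contig) // 2, closure_min - 1, -1):
        if contig.startswith(contig[-k:]):
            return k
    return 0


def close_and_monomerize(contig: str, closure_min: int = 100) -> ReconstructionResult:
    """Detect ring closure and trim the terminal duplication.

    Closure requires exact terminal identity over >= closure_min nt; an
    additional terminal repeat inside the candidate monomer signals a
    tandem-repeat ambiguity and raises rather than guessing.
    """
    if len(contig) < 1000:
        raise ValueError("contig must be at least 1 kb for closure detection")
    k = _terminal_repeat_length(contig, closure_min)
    if k == 0:
        return ReconstructionResult(None, contig, False, 0)
    monomer = contig[:-k]
    k2 = _terminal_repeat_length(monomer, closure_min)
    if k2:
        raise ClosureAmbiguityError(
            "multiple closure candidates: terminal repeats of "
            f"{k} nt (at {len(contig) - k}..{len(contig)}) and {k2} nt inside "
            "the candidate monomer suggest a tandem repeat"
        )
    return ReconstructionResult(
        CircularSequence(monomer, "reconstructed"), contig, True, 0, terminal_repeat_len=k
    )


# ---------------------------------------------------------------- rotation


def rotate_to_reference(
    monomer: CircularSequence, reference: Optional[CircularSequence] = None, probe: int = 200
) -> CircularSequence:
    """Set the start base to match a reference, or canonicalize without one."""
    if reference is None:
        return monomer.canonical()
    import edlib

    probe_seq = reference.seq[: min(probe, len(reference))]
    best = None
    for strand, cand in (("+", monomer.seq), ("-", revcomp(monomer.seq))):
        res = edlib.align(probe_seq, cand + cand[: len(probe_seq)], mode="HW",
                          task="locations")
        if res["editDistance"] >= 0 and res["locations"]:
            key = (res["editDistance"], strand)
            if best is None or key < best[0]:
                off = res["locations"][0][0] % len(monomer)
                best = (key, cand[off:] + cand[:off])
    if best is None:
        return monomer.canonical()
    return CircularSequence(best[1], monomer.name)


# ---------------------------------------------------------------- orchestration


def reconstruct(
    pairs,
    references: Sequence[tuple[CircularSequence, Sequence[GeneAnnotation]]],
    cfg: ReconstructionConfig = None,
    reference_for_rotation: Optional[CircularSequence] = None,
) -> ReconstructionResult:
    """Full pipeline: harvest -> seed -> iterated extension -> closure -> rotate.

    Non-closure (insufficient data, stalled extension, round limit) is
    reported as a structured partial result, never silently."""
    cfg = cfg or ReconstructionConfig()
    log: list[dict] = []
    harvested = harvest_seed_reads(pairs, references, cfg.target_gene)
    log.append({"stage": "harvest", "pairs": len(harvested)})
    try:
        seed = build_seed_contig(harvested, cfg)
    except InsufficientCoverageError as exc:
        log.append({"stage": "seed", "error": str(exc)})
        return ReconstructionResult(None, exc.contig, False, 0, log=log)
    log.append({"stage": "seed", "length": len(seed.sequence),
                "min_coverage": float(seed.coverage.min())})
    pool = ReadPool(pairs)
    contig = seed.sequence
    rounds = 0
    stalled = 0
    result = None
    while rounds < cfg.max_rounds:
        contig, growth = extend_round(contig, pool, cfg)
        rounds += 1
        log.append({"stage": "extend", "round": rounds, **growth, "length": len(contig)})
        if len(contig) >= 1000:
            candidate = close_and_monomerize(contig, cfg.closure_min)
            if candidate.closed:
                result = candidate
                break
        stalled = stalled + 1 if growth["left"] + growth["right"] == 0 else 0
        if stalled >= cfg.stall_rounds:
            log.append({"stage": "halt", "reason": f"no progress for {stalled} rounds"})
            break
    if result is None:
        return ReconstructionResult(None, contig, False, rounds, log=log)
    monomer = result.monomer
    coverage = None
    if cfg.polish:
        for _ in range(2):
            coverage, polished = _coverage_and_consensus(monomer.seq, pool, cfg, circular=True)
            changed = polished != monomer.seq
            monomer = CircularSequence(polished, monomer.name)
            if not changed:
                break
        log.append({"stage": "polish", "mean_coverage": float(coverage.mean())})
    monomer = rotate_to_reference(monomer, reference_for_rotation)
    return ReconstructionResult(
        monomer, result.contig, True, rounds,
        terminal_repeat_len=result.terminal_repeat_len, coverage=coverage, log=log,
    )
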