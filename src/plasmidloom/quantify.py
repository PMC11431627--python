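"""Fraction-abundance ratios and strand-specific transcription accounting.

Two quantification tasks share the strict ``quant`` mapping preset
(<=1% mismatches, unique placements only, no gaps):

* **fraction abundance** — equal-size subsamples of paired reads from each
  brine fraction (intracellular, dissolved, virus-pellet DNA, ...) are
  mapped to a plasmid; the mapped-read counts, expressed relative to a
  reference fraction, show in which physical fraction the plasmid resides.
  Counts are *reads* (not pairs).  Presentation rounding is one decimal,
  two decimals below 0.1, while raw ratios are retained.
* **stranded transcription** — RNA-seq pairs are first depleted of rRNA by
  mapping against a decoy, then mapped to the plasmid; each surviving
  fragment (pair counted once) is assigned a transcript strand per the
  library convention (default ``reverse`` = dUTP-style, first read
  antisense to the transcript), giving per-gene sense/antisense counts and
  per-strand coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .circular import CircularSequence, GeneAnnotation
from .mapping import map_pairs, map_reads, preset_params


@dataclass
class FractionReport:
    counts: dict[str, int]
    reference_fraction: str
    proportions: dict[str, float]
    presented: dict[str, float]
    n_pairs: int


@dataclass
class StrandedCoverage:
    coverage_top: np.ndarray
    coverage_bottom: np.ndarray
    gene_counts: dict[str, dict[str, int]]  # label -> {sense, antisense}
    zero_coverage_bases: int
    mapped_fragments: int
    rrna_fragments: int
    unmapped_fragments: int


def present_proportion(x: float) -> float:
    """Table-style rounding: one decimal, two decimals below 0.1."""
    return round(x, 2) if x < 0.1 else round(x, 1)


def proportions_from_counts(
    counts: dict[str, int], reference_fraction: str
) -> tuple[dict[str, float], dict[str, float]]:
    """Raw and presentation-rounded mapped-read proportions vs the reference."""
    if reference_fraction not in counts:
        raise ValueError(f"unknown reference fraction {reference_fraction!r}")
    ref = counts[reference_fraction]
    if ref <= 0:
        raise ValueError("reference fraction has no mapped reads")
    raw = {f: c / ref for f, c in counts.items()}
    return raw, {f: present_proportion(v) for f, v in raw.items()}


def fraction_abundance(
    readsets: dict[str, list],
    plasmid: CircularSequence,
    n_pairs: int,
    reference_fraction: str,
    seed: int = 0,
) -> FractionReport:
    """Equal-size seeded subsampling, quant-preset mapping, relative counts."""
    if reference_fraction not in readsets:
        raise ValueError(f"unknown reference fraction {reference_fraction!r}")
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    params = preset_params("quant")
    refdict = {plasmid.name: plasmid.seq}
    for fraction in readsets:
        pairs = readsets[fraction]
        if len(pairs) < n_pairs:
            raise ValueError(
                f"fraction {fraction!r} has only {len(pairs)} pairs (< {n_pairs})"
            )
        idx = rng.choice(len(pairs), size=n_pairs, replace=False)
        sub = [pairs[i] for i in sorted(idx)]
        flat = []
        for i, (r1, r2) in enumerate(sub):
            flat.append((f"{i:08d}/1", r1.seq))
            flat.append((f"{i:08d}/2", r2.seq))
        _placements, stats = map_reads(flat, refdict, params, circular=True)
        counts[fraction] = stats.mapped
    raw, presented = proportions_from_counts(counts, reference_fraction)
    return FractionReport(counts, reference_fraction, raw, presented, n_pairs)


def deplete_rrna(pairs: Sequence, rrna_ref: str) -> tuple[list, int]:
    """Drop pairs with either mate mapping to the rRNA decoy (quant preset)."""
    params = preset_params("quant")
    placements, _ = map_pairs(pairs, {"rRNA": rrna_ref}, params, circular=False)
    kept = [pairs[i] for i, (p1, p2) in placements.items() if p1 is None and p2 is None]
    return kept, len(pairs) - len(kept)


def stranded_transcription(
    rna_pairs: Sequence,
    plasmid: CircularSequence,
    annotations: Sequence[GeneAnnotation],
    rrna_ref: Optional[str] = None,
    strandedness: str = "reverse",
) -> StrandedCoverage:
    """rRNA depletion, quant-preset mapping, and per-gene strand accounting."""
    if strandedness not in {"reverse", "forward"}:
        raise ValueError("strandedness must be 'reverse' or 'forward'")
    bad = [a for a in annotations if a.seqid != plasmid.name]
    if bad:
        raise ValueError(
            f"annotations for {bad[0].seqid!r} do not match plasmid {plasmid.name!r}"
        )
    n_rrna = 0
    pairs = list(rna_pairs)
    if rrna_ref is not None:
        pairs, n_rrna = deplete_rrna(pairs, rrna_ref)
    params = preset_params("quant")
    placements, _ = map_pairs(pairs, {plasmid.name: plasmid.seq}, params, circular=True)
    L = len(plasmid)
    cov_top = np.zeros(L, dtype=np.int64)
    cov_bottom = np.zeros(L, dtype=np.int64)
    gene_counts = {
        a.label: {"sense": 0, "antisense": 0} for a in annotations
    }
    mapped = 0
    for p1, p2 in placements.values():
        anchors = [p for p in (p1, p2) if p is not None]
        if not anchors:
            continue
        mapped += 1
        # mates of an FR pair map to opposite strands, so R1's strand is
        # recoverable even when only R2 placed
        r1_strand = p1.strand if p1 is not None else ("-" if p2.strand == "+" else "+")
        if strandedness == "reverse":
            tstrand = "-" if r1_strand == "+" else "+"
        else:
            tstrand = r1_strand
        lo = min(p.start for p in anchors)
        hi = max(p.end for p in anchors)
        span = min(hi - lo, L)
        pos = np.arange(lo, lo + span) % L
        (cov_top if tstrand == "+" else cov_bottom)[pos] += 1
        for a in annotations:
            if a.overlaps(lo, hi, L):
                key = "sense" if tstrand == a.strand else "antisense"
                gene_counts[a.label][key] += 1
    zero = int(((cov_top + cov_bottom) == 0).sum())
    return StrandedCoverage(
        cov_top, cov_bottom, gene_counts, zero,
        mapped_fragments=mapped,
        rrna_fragments=n_rrna,
        unmapped_fragments=len(pairs) - mapped,
    )
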