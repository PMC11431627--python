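"""ORF calling, core-gene assignment, variant classification, and reports.

The pL6-style plasmids analysed here carry up to seven core genes arranged
in two outward-facing modules: a forward replication module (F1, F2, F3,
with described replacements F1b, F2a, F2b, F2c) and a reverse ATPase module
(R4–R7).  Plasmids are grouped into four variant classes by which
F-module genes they carry:

* ``canonical``     — full-length F1, F2, F3;
* ``no_F2``         — F2 lost entirely;
* ``F2b_F2a``       — F2 replaced by the two smaller genes F2b and F2a;
* ``F1b_F2a_F2c``   — divergent F1 (F1b) followed by F2a and F2c.

Classification is a pure function of the core-gene presence vector and is
applied in that order of precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .circular import CircularSequence, GeneAnnotation, revcomp

CORE_LABELS = ("F1", "F1b", "F2", "F2a", "F2b", "F2c", "F3", "R4", "R5", "R6", "R7")
F2_FAMILY = {"F2", "F2a", "F2b", "F2c"}
DEFAULT_STARTS = ("ATG", "GTG", "TTG")

_KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9, "R": -4.5,
}


@dataclass
class Orf:
    start: int  # 0-based half-open on the circle; end may exceed L (wrap)
    end: int
    strand: str
    start_codon: str
    protein: str

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------- ORFs


def find_orfs(
    seq: CircularSequence,
    min_aa: int = 20,
    starts: Sequence[str] = DEFAULT_STARTS,
    allow_ctg: bool = False,
) -> list[Orf]:
    """Scan both strands, all frames, across the origin.

    For each stop-anchored frame segment the longest ORF with a permitted
    start codon is reported.  ORFs spanning the origin appear once, with a
    wrapped interval on the forward strand.
    """
    if min_aa < 20:
        raise ValueError("min_aa must be >= 20")
    start_set = set(starts) | ({"CTG"} if allow_ctg else set())
    L = len(seq)
    orfs: dict[tuple[int, int, str], Orf] = {}
    for strand in "+-":
        s = seq.doubled if strand == "+" else revcomp(seq.doubled)
        for frame in range(3):
            seg_begin = None  # only stop-anchored segments are collected;
            # the doubled scan sees every circular segment in anchored form
            for i in range(frame, len(s) - 2, 3):
                if s[i : i + 3] in ("TAA", "TAG", "TGA"):
                    if seg_begin is not None:
                        _collect_orf(orfs, s, seg_begin, i + 3, strand, L, start_set, min_aa)
                    seg_begin = i + 3
    return sorted(orfs.values(), key=lambda o: (o.start, o.end, o.strand))


def _collect_orf(orfs, s, seg_begin, seg_end, strand, L, start_set, min_aa):
    """Record the longest permitted-start ORF of a stop-terminated segment.

    ``s`` is the doubled sequence on the scanned strand; every circular ORF
    shows up at least once fully inside it (twice when short), so results
    are deduplicated by their wrapped circle interval.
    """
    for i in range(seg_begin, seg_end - 3, 3):
        if s[i : i + 3] not in start_set:
            continue
        length = seg_end - i
        n_aa = length // 3 - 1  # protein residues excluding the stop
        if length > L or n_aa < min_aa:
            return
        if strand == "+":
            start = i
        else:  # s[i:j) mirrors doubled[2L-j : 2L-i) on the forward strand
            start = 2 * L - seg_end
        start_mod = start % L
        end = start_mod + length
        protein = str(Seq(s[i : i + 3 * n_aa]).translate())
        key = (start_mod, end % L if end % L else L, strand)
        if key not in orfs:
            orfs[key] = Orf(start_mod, end, strand, s[i : i + 3], protein)
        return


# ---------------------------------------------------------------- core genes


@dataclass
class CoreGeneRef:
    """Reference protein set for core-gene assignment, keyed by label."""

    proteins: dict[str, list[str]]

    def __post_init__(self):
        if not self.proteins:
            raise ValueError("reference protein set is empty")
        unknown = set(self.proteins) - set(CORE_LABELS)
        if unknown:
            raise ValueError(f"unknown core labels: {sorted(unknown)}")


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    aligner.end_gap_score = 0.0
    return aligner


def _identity_and_coverage(aln, ref_len: int) -> tuple[float, float]:
    """(identity over aligned columns excl. terminal gaps, ref coverage)."""
    a, b = aln[0], aln[1]
    # trim terminal overhang columns
    lead = 0
    while lead < len(a) and (a[lead] == "-" or b[lead] == "-"):
        lead += 1
    tail = len(a)
    while tail > lead and (a[tail - 1] == "-" or b[tail - 1] == "-"):
        tail -= 1
    cols = tail - lead
    if cols <= 0:
        return 0.0, 0.0
    matches = sum(1 for i in range(lead, tail) if a[i] == b[i] and a[i] != "-")
    ref_aligned = sum(1 for i in range(lead, tail) if a[i] != "-")
    return matches / cols, ref_aligned / ref_len


def assign_core_genes(
    orfs: Sequence[Orf],
    refs: CoreGeneRef,
    seqid: str = "plasmid",
    min_identity: float = 0.35,
    min_coverage: float = 0.5,
) -> list[GeneAnnotation]:
    """Label ORFs by best global-protein-alignment match to the references.

    Each ORF gets the best-matching core label with identity >=
    ``min_identity`` and reference coverage >= ``min_coverage``; others are
    ``accessory``.  At most one ORF keeps each core label (best identity
    wins; the runner-up is flagged), and an ORF whose top two labels tie is
    flagged ambiguous rather than silently assigned.
    """
    aligner = _protein_aligner()
    annotations = []
    best_by_label: dict[str, tuple[float, GeneAnnotation]] = {}
    for orf in orfs:
        scored = []
        for label, prots in refs.proteins.items():
            for ref_prot in prots:
                aln = aligner.align(ref_prot, orf.protein)[0]
                ident, cov = _identity_and_coverage(aln, len(ref_prot))
                if ident >= min_identity and cov >= min_coverage:
                    scored.append((ident, label))
        attrs = {}
        if scored:
            scored.sort(reverse=True)
            ident, label = scored[0]
            if len(scored) > 1 and scored[1][0] == ident and scored[1][1] != label:
                label = "accessory"
                attrs["ambiguous"] = "+".join(sorted({s[1] for s in scored if s[0] == ident}))
            attrs["identity"] = f"{ident:.3f}"
        else:
            ident, label = 0.0, "accessory"
        ann = GeneAnnotation(seqid, label, orf.start, orf.end, orf.strand, attributes=attrs)
        if label != "accessory":
            prev = best_by_label.get(label)
            if prev is not None:
                if ident > prev[0]:
                    prev[1].label = "accessory"
                    prev[1].attributes["runner_up_for"] = label
                    best_by_label[label] = (ident, ann)
                else:
                    ann.label = "accessory"
                    ann.attributes["runner_up_for"] = label
            else:
                best_by_label[label] = (ident, ann)
        annotations.append(ann)
    return annotations


# ---------------------------------------------------------------- variants


@dataclass
class VariantClass:
    value: str
    evidence: dict = field(default_factory=dict)


def classify_variant(annotations) -> VariantClass:
    """Variant group from the core-gene presence vector (pure function).

    ``annotations`` may be GeneAnnotation objects or bare label strings.
    Rules in order: F1b&F2a&F2c -> F1b_F2a_F2c; F2b&F2a -> F2b_F2a;
    F2 -> canonical; F1&F3 without any F2-family gene -> no_F2; otherwise
    unclassified.  F3 is universal in the family, so its absence always
    yields unclassified.
    """
    labels = {a.label if hasattr(a, "label") else str(a) for a in annotations}
    present = {lbl: lbl in labels for lbl in CORE_LABELS}
    if not present["F3"]:
        return VariantClass("unclassified", present)
    if present["F1b"] and present["F2a"] and present["F2c"]:
        return VariantClass("F1b_F2a_F2c", present)
    if present["F2b"] and present["F2a"]:
        return VariantClass("F2b_F2a", present)
    if present["F2"]:
        return VariantClass("canonical", present)
    if present["F1"] and not (labels & F2_FAMILY):
        return VariantClass("no_F2", present)
    return VariantClass("unclassified", present)


# ---------------------------------------------------------------- structure


_JUNCTIONS = (("F1", "F2"), ("F2", "F3"), ("R4", "R5"), ("R5", "R6"), ("R6", "R7"))


def module_structure_report(annotations: Sequence[GeneAnnotation], seq: CircularSequence) -> dict:
    """Per-junction overlap/intergenic distances plus insertion and TMD flags.

    The junction value is signed: negative = overlap length, positive =
    intergenic distance, 0 = abutting.  An inserted CDS between two core
    genes is flagged without reordering the module.
    """
    L = len(seq)
    by_label = {a.label: a for a in annotations}
    report: dict = {"junctions": {}, "insertions": [], "r4_tmd": None}
    for left, right in _JUNCTIONS:
        a, b = by_label.get(left), by_label.get(right)
        if a is None or b is None:
            continue
        # order on the circle irrespective of module orientation
        first, second = (a, b) if a.start <= b.start else (b, a)
        gap = second.start - first.end
        kind = "overlap" if gap < 0 else "intergenic"
        report["junctions"][f"{left}/{right}"] = {
            "relation": kind,
            "value": -gap if gap < 0 else gap,
        }
        inserted = [
            c.label
            for c in annotations
            if c not in (a, b)
            and first.end <= c.start and c.end <= second.start
        ]
        if inserted:
            report["insertions"].append({"between": f"{left}/{right}", "labels": inserted})
    r4 = by_label.get("R4")
    if r4 is not None:
        prot = _translate_annotation(seq, r4)
        report["r4_tmd"] = has_cterminal_tmd(prot)
    return report


def _translate_annotation(seq: CircularSequence, ann: GeneAnnotation) -> str:
    nt = seq.fetch(ann.start % len(seq), ann.length)
    if ann.strand == "-":
        nt = revcomp(nt)
    return str(Seq(nt[: 3 * (len(nt) // 3)]).translate()).rstrip("*")


def has_cterminal_tmd(protein: str, window: int = 18, cutoff: float = 1.6, tail: int = 40) -> bool:
    """Kyte–Doolittle heuristic: an >=18-residue window with mean
    hydropathy > cutoff within the C-terminal ``tail`` residues."""
    region = protein[-tail:]
    vals = np.array([_KYTE_DOOLITTLE.get(aa, 0.0) for aa in region])
    if vals.size < window:
        return False
    means = np.convolve(vals, np.ones(window) / window, mode="valid")
    return bool((means > cutoff).any())


# ---------------------------------------------------------------- CIS


@dataclass
class CisReport:
    interval: tuple[int, int]
    region: str
    matches: list[dict] = field(default_factory=list)
    consensus: str = ""


def consensus_at_threshold(seqs: Sequence[str], threshold: float = 0.75) -> str:
    """Column consensus of equal-length sequences; below-threshold columns = N."""
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("consensus requires equal-length sequences")
    cols = []
    for i in range(len(seqs[0])):
        counts: dict[str, int] = {}
        for s in seqs:
            counts[s[i]] = counts.get(s[i], 0) + 1
        base, n = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        cols.append(base if n / len(seqs) >= threshold else "N")
    return "".join(cols)


def cis_report(
    seq: CircularSequence,
    annotations: Sequence[GeneAnnotation],
    cis_profiles: dict[str, str],
    threshold: float = 0.75,
) -> CisReport:
    """Extract the R4–F1 intergenic region and scan it for conserved motifs.

    The region hosts the promoters driving both outward-facing modules.  A
    profile matches when its best gap-aware occurrence in the region has
    identity >= ``threshold``.
    """
    import edlib

    by_label = {a.label: a for a in annotations}
    if "R4" not in by_label or "F1" not in by_label and "F1b" not in by_label:
        raise ValueError("R4 and F1 must both be annotated to locate the intergenic region")
    f1 = by_label.get("F1") or by_label["F1b"]
    r4 = by_label["R4"]
    L = len(seq)
    start = r4.end % L  # downstream end of R4 (its start codon side, minus strand)
    span = (f1.start - start) % L
    region = seq.fetch(start, span)
    report = CisReport((start, start + span), region)
    for name, profile in cis_profiles.items():
        res = edlib.align(profile.upper(), region, mode="HW", task="locations")
        dist = res["editDistance"]
        identity = 1 - dist / len(profile)
        if identity >= threshold and res["locations"]:
            off = res["locations"][0][0]
            report.matches.append(
                {"cis": name, "match": True, "offset": off, "identity": round(identity, 3)}
            )
        else:
            report.matches.append({"cis": name, "match": False, "identity": round(identity, 3)})
    return report


# ---------------------------------------------------------------- summary


def table_summary(records: Sequence[dict]) -> dict:
    """Min/max/mean/median over per-plasmid size and %G+C records.

    ``records`` rows carry ``size`` (bp) and ``gc`` (percent).  Mean size is
    reported to the nearest integer and %G+C statistics to one decimal,
    matching how such tables are conventionally printed.
    """
    if not records:
        raise ValueError("empty summary table")
    sizes = [r["size"] for r in records]
    gcs = [r["gc"] for r in records]
    return {
        "n": len(records),
        "size_min": min(sizes),
        "size_max": max(sizes),
        "size_mean": round(sum(sizes) / len(sizes)),
        "size_median": median(sizes),
        "gc_min": round(min(gcs), 1),
        "gc_max": round(max(gcs), 1),
        "gc_mean": round(sum(gcs) / len(gcs), 1),
        "gc_median": round(median(gcs), 1),
    }
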