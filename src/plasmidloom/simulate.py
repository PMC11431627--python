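"""Synthetic plasmids, read sets, transcriptomes, and CRISPR-bearing contigs.

The generator emulates the statistical structure of the real study system —
~6 kb circular haloarchaeal plasmids with two outward-facing gene modules —
so every downstream stage of the pipeline can be exercised without any
download:

* a circular plasmid with forward replication-module genes (F1, F2, F3)
  overlapping at 4-base ATGA stop/start junctions, reverse ATPase-module
  genes (R4–R7) with realistic intergenic spacing, controlled %G+C, and
  blacklisted restriction-site words (GGCC, CTAG) scrubbed to zero circular
  occurrences by codon-compatible resampling;
* paired-end reads with uniform fragment starts on the circle (fragments
  may span the origin), Gaussian insert sizes, and uniform substitution
  errors;
* strand-specific RNA-seq with configurable antisense fraction and an rRNA
  decoy admixture;
* host-like contigs carrying CRISPR repeat/spacer arrays whose spacers are
  copied from the plasmids, with a truth table for recall scoring.

All simulators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .circular import CircularSequence, GeneAnnotation, revcomp
from .io import FastqRead, ReadPair

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}

_CODON_TABLE: dict[str, str] = {}
for _c1 in "TCAG":
    for _c2 in "TCAG":
        for _c3 in "TCAG":
            _codon = _c1 + _c2 + _c3
            from Bio.Seq import Seq as _Seq

            _CODON_TABLE[_codon] = str(_Seq(_codon).translate())

_SYNONYMS: dict[str, list[str]] = {}
for _codon, _aa in _CODON_TABLE.items():
    _SYNONYMS.setdefault(_aa, []).append(_codon)


# ---------------------------------------------------------------- specs


@dataclass
class PlasmidSpec:
    """Blueprint for one synthetic plasmid."""

    length: int = 6000
    gc_target: float = 0.525
    motif_blacklist: tuple[str, ...] = ("GGCC", "CTAG")
    variant: str = "canonical"
    seed: int = 0
    name: str = "synthetic"
    # reverse-module intergenic distances (nt): R4/R5, R5/R6, R6/R7
    r_gaps: tuple[int, int, int] = (25, 2, 100)

    def __post_init__(self):
        if not 5000 <= self.length <= 8000:
            raise ValueError("target length must be in [5000, 8000]")
        if not 0 < self.gc_target < 1:
            raise ValueError("gc_target must be in (0, 1)")
        if self.variant not in {"canonical", "no_F2", "F2b_F2a", "F1b_F2a_F2c"}:
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class ReadSimParams:
    read_length: int = 150
    insert_mean: int = 350
    insert_sd: int = 40
    error_rate: float = 0.0
    n_pairs: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.insert_mean <= self.read_length:
            raise ValueError("insert_mean must exceed read_length")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")


@dataclass
class TranscriptomeSimParams:
    sense_rate_forward: float = 1.0
    sense_rate_reverse: float = 1.0
    antisense_fraction: float = 0.0
    strandedness: str = "reverse"
    rrna_fraction: float = 0.0
    n_pairs: int = 1000
    read_length: int = 100
    insert_mean: int = 220
    insert_sd: int = 20
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.antisense_fraction < 1:
            raise ValueError("antisense_fraction must be in [0, 1)")
        if not 0 <= self.rrna_fraction < 1:
            raise ValueError("rrna_fraction must be in [0, 1)")
        if self.strandedness not in {"reverse", "forward"}:
            raise ValueError("strandedness must be 'reverse' or 'forward'")


@dataclass
class CommunitySpec:
    """A mock brine community: plasmids at set abundances plus host decoys."""

    plasmids: list  # [(CircularSequence, relative_abundance)]
    background: list = field(default_factory=list)  # [CircularSequence]
    background_abundance: float = 1.0
    fraction_multipliers: dict = field(
        default_factory=lambda: {"iDNA": 1.0, "FdDNA": 2.6, "CdDNA": 1.6, "vDNA": 0.03}
    )

    def __post_init__(self):
        if any(a <= 0 for _, a in self.plasmids):
            raise ValueError("plasmid abundances must be positive")
        if any(m < 0 for m in self.fraction_multipliers.values()):
            raise ValueError("fraction multipliers must be non-negative")


# ---------------------------------------------------------------- plasmid


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"AGCT", dtype=np.uint8), size=n, p=p).tobytes().decode()


def _random_codon(rng, gc: float) -> str:
    while True:
        c = _random_bases(rng, 3, gc)
        if c not in _STOPS:
            return c


def _make_gene(rng, aa_len: int, gc: float, head_A: bool = False, tail_ATGA: bool = False) -> str:
    """One ORF: ATG start, aa_len sense codons, TGA stop.

    ``head_A`` forces the first internal codon to begin with A (required for
    a gene entered through an ATGA overlap); ``tail_ATGA`` forces the last
    4 nt to read ATGA so the next gene's start can overlap the stop.
    """
    codons = ["ATG"]
    for i in range(aa_len):
        while True:
            c = _random_codon(rng, gc)
            if i == 0 and head_A and not c.startswith("A"):
                continue
            if i == aa_len - 1 and tail_ATGA and not c.endswith("A"):
                continue
            codons.append(c)
            break
    codons.append("TGA")
    return "".join(codons)


_VARIANT_FORWARD = {
    "canonical": [("F1", 140), ("F2", 190), ("F3", 290)],
    "no_F2": [("F1", 140), ("F3", 290)],
    "F2b_F2a": [("F1", 140), ("F2b", 80), ("F2a", 95), ("F3", 290)],
    "F1b_F2a_F2c": [("F1b", 140), ("F2a", 95), ("F2c", 80), ("F3", 290)],
}
_REVERSE_GENES = [("R7", 60), ("R6", 170), ("R5", 70), ("R4", 110)]


def _build_r4_tail(rng) -> str:
    """C-terminal hydrophobic stretch (transmembrane-like) for R4."""
    hydrophobic = [c for aa in "ILVFA" for c in _SYNONYMS[aa]]
    return "".join(rng.choice(hydrophobic) for _ in range(20))


def simulate_plasmid(spec: PlasmidSpec) -> tuple[CircularSequence, list[GeneAnnotation]]:
    """Generate a circular plasmid plus its gene annotations.

    Layout on the forward strand, origin (base 0) inside the R4–F1
    intergenic region:
    ``[5' intergenic] F1 F2 F3 [accessory filler] R7 R6 R5 R4 [3' intergenic]``
    with the reverse-module genes encoded on the minus strand.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_target

    # Each gene draws from its own (seed, label) substream, so a given seed
    # yields identical gene sequences across variants that share the label.
    label_ids = {lbl: i for i, lbl in enumerate(
        ("F1", "F1b", "F2", "F2a", "F2b", "F2c", "F3", "R4", "R5", "R6", "R7"), start=1)}

    def gene_rng(label):
        return np.random.default_rng([spec.seed, label_ids[label]])

    forward_plan = _VARIANT_FORWARD[spec.variant]
    gene_seqs: dict[str, str] = {}
    for i, (label, aa) in enumerate(forward_plan):
        gene_seqs[label] = _make_gene(
            gene_rng(label), aa, gc, head_A=(i > 0), tail_ATGA=(i < len(forward_plan) - 1)
        )
    for label, aa in _REVERSE_GENES:
        grng = gene_rng(label)
        g = _make_gene(grng, aa, gc)
        if label == "R4":
            # splice a hydrophobic C-terminal segment in front of the stop
            g = g[:-63] + _build_r4_tail(grng) + g[-3:]
        gene_seqs[label] = g

    head_len = 60  # downstream part of the R4–F1 intergenic region
    tail_len = 80  # upstream part (ahead of R4 start, across the origin)
    fwd_len = sum(len(gene_seqs[lbl]) for lbl, _ in forward_plan) - 4 * (len(forward_plan) - 1)
    rev_len = sum(len(gene_seqs[lbl]) for lbl, _ in _REVERSE_GENES) + sum(spec.r_gaps)
    filler_len = spec.length - head_len - tail_len - fwd_len - rev_len
    if filler_len < 50:
        raise ValueError("target length too small for the requested gene plan")

    parts: list[str] = []
    annotations: list[GeneAnnotation] = []
    pos = 0

    def _emit(s: str):
        nonlocal pos
        parts.append(s)
        pos += len(s)

    fixed_gc = sum(c in "GC" for s in gene_seqs.values() for c in s)
    fixed_len = sum(len(s) for s in gene_seqs.values())
    inter_len = spec.length - (fixed_len - 4 * (len(forward_plan) - 1))
    # solve the intergenic G+C content so the whole circle hits gc_target
    need = spec.gc_target * spec.length - (fixed_gc - 2 * (len(forward_plan) - 1))
    inter_gc = min(max(need / inter_len, 0.05), 0.95)

    _emit(_random_bases(rng, head_len, inter_gc))
    for i, (label, _aa) in enumerate(forward_plan):
        g = gene_seqs[label]
        if i == 0:
            start = pos
            _emit(g)
        else:
            start = pos - 4  # ATGA overlap with the previous stop
            _emit(g[4:])
        annotations.append(GeneAnnotation(spec.name, label, start, start + len(g), "+"))
    _emit(_random_bases(rng, filler_len, inter_gc))
    r_gaps = {"R6": spec.r_gaps[2], "R5": spec.r_gaps[1], "R4": spec.r_gaps[0]}
    for label, _aa in _REVERSE_GENES:
        if label in r_gaps:
            _emit(_random_bases(rng, r_gaps[label], inter_gc))
        g = gene_seqs[label]
        annotations.append(GeneAnnotation(spec.name, label, pos, pos + len(g), "-"))
        _emit(revcomp(g))
    _emit(_random_bases(rng, tail_len, inter_gc))

    seq = "".join(parts)
    assert len(seq) == spec.length
    seq = _scrub_motifs(seq, annotations, spec.motif_blacklist, rng)

    plasmid = CircularSequence(seq, spec.name)
    realized_gc = plasmid.gc_fraction()
    if abs(realized_gc - spec.gc_target) > 0.02:
        raise ValueError(
            f"unsatisfiable spec: realized G+C {realized_gc:.3f} vs target {spec.gc_target:.3f}"
        )
    return plasmid, annotations


def _motif_positions(seq: str, motifs: Sequence[str]) -> list[tuple[int, str]]:
    """Circular occurrences (start, motif) of each motif on either strand."""
    L = len(seq)
    hits = []
    for m in motifs:
        for word in {m, revcomp(m)}:
            text = seq + seq[: len(word) - 1]
            start = 0
            while True:
                i = text.find(word, start)
                if i == -1:
                    break
                hits.append((i % L, word))
                start = i + 1
    return sorted(set(hits))


def _scrub_motifs(seq, annotations, blacklist, rng, max_attempts=10000) -> str:
    """Remove every circular occurrence of the blacklisted words.

    Positions inside a CDS are changed only through synonymous codon
    substitutions; intergenic positions get GC-preserving swaps where
    possible.  Fails loudly when the budget is exhausted rather than
    returning a partially depleted sequence.
    """
    if not blacklist:
        return seq
    s = list(seq)
    L = len(s)

    def covering_gene(p):
        for ann in annotations:
            if ann.start <= p < ann.end:
                return ann
        return None

    overlap_zones = set()
    for a in annotations:
        for b in annotations:
            if a is not b and a.strand == b.strand == "+" and a.start < b.start < a.end:
                overlap_zones.update(range(b.start, a.end))

    attempts = 0
    while True:
        hits = _motif_positions("".join(s), blacklist)
        if not hits:
            return "".join(s)
        pos0, word = hits[0]
        fixed = False
        for off in rng.permutation(len(word)):
            p = (pos0 + int(off)) % L
            if p in overlap_zones:
                continue
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"motif scrubbing failed after {max_attempts} attempts "
                    f"(unsatisfiable spec for blacklist {list(blacklist)})"
                )
            ann = covering_gene(p)
            if ann is None:
                old = s[p]
                swap = {"G": "C", "C": "G", "A": "T", "T": "A"}[old]
                choices = [swap] + [b for b in "ACGT" if b not in (old, swap)]
                for new in choices:
                    s[p] = new
                    if not _word_at(s, L, pos0, word):
                        fixed = True
                        break
                    s[p] = old
            else:
                if _try_synonymous(s, L, ann, p, pos0, word, rng):
                    fixed = True
            if fixed:
                break
        if not fixed:
            attempts += len(word)
            if attempts > max_attempts:
                raise RuntimeError(
                    f"motif scrubbing failed after {max_attempts} attempts "
                    f"(unsatisfiable spec for blacklist {list(blacklist)})"
                )


def _word_at(s, L, pos, word) -> bool:
    return all(s[(pos + i) % L] == word[i] for i in range(len(word)))


def _try_synonymous(s, L, ann: GeneAnnotation, p: int, pos0: int, word: str, rng) -> bool:
    """Codon-compatible fix at a CDS position: synonymous swap if one breaks
    the word, else any single-base change keeping the ORF valid (no stop
    created; start and stop codons untouched)."""
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    if ann.strand == "+":
        local = p - ann.start
    else:
        local = (ann.end - 1) - p
    ci = local // 3
    if ann.strand == "+":
        cpos = [ann.start + 3 * ci + j for j in range(3)]
        codon = "".join(s[q] for q in cpos)
    else:
        cpos = [(ann.end - 1) - (3 * ci + j) for j in range(3)]
        codon = "".join(comp[s[q]] for q in cpos)
    aa = _CODON_TABLE.get(codon)
    if aa is None or aa == "*" or ci == 0:  # never touch start or stop codons
        return False
    alts = [c for c in _SYNONYMS[aa] if c != codon]
    rng.shuffle(alts)
    # fallback: conservative single-base edits at the motif position itself
    j = cpos.index(p)
    for new in "ACGT":
        base = new if ann.strand == "+" else comp[new]
        if base == codon[j]:
            continue
        cand = codon[:j] + base + codon[j + 1 :]
        if _CODON_TABLE[cand] != "*":
            alts.append(cand)
    for alt in alts:
        alt_on_plus = [comp[b] for b in alt] if ann.strand == "-" else list(alt)
        old = [s[q] for q in cpos]
        for q, b in zip(cpos, alt_on_plus):
            s[q] = b
        if not _word_at(s, L, pos0, word):
            return True
        for q, b in zip(cpos, old):
            s[q] = b
    return False


# ---------------------------------------------------------------- DNA reads


def _apply_errors(seq: str, rng, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hit:
        choices = BASES[BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _pair_from_fragment(frag: str, strand: str, read_len: int, rng, error_rate, rid) -> ReadPair:
    if strand == "-":
        frag = revcomp(frag)
    r1 = frag[:read_len]
    r2 = revcomp(frag[-read_len:])
    r1 = _apply_errors(r1, rng, error_rate)
    r2 = _apply_errors(r2, rng, error_rate)
    return FastqRead(f"{rid}/1", r1), FastqRead(f"{rid}/2", r2)


def simulate_paired_reads(
    template: CircularSequence, params: ReadSimParams
) -> list[ReadPair]:
    """Uniform paired-end sampling on the circle; fragments may wrap the origin."""
    if params.n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    L = len(template)
    if L <= params.insert_mean:
        raise ValueError("template shorter than the mean insert")
    rng = np.random.default_rng(params.seed)
    pairs = []
    for i in range(params.n_pairs):
        start = int(rng.integers(0, L))
        insert = int(np.clip(rng.normal(params.insert_mean, params.insert_sd),
                             params.read_length + 10, L - 1))
        strand = "+" if rng.random() < 0.5 else "-"
        frag = template.fetch(start, insert)
        rid = f"{template.name}.frag{i:06d}.{start}.{strand}"
        pairs.append(_pair_from_fragment(frag, strand, params.read_length, rng,
                                         params.error_rate, rid))
    return pairs


# ---------------------------------------------------------------- RNA reads


def simulate_rnaseq(
    template: CircularSequence,
    annotations: Sequence[GeneAnnotation],
    params: TranscriptomeSimParams,
    rrna_seq: Optional[str] = None,
) -> tuple[list[ReadPair], list[str]]:
    """Strand-specific RNA-seq pairs plus a truth label per pair.

    Sense reads are drawn from the two transcription units (forward module
    F1..F3 as one unit; reverse module R4..R7 as the other); antisense
    reads come from the opposite strand at ``antisense_fraction``; rRNA
    decoy reads are mixed in at ``rrna_fraction``.  Labels are
    ``sense``/``antisense``/``rrna``.
    """
    if not annotations:
        raise ValueError("annotations are required to define transcription units")
    if params.rrna_fraction > 0 and rrna_seq is None:
        raise ValueError("rrna_fraction > 0 requires an rRNA decoy sequence")
    L = len(template)
    units = []
    for strand in "+-":
        genes = [a for a in annotations if a.strand == strand]
        if genes:
            start = min(a.start for a in genes)
            end = max(a.end for a in genes)
            rate = params.sense_rate_forward if strand == "+" else params.sense_rate_reverse
            units.append((strand, start, end, rate))
    rates = np.array([u[3] for u in units], dtype=float)
    rates /= rates.sum()
    rng = np.random.default_rng(params.seed)
    pairs, labels = [], []
    for i in range(params.n_pairs):
        insert = int(np.clip(rng.normal(params.insert_mean, params.insert_sd),
                             params.read_length + 4, None))
        if rrna_seq is not None and rng.random() < params.rrna_fraction:
            src, label, tstrand = rrna_seq, "rrna", "+"
            start = int(rng.integers(0, max(1, len(rrna_seq) - insert)))
            frag = rrna_seq[start : start + insert]
        else:
            u = units[int(rng.choice(len(units), p=rates))]
            tstrand = u[0]
            span = u[2] - u[1]
            insert = min(insert, span)
            start = u[1] + int(rng.integers(0, span - insert + 1))
            frag = template.fetch(start, insert)
            if rng.random() < params.antisense_fraction:
                label = "antisense"
                tstrand = "-" if tstrand == "+" else "+"
            else:
                label = "sense"
        # fragment as written on the transcript strand
        t_frag = frag if tstrand == "+" else revcomp(frag)
        # library convention: 'reverse' = dUTP-style, R1 opposite the transcript
        if params.strandedness == "reverse":
            r1 = revcomp(t_frag[-params.read_length :])
            r2 = t_frag[: params.read_length]
        else:
            r1 = t_frag[: params.read_length]
            r2 = revcomp(t_frag[-params.read_length :])
        rid = f"{template.name}.rna{i:06d}"
        pairs.append(
            (
                FastqRead(f"{rid}/1", _apply_errors(r1, rng, params.error_rate)),
                FastqRead(f"{rid}/2", _apply_errors(r2, rng, params.error_rate)),
            )
        )
        labels.append(label)
    return pairs, labels


# ---------------------------------------------------------------- CRISPR


def simulate_crispr_contigs(
    plasmids: Sequence[CircularSequence],
    dr_table: Sequence[tuple[str, str]],
    n_arrays: int,
    seed: int = 0,
    n_repeats: int = 4,
    spacer_mutations: int = 0,
    flank: tuple[int, int] = (300, 800),
) -> tuple[dict[str, str], list[dict]]:
    """Host-like contigs carrying CRISPR arrays targeting the plasmids.

    Each contig embeds one array of ``n_repeats`` copies of a genus direct
    repeat alternating with spacers copied from random plasmid positions and
    strands (optionally with up to ``spacer_mutations`` substitutions).
    Returns (contigs, truth rows); truth positions are 1-based first
    matching bases on the plasmid forward strand.
    """
    if not dr_table:
        raise ValueError("direct-repeat reference table is empty")
    if n_repeats < 3:
        raise ValueError("an array needs at least 3 repeat copies")
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    truth: list[dict] = []
    for a in range(n_arrays):
        genus, dr = dr_table[int(rng.integers(0, len(dr_table)))]
        name = f"contig{a:03d}"
        left = _random_bases(rng, int(rng.integers(*flank)), 0.5)
        right = _random_bases(rng, int(rng.integers(*flank)), 0.5)
        for _attempt in range(100):
            spacer_rows = []
            for si in range(n_repeats - 1):
                plasmid = plasmids[int(rng.integers(0, len(plasmids)))]
                slen = int(rng.integers(30, 41))
                pos = int(rng.integers(0, len(plasmid)))
                strand = "+" if rng.random() < 0.5 else "-"
                spacer = plasmid.fetch(pos, slen)
                if strand == "-":
                    spacer = revcomp(spacer)
                emitted = spacer
                if spacer_mutations:
                    sl = list(emitted)
                    for q in rng.choice(slen, size=spacer_mutations, replace=False):
                        sl[q] = str(rng.choice([b for b in "ACGT" if b != sl[q]]))
                    emitted = "".join(sl)
                spacer_rows.append((emitted, plasmid.name, pos, strand))
            # Reject boundary-degenerate draws: when the bases adjacent to a
            # repeat edge coincide across all instances, the repeat/spacer
            # boundary is genuinely unidentifiable from the array alone and
            # truth would be ill-posed.  Check the two columns nearest each
            # edge.
            ok = True
            for col in (0, 1):
                firsts = {s[0][col] for s in spacer_rows} | {right[col]}
                lasts = {s[0][-1 - col] for s in spacer_rows} | {left[-1 - col]}
                if len(firsts) == 1 or len(lasts) == 1:
                    ok = False
            if ok:
                break
        parts = [left, dr]
        for si, (emitted, pname, pos, strand) in enumerate(spacer_rows):
            parts.extend([emitted, dr])
            truth.append(
                {
                    "contig": name,
                    "spacer_id": f"{name}.sp{si}",
                    "plasmid": pname,
                    "position": pos + 1,
                    "strand": strand,
                    "genus": genus,
                    "mutations": spacer_mutations,
                }
            )
        contigs[name] = "".join(parts + [right])
    return contigs, truth


# ---------------------------------------------------------------- fractions


def simulate_fractions(
    community: CommunitySpec, params: ReadSimParams
) -> tuple[dict[str, list[ReadPair]], dict[str, int]]:
    """One equal-size paired readset per brine fraction.

    Plasmid read counts per fraction are proportional to plasmid abundance
    times the fraction multiplier; the remainder of each readset comes from
    the background contigs.  Returns (fraction -> pairs, fraction ->
    plasmid-derived pair count).
    """
    rng = np.random.default_rng(params.seed)
    out: dict[str, list[ReadPair]] = {}
    plasmid_pairs: dict[str, int] = {}
    sources: list[tuple[str, CircularSequence]] = [("plasmid", p) for p, _ in community.plasmids]
    sources += [("background", c) for c in community.background]
    for fraction, mult in community.fraction_multipliers.items():
        weights = [a * mult for _, a in community.plasmids]
        weights += [
            community.background_abundance * len(c) / 1000 for c in community.background
        ]
        w = np.array(weights, dtype=float)
        if w.sum() <= 0:
            raise ValueError(f"fraction {fraction}: no positive source weights")
        w /= w.sum()
        pairs: list[ReadPair] = []
        n_plasmid = 0
        choices = rng.choice(len(sources), size=params.n_pairs, p=w)
        for i, src_i in enumerate(choices):
            kind, src = sources[src_i]
            L = len(src)
            insert = int(np.clip(rng.normal(params.insert_mean, params.insert_sd),
                                 params.read_length + 10, L - 1))
            if kind == "plasmid":
                start = int(rng.integers(0, L))
                n_plasmid += 1
            else:
                start = int(rng.integers(0, max(1, L - insert)))
            strand = "+" if rng.random() < 0.5 else "-"
            frag = src.fetch(start, insert)
            rid = f"{fraction}.{i:07d}.{src.name}"
            pairs.append(
                _pair_from_fragment(frag, strand, params.read_length, rng, params.error_rate, rid)
            )
        out[fraction] = pairs
        plasmid_pairs[fraction] = n_plasmid
    return out, plasmid_pairs
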