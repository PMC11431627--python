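"""Seed-and-extend reconstruction: seeds, extension, closure, rotation."""

import pytest

from plasmidloom.circular import CircularSequence, revcomp
from plasmidloom.reconstruct import (ClosureAmbiguityError, ReadPool,
                                     ReconstructionConfig, build_seed_contig,
                                     close_and_monomerize, extend_round,
                                     harvest_seed_reads, rotate_to_reference)
from plasmidloom.simulate import PlasmidSpec, ReadSimParams, simulate_paired_reads, simulate_plasmid
from tests.conftest import random_dna


def tiling_pairs(seq: str, read_len=150, step=10):
    """Error-free synthetic pairs tiling a linear sequence."""
    from plasmidloom.io import FastqRead

    pairs = []
    i = 0
    for start in range(0, len(seq) - 2 * read_len, step):
        r1 = seq[start : start + read_len]
        r2 = revcomp(seq[start + read_len : start + 2 * read_len])
        pairs.append((FastqRead(f"t{i:05d}/1", r1), FastqRead(f"t{i:05d}/2", r2)))
        i += 1
    return pairs


# ------------------------------------------------------------- harvest


def test_harvest_returns_target_gene_reads_and_mates(plasmid6k):
    plasmid, ann = plasmid6k
    pairs = simulate_paired_reads(plasmid, ReadSimParams(n_pairs=400, seed=13))
    harvested = harvest_seed_reads(pairs, [(plasmid, ann)], "F3")
    assert 0 < len(harvested) < len(pairs)
    f3 = next(a for a in ann if a.label == "F3")
    # every harvested pair has a mate overlapping F3 (ids encode fragment start)
    for r1, _ in harvested:
        start = int(r1.read_id.split(".")[-2])
        frag_end = start + 500  # generous insert bound
        assert f3.start < frag_end and start < f3.end + 500


def test_harvest_without_target_gene_errors(plasmid6k):
    plasmid, ann = plasmid6k
    with pytest.raises(ValueError, match="F9"):
        harvest_seed_reads([], [(plasmid, ann)], "F9")


def test_harvest_from_background_reads_is_empty(plasmid6k, rng):
    plasmid, ann = plasmid6k
    decoy = CircularSequence(random_dna(rng, 6000), "decoy")
    pairs = simulate_paired_reads(decoy, ReadSimParams(n_pairs=100, seed=14))
    assert harvest_seed_reads(pairs, [(plasmid, ann)], "F3") == []


# ------------------------------------------------------------- seed


def test_seed_contig_exact_in_zero_error_limit(rng):
    truth = random_dna(rng, 1000)
    pairs = tiling_pairs(truth, step=10)
    seed = build_seed_contig(pairs)
    # de novo assembly is strand-agnostic: either orientation is exact
    assert seed.sequence in truth or revcomp(seed.sequence) in truth
    assert len(seed.sequence) >= 400
    assert seed.coverage.min() >= 10


def test_seed_window_never_exceeds_1200(rng):
    truth = random_dna(rng, 3000)
    seed = build_seed_contig(tiling_pairs(truth, step=8))
    assert 400 <= len(seed.sequence) <= 1200


def test_seed_requires_enough_reads(rng):
    from plasmidloom.reconstruct import InsufficientCoverageError

    truth = random_dna(rng, 800)
    with pytest.raises(InsufficientCoverageError):
        build_seed_contig(tiling_pairs(truth, step=200))


def test_seed_consensus_suppresses_read_errors(rng):
    truth, _ = simulate_plasmid(PlasmidSpec(seed=31))
    pairs = simulate_paired_reads(
        truth, ReadSimParams(n_pairs=600, error_rate=0.01, seed=15)
    )
    # restrict to reads from one 1.5 kb region to mimic a harvested subset
    sub = [p for p in pairs if 1000 <= int(p[0].read_id.split(".")[-2]) <= 2200]
    seed = build_seed_contig(sub)
    # consensus identical to truth (either orientation)
    assert seed.sequence in truth.doubled or revcomp(seed.sequence) in truth.doubled


# ------------------------------------------------------------- extension


def test_extension_grows_both_termini(rng):
    truth = random_dna(rng, 4000)
    pairs = tiling_pairs(truth, step=12)
    contig = truth[1500:2500]
    pool = ReadPool(pairs)
    grown, log = extend_round(contig, pool)
    assert log["left"] > 0 and log["right"] > 0
    assert grown in truth  # extension bases equal the truth


def test_99nt_overlap_not_used_for_extension(rng):
    from plasmidloom.io import FastqRead
    from plasmidloom.reconstruct import _consensus_overhang, _right_overhangs

    truth = random_dna(rng, 600)
    contig = truth[:400]
    cfg = ReconstructionConfig()
    # three identical reads overlapping the terminus by 99 nt: below anchor
    reads99 = [FastqRead(f"a{i}", truth[301:451]) for i in range(3)]
    pool = ReadPool([(r, r) for r in reads99])
    assert _right_overhangs(contig, pool, cfg.min_anchor, cfg.mismatch_frac) == []
    # at exactly 100 nt the same reads qualify
    reads100 = [FastqRead(f"b{i}", truth[300:450]) for i in range(3)]
    pool = ReadPool([(r, r) for r in reads100])
    overhangs = _right_overhangs(contig, pool, cfg.min_anchor, cfg.mismatch_frac)
    assert overhangs and all(o == truth[400:450] for o in overhangs)
    assert _consensus_overhang(overhangs, 3) == truth[400:450]


def test_consensus_requires_support_and_halts_on_tie():
    from plasmidloom.reconstruct import _consensus_overhang

    assert _consensus_overhang(["AAA", "AAA", "AAA"], 3) == "AAA"
    assert _consensus_overhang(["AAA", "AAA"], 3) == ""
    # tie at the first column halts immediately
    assert _consensus_overhang(["AAAA", "AAAA", "CCCC", "CCCC"], 3) == ""
    # support decays along the overhang
    assert _consensus_overhang(["ACGT", "ACG", "AC"], 3) == "AC"


# ------------------------------------------------------------- closure


def test_constructed_closure_and_monomer_conservation(rng):
    s = random_dna(rng, 6000)
    contig = s + s[:150]
    result = close_and_monomerize(contig)
    assert result.closed
    assert result.terminal_repeat_len == 150
    assert result.monomer.seq == s
    # monomer conservation: pre-trim = monomer + monomer prefix
    assert result.contig == result.monomer.seq + result.monomer.seq[:150]


def test_no_terminal_repeat_not_closed(rng):
    result = close_and_monomerize(random_dna(rng, 3000))
    assert not result.closed and result.monomer is None


def test_internal_repeat_does_not_confuse_closure(rng):
    s = list(random_dna(rng, 6000))
    repeat = random_dna(rng, 120)
    s[2000:2120] = repeat
    s[4000:4120] = repeat  # internal 120 nt duplication away from termini
    s = "".join(s)
    contig = s + s[:150]
    result = close_and_monomerize(contig)
    assert result.closed and result.terminal_repeat_len == 150
    assert result.monomer.seq == s


def test_tandem_repeat_raises_ambiguity(rng):
    unit = random_dna(rng, 900)
    contig = unit * 3 + unit[:200]
    with pytest.raises(ClosureAmbiguityError):
        close_and_monomerize(contig)


# ------------------------------------------------------------- rotation


def test_rotation_recovers_reference_frame(rng):
    ref = CircularSequence(random_dna(rng, 5000), "ref")
    rotated = ref.rotate(1234)
    back = rotate_to_reference(rotated, ref)
    assert back.seq == ref.seq


def test_rotation_strand_invariant(rng):
    ref = CircularSequence(random_dna(rng, 5000), "ref")
    flipped = ref.rotate(777).reverse_complement()
    assert rotate_to_reference(flipped, ref).seq == ref.seq


def test_canonicalization_without_reference(rng):
    m = CircularSequence(random_dna(rng, 2000), "m")
    assert rotate_to_reference(m, None).seq == m.canonical().seq


# ------------------------------------------------------------- end-to-end


def test_low_coverage_reports_partial_not_closed():
    from plasmidloom.experiments import reconstruction_replicate

    outcome = reconstruction_replicate(seed=5, coverage=2.0)
    assert not outcome.closed


def test_rna_and_dna_seeds_converge_to_same_monomer(rng):
    """Two different seed windows of the same plasmid close to one circle."""
    truth, _ = simulate_plasmid(PlasmidSpec(seed=55))
    pairs = simulate_paired_reads(truth, ReadSimParams(n_pairs=1000, seed=16))
    pool = ReadPool(pairs)
    cfg = ReconstructionConfig()
    monomers = []
    for window_start in (500, 3200):  # DNA-derived vs transcript-like window
        contig = truth.fetch(window_start, 450)
        for _ in range(cfg.max_rounds):
            contig, growth = extend_round(contig, pool, cfg)
            if len(contig) >= 1000:
                res = close_and_monomerize(contig)
                if res.closed:
                    monomers.append(res.monomer.canonical().seq)
                    break
            if growth["left"] + growth["right"] == 0:
                break
    assert len(monomers) == 2
    assert monomers[0] == monomers[1] == truth.canonical().seq
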