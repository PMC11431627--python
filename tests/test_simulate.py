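"""Synthetic-data generator: invariants the downstream analysis relies on."""

import numpy as np
import pytest
from scipy import stats

from plasmidloom.circular import CircularSequence, revcomp
from plasmidloom.simulate import (CommunitySpec, PlasmidSpec, ReadSimParams,
                                  TranscriptomeSimParams, simulate_crispr_contigs,
                                  simulate_fractions, simulate_paired_reads,
                                  simulate_plasmid, simulate_rnaseq)


def brute_force_circular_count(seq: str, word: str) -> int:
    text = seq + seq[: len(word) - 1]
    return sum(1 for i in range(len(seq)) if text[i : i + len(word)] == word)


# ------------------------------------------------------------- plasmids


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_blacklisted_motifs_absent_circularly(seed):
    plasmid, _ = simulate_plasmid(PlasmidSpec(seed=seed))
    for motif in ("GGCC", "CTAG"):
        assert brute_force_circular_count(plasmid.seq, motif) == 0
        assert brute_force_circular_count(revcomp(plasmid.seq), motif) == 0


def test_length_and_gc_within_tolerance():
    spec = PlasmidSpec(length=6200, gc_target=0.50, seed=9)
    plasmid, _ = simulate_plasmid(spec)
    assert abs(len(plasmid) - 6200) <= 0.05 * 6200
    assert abs(plasmid.gc_fraction() - 0.50) <= 0.02


def test_same_seed_byte_identical_outputs(tmp_path):
    from plasmidloom.io import write_fasta, write_gff3

    for run in ("a", "b"):
        plasmid, ann = simulate_plasmid(PlasmidSpec(seed=77))
        write_fasta(tmp_path / f"{run}.fasta", [plasmid])
        write_gff3(tmp_path / f"{run}.gff3", plasmid, ann)
    assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()
    assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()


def test_variant_gene_plans():
    _, ann = simulate_plasmid(PlasmidSpec(seed=3, variant="no_F2"))
    labels = {a.label for a in ann}
    assert "F1" in labels and "F3" in labels
    assert not labels & {"F2", "F2a", "F2b", "F2c"}
    _, ann2 = simulate_plasmid(PlasmidSpec(seed=3, variant="F1b_F2a_F2c"))
    assert {"F1b", "F2a", "F2c", "F3"} <= {a.label for a in ann2}


def test_gene_plan_is_consistent(plasmid6k):
    plasmid, ann = plasmid6k
    by_label = {a.label: a for a in ann}
    # forward genes overlap at 4-base ATGA stop/start junctions
    for left, right in (("F1", "F2"), ("F2", "F3")):
        a, b = by_label[left], by_label[right]
        assert a.end - b.start == 4
        assert plasmid.seq[b.start : a.end] == "ATGA"
    # reverse genes do not overlap and keep configured spacing
    assert by_label["R5"].start - by_label["R6"].end == 2
    assert by_label["R4"].start - by_label["R5"].end == 25


def test_unsatisfiable_spec_fails_loudly():
    # extreme G+C cannot be reached once stop codons and blacklisted words
    # are excluded; the generator must fail, not silently under-deliver
    with pytest.raises((ValueError, RuntimeError)):
        simulate_plasmid(PlasmidSpec(gc_target=0.95, seed=0))


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        PlasmidSpec(length=2000)
    with pytest.raises(ValueError):
        PlasmidSpec(variant="bogus")
    with pytest.raises(ValueError):
        ReadSimParams(error_rate=0.2)
    with pytest.raises(ValueError):
        ReadSimParams(read_length=150, insert_mean=100)


# ------------------------------------------------------------- DNA reads


def test_error_free_reads_are_exact_wrapped_substrings(plasmid6k):
    plasmid, _ = plasmid6k
    pairs = simulate_paired_reads(plasmid, ReadSimParams(n_pairs=1000, seed=1))
    doubled = plasmid.doubled
    for r1, r2 in pairs:
        for r in (r1, r2):
            assert r.seq in doubled or revcomp(r.seq) in doubled


def test_mean_coverage_matches_arithmetic(plasmid6k):
    plasmid, _ = plasmid6k
    pairs = simulate_paired_reads(plasmid, ReadSimParams(n_pairs=2000, seed=2))
    depth = np.zeros(len(plasmid))
    doubled = plasmid.doubled
    for r1, r2 in pairs:
        for r in (r1, r2):
            s = r.seq if r.seq in doubled else revcomp(r.seq)
            i = doubled.find(s)
            pos = np.arange(i, i + len(s)) % len(plasmid)
            depth[pos] += 1
    expected = 2000 * 300 / len(plasmid)
    assert abs(depth.mean() - expected) <= 0.15 * expected


def test_some_pairs_span_the_origin(plasmid6k):
    plasmid, _ = plasmid6k
    pairs = simulate_paired_reads(plasmid, ReadSimParams(n_pairs=1000, seed=3))
    L = len(plasmid)
    spanning = 0
    for r1, _r2 in pairs:
        start = int(r1.read_id.split(".")[-2])
        # fragment covers the origin when start + insert wraps past L
        if start + 400 > L:  # conservative insert bound
            spanning += 1
    assert spanning >= 1


def test_coverage_uniform_on_circle_chi_square(plasmid6k):
    # uniformity is tested on fragment start positions (independent draws);
    # per-base coverage itself is block-correlated and would inflate chi2
    plasmid, _ = plasmid6k
    pairs = simulate_paired_reads(plasmid, ReadSimParams(n_pairs=5000, seed=4))
    L = len(plasmid)
    starts = np.array([int(r1.read_id.split(".")[-2]) for r1, _ in pairs])
    bins = np.bincount(starts * 100 // L, minlength=100)
    _chi2, p = stats.chisquare(bins)
    assert p > 0.001


def test_n_pairs_validation(plasmid6k):
    plasmid, _ = plasmid6k
    with pytest.raises(ValueError):
        simulate_paired_reads(plasmid, ReadSimParams(n_pairs=0))


# ------------------------------------------------------------- RNA reads


def test_rnaseq_zero_antisense_all_sense(plasmid6k):
    plasmid, ann = plasmid6k
    pairs, labels = simulate_rnaseq(
        plasmid, ann, TranscriptomeSimParams(antisense_fraction=0.0, n_pairs=500, seed=5)
    )
    assert set(labels) == {"sense"}


def test_rnaseq_antisense_proportion_within_binomial_ci(plasmid6k):
    plasmid, ann = plasmid6k
    n = 10000
    pairs, labels = simulate_rnaseq(
        plasmid, ann, TranscriptomeSimParams(antisense_fraction=0.2, n_pairs=n, seed=6)
    )
    share = labels.count("antisense") / n
    ci = 2.58 * np.sqrt(0.2 * 0.8 / n)  # 99% CI
    assert abs(share - 0.2) <= ci


def test_rnaseq_requires_annotations(plasmid6k):
    plasmid, _ = plasmid6k
    with pytest.raises(ValueError):
        simulate_rnaseq(plasmid, [], TranscriptomeSimParams(n_pairs=10))


# ------------------------------------------------------------- CRISPR contigs


def test_crispr_fencepost_four_repeats_three_spacers(plasmid6k):
    plasmid, _ = plasmid6k
    contigs, truth = simulate_crispr_contigs(
        [plasmid], [("Haloquadratum", "GTTTCAGACGAACCCTTGTAGGGTTGAAGC")], 1,
        seed=0, n_repeats=4,
    )
    assert len(truth) == 3
    (seq,) = contigs.values()
    assert seq.count("GTTTCAGACGAACCCTTGTAGGGTTGAAGC") == 4


def test_crispr_reverse_strand_spacer_recorded_on_minus(plasmid6k):
    plasmid, _ = plasmid6k
    contigs, truth = simulate_crispr_contigs(
        [plasmid], [("Halorubrum", "GTTTCAGACGAACCCTTGTAGGGTTGAAGC")], 8, seed=1
    )
    strands = {t["strand"] for t in truth}
    assert strands == {"+", "-"}
    for t in truth:
        spacer = plasmid.fetch(t["position"] - 1, 30)
        # emitted spacer appears in its contig on the recorded strand
        emitted = spacer if t["strand"] == "+" else revcomp(spacer)
        assert emitted[:25] in contigs[t["contig"]] or spacer[:25] in plasmid.doubled


def test_crispr_empty_dr_table_rejected(plasmid6k):
    plasmid, _ = plasmid6k
    with pytest.raises(ValueError):
        simulate_crispr_contigs([plasmid], [], 1)


# ------------------------------------------------------------- fractions


def test_fraction_totals_equal_and_zero_multiplier(plasmid6k):
    plasmid, _ = plasmid6k
    bg = CircularSequence("ACGT" * 500, "host0")
    community = CommunitySpec(
        plasmids=[(plasmid, 1.0)],
        background=[bg],
        fraction_multipliers={"a": 1.0, "b": 0.0},
    )
    readsets, plasmid_pairs = simulate_fractions(
        community, ReadSimParams(n_pairs=300, seed=7)
    )
    assert {len(v) for v in readsets.values()} == {300}
    assert plasmid_pairs["b"] == 0
    assert plasmid_pairs["a"] > 0


def test_community_validation():
    with pytest.raises(ValueError):
        CommunitySpec(plasmids=[(CircularSequence("ACGT" * 100), -1.0)])
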