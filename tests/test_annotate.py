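"""ORF calling, core-gene assignment, variant rules, structure and summary."""

import pytest
from Bio.Seq import Seq

from plasmidloom.annotate import (CORE_LABELS, CoreGeneRef, assign_core_genes,
                                  cis_report, classify_variant,
                                  consensus_at_threshold, find_orfs,
                                  module_structure_report, table_summary)
from plasmidloom.circular import CircularSequence, GeneAnnotation, revcomp
from plasmidloom.datasets import (core_gene_variant_table, presence_labels)
from tests.conftest import random_dna


def _translate(plasmid, ann):
    nt = plasmid.fetch(ann.start % len(plasmid), ann.end - ann.start)
    if ann.strand == "-":
        nt = revcomp(nt)
    return str(Seq(nt).translate()).rstrip("*")


def brute_force_orfs(seq: CircularSequence, min_aa, starts):
    """Independent ORF oracle: walk forward from every permitted start codon
    to the first in-frame stop, on both strands, wrapping the circle."""
    L = len(seq)
    found = {}
    for strand in "+-":
        s = seq.seq if strand == "+" else revcomp(seq.seq)
        for p in range(L):
            if (s + s)[p : p + 3] not in starts:
                continue
            q = p + 3
            while q < p + L:
                codon = (s + s)[q : q + 3]
                if codon in ("TAA", "TAG", "TGA"):
                    break
                q += 3
            else:
                continue
            if codon not in ("TAA", "TAG", "TGA"):
                continue
            length = q + 3 - p
            if length // 3 - 1 < min_aa:
                continue
            if strand == "+":
                start = p
            else:
                start = (L - (q + 3)) % L
            end_key = (start + length) % L or L
            key = (start % L, end_key, strand)
            # keep the longest ORF per stop (first permitted start)
            if key not in found or length > found[key]:
                found[key] = length
    # per stop-anchored segment keep only the longest ORF; the stop sits at
    # the interval end on the plus strand but at the interval start on minus
    best = {}
    for (start, end, strand), length in found.items():
        k = (end, strand) if strand == "+" else (start, strand)
        if k not in best or length > best[k][1]:
            best[k] = ((start, end, strand), length)
    return {v[0] for v in best.values()}


# ------------------------------------------------------------- ORFs


def test_constructed_300nt_orf():
    rng_seq = "ATG" + "GCT" * 98 + "TAA"  # 300 nt, 99 codons + stop
    seq = CircularSequence("TAATAA" + rng_seq + "TAATAA" + "C" * 88)
    orfs = [o for o in find_orfs(seq, min_aa=90) if o.strand == "+"]
    assert len(orfs) == 1
    assert len(orfs[0].protein) == 99
    assert orfs[0].protein == "M" + "A" * 98


def test_orf_spanning_origin_reported_once_wrapped(rng):
    gene = "ATG" + "GAA" * 60 + "TAG"
    filler = "TTAA" * 60
    linear = CircularSequence(filler + gene + filler)
    rotated = linear.rotate(len(filler) + 90)  # origin now inside the gene
    orfs = [o for o in find_orfs(rotated, min_aa=55) if o.strand == "+"]
    assert len(orfs) == 1
    (o,) = orfs
    assert o.end > len(rotated)  # wrapped interval
    assert o.protein == "M" + "E" * 60


def test_ctg_start_found_only_with_flag():
    gene = "CTG" + "GAC" * 50 + "TGA"
    seq = CircularSequence("TAGTAA" + gene + "TAATGA" + "ACCT" * 30)
    assert not [o for o in find_orfs(seq, min_aa=45) if o.strand == "+"]
    with_flag = [o for o in find_orfs(seq, min_aa=45, allow_ctg=True)
                 if o.strand == "+" and o.start_codon == "CTG"]
    assert len(with_flag) == 1


def test_orf_caller_agrees_with_brute_force(rng):
    starts = {"ATG", "GTG", "TTG"}
    for _ in range(5):
        seq = CircularSequence(random_dna(rng, 1500))
        got = {(o.start, o.end % len(seq) or len(seq), o.strand)
               for o in find_orfs(seq, min_aa=20)}
        expected = brute_force_orfs(seq, 20, starts)
        assert got == expected


# ------------------------------------------------------------- assignment


def test_core_genes_self_recovery(plasmid6k):
    plasmid, ann = plasmid6k
    refs = CoreGeneRef({a.label: [_translate(plasmid, a)] for a in ann})
    orfs = find_orfs(plasmid, min_aa=50)
    assigned = assign_core_genes(orfs, refs, seqid=plasmid.name)
    labels = {a.label for a in assigned}
    assert {a.label for a in ann} <= labels
    for a in assigned:
        if a.label in {x.label for x in ann}:
            assert float(a.attributes["identity"]) == 1.0


def test_f2_deleted_plasmid_lacks_f2_assignment(plasmid6k):
    from plasmidloom.simulate import PlasmidSpec, simulate_plasmid

    plasmid, ann = plasmid6k
    refs = CoreGeneRef({a.label: [_translate(plasmid, a)] for a in ann})
    no_f2, _ = simulate_plasmid(PlasmidSpec(seed=11, variant="no_F2"))
    assigned = assign_core_genes(find_orfs(no_f2, min_aa=50), refs, seqid="no_f2")
    labels = {a.label for a in assigned}
    assert "F2" not in labels
    assert {"F1", "F3"} <= labels


def test_distant_references_stay_unassigned(plasmid6k, rng):
    plasmid, ann = plasmid6k
    # references of scrambled composition: identity ~ background, below 0.35
    refs = CoreGeneRef({
        a.label: ["".join(rng.permutation(list(_translate(plasmid, a) * 1)))]
        for a in ann if a.strand == "+"
    })
    orfs = [o for o in find_orfs(plasmid, min_aa=50)]
    assigned = assign_core_genes(orfs, refs, seqid=plasmid.name)
    core = [a for a in assigned if a.label in CORE_LABELS]
    # scrambled references should rescue few to none of the core labels
    assert len(core) <= 2


# ------------------------------------------------------------- variants


def test_published_variant_table_classifies_exactly():
    table = core_gene_variant_table()
    normalize = {"canonical": "canonical", "no_F2": "no_F2",
                 "F2b/F2a": "F2b_F2a", "F1b/F2a/F2c": "F1b_F2a_F2c"}
    for _, row in table.iterrows():
        got = classify_variant(presence_labels(row)).value
        assert got == normalize[row["variant"]], row["plasmid"]


def test_variant_counts_match_published_groups():
    table = core_gene_variant_table()
    counts = table["variant"].value_counts().to_dict()
    assert counts == {"canonical": 12, "no_F2": 3, "F2b/F2a": 3, "F1b/F2a/F2c": 2}


def test_missing_f3_unclassified():
    assert classify_variant(["F1", "F2", "R4"]).value == "unclassified"


def test_variant_rule_precedence():
    assert classify_variant(["F1b", "F2a", "F2c", "F3"]).value == "F1b_F2a_F2c"
    assert classify_variant(["F1", "F2b", "F2a", "F3"]).value == "F2b_F2a"
    assert classify_variant(["F1", "F2", "F3"]).value == "canonical"
    assert classify_variant(["F1", "F3", "R4"]).value == "no_F2"
    assert classify_variant(["F1", "F2a", "F3"]).value == "unclassified"


# ------------------------------------------------------------- structure


def _mk(label, start, end, strand="+"):
    return GeneAnnotation("p", label, start, end, strand)


def test_atga_overlap_reported_as_4(rng):
    seq = CircularSequence(random_dna(rng, 2000))
    ann = [_mk("F1", 100, 400), _mk("F2", 396, 700)]
    rep = module_structure_report(ann, seq)
    assert rep["junctions"]["F1/F2"] == {"relation": "overlap", "value": 4}


def test_intergenic_distance_reported(rng):
    seq = CircularSequence(random_dna(rng, 2000))
    ann = [_mk("R6", 500, 800, "-"), _mk("R7", 300, 400, "-")]
    rep = module_structure_report(ann, seq)
    assert rep["junctions"]["R6/R7"] == {"relation": "intergenic", "value": 100}


def test_inserted_cds_flagged_between_core_genes(rng):
    seq = CircularSequence(random_dna(rng, 3000))
    ann = [_mk("R5", 1200, 1500, "-"), _mk("ins1", 800, 1100, "-"),
           _mk("R4", 300, 700, "-")]
    rep = module_structure_report(ann, seq)
    assert rep["insertions"] == [{"between": "R4/R5", "labels": ["ins1"]}]


# ------------------------------------------------------------- CIS


def test_cis_exact_match_and_offset(plasmid6k):
    plasmid, ann = plasmid6k
    cis = plasmid.fetch(len(plasmid) - 50, 30)  # string inside R4-F1 region
    rep = cis_report(plasmid, ann, {"CIS1": cis})
    (m,) = rep.matches
    assert m["match"] and m["identity"] == 1.0


def test_cis_heavily_mutated_no_match(plasmid6k, rng):
    plasmid, ann = plasmid6k
    cis = list(plasmid.fetch(len(plasmid) - 50, 30))
    for i in rng.choice(30, size=12, replace=False):  # 40% of positions
        cis[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[cis[i]]
    rep = cis_report(plasmid, ann, {"CIS1": "".join(cis)})
    assert rep.matches[0]["match"] is False


def test_cis_requires_annotated_genes(plasmid6k):
    plasmid, _ = plasmid6k
    with pytest.raises(ValueError):
        cis_report(plasmid, [], {"CIS1": "ACGT" * 8})


def test_consensus_degenerate_and_threshold():
    seqs = ["ACGTACGT"] * 17
    assert consensus_at_threshold(seqs) == "ACGTACGT"
    mixed = ["AAAA", "AAAA", "AAAC", "AAAG"]
    assert consensus_at_threshold(mixed, 0.75) == "AAAN"


# ------------------------------------------------------------- summary


def test_summary_of_published_sizes_and_gc():
    from plasmidloom.datasets import plasmid_summary_table

    df = plasmid_summary_table()
    stats = table_summary([{"size": r.size_bp, "gc": r.gc_percent}
                           for r in df.itertuples()])
    assert stats["n"] == 20
    assert stats["size_mean"] == 6002
    assert stats["gc_mean"] == 52.5
    assert stats["gc_median"] == 52.2
    assert stats["size_min"] == 5007 and stats["size_max"] == 7625


def test_summary_single_record_and_empty():
    s = table_summary([{"size": 6000, "gc": 52.0}])
    assert s["size_mean"] == s["size_median"] == 6000
    assert s["gc_mean"] == s["gc_median"] == 52.0
    with pytest.raises(ValueError):
        table_summary([])
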