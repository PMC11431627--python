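# plasmidloom

Recovery and characterization of small cryptic plasmids from hypersaline
metagenomes.

Haloarchaea such as *Haloquadratum walsbyi* — the square-celled archaeon
that dominates many salt lakes and saltern crystallizer ponds — often carry
~6 kb circular plasmids with a strictly conserved architecture: a forward
**replication module** (genes F1–F3, overlapping at stop/start codons, with
F3 encoding a pleolipovirus-like replicase) and a reverse **ATPase module**
(R4–R7), facing outward from a shared intergenic promoter region.  These
plasmids can be reconstructed directly from public metagenomic reads, and
their sequences interrogated for restriction-site avoidance, gene-content
variation, CRISPR targeting history, physical fractionation, and
transcription.

`plasmidloom` implements that complete analysis as a tested, reusable
library and CLI:

| stage | module | what it does |
| --- | --- | --- |
| read mapping | `plasmidloom.mapping` | shared deterministic mapper with three presets: *relaxed* (35% mismatches, ambiguity 5, gaps 2%/max 6), *stringent* (2%, ambiguity 2), *quant* (1%, unique, no gaps) |
| reconstruction | `plasmidloom.reconstruct` | seed-and-extend assembly: bait reads on a conserved gene (default F3), build a 400–1200 nt ≥10× seed window, extend both termini by consensus of reads (or mates) overlapping ≥100 nt, detect ring closure as an exact ≥100 nt terminal repeat, trim to the monomer, polish, rotate |
| word statistics | `plasmidloom.motifs` | circular k-mer counts and maximal-order Markov expectations, e.g. the second-order estimate `E(b1b2b3b4) = N(b1b2b3)·N(b2b3b4)/N(b2b3)`; classifies words as absent / under-represented (ratio < 0.70) / at expected level, with region-masked re-analysis |
| annotation | `plasmidloom.annotate` | circular ORF calling, core-gene assignment by protein alignment, variant grouping (canonical, no_F2, F2b/F2a, F1b/F2a/F2c), module-structure and conserved-intergenic-sequence reports, summary statistics |
| CRISPR | `plasmidloom.crispr` | repeat/spacer array detection (repeats 23–47 nt ×≥3, spacers 26–50 nt), exhaustive spacer matching on circular plasmids (≤2 mismatches), host-genus calls from direct repeats (≥90% identity over ≥90% length) |
| quantification | `plasmidloom.quantify` | equal-subsample fraction-abundance ratios and strand-specific (dUTP-style) sense/antisense transcription accounting after rRNA depletion |
| phylogenetics | `plasmidloom.compare` | global-alignment percent identity (rotation-aware for circles), p-distance neighbor-joining (Saitou–Nei / Studier–Keppler), column-resampling bootstrap, lossless Newick IO |
| synthetic data | `plasmidloom.simulate` | generators for plasmids (controlled %G+C, scrubbed GGCC/CTAG), paired reads on the circle, stranded RNA-seq with antisense, CRISPR-bearing host contigs with truth tables, and fractionated community readsets |

The packaged tables `plasmid_summary.tsv` and `core_gene_variants.tsv`
carry the published per-plasmid sizes, %G+C values and core-gene presence
vectors of the twenty known family members, so the summary statistics and
variant classification can be verified without any download.

## Worked example

Reconstruct a plasmid from synthetic reads using a diverged relative
(75% identity) as the bait reference — the same situation as recovering a
new family member from a metagenome:

```python
from plasmidloom import (PlasmidSpec, ReadSimParams, simulate_plasmid,
                         simulate_paired_reads, reconstruct, ReconstructionConfig,
                         motif_report, CircularSequence, GeneAnnotation)
from plasmidloom.experiments import mutate_sequence

truth, genes = simulate_plasmid(PlasmidSpec(length=6000, gc_target=0.525, seed=7))
reads = simulate_paired_reads(truth, ReadSimParams(n_pairs=1000, error_rate=0.005, seed=8))
reference = CircularSequence(mutate_sequence(truth.seq, 0.25, 9), "relative")
ref_genes = [GeneAnnotation("relative", g.label, g.start, g.end, g.strand) for g in genes]

result = reconstruct(reads, [(reference, ref_genes)], ReconstructionConfig(),
                     reference_for_rotation=reference)
print(f"closed: {result.closed} after {result.rounds} rounds; "
      f"monomer {len(result.monomer)} bp, terminal repeat {result.terminal_repeat_len} nt")
print("exact recovery:", result.monomer.canonical().seq == truth.canonical().seq)
for rep in motif_report(result.monomer, ["GGCC", "CTAG", "TTAA"]):
    print(f"{rep.motif}: observed {rep.observed}, {rep.classification}")
```

prints

```
closed: True after 4 rounds; monomer 6000 bp, terminal repeat 839 nt
exact recovery: True
GGCC: observed 0, absent
CTAG: observed 0, absent
TTAA: observed 17, expected_level
```

The 1000 read pairs give ~50× coverage; four extension rounds traverse the
circle, the termini repeat exactly over 839 nt (ring closure), and trimming
that duplication yields a monomer identical to the generating plasmid after
rotation/strand normalization.  The two blacklisted restriction words are
absent, as built into the generator, while the control word TTAA sits at
its Markov-expected frequency.

The same stages are available from the shell:

```
plasmidloom simulate plasmid --seed 7 --out demo
plasmidloom simulate reads --fasta demo.fasta --n-pairs 1000 --out demo_reads
plasmidloom motifs --fasta demo.fasta --out motifs.tsv
plasmidloom summarize            # published-table statistics
plasmidloom tree --fasta plasmids.fasta --bootstrap 1000 --seed 1
```

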