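# Methods

This note records the models, procedures, parameter choices and known
limitations behind each stage of the pipeline, in the package's own terms.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and circular sequences

All internal coordinates are 0-based half-open; user-facing reports
(GFF3, spacer positions) are 1-based inclusive.  Intervals on a circle may
wrap: `end > length` means positions are taken modulo the length.  Two
reconstructions of the same molecule are compared through the *canonical
form*: the lexicographically minimal rotation over both strands (Booth's
least-rotation algorithm), which is idempotent and strand-invariant.

## Read mapper

One deterministic mapper serves the whole pipeline, configured by three
named presets that correspond to the stages of plasmid recovery:

| preset | max mismatches | ambiguity | gaps | seed k |
| --- | --- | --- | --- | --- |
| relaxed | 35% of read | 5 | 2% of read, gap ≤ 6 | 9 |
| stringent | 2% | 2 | 2%, gap ≤ 6 | 21 |
| quant | 1% | 1 | none | 21 |

Placement search is exact-k-mer seeded.  When the mismatch budget is below
the number of disjoint k-blocks in the read, probes are placed on those
disjoint blocks: by pigeonhole at least one probe is then error-free, so no
placement within budget can be missed and the mapper is provably equivalent
to an exhaustive scan (a property the suite asserts against a brute-force
oracle).  Above that budget (the relaxed preset) probing is dense.  The
relaxed seed length is 9 because the preset must tolerate ~25–35%
divergence: the probability that a 150 nt read at 25% divergence contains
any clean k-mer run is ≈ exp(−n·0.75^k·0.25), which is only ~0.6 at k=13
but ~0.94 at k=9.

The mismatch budget is `ceil(frac × read length)`.  "Ambiguity" is the
number of tied best placements tolerated before the read is discarded.
Ties are broken by fewest mismatches, then reference order, leftmost
coordinate, then + strand, making output independent of read input order.
Gapped placements (banded edit-distance alignment, via edlib) are attempted
only when the gapless evaluation of a candidate diagonal exceeds budget.
Circular references are unrolled by one read length plus a maximum insert
so origin-spanning reads place correctly; placements are reported modulo
the reference length.  There is deliberately no FM-index machinery —
references are tens of kb and read sets at most millions.

## Reconstruction

The reconstructor mirrors manual read-extension assembly of circular
replicons:

1. **Harvest.** All reads are mapped at the relaxed preset to the known
   family members; reads (and their mates) whose placement overlaps the
   annotated target gene — default F3, the most conserved gene — are kept.
2. **Seed.** The harvested reads are assembled greedily under stringent
   parameters (overlap mismatches ≤ 2%): the read sitting in the
   k-mer-densest region seeds a contig that is tip-extended in both
   directions, then polished by column-majority consensus of a stringent
   re-mapping.  A window of 400–1200 nt maximizing minimum coverage is
   selected and must reach ≥ 10×; length ties go to the longer window.
3. **Extension rounds.** Each round, both termini grow by the majority
   consensus of read overhangs.  A pair qualifies when *either* member
   overlaps the terminus by ≥ 100 nt with ≤ 2% mismatches in the overlap;
   the member that extends beyond the terminus contributes its overhang,
   anchored by its own overlap (which may be as short as 30 nt when the
   mate provides the ≥ 100 nt anchor).  The mate route matters: with
   150 nt reads a direct-overlap-only rule confines extension to a 50 nt
   window of read starts per step, and a local trough in the (Poisson)
   read-start process then stalls both tips permanently.  A consensus
   column is accepted with support ≥ 3 and a unique majority; a tie halts
   that terminus for the round.  One round batches up to 8 such consensus
   steps per terminus, so a round advances each end by up to a few hundred
   nt — matching how interactive mapping rounds behave, where one round of
   re-mapping incorporates every read the previous extension exposed.
   Rounds stop at closure, after 3 zero-progress rounds, or at max_rounds
   (50).
4. **Closure and monomerization.** The circle is closed when the contig's
   suffix equals its prefix exactly over ≥ 100 nt (the longest such repeat
   is used).  Exact identity is required: a near-miss caused by a consensus
   error yields more extension rounds, never a chimeric closure.  If the
   candidate monomer itself still carries a ≥ 100 nt terminal repeat the
   situation is ambiguous (tandem repeat) and an error is raised with
   coordinates.  The monomer is the contig minus the duplicated suffix.
5. **Polish and rotate.** The monomer consensus is re-called from a full
   stringent circular re-mapping (column majority at final coverage, two
   passes).  This step is what guarantees that rare low-support consensus
   errors committed at extension time (columns decided with support 3) are
   corrected before the sequence is reported; without it a closed sequence
   could differ from the truth by isolated bases.  Finally the start base
   is set by locating the reference's first 200 nt on the doubled monomer
   (both strands); without a reference the canonical form is returned.

Failure modes are structured: insufficient harvest or coverage yields a
partial, unclosed result carrying the best contig and a log entry; every
round appends its per-terminus extension to the log.

## Word-avoidance statistics

Counting is circular by default (all L wrapped start positions; counts of
all words of length k sum to exactly L); linear mode serves contigs and
mask-excluded segments.  The expectation of a word under the maximal-order
Markov model is `N(prefix)·N(suffix)/N(core)` from the word's own sub-word
counts — for tetramers the second-order estimate, for 6-mers the order-4
analogue.  Classification: observed 0 → `absent`; ratio < 0.70 with
expectation ≥ 5 → `under_represented`; otherwise `expected_level`.  The
minimum-expectation guard exists because a ratio threshold alone misfires
on words too rare to assess: a 6-mer on a 6 kb circle has expectation
≈ 1.5, where a single occurrence already gives ratio ≈ 0.68.  Both
thresholds are arguments.  Masked re-analysis excises the given intervals
and analyses the remaining segments linearly, forming no artificial
junction words — used to ask whether a word is depleted outside an acquired
region.

## Annotation

The ORF caller scans both strands and all frames of the doubled sequence,
so origin-spanning ORFs are found once with a wrapped interval; per
stop-anchored frame segment the longest ORF with a permitted start (ATG,
GTG, TTG; CTG behind a flag) is reported.  Core-gene assignment aligns ORF
translations globally (BLOSUM62, 11/1 gaps, free end gaps) against
reference proteins; a label requires identity ≥ 0.35 over ≥ 0.5 of the
reference, at most one ORF keeps a label (runner-up flagged), and ties
between labels are flagged ambiguous rather than silently resolved.
Reference proteins are user-supplied or test-generated — the package ships
none, keeping it download-free.

Variant grouping is a pure function of the core-label presence vector,
applied in order: F1b∧F2a∧F2c → `F1b_F2a_F2c`; F2b∧F2a → `F2b_F2a`;
F2 → `canonical`; F1∧F3 with no F2-family gene → `no_F2`; anything else
(including missing F3, universal in the family) → `unclassified`.

The structure report gives signed junction relations (overlap length or
intergenic distance) for F1/F2, F2/F3, R4/R5, R5/R6, R6/R7, flags CDS
inserted between core genes, and tests R4 for a C-terminal
transmembrane-like segment (Kyte–Doolittle window of ≥ 18 residues with
mean hydropathy > 1.6 within the last 40 aa — a heuristic, not a topology
prediction).  The conserved-intergenic-sequence report extracts the R4–F1
region (which hosts the promoters of both outward-facing modules) and
scans it for profile motifs by infix alignment; a profile matches at
identity ≥ 0.75, the same threshold used for column consensus.

## CRISPR

Array detection is seeded by exact 8-mers recurring at array-compatible
periods (repeat 23–47 plus spacer 26–50 nt), expanded into a repeat window
by 75%-majority columns and trimmed back to unanimous boundary columns —
majority expansion tolerates a mutated repeat instance, unanimity trimming
restores exact boundaries on clean arrays, where a by-chance majority
column just outside the repeat is almost never unanimous.  Because a chance
extra occurrence of a seed k-mer can corrupt an anchor chain, the drafted
consensus is then re-located across the contig (≤ 2 mismatches) and the
array is rebuilt from the full occurrence set before validation (≥ 3
near-identical repeats, spacer lengths in range).  Spacer matching is an
exhaustive Hamming scan of each spacer and its reverse complement over the
origin-unrolled plasmid, reporting every position within 2 mismatches as a
1-based first matching base on the forward strand.  Host genus is called
from the repeat consensus by global alignment against a genus→repeat
reference table: identity ≥ 0.90 over a reference within 10% of the query
length; ties across genera are reported as no call.  The 0.90/0.90 rule is
a reproducible local stand-in for database searches, and both thresholds
are arguments.

## Quantification

Fraction abundance: an equal-size seeded subsample of pairs per fraction
is mapped (quant preset, circular) and mapped *reads* are counted;
proportions are counts relative to the reference fraction, with
presentation rounding to one decimal (two decimals below 0.1) alongside the
raw values.  Transcription: pairs are first depleted against an rRNA decoy,
the rest mapped with the quant preset; each mapped fragment (pair counted
once) is assigned a transcript strand by the library convention — default
`reverse` (dUTP-style, first read antisense to the transcript) — and
counted as sense or antisense per overlapping gene, alongside per-strand
coverage and the number of uncovered bases.

## Phylogenetics

Percent identity is a true global alignment (match +2, mismatch −3, gap
open 12, extend 1; end gaps penalized) with identity = matches / aligned
columns after trimming terminal overhang columns.  End gaps must be
penalized: with free end gaps the optimal "alignment" of unrelated
sequences is a one-column overlap with identity 1.  For circular
comparisons the second sequence is first rotated (and strand-flipped if
better) to start where the first starts, located by infix alignment of a
200 nt probe on the doubled sequence.

Neighbor joining is the canonical Saitou–Nei agglomeration with the
Studier–Keppler Q-criterion; on additive matrices it reproduces the
generating topology and path lengths exactly (asserted to 1e−9, and
cross-checked against an independent library implementation).  Distances
from sequences are p-distances (1 − identity), with Jukes–Cantor correction
available but off by default — the tree is descriptive, not a dated
phylogeny.  Negative branch estimates are clamped to zero and the node
annotated.  Bootstrap support resamples the columns of each induced
pairwise alignment with replacement, rebuilds the tree, and scores each
internal bipartition; supports attach to Newick as internal node labels,
and round-trips through Newick are lossless.  Multiple sequence alignment
is out of scope, so tree construction from sequences rests on pairwise
distances — a documented method deviation from alignment-based trees; the
two approaches agree on clearly separated clades, which is what the tests
assert.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis relies on:

* **Plasmids** — target length 5–8 kb (realized exactly), %G+C steered to
  the target within ±2 points by solving for the intergenic composition,
  forward genes overlapping at 4-base ATGA stop/start junctions, reverse
  genes at configurable intergenic spacings (defaults 25/2/100 nt for
  R4/R5, R5/R6, R6/R7), an R4 with a hydrophobic C-terminal stretch, and
  blacklisted words (default GGCC, CTAG) scrubbed to zero circular
  occurrences.  Scrubbing substitutes inside motif occurrences —
  synonymous codon swaps where possible, otherwise single-base changes that
  never create a stop or touch a start/stop codon — and fails loudly after
  10,000 attempts rather than under-delivering.  Gene sequences derive from
  a per-(seed, label) substream, so variants of the same seed share their
  common genes.
* **Reads** — uniform fragment starts on the circle (fragments wrap the
  origin), Gaussian insert (default 350 ± 40 nt), uniform substitution
  errors, constant Q37 qualities.  No indels, no quality-dependent error
  model, no adapter or trimming artifacts: quality trimming is treated as
  upstream.
* **RNA-seq** — two transcription units (forward module, reverse module),
  antisense reads at a set fraction from the opposite strand, rRNA decoy
  admixture, dUTP-style or forward library encoding.  Real operon
  structure, TSSs, and expression gradients are not modeled.
* **CRISPR contigs** — arrays of a genus repeat alternating with spacers
  copied from plasmid positions/strands (optionally mutated), with a truth
  table of 1-based positions.  Draws in which every spacer base adjacent
  to a repeat edge coincides across instances (two columns deep) are
  rejected and redrawn: there the repeat/spacer boundary is genuinely
  unidentifiable and a truth table would be ill-posed.
* **Fraction readsets** — equal pair totals per fraction; source drawn per
  pair with probability proportional to abundance × fraction multiplier
  (plasmids) or abundance × length (background).  Because totals are
  fixed, mapped-count ratios equal multiplier ratios only in the
  low-plasmid-share regime; the experiments keep the plasmid at a few
  percent of the community, where the saturation bias is ≤ ~3%.

Passing tests on these generators demonstrate correctness of the
*computations* under the stated statistical assumptions — uniform coverage,
substitution-only errors, single dominant haplotype.  They do not
demonstrate robustness to real-data phenomena such as coverage bias,
indels, chimeric reads, or co-circulating related strains; mapping
stringency (2%) is the only defense against the latter, as in the original
procedure.

## Experiment problem sizes

The headline experiments (in `plasmidloom.experiments`, shared by the test
suite and the acceptance script) use: 20 reconstruction replicates of a
6 kb plasmid at 50× coverage, 0.5% error, harvest reference at 75%
identity; 1000 random 6 kb sequences for motif-classifier specificity;
6 CRISPR arrays over 2 plasmids for recall; 60,000 pairs per fraction at a
~2% plasmid share for ratio recovery; 20,000 stranded pairs at 20%
antisense for transcription recovery.  These sizes give each estimate a
sampling error comfortably inside its assertion tolerance while keeping a
full run in the minutes range on one CPU.

## Known limitations

* The mapper reports one best placement per read; it does not emit
  multi-placements or mapping qualities.
* The reconstructor resolves a single consensus per run; co-circulating
  relatives above ~98% identity would be merged rather than separated.
* CRISPR detection is mismatch-only (no indels in repeats or spacers), as
  is spacer matching.
* The NJ bootstrap resamples pairwise-alignment columns independently per
  pair, which is the natural analogue under pairwise distances but not
  identical to resampling columns of one multiple alignment.
* `run_pipeline` chains the simulate → reconstruct → annotate → motifs
  stages for reproducible smoke runs; quantification and phylogenetics run
  through their own commands.
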