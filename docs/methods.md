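# Methods

This note documents the models, parameter choices and numerical details
behind `gonadmir`, and what the synthetic benchmark does and does not show.

## Study design being emulated

The pipeline reproduces a classic two-pool small-RNA contrast: all-female
(XX) and all-male (XY) gonad pools sequenced as one library each, compared
without biological replicates, combined with a per-sex mRNA expression table
(FPKM) to isolate miRNA–target pairs with opposite expression bias. Library
"a" is the female pool and "b" the male pool throughout.

## Hairpin folding and the stem-loop verdict

Structure prediction uses a weighted maximum-pairing dynamic program
(Nussinov-style): admissible nested structures score the sum of their pair
weights (G:C = 3, A:U = 2, G:U = 1) with a minimum hairpin loop of 3 nt,
solved in O(n³) and traced back to dot-bracket. The negated score is
reported as a stability surrogate ("fold energy", arbitrary units). The DP
is verified against exhaustive enumeration of all nested structures for
sequences ≤ 20 nt.

A maximum-pairing model carries no loop or bulge penalties, so *any* 100+ nt
sequence folds densely: random sequence typically reaches a paired fraction
near 0.8 and fragments into several terminal loops, and genuine hairpins
flanked by genomic context grow spurious micro-hairpins in the flanks. The
topology of the optimal structure therefore cannot by itself distinguish a
real precursor from background, and the acceptance verdict instead asks for
exactly one *substantive stem*: a local alignment of the sequence against
its own reverse complement (pair weights as above, mismatch −4, gap −8,
arms separated by ≥ 3 nt) must find exactly one disjoint helix scoring
≥ 32. The penalties were chosen from the score distributions of planted
hairpins (25 nt arms, ≤ 2 mismatches: scores ≥ 37) versus random 122 nt
sequence (scores ≤ 28 in 80 draws); 32 splits the gap. On top of the
single-stem requirement the verdict demands ≥ 18 base pairs and a paired
fraction ≥ 0.5 in the optimal structure. Measured operating point: 100/100
planted hairpins (with 30 nt flanks) accepted, 99/100 random 122 nt windows
rejected. All three thresholds are keyword arguments of `fold_hairpin`.

The stem alignment also supplies the terminal-loop span used by the novel
miRNA arm rule (a candidate tag must lie wholly within one arm).

## Homology search

A seeded, ungapped local aligner stands in for a nucleotide BLAST at desk
scale: exact 11-mer words, ±1/−2 scoring, X-drop 10, ungapped
Karlin–Altschul statistics (K = 0.711, λ = 1.37) with the database length
m·n taken as query length × total genome length, E-value cutoff 10⁻³, both
strands searched, overlapping hits merged keeping the best score. Because
hairpins are near-palindromic, a locus usually also scores on the wrong
strand; locus deduplication is therefore strand-agnostic and keeps the
better alignment (the true strand wins whenever the arms carry at least one
mismatch). Reciprocal best hits between candidates and the known database
assign orthologous names, stripping 3–4 letter species codes but never
family stems (mir/let/...).

## Small-RNA processing

* Adapter location: leftmost exact match of the adapter's first 10 nt, then
  a ≤ 1-mismatch match of that prefix, then the longest ≥ 6 nt
  suffix–prefix overlap at the read end. The one-mismatch fallback matters:
  with a 0.5 % per-base error rate, ~5 % of reads carry an error inside the
  adapter prefix and would otherwise be discarded.
* Quality filter: mean Phred ≥ 20 and no N (a concrete rendering of
  "remove low-quality reads").
* Length window 18–32 nt inclusive; tags collapsed exactly, sorted by
  sequence.
* Genome mapping reports *all* loci with Hamming distance ≤ 1 on either
  strand. Pigeonhole seeding on two exact halves guarantees completeness
  (any ≤ 1-mismatch occurrence contains one exact half); equivalence with a
  full Hamming scan is tested on 10 kb genomes.
* Known-mature matching: equal-length Hamming ≤ 1, or substring/superstring
  alignment with ≤ 2 nt terminal overhang (isomiR trimming) and ≤ 1
  mismatch; ties resolved by fewest mismatches then lexicographically
  smallest id. TPM uses the post-trim clean-read total of each library as
  denominator.

## Differential expression

With one pooled library per sex there are no replicates, so significance
comes from a two-sided Fisher's exact test on
[(count_a, clean_a − count_a), (count_b, clean_b − count_b)], computed
in-house in log space (hypergeometric point probabilities summed under the
minimum-likelihood rule with the conventional 1 + 10⁻⁷ tie tolerance) so
million-read margins cannot underflow. The caller requires
|log₂ ratio| ≥ 1 *and* p < 0.01. The 0.01-TPM pseudocount enters the ratio
only when one library has zero counts — it exists to keep exclusive ratios
finite, and applying it unconditionally would push an exact two-fold pair
just off the inclusive boundary. No multiple-testing correction is applied
to the calls (the design uses a raw p cutoff); Benjamini–Hochberg q-values
are reported as an extra column. Sex-exclusivity is count-based
(other library = 0) and flagged "high-confidence" above 15 reads.

## Target prediction and integration

Seed sites require perfect Watson–Crick complementarity to miRNA positions
2–7 and are classified canonically (8mer / 7mer-m8 / 7mer-A1 / 6mer, A1
meaning a genomic A opposite position 1). The duplex score walks ungapped
from the seed toward the miRNA 3' end (G:U allowed outside the seed) using
the same pair weights as the folder, plus the position-1 pair when present;
`delta_g` is the negated score and the default cutoff of 14 equals a pure
A:U seed plus position-8 match, so any planted perfect 8mer survives.

Gene bias: the undefined-bias carve-out (> 0.5 FPKM in one sex, exactly 0
in the other) is evaluated *before* the joint FPKM ≥ 0.5 filter, then a
2-fold ratio separates female-up / male-up from unbiased. The 2-fold value
is a declared default. Integration keeps only strict opposite-direction
pairs; sex-exclusive miRNAs participate as their sex's "up"; undefined-bias
genes count as "up" for their sex. The reduction factor is the mean number
of predicted target genes per sex-biased miRNA before vs after this filter;
on the synthetic panel (60 genes) it is ~3, far below published
genome-scale values (> 50-fold over ~20k gene models), because the ratio
scales with the size and bias composition of the gene panel.

## Synthetic data: what it emulates and what it does not

Defaults define the benchmark conditions: 4 × 50 kb chromosomes; 30
hairpins placed 0/12/8/10 per chromosome (one empty chromosome, mirroring
real chromosomal skew); hairpins are arm (27–36 nt) + loop (6–12 nt) +
reverse-complemented arm with 1–2 mismatches (a perfect palindrome would
make the locus strand unknowable); matures are 20–24 nt arm substrings.
Ten miRNAs are planted DE at fold 4 (alternating direction); per-miRNA
abundances are log-normal (σ = 0.6); each library is one multinomial draw
of 200,000 36 nt reads (insert + adapter, truncated) with ±1 nt 3'
trimming/extension variability (15 % each), uniform substitution errors at
0.005/base, and 5 % blacklist (ncRNA) reads. The known databases emulate a
related species: pre-miRNA backbones mutate at `divergence` (default 0.05)
while matures use a separate `mature_divergence` (default 0) — mature
miRNAs are far more conserved than precursor backbones, and a 5 % mature
divergence would make a 1-error read 2 mismatches from the database,
artificially capping the annotation rate. The mRNA panel has 60 genes with
500 nt UTRs: every DE miRNA gets one perfect 8mer site in a gene whose
FPKM bias (4-fold separation, log-normal jitter) opposes it; 6 genes sit
below the FPKM floor and 4 exercise the undefined-bias rule.

The generator does **not** model indels, quality-score decay, ligation or
PCR bias, multi-locus miRNA families, non-templated additions, isomiR
5'-end variation, or UTR sequence composition — so passing the end-to-end
benchmark shows the machinery is correct and complete under clean
assumptions, not that the thresholds are optimal for real libraries.
Blacklist ncRNAs are deliberately absent from the genome, so contaminant
reads exit via the unmapped route as well as the blacklist route.

Problem sizes (200 kb genome, 2 × 10⁵ reads, 60 genes) were chosen so a
full run finishes in well under a minute on one CPU while leaving every
recovery metric statistically stable across seeds.

## Numerical details and tie-breaks

* Folding traceback prefers the outermost co-optimal pairing (long-range
  nesting over fragmentation); co-optimal structures share the score, so
  reported pair counts are well-defined even where the structure is not.
* Percentages in the library report use decimal half-up rounding (1 decimal
  for genome-mapped, 2 for database-matched), matching how such tables are
  conventionally printed; zero clean reads yield "NA", never a division
  error.
* All simulator randomness flows from one integer seed through per-stage
  child generators (`np.random.default_rng([seed, stage])`); identical
  configurations give byte-identical output files.
* The χ² distribution test supports uniform and chromosome-length-weighted
  expectations (default length-weighted; the claim under test concerns
  genomic position, and chromosomes differ in size).

## Known limitations

Energies are weighted-pair surrogates, not nearest-neighbour
thermodynamics; the homology search is ungapped; multi-mapping tags count
fully toward each matched miRNA but once toward library totals; novel-miRNA
calls from multi-error reads at real loci are reported as such (they are
indistinguishable from lowly expressed variants without replicates).
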