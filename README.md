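# gonadmir

Integrated small-RNA / mRNA analysis of miRNA expression in early gonadal
sex differentiation: a desk-scale, fully testable re-implementation of the
classic two-library (XX vs XY gonad pool) study design used in teleost fish.

## What it does

Given a genome, known pre-miRNA / mature-miRNA databases, two small-RNA
sequencing libraries (one per sex), an ncRNA blacklist and a gene model with
3'UTRs plus per-sex FPKM values, the pipeline:

1. **Discovers conserved pre-miRNA genes** — seeded ungapped homology search
   (word size 11, match +1 / mismatch −2, X-drop 10; ungapped Karlin–Altschul
   E-values E = K·m·n·e^(−λS) with K = 0.711, λ = 1.37; cutoff 10⁻³),
   extends hits by ~30 bp of flanking sequence, validates stem-loop folding,
   assigns orthologous names by reciprocal best hit (species prefix
   stripped), and tests the chromosomal distribution with a χ² goodness of
   fit.
2. **Annotates the small-RNA libraries** — 3' adapter trimming, quality
   filtering, 18–32 nt length selection, collapsing to unique tags with
   per-library counts, genome mapping with ≤ 1 mismatch (pigeonhole-seeded,
   provably complete), ncRNA blacklist removal, matching to known matures
   (≤ 1 mismatch, ≤ 2 nt isomiR overhangs), and novel-precursor nomination
   by folding uniquely mapping leftover tags with 50 nt flanks.
3. **Calls sex-biased expression** — TPM = count / total clean reads × 10⁶;
   a miRNA is sex-biased when |log₂(TPM_XX / TPM_XY)| ≥ 1 and the two-sided
   Fisher's exact p < 0.01; sex-exclusive detection is tracked separately
   (flagged above 15 reads) and expression ratios are binned into the
   > 2 / mid / ≤ ½ classes.
4. **Predicts targets** — canonical seed sites (8mer, 7mer-m8, 7mer-A1,
   6mer) in 3'UTRs with a weighted-pair duplex score (G:C = 3, A:U = 2,
   G:U = 1) extended from the seed toward the miRNA 3' end; sites below a
   declared score threshold (default 14) are dropped.
5. **Integrates miRNA and mRNA expression** — genes are filtered at
   FPKM 0.5 (with the undefined-bias carve-out for genes > 0.5 in one sex
   and zero in the other), classified by a 2-fold rule, and a regulatory
   edge is emitted only when a sex-biased miRNA targets a gene biased toward
   the *opposite* sex. The network summary reports how many-fold this
   inverse-expression requirement shrinks the predicted target lists.

The hairpin folder is a weighted maximum-pairing (Nussinov-style) dynamic
program with dot-bracket traceback; the stem-loop verdict additionally
requires exactly one substantive helix, found by a gapped local alignment of
the candidate against its own reverse complement (see `docs/methods.md`).

A first-class **synthetic-data generator** (`gonadmir.simulate`) produces
every input with a machine-readable truth table — planted hairpins at
uneven chromosomal density, adapter-ligated reads with a planted fold-change
contrast and sequencing errors, ncRNA contamination, and 3'UTRs carrying
seed sites in oppositely biased genes — so the whole pipeline is testable
end-to-end without downloads.

## Worked example

```bash
gonadmir run --simulate --seed 1 --outdir demo
```

generates the default synthetic study (30 hairpins over 4 chromosomes with
one left empty, 10 DE miRNAs at fold 4, 2 × 10⁵ reads per library, 0.5 %
error) under `demo/data/`, runs every stage into `demo/results/`, and prints
the truth-vs-called comparison:

```
locus_recovery             1.000000
locus_named_recovery       1.000000
mature_read_annotation     0.993557
de_sensitivity             1.000000
de_fpr                     0.000000
edge_recovery              1.000000
same_direction_edges       0.000000
reduction_factor           3.260870
chrom_distribution_p       0.011371
```

All 30 planted loci are recovered and correctly named; 99.4 % of the reads
simulated from mature miRNAs end up annotated as known miRNAs (the rest
carry ≥ 2 sequencing errors); all 10 planted DE miRNAs are called with no
false positives among the 20 neutral ones; every planted inverse
miRNA–gene pair appears as an integrated edge, no edge pairs a miRNA and a
gene biased toward the same sex, and the empty chromosome makes the
chromosomal distribution test reject uniformity (p ≈ 0.011 < 0.05).

`demo/results/de_calls.tsv` holds the per-miRNA table, e.g.

```
mirna_id       count_a  count_b  tpm_a       tpm_b        log2_ratio  status  ratio_class
aaa-mir-1-3p   12906    2482     64623.3808  12428.6430    2.3784     a_up    gt2
aaa-mir-12-5p  10553    33322    52841.3558  166860.2904  -1.6589     b_up    le_half
```

and `demo/results/edges.tsv` the integrated network
(`aaa-mir-1-3p → gene_0001`, miRNA up in females, gene up in males, one
8mer site at ΔG −19).

Each stage is also exposed separately (`gonadmir simulate / discover /
annotate / de / targets / integrate`) and as plain library functions.

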