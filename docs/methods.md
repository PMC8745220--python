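# Methods

`varfunnel` implements a combined genomic–transcriptomic prioritization of
candidate disease variants. The motivating setting is a study of vascular
components in multiple sclerosis (MS): a transcriptome of the internal
jugular vein (IJV) wall in MS patients versus controls, whole-exome
sequencing (WES) of MS families with vertical transmission of disease, and
public population allele-frequency resources. The package implements each
analysis stage as a library module, chains them into a file-based pipeline,
and ships a synthetic-data generator that plants known signal at every
stage so the whole funnel is testable without access to patient data.

## The funnel

1. **Differential expression.** Per-gene two-sample comparison of log2
   expression between cases and controls; genes pass at fold change ≥ 2 and
   (adjusted) p ≤ 0.05, both boundaries inclusive.
2. **GWAS reference gene set.** From a GWAS-catalog export, SNPs listed
   under the trait of interest (exact, case-insensitive match) with
   association p ≤ 5×10⁻⁶ (inclusive) are selected; the reference set is the
   union of their mapped genes.
3. **Family transmission filter.** From a multi-sample VCF plus pedigree,
   variants showing vertical transmission of disease are retained (rule
   below).
4. **Gene-set restriction.** Transmitted variants are kept when their gene
   lies in the intersection of the GWAS set and the DE set (shared-gene
   arm), or in the configured list of functional-partner genes that are
   themselves differentially expressed (partner arm).
5. **Consequence annotation and prioritization.** Each variant is
   classified against its gene's transcript model. The shared-gene arm is
   restricted to low-frequency (MAF ≤ 0.04, inclusive) nonintronic
   variants; the partner arm to nonintronic variants only.
6. **Allele-frequency tests.** Each prioritized variant is compared between
   the affected cohort and each control population with a pooled
   two-proportion z-test, tiered against a Bonferroni family threshold.

## Statistics

**Moderated t-test.** For gene *g* with group sizes n₁, n₀, the pooled
variance s²_g has d_g = n₁+n₀−2 degrees of freedom. An empirical-Bayes
prior (d₀, s₀²) is fitted to all genes by moment matching on
e_g = log s²_g − ψ(d_g/2) + log(d_g/2): the excess of var(e_g) over the
mean trigamma term identifies d₀ through inversion of ψ′ (Newton iteration
on the trigamma function), and s₀² follows from mean(e_g). When the excess
is ≤ 0, d₀ = ∞ and the posterior variance is constant at s₀². The statistic

  t_g = (x̄₁ − x̄₀) / √( ŝ²_g (1/n₁ + 1/n₀) ),  ŝ²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)

is referred to a t distribution on d₀ + d_g degrees of freedom. With
shrinkage disabled this is exactly the ordinary pooled two-sample t-test
(verified to 1e−12 in the tests, and cross-checked against Bioconductor
limma's `eBayes`). Benjamini–Hochberg adjustment is delegated to
`statsmodels.stats.multitest` and cross-checked against the direct step-up
formula. Fold change is computed from group means on the log2 scale:
FC = 2^|x̄₁ − x̄₀|, reported as an absolute ratio with an up/down direction
(an exact tie is reported as "up" for determinism).

**Transmission rule.** The default model is dominant carrier logic: a
variant passes in a family when (i) every affected member carries at least
one alternate allele, and (ii) at least one affected parent–affected child
pair both carry. Unaffected carriers are tolerated by default (incomplete
penetrance); a flag excludes them. Missing genotypes fail the variant in
that family when the member is affected (conservative) and count as
non-carrier when unaffected; both policies are configurable. A variant
passes overall when it passes in ≥ 1 family (`min_families_passing`). The
underlying study never states its exact criterion, so every component of
the rule is exposed in configuration; the defaults are the package's own
choice, validated against an exhaustive enumeration oracle on 4-member
families.

**Consequence calling.** Transcript models carry strand, 1-based inclusive
exon intervals, genomic CDS bounds, and the spliced sequence in transcript
orientation. A single-nucleotide substitution is mapped into transcript
space (reverse-complemented on the minus strand), checked against the
model sequence (a reference mismatch is an error), and classified:
within-CDS codons are compared before/after the edit (synonymous /
missense / stop-gained under the standard nuclear code), positions
upstream of the CDS are 5′-UTR with c.−N numbering counted back from the
first CDS base, downstream positions 3′-UTR, non-exonic positions inside
the gene span intronic, and everything else intergenic. Splice-region
classes are deliberately not modelled — the analysis only needs the
intronic/nonintronic dichotomy. Codon-change strings use the compact
convention with the substituted base uppercased (`Ggt/Agt`), and protein
changes three-letter HGVS-style notation (`p.Gly482Ser`). The classifier
is validated against a brute-force oracle that rebuilds the genomic
sequence, re-splices, and fully retranslates the CDS before and after each
edit.

**Two-proportion z-test.** With allele counts x₁/n₁ and x₂/n₂ and pooled
p̂ = (x₁+x₂)/(n₁+n₂),

  z = (x₁/n₁ − x₂/n₂) / √( p̂(1−p̂)(1/n₁ + 1/n₂) ),  p = 2Φ(−|z|).

z² is identical to the Pearson chi-square statistic without continuity
correction (tested to 1e−10). When p̂ is 0 or 1 the test is degenerate and
reported as z = 0, p = 1 with a flag. Counts are required; when an input
table supplies only frequencies plus allele numbers, counts are
reconstructed by rounding with the residual logged.

**Significance tiers.** The family threshold is t = α/m with α = 0.05 and
m the number of *distinct variants* tested (the convention that yields the
0.002 threshold for a 25-variant family; m = variants × comparisons is
available by configuration). Tiers: significant p < t (strict), borderline
t ≤ p < 5t, nominal 5t ≤ p < 0.05, else not significant. The borderline
band multiplier 5 is a package choice — it reproduces the borderline
labels attached to p = 0.0093 and p = 0.0067 in the motivating study,
which never defines the band — and is configurable.

## Synthetic data

One integer seed drives independent sub-streams (expression, catalog,
transcripts, families, frequencies), so each generator is reproducible on
its own; regeneration from the same seed is byte-identical.

Default configuration, chosen to emulate the study design:

| parameter | default | meaning |
|---|---|---|
| genes × samples | 20,000 × (10+10) | log2 microarray-like matrix |
| planted DE genes | 923 | shifted by 1.5–3.2 log2 units in cases |
| gene-variance prior | d₀ = 10, s₀² = 0.04 | scaled inverse-chi-square |
| catalog | 805 qualifying SNPs / 543 genes | plus trait and p-value decoys |
| shared genes | 18 (16 coding, 2 ncRNA) | catalog ∩ planted-DE overlap |
| families | 3 families, 11 members, 7 affected | fixed pedigree template |
| shared-gene variants | 127 in 15 genes | 7 low-frequency nonintronic |
| partner variants | 57 in 7 genes | 39 intronic, 18 nonintronic |
| background variants | 950 | rejection-sampled to violate the rule |
| populations | affected 2,196 alleles; controls 214 and 68,000 | allele counts ~ Binomial |
| planted frequency effects | 3 + 5 variants, 2.6 log-odds | see below |

Planted co-segregating variants satisfy the transmission rule by
construction (all affected members of one randomly chosen family carry,
including a transmitting parent–child pair); background variants draw
founder genotypes from Hardy–Weinberg at MAF 0.05–0.40, transmit
Mendelian-style, and are rejection-sampled (cap 1,000 attempts, then an
error rather than silent leakage) until they violate the rule. Planted
low-frequency variants realize control frequencies ≤ 0.04 by construction
(truncated binomial draws), so the MAF filter sees its planted truth
exactly.

The planted frequency-difference effect (2.6 on the log-odds scale) was
sized with the closed-form power of the pooled z-test so that detection at
the 0.002 threshold is essentially certain even at the smallest
low-frequency baseline (0.002) against the large control population
(analytic |z| ≈ 7 at the worst case); at common baselines the effect is
far above threshold. Truth tables record every planted feature, so each
stage's recall and false-positive count can be scored exactly.

Two hand-crafted minus-strand transcript fixtures are always included:
one whose codon 482 is GGT with a genomic C>T at chr4:23,814,039 (calling
`Ggt/Agt`, `p.Gly482Ser`), and one with a C at transcript position −54
relative to the CDS with a genomic G>A at chr17:40,100,148 (calling
`c.-54C > T`, 5′-UTR). They pin the strand-aware arithmetic to two
published-style annotations.

**What the generator does not emulate:** linkage disequilibrium, sequencing
error, genotyping batch effects, population demography and relatedness
beyond the three nuclear families, multi-transcript genes, indels, and
probe-level microarray noise. Passing tests therefore demonstrate the
correctness and calibration of the *methods*, not performance on real
cohort data, where these factors matter.

## Numerical and design choices

- Coordinates are 1-based (VCF convention) throughout; internal intervals
  1-based inclusive.
- Multiallelic VCF sites are split into biallelic records (never dropped);
  half-calls (`./1`) and `./.` map to a single missing sentinel.
- Gene symbols match case-sensitively and exactly; no alias resolution.
  Catalog `mapped_genes` cells split on commas, semicolons and *spaced*
  hyphens (` - `), so hyphenated symbols like `NKX2-1` survive.
- The MAF filter thresholds the maximum frequency across the *control*
  populations by default (the study does not state which frequency it
  thresholded); the affected cohort is available by configuration.
- Trigamma inversion uses Newton iteration from the asymptotic start
  1/y + 1/2, with closed-form limits for extreme arguments; shrinkage
  fitting requires ≥ 10 genes with positive variance and errors when all
  variances are zero.
- Zero pooled variance without a prior follows the limit convention:
  p = 0 when the means differ, p = 1 otherwise, flagged as degenerate.
- The DE boundary cases (FC exactly 2, p exactly 0.05; catalog p exactly
  5×10⁻⁶; MAF exactly 0.04) are all inclusive; the significance tier
  boundary is exclusive (p exactly at α/m is borderline, not significant).
- Pipeline outputs are deterministic byte-for-byte given config + seed
  (no timestamps; JSON with sorted keys), and running the stage
  subcommands in order produces exactly the files of the monolithic run.

Problem sizes in the test suite and acceptance script (planted-recovery at
~1,100 variants, oracle identities at ≥ 1,000 random cases each, type-I
calibration at 10,000 replicates, shrinkage recovery at 5,000 genes, null
end-to-end at 20 seeds of the full 20,000-gene study) were chosen so each
property is measured at the scale its guarantee is stated for.

## Known limitations

- Single transcript per gene; the canonical-transcript choice is the
  input's burden. Indels and splice-region consequences are out of scope.
- The z-test uses the normal approximation without continuity correction;
  at very small allele counts an exact test would be preferable (the
  motivating analysis specifies the z-test).
- The published p-values of the motivating study cannot be reproduced
  from its printed summary statistics (control allele numbers are not
  published); the statistics here are validated against oracles and
  calibration instead.
- With `m` counted as distinct variants while testing against two control
  populations, the family-wise error is controlled per variant, not per
  test; the stricter variants×comparisons convention is available.
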