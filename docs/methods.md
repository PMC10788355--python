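# Methods

## The inference problem

A single full-sib family with balanced sexes (default 16 males, 16 females)
is genotyped at two kinds of reduced-representation markers: codominant SNP
loci and dominant presence/absence (PA) restriction fragments. If the
species carries a genetically determined but cytologically invisible sex
chromosome pair, a minority of loci should co-segregate with sex. The
package quantifies that signal per locus, aggregates it into a call of the
sex-determination system, and bounds how much of it chance alone would
produce.

## Conformity screen

For a hypothesised system the *heterogametic* sex is males (XY) or females
(ZW). The linked state is:

| marker | direction | heterogametic sex | homogametic sex |
|---|---|---|---|
| SNP | heterozygous-in-heterogametic | code 1 | code 0 or 2 |
| PA | present-in-heterogametic | code 1 | code 0 |
| PA | absent-in-heterogametic (optional) | code 0 | code 1 |

Conformity of a sex at a locus is the fraction of its **called** individuals
in the predicted state; missing calls never enter a denominator, and a locus
needs at least `min_calls_per_sex` (default 8 of 16 — half the sex) calls in
each sex to be screened at all. A locus is a candidate at threshold
*t* ∈ {70, 80, 90, 100} iff heterogametic conformity ≥ *t*/100 **and**
homogametic nonconformity ≤ (100 − *t*)/100. Both comparisons are evaluated
in integer arithmetic (100 × conforming-count vs *t* × called-count), so
boundary fractions like 12/16 at *t* = 75 never suffer float round-off.
Candidates at 100 % are classified sex-specific; 70–90 % sex-linked.
Nesting of candidate sets across thresholds follows directly and is
property-tested.

**PA direction policy.** By default PA loci are screened only in the
*present-in-heterogametic* direction. Two reasons. (i) Dominance: a
fragment on the homogametic chromosome remains visible in the heterogametic
sex through its retained copy, so a heterogametic-*absent* fragment has no
simple young-sex-chromosome interpretation. (ii) Identifiability: a fully
sex-divided fragment is mirror-symmetric — male-present/female-absent passes
the XY screen as PRESENT and the ZW screen as ABSENT — so screening both
directions under both systems makes PA markers useless for distinguishing
the systems (every XY PA candidate would re-appear as a ZW candidate).
`screen(..., include_absent=True)` restores the two-direction behaviour for
exploratory use.

**System call.** Both orientations are screened at all thresholds; the
system with the larger union of sex-linked-band (70–90 %) candidate loci is
called, with an explicit `inconclusive` outcome on ties or double zeros. In
a single family, segregating autosomes (any cross with a heterozygous
parent gives offspring heterozygosity ≈ 0.5) pass a 70 % criterion by
chance at roughly 0.04² ≈ 1.5 × 10⁻³ per locus and orientation, so both
orientations accumulate tens of chance candidates at study scale; the call
rests on the *excess* on one side, which is why it uses the band union
rather than any single threshold.

## Chance expectation

`spurious_linkage(n, L)` implements P = 0.5ⁿ — the probability that each of
*n* informative individuals independently lands in its sex-conforming state
— and the expectation L·0.5ⁿ over L loci. This describes the **100 %
(sex-specific) criterion only**; at relaxed thresholds the chance rate is
governed by binomial tails and is orders of magnitude larger (see above).
Tests and the acceptance script therefore hold the observed *sex-specific*
count (and the shuffled-sex control's) against 3× this expectation, and
treat relaxed-threshold chance candidates as an expected descriptive
feature, not a violation.

## Statistics

- **CATT**: χ² = N·r², r the Pearson correlation between genotype score and
  the sex indicator over the 2×k count table; df = 1. Scores (0, 1, 2) for
  SNP, (0, 1) for PA (the 2×2 trend test). Degenerate tables (no score
  variation or an empty row) return (0, 1) with a warning — a locus with no
  variation carries no trend information and must not abort a genome scan.
  The statistic is invariant under affine re-scoring and under simultaneous
  row swap with score reversal.
- **Pearson goodness-of-fit**: Σ(O−E)²/E with df = cells − 1 (the expected
  table is externally given; one constraint for the total).
- **PIC** = 2p(1−p) with p the alternate-allele frequency
  ((2·hom_alt + het)/2·called for SNPs, presence frequency for PA). This is
  the DArT-conventional index with maximum 0.5, not Botstein's three-term
  PIC.
- **Kruskal–Wallis**: scipy's tie-corrected H; the fully degenerate
  all-identical case is defined as (H = 0, p = 1).
- **Nemenyi post-hoc**: pairwise q = |R̄ᵢ − R̄ⱼ| / √(N(N+1)/12 · (1/nᵢ + 1/nⱼ))
  against the studentized range distribution (k groups, ∞ df) — the Tukey
  variant of R's PMCMR; no tie correction.
- Raw p-values are compared to 0.05 with no multiplicity correction by
  default, matching common practice in sex-marker screens where the
  candidate set is already conformity-filtered; Benjamini–Hochberg can be
  applied downstream by the user.

## Distances and ordination

Hamming distance between two individuals = differing co-called loci /
co-called loci (pairwise-complete missing-data policy). Dispersion of the
within-male / within-female / between-sex strata is reported both as SE and
SD over pairs; the headline "±" uses SE. PCoA is Gower double centering of
squared distances with an `eigh` eigendecomposition; negative eigenvalues
(non-Euclidean input) are reported by magnitude and their axes dropped, with
no Cailliez correction — for near-Euclidean genotype distances the
correction only rescales axes without changing the picture. The genotype
index matrix orders individuals females-then-males and keeps screen order
for loci, for direct heatmap rendering.

## Simulator

`simulate_family` emulates the study design end to end:

- **Autosomal loci**: per-locus allele frequency ~ Uniform(0.05, 0.95), two
  parents drawn from Hardy–Weinberg proportions, offspring by Mendelian
  segregation; PA loci scored dominantly (present iff ≥ 1 fragment allele).
  This reproduces the family-structured chance-candidate rate discussed
  above, which population-style i.i.d. genotypes would understate.
- **Linked loci**: marginal (no recombination map — the screen is
  per-locus): heterogametic individuals show the linked state with
  probability `penetrance` (default 0.9, a young, partially recombining
  sex-determining region), homogametic ones with `leakage` (default 0.05).
- **Missingness**: i.i.d. at `missing_rate` (default 0.05, consistent with
  a > 0.8 call-rate QC regime).
- **Metadata**: reproducibility, depth and balance sampled inside the QC
  acceptance region (U(0.96–1.0), U(6–40), U(0.92–1.0)); call rate is the
  realised non-missing fraction, so panels are internally consistent.
- Offspring sex counts are exact (16/16), matching balanced sampling rather
  than Bernoulli sexing; locus order is permuted so planted loci are
  interspersed; a single `numpy` Generator seeded from `seed` makes runs
  byte-identical.

`emulate_study_scale` pins the dimensions to 20,129 SNP + 17,025 PA loci ×
32 individuals with 63 planted male-linked loci (15 SNP / 48 PA) and runs in
about a second.

What the simulator does **not** model — and what passing tests therefore do
not demonstrate about real data: linkage disequilibrium among loci (each
locus segregates independently), locus-specific missingness or genotyping
error correlated with sex, allelic dropout of dominant markers, batch
effects, or a sequence-level mutational process (there are no real trimmed
sequences, so chromosome mapping is exercised on synthetic BLAST tables).

## Numerical and degenerate-input choices

- Screen comparisons in exact integer arithmetic; conformity of a
  zero-call sex is NaN and the locus is skipped with a log notice.
- QC uses strict `>` on all four thresholds, attributing each rejection to
  the first failing criterion in the fixed order reproducibility → depth →
  balance → call rate, so kept + per-criterion rejected partitions the
  input. The default reproducibility bound is 0.95 on the standard 0–1
  scale, with `reproducibility_scale` for 0–100-scaled inputs and any
  literal bound settable in config.
- BLAST best-hit tie-break: highest bit score, then lowest e-value, then
  first input occurrence — making the result row-order independent.
- Missing genotype tokens accepted on read: `-`, `NA`, empty; `-` written.
  The two-row SNP dialect collapses (ref, alt) score pairs
  (1,0)→0, (1,1)→1, (0,1)→2; a double-missing pair is missing; (0,0) or a
  half-missing pair is a format error naming locus and sample.

## Known limitations

- The system call is count-based; it does not attach a posterior or test
  statistic to "XY vs ZW" (the shuffled-sex control gives an empirical
  chance reference instead).
- PA markers cannot distinguish the systems on their own (mirror symmetry);
  the discriminating signal is SNP heterozygosity patterning plus the
  one-directional PA policy.
- Hamming/PCoA treat all loci equally; no weighting by information content.
- The spurious-linkage formula assumes independent individuals and a
  half-half conforming probability; within-family allele sharing makes it
  exact only at the 100 % criterion, as discussed.
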