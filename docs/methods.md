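# Methods

## SSR detection model

A microsatellite locus over a motif of length k (1–6 bp) is scored
`S = L − c·m`, where L is the locus length in bp, m the number of positions
deviating from the periodic expectation, and c the mismatch penalty. The
defaults — minimum score 15, penalty 5 — are the standard fixed-penalty
search settings for genome SSR surveys. Under them a reported locus shorter
than `min_score + penalty` = 20 bp can never contain a mismatch, because one
mismatch would cost 5 score points and push it below threshold; the test
suite asserts this property directly.

The search itself is seed-and-extend:

* **Seeds** are maximal perfect runs of period k containing at least 3
  tandem units and at least 8 bp. Non-primitive seed motifs (e.g. `ATAT`
  as a 4-mer) are skipped; the primitive period covers them.
* **Extension** walks outward under the phase fixed by the seed (+1 score
  per match, −(c−1) per mismatch), stopping at an N, at more than 3
  consecutive mismatching bases, or when the running score drops more than
  one penalty below its running maximum. The record is trimmed back to the
  earliest maximal-score position, so records always start and end on a
  match. At the default penalty the drift rule is the binding constraint:
  two consecutive mismatches cost 8 > 5 and terminate extension, and two
  mismatches on the same side of the seed must be at least four positions
  apart to survive.
* **Overlap resolution** across motif lengths keeps the highest score,
  breaking ties by shorter motif, then leftmost start — a deterministic
  total order.

Motif classes merge all cyclic rotations of a motif and of its reverse
complement; the class representative is the lexicographically smallest
member after reduction to the primitive period. This yields the standard
2/4/10/33/102/350 classes for k = 1..6.

The test suite checks the scanner against a brute-force oracle that
enumerates every (interval, motif, phase) candidate on sequences up to
200 bp, applies the same record-level rules, and resolves overlaps
identically; agreement is exact on random and planted sequences.

## Genome profile

Relative abundance = loci per Mb; relative density = Kb of SSR per Mb. The
genome length denominator is the raw assembly total including N runs, which
matches how published surveys normalize. Length tabulations use 3-bp bins
from 12 bp with an open 70+ bin; the perfect/imperfect and mean-mismatch
curves are restricted to 20–70 bp, the range where imperfect loci can exist
under the default scan parameters and where counts are dense enough to be
interpretable.

## Candidate filtering

Rules are evaluated independently (no short-circuiting) so the audit lists
every violated rule, and each is re-checkable from the stored context:

* motif length ∈ {3, 4} — di-nucleotides stutter under PCR;
* more than seven complete repeat units (≥ 8 units);
* zero mismatches;
* a primer pair exists: windows of 18–24 bp from the 300-bp flanks with
  nearest-neighbour Tm in 58–62 °C and pair ΔTm < 4 °C, ranked by
  `|len − 20| + |Tm − 60|` summed over both primers;
* both primer 3′ ends more than 10 bp from the repeat;
* the amplicon contains exactly one SSR, no secondary tandem repeat of ≥ 4
  units (motif 2–6 bp), and no homopolymer ≥ 8 bp. "Secondary repeat" and
  "homopolymer" thresholds operationalize the informal notion of
  nanosatellites contaminating an amplicon; mononucleotide runs are judged
  only by the homopolymer rule so that the two rules do not double-count.

Tm is computed with Biopython's nearest-neighbour model (SantaLucia
parameters, 50 mM monovalent salt, 0.25 µM primer) and is fixed
package-wide; the filter's semantics do not depend on which consistent NN
table is used, only on it being held constant.

The target interval used by the clean-amplicon rule is the scanner's own
call on the amplicon (which may be a base or two wider than the planted
coordinates at junctions), preventing spurious "secondary repeat" hits from
the target's own edges.

## Population-genetic estimators

* **He**: Nei's unbiased estimator `(2n/(2n−1))(1 − Σ p_i²)` from 2n genes.
* **Allelic richness**: rarefaction to g genes,
  `AR = Σ_a [1 − C(2n − c_a, g)/C(2n, g)]`; g defaults to twice the
  smallest per-population complete sample at the locus.
* **HWE**: the exact conditional test with probability ordering — the
  p-value is the total probability, given allele counts, of genotype arrays
  no more probable than the observed one. The array space is enumerated
  when small (counted in closed form for 2–3 alleles; for ≥ 4 alleles
  enumeration is attempted only for spaces up to 2·10⁴ arrays, since larger
  multi-allelic spaces are counted slowly and virtually always end up far
  beyond any enumeration budget); otherwise the null is sampled by randomly
  re-pairing the observed genes, vectorized in batches, with 10⁵ seeded
  draws by default and the add-one p-value estimator.
* **LD**: log-likelihood-ratio G on the genotype×genotype contingency
  table, null by permuting one locus across individuals (10⁴ permutations
  by default, seeded); fewer than 5 complete individuals → flagged NaN.
* **F-statistics**: Weir & Cockerham (1984) variance components, summed
  over alleles and loci; θ = Σa/Σ(a+b+c), f = 1 − Σc/Σ(b+c).
* **Null alleles**: EM under the model where a visible homozygote ii arises
  with probability p_i² + 2p_i r and whole-locus missing individuals are
  null homozygotes (r²). Convergence at |Δr| < 10⁻⁶, cap 10⁴ iterations;
  the observed-data log-likelihood is asserted non-decreasing at every
  step, and non-convergence raises an error carrying the last iterate. When
  the data are all homozygotes the estimate saturates and is flagged.
* **Multiple testing**: Holm's step-down ("sequential Bonferroni"), applied
  per family (HWE over locus×population pairs; LD over locus pairs within
  populations).

Missing data are handled by pairwise-complete deletion per statistic; no
imputation anywhere.

## Panels

* **SNI detection**: a locus is flagged when its allele sizes are not all
  congruent modulo the motif length — one off-ladder (+1 bp) allele
  suffices. The test is invariant under shifting all sizes by a constant.
* **MP**: non-SNI loci ranked by allele number; the top k = 8 with every
  locus tied at the cut included (the bundled reference table exercises
  exactly this: a four-way tie at Na = 11 fills ranks 5–8).
* **SS**: amplified in the whole cohort, no SNI, unambiguous peaks, and not
  HWE-deviant *in every* population after correction. The every-population
  reading (rather than any-population) is what reproduces the reference
  table's SS membership: one SS locus there deviates in a single
  population, and only dual-population deviants are excluded. Peak
  ambiguity cannot be computed from allele calls; it is a metadata flag.
* **Assignment**: leave-one-out likelihood assignment — per-population
  allele frequencies recomputed excluding the focal individual, zero
  frequencies smoothed to 1/(2n+1), multilocus HWE log-likelihood,
  Q = normalized likelihoods. An individual is correctly assigned when the
  maximum-Q population is its true one and Q ≥ 0.60. This replaces Bayesian
  MCMC clustering: the correctness criterion only needs per-individual
  membership probabilities, which the leave-one-out likelihood provides
  deterministically and in milliseconds.
* **Mann–Whitney**: W is reported as the U statistic of the first sample
  (the R `wilcox.test` convention); exact when both samples are ≤ 12 with
  no ties, normal-approximate otherwise. Agreement with full enumeration is
  tested for all shapes with m+n ≤ 10.
* **PCA**: covariance PCA of individuals on 0/1/2 allele-count indicator
  columns, missing filled with column means, component signs fixed by
  forcing the largest-magnitude loading positive.

## Synthetic data: what it does and does not emulate

The genome generator plants repeats with exact coordinates and mismatch
counts in background DNA rejection-sampled to contain no detectable SSR,
with ≥ 50 bp spacing; after assembly it re-scans and rebuilds if junction
bases created an unplanned locus or shifted a planted boundary by a full
motif unit. Truth tables are therefore exactly recoverable, which is what
makes 100% recall/precision a meaningful scanner check. Real genomes differ:
repeats cluster, backgrounds are repetitive, and boundaries are fuzzy — so
passing these tests validates the algorithmic contract, not field
performance on any particular assembly.

The genotype generator draws ancestral frequencies Dirichlet(1,…,1) over
4–17 alleles on a motif-length ladder (offset 150 bp by default, so the
off-ladder SNI arithmetic is exercised on realistic fragment sizes),
differentiates populations by Balding–Nichols at a target F_ST (chosen over
coalescent simulation for its closed-form target), and samples diploids
under HWE. Null alleles hide one copy (apparent homozygote) or two
(missing); technical missingness is applied afterwards so the truth table
distinguishes the two causes. Defaults (23 + 24 individuals, 30 loci,
tri/tetra motifs) mirror a two-site marker-validation cohort. Not emulated:
stepwise mutation dynamics, allele-size constraints over generations,
linkage.

## Problem sizes used in checks

The automated checks run at deliberately desk-friendly sizes chosen as the
smallest that leave the assertions statistically meaningful: oracle
equivalence on sequences up to 200 bp; planted-recall genomes of 2×5–6 kb;
HWE type-I error over 1,000 simulated equilibrium loci of 25 individuals;
θ recovery at 20 loci × (50+50) individuals against a 0.10 target (accepted
band ±0.04, dominated by across-locus Balding–Nichols variance); null-EM
recovery at 200 individuals with r = 0.2 (band ±0.08); LD null calibration
over 150 independent pairs at 2,000 permutations (the operational default
stays at 10⁴).

## Known limitations

* The scanner's seed/extension constants reproduce the fixed-penalty score
  semantics but are not bit-compatible with any particular legacy SSR
  search binary; genome-wide totals on real assemblies will differ from
  surveys run with other tools' internals.
* The candidate filter's counts on a real genome depend on the primer
  windows the Tm model admits; it is a reproducible stand-in for a full
  primer-design stack, not a replica of one.
* The HWE Monte Carlo is plain re-pairing, not an MCMC chain; for highly
  multi-allelic loci with tiny counts the add-one estimator is conservative.
* Assignment assumes HWE and linkage equilibrium within populations, as
  likelihood assignment always does; strong deviations bias Q.
* GENEPOP support covers the common dialect (title, locus list, `Pop`
  blocks, 2/3-digit diploid codes); haploid and multi-file variants are out
  of scope.
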