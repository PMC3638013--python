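# Methods

This note documents the models, statistics and numerical choices behind
`cescan`, and what the simulation-based tests do and do not demonstrate.

## Compositional models and their symmetry

A two-locus compositional model is a 3×3 table of binary risk levels over
the joint genotypes, rows = first SNP, columns = second SNP, genotype order
AA, Aa, aa (codes 0/1/2 internally, displayed 1/2/3 in documentation
tables). The label of a table is the decimal value of its row-major 9-bit
string, so the dominant model (000/011/011) is 27 and the recessive model
(high risk only for the double minor homozygote) is 1.

Two tables describe the same pattern when related by: reversing the row
order (relabelling which allele of SNP 1 is minor), reversing the column
order, transposing (swapping the two SNPs' roles), or complementing the
risk levels. These generators produce a group of order 16. `cescan` does
not *assume* the class count: `enumerate_classes()` applies the full group
to every label and merges orbits, and the test suite re-derives the
partition with an independent brute-force union over all 512 tables. The
result is 51 classes whose canonical (minimum) labels include 1, 2, 27, 78
and 170, consistent with the published class names. The count of 51 is
reproduced only when the constant class {0, 511} is included; it is
enumerated but excluded from per-pair testing because its risk table has an
empty column, making the χ² undefined (the zero-margin convention below
would force it to 0 anyway).

Orbit sizes divide 16; they sum to 512.

## The per-pair test

For SNPs p, q the data are the 3×3×2 counts n<sub>ijk</sub>. A model's
risk partition collapses them to a 2×2 table (a, b; c, d) — controls/cases
split into low/high risk — scored by the Pearson statistic
(ad − bc)²·n / [(a+b)(c+d)(a+c)(b+d)] on 1 df, with no continuity
correction.

Numerical conventions:

- **Zero margin** (empty row or column of the 2×2): statistic 0 and a
  degenerate flag. Independence is not assessable; returning 0 can only
  lose power, never create a false positive.
- **Per-class statistic = max over the orbit.** An asymmetric count table
  collapses differently under different members of one class; taking the
  class maximum makes the reported statistic invariant under swapping SNP
  roles or relabelling alleles, so results do not depend on column order in
  the input file. Complementary members give identical statistics (the 2×2
  column swap leaves the statistic unchanged), so at most 8 distinct
  collapses matter per class. Whether the original method evaluated one
  representative or the orbit maximum is not documented; the invariant
  choice is made here and affects at most which member of a class is
  reported.
- **Missing genotypes**: a subject missing at either SNP of a pair is
  dropped from that pair only (pairwise deletion), preserving per-pair
  sample size maximally.

## Screening: the sorted-split bound

Sort the 9 cells of a pair by case proportion t/(s+t); empty cells sort
first (sentinel key −1) and ties keep row-major cell order, making the
permutation deterministic. For the two-class problem, the optimal binary
grouping of a categorical predictor is one of the M−1 contiguous splits of
this sorted order; with fixed case/control margins the 2×2 χ² is a fixed
positive multiple of the Gini impurity gain, so the maximum of the χ² over
the 8 contiguous splits equals its maximum over all 2⁹ − 2 binary
groupings. Every model collapse is such a grouping, hence

    model statistic  ≤  max-split statistic        (for every model, always)

and screening at τ removes no pair whose best model statistic reaches τ.
Both facts are property-tested against a brute-force oracle that evaluates
all 510 partitions on 1000+ random tables, including tables with empty
cells (whose placement in the sort provably cannot change any split's
value, since they contribute zero counts).

The default τ = 20 corresponds to an unadjusted p of 7.744 × 10⁻⁶ —
deliberately liberal relative to genome-wide Bonferroni thresholds, so
screening is lossless in practice as well as in theory. The screened and
exhaustive scans are verified to produce identical significant sets on
simulated data whenever τ does not exceed the reporting threshold on the
χ² scale.

Counting uses per-SNP bit-planes: six packed bitmasks per SNP (3 genotypes
× 2 phenotype classes), combined pairwise by AND + popcount, 8 subjects
per byte. This CPU bit-parallel path is contract-tested to agree exactly
with the naive per-subject tally, including missing data (a missing call
falls outside all three genotype planes).

## Multiplicity: why pairs × models

The testing stage reports, per pair, the best statistic over the 50
non-degenerate classes. Because the classes jointly cover every binary
collapse, this maximum equals the global max-partition statistic, whose
null tail was measured at ~50× the nominal 1-df tail (200 000 simulated
null pairs at n = 1000; the factor is ~38 at p = 10⁻³ and plateaus near 51
by p = 10⁻⁴). A Bonferroni correction by pairs alone therefore inflates
the family-wise error rate to near 1 regardless of L. The default
correction is pairs × models, L(L−1)/2 × 50, which matches the measured
inflation and holds the empirical FWER at its nominal level (verified on
100 null datasets in the acceptance suite);
`ScanConfig(models_correction=False)` restores the pairs-only convention
for sensitivity analyses. For head-to-head power comparisons the per-pair
p-value is instead the best statistic's 1-df tail × 8 (the number of free
sorted splits searched), exposed as `comparison_p_value`.

The optional single-locus prefilter (`single_locus_prefilter_p`, default
off) removes SNPs with individually significant 3×2 χ² tests before
pairing, the usual companion of the df-8 full-association test; the
Bonferroni L counts SNPs after this prefilter, i.e. the SNPs actually
entering the pairwise stage.

## Comparison statistics

Indicator (dummy) coding with two levels per SNP is used throughout the
logistic models — the only coding consistent with 4 interaction and 8
total degrees of freedom (a literal numeric product of genotype codes
would give a single interaction parameter). The saturated model's
log-likelihood has the closed form Σ n<sub>ijk</sub> log(n<sub>ijk</sub> /
n<sub>ij·</sub>) with 0·log 0 ≡ 0; the main-effects model (intercept + 2
indicators per SNP) is fitted by damped Newton/IRLS on the 9 weighted
covariate patterns — cost independent of sample size — starting at the
intercept-only optimum with step halving, log-likelihood tolerance 10⁻⁸,
at most 50 iterations. Separation is flagged (`converged=False`), never
raised; the attained likelihood is still sandwiched in [L₀, L_F]. The
telescoping identity 2(L_F − L₀) = 2(L_F − L_M) + 2(L_M − L₀) and
agreement with a statsmodels GLM oracle are tested to 10⁻⁶.

## Simulator

Four built-in odds-table shapes generate penetrances via
p = ODD/(1 + ODD); model 1 is multiplicative within its epistatic block
(odds α(1+θ)^k), model 2 a threshold/interference shape, model 3 diagonal,
model 4 a checkerboard. Given a target prevalence and heritability the
solver runs nested Brent root-finding: for fixed θ the prevalence is
strictly monotone in α (inner solve, bracket [10⁻¹², ∞) by expansion); the
resulting heritability is monotone in θ for all four shapes (outer solve).
Tolerances 10⁻¹⁴/10⁻¹² on the root scale; the round trip reproduces the
targets to 10⁻⁸. An unattainable heritability raises with the attainable
supremum. The printed reference point — model 1, MAF 0.1, p(D) = 0.1,
h² = 0.03 → α ≈ 0.0999, θ ≈ 3.448 — is recomputed in the acceptance
script.

Case-control ascertainment draws joint genotypes from the HWE product
distribution, assigns disease by penetrance, and retains subjects until
the case and control quotas fill (rejection sampling; a direct
conditional-sampling fast path is provided and tested for distributional
equivalence). Cases converge to the conditional law p(G)p(D|G)/p(D),
verified by a multinomial check at n = 10⁵. Unassociated SNPs are HWE
draws at MAFs uniform on [0.05, 0.5], independent of phenotype. Both
causal loci share the stated MAF by default (a per-locus override exists).
"Balanced design" is interpreted as equal case and control counts.

What the generator does *not* emulate: linkage disequilibrium between
SNPs, genotyping error, missingness (inputs may still contain missing
codes), population structure, or covariates. Passing power/type-I tests
therefore demonstrate the statistical machinery under idealized sampling,
not robustness to real-data artefacts.

The variance decomposition used to characterize models splits the centred
penetrance into two marginal deviations plus an interaction residual —
orthogonal under locus independence — so h²_total = h²_marginal +
h²_interaction exactly; it requires (and checks for) a rank-one joint
genotype distribution. The formula behind the published variance figures
is not printed anywhere, so this standard ANOVA decomposition is a
reconstruction. Note that the checkerboard class M170 (not the class
called "XOR" in some published discussions, M78) is the pattern whose
marginal component vanishes exactly at MAF 0.5.

## Experiment scales

The built-in experiment drivers default to the published study design
(1000 SNPs, 800/1600 balanced samples, 100 replicates; null calibration
2000 SNPs × 2000 samples). The shipped acceptance suite runs them at
reduced scale as the package's own test design — type-I calibration on
100 null datasets of 200 SNPs × 1000 subjects (exact binomial acceptance
band around FWER ≤ 0.05), and power ordering with 20 replicates at
n ∈ {800, 1600} — sizes at which the qualitative claims (compositional ≥
interaction at low MAF; power monotone in n; FWER at nominal level) are
stable across seeds while the whole suite stays fast. Exact published
power curves are figure-derived and are not asserted numerically.

## Known limitations

- Binary phenotypes only; no covariate adjustment; no permutation or FDR
  alternatives to Bonferroni.
- The scan is single-process; the bit-parallel counting path is the CPU
  analogue of the original GPU design, not a distributed implementation.
- The constant model class is untestable by construction; pairs whose
  every collapse is degenerate (e.g. an all-missing SNP) report statistic
  0 rather than an error.
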