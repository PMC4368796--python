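# Methods

This note records the statistical procedures, the numerical rules at their
edges, the design choices that were genuinely open, and what the synthetic
cohorts do and do not establish.

## Data model and conventions

Genotypes are biallelic SNP dosages counting the **observed minor allele**
(ties at frequency 0.5 broken lexicographically and noted in the variant
metadata); missing genotypes are NaN throughout. Coordinates are 1-based
MAP-file positions; alleles are taken as given on the forward strand.
Pedigrees follow FAM conventions (missing parent code `0`); an individual
with both parents missing is a founder. Individual ids must be unique
across the whole dataset (stricter than the per-family requirement of the
file format) so phenotype joins are unambiguous. BMI must be strictly
positive; the analysed trait is ln(BMI), which brings the right-skewed BMI
distribution close to normal and makes per-allele effects multiplicative
on the original scale.

## SNP quality control

A SNP passes when **all** of: missing rate < 0.05, exact Hardy–Weinberg
p > 1e-4, MAF > 0.01. All three inequalities are strict, so a variant
sitting exactly on a threshold is excluded. The HWE test is the
conditional exact test: with the allele counts fixed, every heterozygote
count of the same parity is enumerated, and the p-value is the sum of the
probabilities of configurations no more probable than the observed one
(two-sided minimum-likelihood rule; computed in log space, with a 1e-12
relative tolerance when comparing probabilities so ties are not lost to
rounding). The exact test was chosen over the chi-square approximation
because candidate-region panels are small enough that exactness is free;
by default it uses all genotyped individuals, relatives included — a
founders-only option exists for users who want independence at the cost of
sample size. QC runs before phasing, so only clean SNPs enter the phaser.

## Parental-origin phasing

Phasing is a deterministic single-marker **Mendelian constraint solver**.
Per family and variant, each individual carries the set of ordered
(paternal, maternal) allele pairs compatible with its genotype (four pairs
when the genotype is missing); the transmission constraint — a child's
paternal allele must be one of the father's two alleles, symmetrically for
the mother — is applied in synchronous sweeps, pruning in both directions,
until a fixpoint. The pruning is monotone, so the fixpoint is unique and
the result is independent of processing order. Cells whose domain resolves
to a single value on both components are emitted with a provenance tag
(homozygote / trio-forced for first-sweep deductions / propagated for
multi-generation chains); everything else is **unresolved** and stays
missing downstream. The solver is sound by construction — it never guesses
— which the tests verify against the simulator's stored transmission truth
(zero disagreements over 500 seeded families).

Consequences worth knowing:

* A fully heterozygous parent–offspring trio is unresolvable at a single
  marker by any method that uses only Mendelian logic: a heterozygous
  parent transmits either allele with probability ½ regardless of
  grandparental phase. Such sites are the main source of unresolved cells
  (expected rate ≈ P(het)³ per fully-heterozygous trio configuration).
* Genuinely multi-generational deductions do occur: grandparents can pin a
  missing parental genotype, and a child's resolved allele can feed back
  into its parent's own phase when the parent's other allele is pinned
  from above.
* Founders have no recorded parents, so origin labels are undefined for
  them; they are emitted only at homozygous sites, where the labelling is
  vacuous. The per-SNP **unphased rate** is therefore computed over
  non-founders, and the parental-mode regressions use non-founders only
  (including founders would add rows with paternal ≡ maternal allele).
* Mendelian-inconsistent family/variant combinations abstain: the whole
  family is left unresolved at that variant and the event is logged —
  robustness to genotyping error rather than a hard failure.

This solver is a stand-in for haplotype-library long-range phasing. It
produces the same kind of output (origin-labelled alleles with
missingness) and is exact wherever it resolves, but it uses no linkage
information across markers, so it abstains more often than a
population-scale phaser would. SNPs with unphased rate **≥ 0.30**
(inclusive) are excluded before association testing; pre-phased input can
be supplied as a `|`-separated-GT VCF, bypassing the solver.

## Association tests and effect comparison

All three modes are ordinary least squares with intercept on ln(BMI),
adjusted for age (years), sex (indicator, female = 1) and T2D status
(indicator), complete-case per SNP so n varies by SNP. Modes differ only
in the predictor: dosage 0–2 (standard), paternal allele 0/1, maternal
allele 0/1. A predictor that is constant after missing-data removal, or a
sample smaller than the parameter count, raises an error rather than
returning a degenerate fit. 95% CIs are beta ± 1.959964·se. Relatedness is
deliberately **not** modelled (no kinship mixed model): this matches the
single-marker OLS analysis the design emulates and is listed as a known
limitation — within-family residual correlation makes nominal SEs slightly
optimistic in extended pedigrees.

Some diploid-only tools encode a parental 0/1 allele by doubling it to
0/2; that halves the slope and SE and leaves t and p unchanged. Results
here are on the natural per-allele scale, and the report also emits the
doubled-coding slope for comparability.

The paternal-vs-maternal comparison uses
`t = (b_pat − b_mat)/√(se_pat² + se_mat²)` referred to the standard
normal; a degrees-of-freedom override switches to a t reference (at
cohort sizes of several hundred the difference is negligible). The two
estimates come from the same individuals, so the independence assumption
behind the denominator is approximate; the type-I error simulation in the
acceptance suite shows it holds at the nominal level in practice (the two
predictors are uncorrelated transmissions). `compare_betas` on fitted
results requires both estimates to be oriented to the same effect allele
and errors otherwise. A separate entry point,
`compare_reported_estimates`, reconstructs the comparison from published
betas and 95% CIs: SEs are recovered as (high − low)/(2·1.959964) after
normalising bound order, and the printed betas are taken **at face
value — each on its own reported effect allele**, because that is how the
published comparison behaves (re-orienting both estimates to a shared
allele changes the answer when the two parental analyses report different
alleles; the face-value route reproduces the published significance
calls). Bonferroni correction is alpha/(m·k) for m SNPs and k = 3 tests.

## Parental asymmetry test

For a designated allele (default: the major allele; the p-value is
invariant to the choice, the counts swap), each trio with a heterozygous
affected offspring is classified by the transmitting parent. The parent
assignments are forced exactly when not both parents are heterozygous;
both-parents-heterozygous trios are excluded as ambiguous (the
transmitting parent is undefined there — the standard treatment), and
Mendelian-impossible configurations are excluded and logged. All offspring
are assumed affected unless an `affected` column says otherwise, matching
an affected-ascertained design. The p-value is the exact two-sided
binomial probability at null ½: twice the smaller tail CDF, capped at 1.
The doubling rule was fixed for determinism; at the study's count sizes it
agrees with the minimum-likelihood two-sided rule to two decimals (tested
against scipy's independent implementation). Being a discrete exact test
its p-values are **super-uniform** under the null: the rejection rate at
0.05 is slightly below 0.05 (≈ 0.038 at ~66 informative trios), and the
p-value distribution has visible atoms — the calibration tests assert the
rejection-rate band and super-uniformity, which are the properties that
matter for validity.

## Linkage disequilibrium

r² = D²/(pA·pa·pB·pb) with D = pAB − pA·pB, counted directly over
haplotypes (one paternal, one maternal per individual) with both sites
resolved — phase is known, so no EM over double heterozygotes is needed,
and unresolved cells are dropped pairwise. A variant monomorphic among the
jointly resolved haplotypes makes r² undefined; such pairs are flagged and
reported as missing, never as 0.

## Synthetic cohorts

The generator emulates the statistical structure the methods consume, not
the biology of any real population:

* **Pedigrees/genotypes**: founder allele pairs iid Bernoulli(MAF)
  (Hardy–Weinberg), descendants gene-dropped one uniform allele per
  parent, truth recorded before missingness. Defaults: 141 families,
  three-generation shape, 22 SNPs at MAF 0.3, 1.3% genotype missingness
  (98.7% call rate). SNPs are independent (no LD) by default; a two-locus
  phased-haplotype generator with a target r² exercises the LD module.
* **Trait**: ln(BMI) = 3.25 + b_pat·X_pat + b_mat·X_mat + 0.003·age −
  0.02·sex + 0.06·T2D + N(0, 0.15). The intercept puts median BMI near 26
  kg/m²; the residual sd 0.15 matches a coefficient of variation of ~15%
  for adult BMI; covariate effects are small but nonzero so the adjustment
  is exercised. Ages are drawn per generation (≈68/47/22 y) so the age
  covariate has realistic structure.
* **Trios**: parents at Hardy–Weinberg, child gene-dropped, offspring
  affected with probability baseline·rr_pat^X_pat·rr_mat^X_mat capped at
  1 (multiplicative risk chosen for a closed-form expected transmission
  asymmetry); only affected-offspring trios are retained, drawn in
  vectorised rejection batches with a hard candidate budget. Defaults: 705
  trios, MAF 0.3, baseline risk 0.05.

One integer seed drives everything; sub-streams are spawned
deterministically per stage, so identical seeds give byte-identical
outputs (the pipeline writes no timestamps, enabling golden-file tests).

What passing tests on these cohorts show: the estimators recover the
generating parameters under the model's own assumptions (independent
transmissions, Gaussian residuals on the log scale, missingness completely
at random, no LD, no population structure). What they do not show:
robustness to genotyping error beyond abstention, to informative
missingness, to assortative mating or stratification, or to
cross-marker haplotype structure — real-data features the generator
deliberately omits.

One subtlety the synthetic runs expose: conditioning on *resolved phase*
selects genotype configurations (homozygous children are always resolved,
and for them X_pat = X_mat), which induces correlation between the
paternal and maternal predictors in the resolved subsample. With a
single-parent effect this leaks a little signal into the other parent's
regression (visible in the worked example's maternal row); it does not
bias the affected parent's estimate when the other effect is zero, and it
is a property of any analysis restricted to phase-resolved sites.

## Problem sizes used in the validation suite

Simulation-based checks run at: n = 5000 individuals for effect
recovery/dilution; 500 families for phasing soundness; 2000 replicates of
200 trios for PAT null calibration; 2000 replicates of n = 300 for the
effect-comparison type-I error; 2000 replicates of n = 200 for HWE-test
calibration. These sizes give Monte-Carlo error comfortably inside the
asserted tolerance bands while keeping the suite quick on one core.
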