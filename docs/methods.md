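# Methods

This note records the statistical models, the synthetic-data generator,
the numerical conventions, and the design decisions behind `onsetmod`.

## The generative model behind the synthetic cohorts

`syndata.simulate_cohort` emulates a multiplex-family sampling frame:
nuclear families with two (or more) siblings affected by the disorder,
both parents available for genotyping, and a separate unrelated
community-control pool.

**Genotypes.** Each marker has a minor-allele frequency drawn uniformly
from `maf_range` (default 0.05–0.5). Founder haplotypes are Bernoulli
draws at that frequency; offspring receive one uniformly chosen allele
from each parent (gene dropping), so Mendelian consistency holds by
construction and is asserted in tests. Markers are unlinked; the only
LD in the package is the explicitly constructed candidate-fixture
clique (three near-copies of one marker within 300 bp). With `fst > 0`
the two subpopulations get Balding–Nichols Beta-distributed frequencies
around the ancestral value, which is what drives the MDS-stratification
and ancestry-outlier machinery. After simulation every marker is
re-oriented to its *realized* pooled minor allele — exactly what a
PED/MAP or VCF reader would compute — so write→read round trips are
lossless and group-wise MAF columns are comparable.

**Age at onset.** For affected sibling *i* in family *f*:

    AAO_i = mu + sum_j beta_j * g_ij + u_f + e_i,   AAO >= 7

with baseline `mu = 23.7` years, family random effect
`u_f ~ N(0, 4^2)` and residual `e_i ~ N(0, 7^2)`. The default planted
modifier shifts onset by −4 years per minor allele at MAF 0.3. The
variance split between family and residual is a modelling choice (the
total SD, including the genetic term, lands near 9 years); the family
term is what makes ranking families by mean sibling AAO meaningful.
Current age is AAO plus an illness duration ~ Uniform(5, 20) years,
which reproduces the strong age–AAO correlation seen in chronic-illness
cohorts (r ≈ 0.5) without fitting anything.

**Affection.** Siblings are affected by ascertainment, not by a
liability model: the design conditions on families with ≥ 2 affected
children, so modelling penetrance would add parameters without changing
any statistic computed here. A susceptibility locus can optionally be
planted by biasing transmission from heterozygous parents to (affected)
offspring with probability GRR/(1+GRR) — the minimal mechanism that
makes the family-based test non-null while leaving everything else
untouched. Modifier loci shift AAO only; they are exactly null for
transmission and for case-control frequency, which is the contrast the
end-to-end tests verify.

**What the generator does not capture.** No linkage or LD structure, no
X chromosome, no genotyping-batch or plate effects, no assortative
mating, no parental phenotypes driving ascertainment, and missingness
is completely at random. Passing tests therefore demonstrate the
*statistical machinery* under the stated model, not robustness to the
messier failure modes of real array data.

## Extreme-group selection

Families are ranked by the mean AAO of their affected siblings; the
`n_extreme` families at each tail become the `earliest`/`latest`
groups and the next `n_middle` per side become `earlier`/`later`
(defaults 95 and 66, giving the 190-proband screening set and a
four-group gradient). One proband per family is the affected sib whose
AAO conforms to the family's side — minimum AAO on the early side,
maximum on the late side — and remaining affected sibs are co-siblings.
Ties in family means break by family id, and sibling ties by individual
id, so selection is deterministic and invariant to input order.

## Quality control

Sample checks run in a fixed order, and a sample failing several is
reported under the first: call rate (> 0.98), then KING-robust kinship
(φ̂ > 0.354 flags duplicate-range pairs; the lower-call-rate member is
dropped — the realistic tie-break, since a re-plated duplicate is
usually the dirtier copy), then ancestry outliers. Outliers are flagged
leave-one-out: a sample whose coordinate on any of the k = 4 MDS
components lies more than 5 SD from the mean of the *other* samples is
removed; leaving the sample out keeps a gross outlier from masking
itself, and a zero-SD (degenerate) component flags nothing. Marker
filters apply call rate → MAF → exact HWE in that order with strict
comparisons (a marker at MAF exactly 0.05 is removed). HWE should be
computed on one member per family (the probands); relatedness distorts
the conditional null.

The exact HWE test sums the probabilities of all heterozygote counts no
more probable than the observed one, conditional on the allele counts;
it is computed in log space with a 1 + 1e−12 comparison guard and
matches an exact-rational enumeration oracle to 1e−12 across a broad
grid. IBS distance is 1 − shared-alleles/(2M) over pairwise-complete
markers (equivalently half the mean absolute dosage difference), and
MDS is plain Torgerson scaling with a sign convention (largest-magnitude
loading positive) for reproducibility. λ is the median association
χ²₁ over its null median 0.4549.

At desk scale the defect fixture uses 10,000 markers: the planted
Fst = 0.1 outliers separate on the leading MDS component with
leave-one-out z ≈ 6–8 there, comfortably over the threshold, while at a
few thousand markers the signal drowns in sampling noise — a useful
reminder that stratification screening is marker-hungry.

## Association and candidates

The per-marker logistic fit is IRLS with convergence when the score
norm falls below 1e−8 (max 50 iterations); complete or quasi-complete
separation is detected by a diverging coefficient (|β| > 15) and
reported as non-converged with missing p-values rather than a huge
spurious OR. The earliest group is coded 1, so OR > 1 means the minor
allele pushes toward earlier onset; every downstream statistic shares
this orientation (the ordinal outcome is coded with earliest highest
for the same reason). MDS components enter as covariates when their
between-group Welch t-test has p < 0.05; with none significant the scan
runs unadjusted and says so.

Permutation p-values refit the model under permuted labels and compare
the Wald |z| of the dosage term. Small samples are enumerated
exhaustively (exact p); otherwise the add-one estimator
(1 + #{perm ≥ obs})/(1 + B) is used with adaptive early stopping after
10 exceedances, which caps the cost of unremarkable markers without
biasing small p-values.

LD collapsing is greedy by ascending p: a candidate is absorbed by an
already-retained marker when dosage r² > 0.8 within 500 kb on the same
chromosome, and records its sink so candidate bookkeeping is conserved
(suggestive = retained + collapsed). On clique-structured LD this
equals the connected-component/min-p oracle and is independent of input
order.

**Design power.** For the two-group design the power routine solves the
baseline penetrance from the early-onset prevalence under HWE genotype
frequencies and heterozygote/homozygote relative risks, derives the
group-wise genotype multinomials by Bayes, and evaluates the 1-df
additive trend test with its null-variance critical region and
alternative-variance non-centrality. This matches direct Monte-Carlo
simulation of the test within ±0.01. The significance level defaults
to 0.05 and is explicit, since power at unstated α is not a
well-defined quantity.

## Confirmation

Sibling replication uses unadjusted logistic fits (the sibling groups
inherit their family's label) with a Bonferroni verdict at 0.05/m; for
m = 14 candidates that is 0.003571…, printed as 0.0036. The four-group
trend is a proportional-odds cumulative-logit model (statsmodels
`OrderedModel`); with two outcome levels it reproduces the binary
logistic coefficient to 1e−4 or better, and the proportional-odds
assumption is deliberately not tested — one trend OR per marker is the
reporting contract, and a partial-odds fallback would change the
estimand.

The GRS is Σ ln(OR_j)·g_j with weights frozen from the learning scan;
applying a profile never refits. Missing genotypes impute at the
learning-set mean dosage 2·MAF, keeping scores comparable across
missingness patterns, and an all-major-homozygote sample scores exactly
0. Scores are reported raw (unstandardized); standardization would not
change any rank-based or linear-trend p-value. Group comparisons use
Mann-Whitney U with midranks, tie-corrected variance and continuity
correction, switching to exhaustive enumeration when the pooled sample
is ≤ 12 (the in-house enumeration accepts ties, which scipy's exact
path does not); the four-group trend is OLS of score on group rank 1–4
(latest → earliest, so a positive slope means higher genetic loading
with earlier onset). Descriptive contrasts use two-sided Fisher exact
tests for sex and Welch (unequal-variance) t-tests for age and AAO.

Because weights are learned on the extreme probands, evaluating the GRS
trend on those same probands is optimistically biased even under the
global null (winner's-curse reuse). The null-calibration test therefore
learns weights on one simulated cohort and evaluates the trend on an
independent one; the pipeline's own trend, like the original design,
reuses the learning samples and should be read as confirmatory
visualization, not an independent test.

## Susceptibility side

The family-based statistic sums the minor-allele dosage transmitted to
genotyped affected offspring over families with both parents genotyped;
its expectation and variance follow from Mendelian transmission
conditional on the parental pair (a heterozygous parent contributes
variance 1/4), offspring independent given parents, and z = (S−E)/√V
with a two-sided normal p. On het × hom-major single-child families
this reduces algebraically to the classical TDT (b−c)/√(b+c). Families
with a missing parental genotype are excluded and counted — a
documented simplification relative to full sufficient-statistic
conditioning, acceptable here because the simulator genotypes all
parents.

Frequency matching computes the case distribution over sex × 5-year age
bins, apportions ratio × count per stratum by the largest-remainder
rule (quotas always sum to ratio × n_cases and deviate from exact
proportionality by at most one control per stratum), and samples
without replacement, erroring with the name of the first deficient
stratum. The case-control model is additive logistic with age and sex
covariates; constant covariates are dropped so the degenerate case
equals the unadjusted fit.

## Orchestration and reproducibility

All randomness flows from one root seed through a fixed per-stage spawn
order (simulate, fixture, qc, scan, perm, controls), so stages can be
re-run in isolation and a run is byte-identical given (config, seed).
Every run writes per-stage TSVs, a JSON run log with in/out counts
(conservation is asserted: samples in = kept + removed; suggestive =
retained + collapsed), and the resolved YAML config. P-values
serialize in scientific notation with 4 significant digits.

## Problem sizes

The shipped tests and the acceptance script run at desk scale by
choice: 10,000 markers for the QC fixture, 340 families for the
extreme-design replicates, 10⁴ marker-tests for null calibration,
250 A/B replicates for GRS-trend calibration, 10⁵ Monte-Carlo
replicates for the power cross-check, and permutation B in the low
thousands with adaptive stopping. Each is large enough for the stated
tolerance (binomial 3σ bands for rates, ±0.01 for power) and small
enough to run in seconds to tens of seconds.

## Known limitations

- No batch-effect modelling, sex checks, or IBD-segment inference in QC.
- No mixed-model association, imputation, or meta-analysis.
- The family-based test does not implement sufficient-statistic
  conditioning for incomplete parental genotypes.
- The GRS is a fixed-panel score; there is no p-value-threshold sweep or
  cross-validated weighting.
- The simulator's independence assumptions (markers, missingness) mean
  LD-aware behaviour is only exercised on the constructed clique
  fixture.
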