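# Methods

## The model

All association machinery rests on the Gaussian linear mixed model with
one random intercept per family. For sample *j* of family *i*,

    y_ij = x_ij' beta + tau_i + e_ij,
    tau_i ~ N(0, var_family),   e_ij ~ N(0, var_resid),

where `x_ij` holds the intercept plus any SNP dosages and covariates.
The family intercept absorbs the phenotypic correlation among sibs —
shared genetics and shared rearing — which in a 7-family cohort is the
dominant source of sample dependence. Assumptions: Gaussian residuals,
additive allele effects (dosage coding 0/1/2), exchangeable samples
within a family, and independence across families. The maternal
half-sib pair violates the last assumption mildly (two families share a
dam, correlating their intercepts); we follow the common practice of
ignoring this at K = 7.

### Fitting

The likelihood is profiled: with the variance ratio
λ = var_family / var_resid fixed, the covariance is block diagonal
(`I + λ·J` per family), so GLS estimates of beta and the residual
variance are closed-form from per-family sums, and λ is optimized by
bounded scalar minimization of the profiled (restricted) likelihood on
the log scale over [1e-8, 1e8]. The lower boundary is accepted as
var_family = 0 without a mixture-chi-square correction; this affects
only tests *of the variance component*, which the package does not
perform. The ML log-likelihood is stored for every fit (also under
REML) so that BIC and likelihood-ratio tests are always comparable.
Agreement with an independent full-covariance evaluation and with
`statsmodels.MixedLM` is enforced in the test suite (dual-route check).

Per-SNP p-values come from the ML likelihood-ratio test with df = 1;
Wald p-values are also exposed for diagnostics. BIC is defined as
`-2·loglik + (n_fixed + 2)·log n` — the two variance components count
as parameters, and n (not the family count) is the sample size.

Family BLUPs are `b_i = λ · S_i / (1 + λ n_i)` with `S_i` the family
residual sum: shrunken family means, used for prediction whenever the
target sample's family was in training.

## Quality control

The filter cascade is applied in a fixed order: folded MAF (computed
over non-missing calls; "minor" means min(f, 1−f)) below the threshold
first, call rate on the remainder, then optional completeness. The
order matters and is preserved in the telescoping report; the fixture
generator plants variants in each stratum and the tests assert that
permuting the cascade changes the counts.

LD pruning follows the classic variant-count windowed procedure
(window 50, step 5, r² > 0.05 by default): within each window one
member of every violating pair is removed — the lower-MAF variant,
ties to the later position (the reference tool's convention). r² is
the squared Pearson correlation of dosages over pairwise-complete
samples (composite LD; genotypes are unphased).

## Kinship and pedigree verification

Pairwise kinship uses the robust estimator
`phi = (N_het,het − 2·N_opp_hom) / (N_het(i) + N_het(j))` over
pairwise-complete loci. Its fixed points make the benchmarks:
duplicates score exactly 0.5 by algebra, full sibs ≈ 0.25, unrelated
HWE founders ≈ 0 in expectation. (Some tool documentation describes a
0–1 kinship scale with twins at 1; the estimator's own scale, with
duplicates at 0.5, is used throughout.) A pair with no heterozygous
call in either member has an undefined coefficient and is reported
missing.

Family verification targets offspring only: parents are pedigree
anchors, and a dam shared between two families genuinely belongs to
both, so her label is not testable. A claim is confirmed when the
claimed family's mean kinship beats every other family's by the
reassignment margin (default 0.05, chosen to separate full sibs ≈ 0.25
from unrelated ≈ 0 and half sibs ≈ 0.125); a different family winning
by the margin means reassignment; anything else is unassignable. Both
kinds of flags are excluded downstream.

PCA runs on per-variant mean-imputed, standardized dosages (constant
variants dropped); hierarchical clustering is complete-linkage on
Euclidean dosage distances.

## Association scan and multiple testing

Each complete, polymorphic variant is tested as the sole genotype fixed
effect against the intercept-only null, both by ML, LRT df = 1.
Monomorphic or incomplete variants are skipped with a warning — the
scan expects the QC-passed complete matrix. The significance threshold
is alpha divided by the number of LD-independent variants (from the
pruner), and the threshold rounded to one significant figure is what
flags hits. No genomic-control correction is applied: inflation is
reported (λ_GC = median implied chi-square / 0.4549), not removed. At
the study's size (105 samples, 7 families) the ML LRT is slightly
anticonservative, so a perfectly specified family model yields
λ_GC ≈ 1.0–1.15; ignoring the family structure on the same data
inflates λ_GC several-fold. Phenotypes are scanned untransformed, so
effect sizes stay in trait units.

## Feature selection

**SES.** Forward max–min selection: each candidate's association is
summarized by the *maximum* p-value over the conditional independence
tests performed so far (mixed-model LRTs given subsets of the selected
set, subset size capped at `max_k`); candidates whose maximum exceeds
alpha are discarded; the candidate with the *minimum* summary is
admitted next. Conditioning subsets are enumerated lazily — only
subsets containing the most recently admitted feature require new
tests — which leaves the selection path unchanged while cutting the
test count. A candidate numerically collinear with its conditioning
set returns p = 1 (no additional information).

Equivalence detection is the package's main reconstruction choice:
when candidate X is discarded because of a subset Z whose last-admitted
member is Y, the symmetric swap test (Y given (Z∖{Y})∪{X}) is run, and
X joins Y's equivalence class when the swap also fails to reject.
Duplicated columns therefore always land in one class, and signatures
are enumerated by Cartesian substitution over the classes. Ties break
deterministically (smaller current summary, then input order = genome
order), so runs are bit-reproducible.

A forward selector of this kind admits on the order of alpha × p null
features by chance; that is controlled by the cross-validated model
grid, not by the selector itself. With calibrated tests, an "always
empty under the null" behavior is not attainable, and the tests assert
the Poisson-consistent false-selection rate instead.

**gOMP.** Plain linear orthogonal matching pursuit on internally
standardized columns and centered response: admit the column most
correlated with the residuals, refit least squares on everything
admitted, stop when the BIC improvement over the previous model is at
most `stop_delta` (2 or 4 BIC units). Residual orthogonality to all
admitted columns guarantees no column is picked twice. The model is
deliberately fixed-effects-only, as is conventional for OMP; the
response may be pre-adjusted by the null mixed model first (off by
default), and both modes are exposed because the choice is genuinely
open.

## Model choice by clustered LOOCV

Every grid configuration (8 SES + 2 gOMP by default) is scored by
leave-one-out cross-validation that respects families: the held-out
sample is predicted from the refit fixed effects plus its family's
training BLUP, and both the mean squared error (the textbook LOOCV
estimate) and the median are reported. The *median* drives model
choice — it is the more robust summary with squared errors this heavy
tailed — while the mean is the overfitting-sensitive diagnostic; ties
go to fewer selected variants, then grid order. Selection is re-run
inside every training fold by default, so the held-out sample can never
influence its own signature (the leakage check flips the held-out
phenotype and asserts the fold's selection is unchanged); a
fixed-signature mode (select once, refit per fold) is available for
speed and for reproducing selection-once workflows. A fold whose
selection exceeds what the training fold can refit keeps only its
leading members; a selector failure falls back to the intercept-only
model for that fold, with a warning in both cases.

## Synthetic cohorts

The generator emulates the target study design: 7 families from 13
parents (7 sires, 6 dams, one dam shared between the first two
families), 105 offspring, founders drawn from Hardy–Weinberg at
frequencies sampled uniformly on [0.01, 0.5] by default, and one
uniformly chosen allele transmitted per parent per locus. Loci are
transmitted independently by default — the LD relevant to this design
arises from family structure itself — with an optional block-wise
transmission mode for within-chromosome LD. Missingness is completely
at random per variant. Default trait models resemble harvest-age sea
bream (weight ≈ 800 g with family SD ≈ 100 g, tag weight ≈ 50 g,
fat ≈ 10%, length/width ≈ 2.7), with family variance a sizeable share
of the total, as expected in a cohort selected for between-family
variation.

What the generator does *not* emulate: genotyping error and allelic
dropout, selective-genotyping ascertainment, linked-marker LD beyond
the optional block mode, non-additive (dominance/epistatic) effects,
and informative missingness. Passing tests therefore demonstrate
correctness of the algorithms under the stated model, not robustness
to those real-data features.

The QC fixture generator is exact rather than stochastic in its
marginals: it plants prescribed numbers of variants in each cascade
stratum (low-MAF singleton-het columns, half of them carrying a
missing call so the cascade order is detectable; low call-rate columns
just below the threshold; complete common columns) and the tests
re-derive each stratum from the filter definitions. The fixture's
thresholds and cohort size are parameters because some strata are
infeasible at extreme sizes — e.g. with 3 samples no variant can have
both a missing call and call rate ≥ 0.9 — and the defaults (118
samples, MAF 0.05, call rate 0.90) match the study profile.

All randomness flows from one integer seed through spawned generator
streams, so each stage is independently reproducible and pipeline
outputs are byte-identical across runs.

## Problem sizes and numerics

The test suite and the acceptance script run on deliberately modest
sizes chosen to make each property measurable in seconds: 15,233-variant
QC fixtures, 400-variant scans, 5,000-locus kinship benchmarks,
200 × 10 mixed-model recovery, 600–1,000-replicate calibration loops,
and 4–7-family LOOCV instances. Tolerances follow the estimator's
sampling noise at those sizes (e.g. full-sib kinship ± 0.03 at 5,000
loci, variance components within 10–15% averaged over replicates).
Numerical guards: residual sums of squares floored at tiny positive
values before logs, collinearity detected by QR/least-squares residual
norms at 1e-8 relative, LRT statistics clipped at 0, p-values clipped
to [0, 1].

## Known limitations

- The LRT is ML-based and slightly anticonservative below ~100 samples;
  at the study size this appears as λ_GC up to ~1.15 under a correct
  model. REML fitting is available but LRTs always use ML likelihoods.
- The half-sib pair's cross-family covariance is ignored by the
  single-level random intercept.
- SES equivalence uses the symmetric swap rule; other formulations of
  "statistical equivalence" can differ in edge cases beyond duplicated
  columns.
- gOMP's BIC uses the fixed-effects linear model even when the
  phenotype has family structure (pre-adjustment optional, off by
  default).
- Conservation flags come from a user-supplied interval file; no
  cross-species lookup is performed.
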