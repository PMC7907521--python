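# Methods

## Trinomial association models

For one SNP (allele dose `g` ∈ {0, 1, 2}) and one binary symptom, each
participant is assigned a trichotomous outcome: 0 = control, 1 = case
without the symptom, 2 = case with the symptom.  The baseline model is a
multinomial logit with the control group as reference:

```
η₁ = α⁻ + β⁻·g     (case without symptom vs control)
η₂ = α⁺ + β⁺·g     (case with symptom vs control)
P(control) = 1 / (1 + e^η₁ + e^η₂)
```

The six hypotheses are linear constraints on `(β⁻, β⁺)` — null (both 0,
k = 2), basic (equal, k = 3), subset (β⁻ = 0, k = 3), inverse subset
(β⁺ = 0, k = 3), general (free, k = 4) — plus the *modifier* model
(k = 3), which factorizes the likelihood into a genotype-free Bernoulli
case-control margin `P(case) = σ(a)` and a case-only logistic symptom
model `P(symptom | case, g) = σ(c + γ·g)`.  The case-margin MLE is the
closed-form case fraction; the symptom part is a two-parameter logistic
fit.

**Fitting.**  The likelihood depends on the data only through the
(dose level × outcome class) contingency table, so all fits operate on
collapsed count tables.  Constrained models are parameterized as
θ = A·φ with a per-model constraint matrix A, and maximized by damped
Newton ascent with step halving, a small ridge (1e-10) on the negative
Hessian, and iterates clipped at |param| = 30 (beyond which the fit is
flagged as separated).  The gradient convergence tolerance is relative
to the total count (1e-8 per observation), since the score scales with
the sample size.  Batching across the leading axis of the count tables
makes permutation replicates share one vectorized Newton path.

**Selection and significance.**  BIC = −2·loglik + k·ln N; the minimum
over converged, non-separated fits wins, with ties (within 1e-6) broken
toward fewer parameters and then a fixed model order.  The chosen
non-null model is tested against null by LRT with χ² reference on
k − 2 df.  Separated or non-converged fits are excluded from selection
rather than silently trusted.

## Permutation and Šidák correction

Testing ten symptoms per SNP inflates the family-wise error, and the
symptom-specific tests are dependent (they share cases and controls), so
the correction uses the permutation distribution of a min-p statistic:
genotypes are permuted across participants (optionally within strata),
keeping the phenotype structure intact, and for each permutation the
statistic is the minimum over symptoms **and over the five non-null
models** of the asymptotic LRT p-value against null.  The minimum over
models is used rather than the p-value of the BIC-selected model because
under the null BIC selects the null model almost always, which puts an
atom at p = 1 and destroys the resolution of the permutation
distribution; the minimum over the fixed model set is a continuous
statistic with the same selective sensitivity.  The corrected p uses the
add-one estimator (1 + #{permuted ≤ observed}) / (B + 1).  Across the M
SNPs of a panel — designed as near-independent candidate loci — a Šidák
step 1 − (1 − p)^M (computed as `-expm1(M·log1p(-p))`) controls the
family-wise error.

## Diagnostic classification and nested samples

Active migraineurs are graded against three criteria adapted from the
second International Classification of Headache Disorders: B — attack
duration 4–72 h; C — at least two of {unilateral pain, pulsating pain,
aggravation by physical activity, inhibition of daily activities}; D —
nausea/vomiting, or photophobia and phonophobia together.  Full migraine
satisfies all three, probable migraine misses exactly one.  Aura and the
dichotomized attack-frequency item are characteristics under study, not
criteria.  Three nested case samples (full only ⊂ full + probable ⊂ all
active) share one control set of never-migraineurs; prior migraineurs
and participants with missing status are excluded.  Percentages in
prevalence tables are 100·count/N rounded half-up to one decimal.

## Latent class analysis

Symptom profiles of cases are modeled as a finite mixture of independent
Bernoulli items with class weights π and item-response probabilities ρ.
EM runs from random starts (ρ ~ U[0.05, 0.95], uniform π) to a relative
log-likelihood tolerance of 1e-8 within 5 000 iterations, with ρ clamped
to [1e-6, 1−1e-6] and monotonicity of the log-likelihood asserted at
every iteration.  A sweep over K fits many restarts per K, discards
degenerate solutions (an emptied class), keeps the best, and counts how
often the best solution recurs across restarts after aligning classes by
a minimum-cost assignment — low recurrence flags an unstable latent
structure.  Model size is (K − 1) + K·J parameters; BIC curves over K
are min-max scaled to [0, 1] for comparison across samples.  Class
membership can replace a symptom in the selective-association machinery:
modal assignments define per-class trichotomous outcomes, and a global
heterogeneity LRT (free per-class slopes vs one shared slope, K − 1 df)
tests whether genotype effects differ across classes.

## Cohort simulator

The generator is the package's specification of its own study
conditions.  Defaults: 21 111 participants, hard-call genotypes in
Hardy-Weinberg equilibrium at configurable allele frequencies,
active-case fraction 0.14, ten binary symptoms with all-migraineur
prevalences (aura 0.392, pulsating 0.530, unilateral 0.596, phonophobia
0.410, photophobia 0.668, duration 0.781, nausea 0.652, aggravation
0.339, inhibition 0.499, frequency 0.350), a 0.09 marginal fraction of
prior migraineurs carved out of non-actives, age ~ truncated normal
(54.6, 7.2, min 45), and standard-normal ancestry PCs with an optional
confounder loading on the case logit.  Trinomial effects act on the two
case-vs-control logits of the target symptom with intercepts anchored so
that the zero-dose case fraction and symptom prevalence match their
configured values; modifier effects tilt the symptom-given-case logit.
A latent-class variant draws class membership and controls from one
multinomial with per-class dose effects.  All randomness derives from a
single seed through `SeedSequence` spawning in a fixed stage order, so
any stage is individually reproducible and written files are
byte-identical across runs.

## Verification and problem sizes

The test suite checks every numerical path against an independent
oracle or a closed form: an iterative grid-refinement maximizer for all
six models (agreement to ~1e-10 on small fixtures, tolerance 1e-3),
closed-form null/logistic/K=1-LCA likelihoods, χ² tails and Šidák
arithmetic, and distributional properties (LRT statistic mean under
null, Kolmogorov-Smirnov uniformity of p-values, permutation calibration
within binomial error, Wald CI coverage).  The sizes used by the
acceptance checks are the package's own choices, balancing statistical
resolution against a few minutes of runtime on one CPU: permutation
calibration with 200 null SNPs at B = 199 and N = 2 000; selection
operating characteristics with 200 replicates per generating model at
N = 21 111 (odds ratios 1.5–2.0) and 60 replicates at N = 200 000 for
BIC consistency; parameter recovery at N = 50 000; CI coverage over 400
replicates; latent-class recovery over 20 replicates of N = 2 000.

## Limitations

* Hard-call genotypes and independent loci only; dosage uncertainty and
  linkage disequilibrium are not modeled (an `ld_r2` helper quantifies
  observed correlation but the generator does not induce it).
* Asymptotic LRT p-values can be anti-conservative in tiny subclasses;
  the permutation correction is the primary inferential guarantee.
* The modifier model's factorization assumes the case-control margin is
  genotype-free; data violating both parts simultaneously are attributed
  by BIC to whichever constrained model loses less likelihood.
* The Šidák step assumes near-independent SNPs; for panels with strong
  LD it is conservative in the family-wise sense but the effective
  number of tests is overstated.
* LCA assumes conditional independence of items given class; correlated
  residuals inflate the selected K.
* The simulator draws symptoms independently (or from an LCA truth)
  among cases; it does not reproduce empirical inter-symptom phi
  structure beyond what the latent classes induce.
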