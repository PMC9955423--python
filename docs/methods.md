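# Methods

## Model

### Hypothesis space and likelihoods

A child's belief about water displacement is a probability 4-vector over
the rules **Size (S)**, **Material (M)**, **Mass (W)** and **Random (R)**;
Size is the task's ground truth, and Mass is defined as size × density
unless a weight is given explicitly. Each deterministic rule predicts the
direction (LEFT / EQUAL / RIGHT) of the sphere with the larger relevant
feature; exact equality predicts EQUAL (stimuli are designed categorically,
so no tolerance band is used).

Two noise parameters turn predictions into likelihoods:

* **ε (evidence noise, default 0.1)** — a deterministic rule assigns
  1−ε to its predicted outcome direction and ε/2 to each other direction;
  Random assigns 1/3 to each. ε = 0 recovers the hard-likelihood variant.
  A non-zero ε is needed for the strong-prior regime to exist at all: a
  child certain of a contradicted rule must retain a graded (not zero)
  likelihood for the outcome, otherwise their posterior is undefined and no
  "limited distributional shift" can occur.
* **η (response noise, default 0.1)** — a deterministic rule spreads 1−η
  uniformly over the 5-point responses asserting its predicted direction
  ({1,2} for LEFT, {3} for EQUAL, {4,5} for RIGHT) and η uniformly over the
  rest; Random is uniform over all five. The uniform split within the
  matching side is this package's concrete response model; a scheme that
  weights "certainly" over "maybe" responses differently would be a
  drop-in replacement for `response_likelihood`.

### The three modelling stages

1. **Priors.** Each child's prior is inferred from their pretest (no
   feedback shown): starting from the uniform vector, multiply in the
   response likelihood of each (trial, response) pair per rule and
   renormalize. Pretest updating therefore uses *response* likelihoods and
   learning updating uses *outcome* likelihoods — the split follows from
   which information the child actually receives in each phase.
2. **Trajectories.** Sequential Bayesian updating against the
   learning-phase outcomes, renormalizing after every trial (equivalent to
   renormalizing once at the end; per-trial normalization keeps
   mid-trajectory states interpretable). States that reach exactly zero
   stay zero. Numerically, a whole trajectory is one cumulative product of
   likelihood rows, normalized row-wise; with 30 trials and ε = 0.1 the
   running product stays ≥ ~1e-39, far from underflow.
3. **Surprise.** For trial t, Shannon information uses the *pre-update*
   state ("given their currently inferred model"): SI = −log Σ_h
   p(d_t|h)·p(h). KL divergence is oriented KLD(posterior‖prior), with the
   0·log 0 := 0 convention. The Jensen–Shannon divergence between the same
   pair of states is carried as a bounded (≤ log 2) robustness companion.
   All metrics default to natural-log units; the base is configurable and
   cosmetic, since Pearson correlations are invariant under the positive
   rescaling a base change applies (asserted to 1e-12 in the tests).

**Convergence** onto a rule is declared at the first state whose posterior
odds against the strongest competitor reach a threshold, default 10 — the
conventional "strong evidence" cut; the criterion names posterior odds but
no published threshold exists, so the value is configurable.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes:

* **94 children**, randomly assigned to Prediction / Postdiction balanced
  within one; 19/94 are *already-knowers* given size-dominant priors.
* **Priors** are Dirichlet draws concentrated on an archetype's dominant
  rule (pseudo-count = concentration, default 20, others 1); the mixed
  archetype splits the concentration between Size and Mass. Non-knowers
  draw their archetype from a mix of material-dominant (0.25),
  mass-dominant (0.45) and mixed (0.30), reflecting that the common
  misconception ties displacement to weight or to a weight/size blend.
* **Trials**: a 10-trial disambiguating pretest without feedback, then a
  learning phase of 9 congruent trials (one side dominates size, density
  and weight, so all rules agree) followed by 21 disambiguating trials
  (a large light sphere against a small dense one, so Size opposes
  Material and Mass). Every learning outcome follows the Size rule. The
  per-child trial count and pretest length are not published; these
  defaults are declared approximations (they put the pooled learning-trial
  count at 94 × 30 = 2820) and are configurable.
* **Responses** are sampled per trial by drawing a rule from the child's
  current belief and a response from that rule's likelihood; beliefs
  advance only on learning trials. Postdiction children respond
  identically — the conditions differ in timing, not response format.
* **Pupil change** is a single per-trial scalar (the analysis consumes one
  baseline-corrected value per trial, so no waveform is simulated):
  gain × standardized(coupled metric) + N(0, noise_sd). Standardizing the
  metric first (cohort-level mean/sd) makes the gain map onto the
  population correlation r = gain/√(gain² + noise_sd²); the default gain
  targets r = 0.15 with unit noise. The default scenario couples KLD in
  Prediction and nothing (pure noise) in Postdiction, encoding as a
  generative scenario the finding the analysis is designed to detect.

  The coupled series is the child's **model-side** surprise series — the
  one computed from their pretest-inferred prior, which is also what the
  analysis correlates against. The alternative (coupling to the
  generative-prior series) turns out to decorrelate almost completely from
  the model-side series (pooled r ≈ 0.006): inference from ten diagnostic
  pretest responses yields priors far sharper than the Dirichlet draws
  (each consistent response multiplies the dominant rule's odds by ~13.5),
  which shifts the belief-revision spikes by several trials. Coupling to
  the model-side series is the reading under which the gain→r mapping is
  meaningful end to end.
* **Reproducibility**: one root seed; the trial sequence and cohort-level
  assignments use dedicated substreams, and each child's randomness derives
  from (seed, child index), so growing the cohort does not reshuffle
  existing children. Identical seeds yield byte-identical tables.

### What the generator does *not* emulate

Eye-tracker artifacts (blinks, luminance oscillation, baseline drift), age
effects, per-child variation in ε/η, trial-count attrition, and — most
importantly — any between-child heterogeneity in how *model-like* a child
is: every simulated child is exactly the ideal learner plus iid noise.
Passing tests therefore show that the statistical machinery recovers
couplings that exist in data of this structure, not that real pupillometry
behaves this way.

## Statistical surface

Trial-level Pearson correlations (two-sided p from the t-distribution on
n−2 df) are pooled across children within condition and scope — trials are
treated as exchangeable, with no mixed-effects correction; this is a
documented limitation shared with the modelled analysis. Four scopes are
analysed: all trials, learners, already-knowers (split by the argmax of the
pretest-inferred belief, with ties involving Size counted as learners), and
the critical learning trials 10–19 (the first disambiguating block, where
belief revision concentrates). Each scope's 4-cell grid forms its own
Bonferroni family (α/4 = 0.0125).

Correlation comparisons: between independent condition samples, Fisher's
r-to-z, z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)); within a
condition, where the KLD and SI correlations share the pupil series,
Steiger's z for dependent overlapping correlations, which adjusts for the
KLD–SI correlation. Comparison p-values are one-sided normal tails by
default and cell p-values two-sided; both are configurable. df is reported
as n−2 throughout (the standard Pearson convention).

The individual-differences analysis computes, per child, the behaviour fit
(responses vs model-expected responses across learning trials, where the
expected response is the belief-weighted mean of each rule's response
distribution) and the pupil fit (pupil vs KLD, and vs SI); children with a
constant series are excluded and counted. The two fits are then correlated
across children for each metric.

## Numerical choices and degenerate inputs

* Belief vectors are validated to sum to 1 within 1e-12 and renormalized
  defensively beyond that drift.
* A zero marginal outcome probability (possible only at ε = 0 with all
  prior mass on contradicted rules) is raised as an error naming the
  trial, never silently patched.
* KL divergence demands absolute continuity (posterior mass on a
  zero-prior entry is an error); Bayesian updating guarantees it.
* Min–max normalization of surprise series (for cross-metric regime
  comparison) errors on constant input rather than returning zeros; its
  scope defaults to pooled-within-condition and can be set to pooled or
  per-child — the modelled analysis does not state which was used.
* Pearson correlation on constant input raises rather than returning NaN.
* Steiger's test rejects correlation triples that are not positive
  semidefinite.

## Emergent behaviour worth knowing about

Two properties of the default scenario are consequences of the model
rather than targets:

* **Induced SI correlation.** Coupling pupil to KLD at population r = 0.15
  induces a (Prediction, SI) correlation of ≈ r × corr(SI, KLD) ≈ 0.05
  (the pooled SI–KLD trial correlation is ≈ 0.31). At ~1410 pooled trials
  this induced correlation clears the corrected threshold in roughly a
  quarter of cohorts, so "only the KLD cell significant" holds in ≈ 74% of
  seeds rather than always — selectivity of the grid is power-limited by
  the SI–KLD overlap, not by the implementation. A weaker true coupling
  (e.g., r ≈ 0.07) induces an undetectable SI correlation and yields clean
  selectivity.
* **Cross-child correlation sign.** With model-exact simulated children,
  the per-child pupil~KLD fit is driven by KLD variance (learners high,
  already-knowers near zero), while the behaviour~model fit is marginally
  *higher* for already-knowers (belief-transition trials make learners'
  5-point responses bimodal, adding conditional response variance). The
  cross-child correlation-of-correlations therefore sits slightly below
  zero (mean ≈ −0.15) under KLD-coupled pupil, and at zero under pure-noise
  pupil. A positive value — as observed in real children — requires genuine
  between-child heterogeneity in model alignment (children for whom the
  ideal-learner description is simply better or worse across the board),
  which this generator deliberately does not fabricate.

## Problem sizes

The default cohort is 94 children × (10 pretest + 30 learning) trials.
Multi-seed rates are computed over 200 cohorts in the test suite and 100
cohorts in the acceptance script; the null-calibration check uses 200
uncoupled cohorts shared across tests.
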