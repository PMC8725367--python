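# Methods

## Measurement model

Both survey modules — capacity (what a person can do given their health
state) and performance (what they actually do in their environment) —
are sets of ordered categorical items, typically five categories from
"no problem" to "extreme problem".  The package models each module with
the partial credit model (PCM): persons and item response categories sit
on one latent logit continuum, oriented so that higher values mean more
disability.  For item *j* with categories 0…m<sub>j</sub>, step
parameters b<sub>jk</sub> = δ<sub>j</sub> + τ<sub>jk</sub> (difficulty
plus centred thresholds, Σ<sub>k</sub>τ<sub>jk</sub> = 0):

    P(X_j = x | θ) ∝ exp( Σ_{k≤x} (θ − b_jk) ),   empty sum = 0.

δ<sub>j</sub> + τ<sub>jk</sub> is the point where categories k−1 and k
are equally probable; these threshold locations are what the "difficulty
range" of a scale summarises.  The PCM is in the Rasch family, so the
raw sum score is sufficient for θ on a fixed item set — two respondents
answering the same items with the same total get the same measure.

## Estimation

*Item parameters.*  Alternating joint maximum likelihood: person
abilities for non-extreme scorers are profiled out by grouping persons
on (answered-item set, raw score) and solving the ML score equation per
group with a damped, fully vectorised Newton iteration; item step
parameters are then updated by per-item Newton steps (the Hessian is
minus the covariance matrix of the cumulative-category indicators, hence
always negative definite).  Difficulties are re-centred to mean zero
every sweep (the identification constraint), and the joint log-likelihood
is recorded; because both half-steps are exact maximisations the trace is
non-decreasing.  Convergence: maximum parameter change < 1e−6, at most
500 sweeps.

After convergence the profiling is repeated with Warm-weighted rather
than plain ML abilities and the items are allowed to settle again; this
removes most of the outward drift of extreme thresholds that plain joint
estimation produces.  Finally the centred parameters are scaled by the
standard (K−1)/K correction (K = number of items).  In simulation at the
default conditions this leaves threshold bias below ~0.03 logits.
Standard errors come from the per-item observed information, with a
delta-method transform to the (δ, τ) parameterisation.

Items with a single observed category are excluded (warned); unobserved
interior categories are collapsed out with the original→fitted index map
stored on the item.  Missing responses contribute nothing to the
likelihood (missingness is assumed ignorable).  Disordered threshold
estimates are reported as-is, never silently repaired.

*Person abilities.*  Warm's weighted likelihood (WLE): solve
r − ΣE<sub>j</sub>(θ) + Σμ₃<sub>j</sub> / (2ΣV<sub>j</sub>) = 0, where
E, V, μ₃ are the conditional score moments of the answered items.  The
correction term keeps estimates finite at zero and perfect raw scores,
which matters here because minimum-score respondents must still be
classified ("score = 0" is its own classification rule).  SE(θ̂) =
1/√I(θ̂).  Persons with no observed responses are excluded with a
warning.

## Reliability and targeting

PSI = (Var(θ̂) − mean(se²)) / Var(θ̂), floored at 0 and capped at 1 —
the share of observed measure variance not attributable to measurement
error; 0.7 is acceptable for population comparison, 0.85+ for individual
measurement.  On data simulated from the model, PSI approaches the
generating reliability Var(θ) / (Var(θ) + E[se²]).

Targeting compares the item and person distributions.  Since calibration
pins mean difficulty at zero, the offset appears on the person side; a
mean absolute offset below half a logit counts as well-centred (a half
logit is the conventional clinically meaningful difference for
polytomous scales).  The threshold range min/max over all
δ<sub>j</sub> + τ<sub>jk</sub> shows the ability span the items cover.

## Residual diagnostics

All residual analyses use non-extreme scorers and standardize by an
estimation-adjusted variance V·(1 − V/I<sub>person</sub>): residuals are
taken at each person's own estimate, which removes the component along
the score direction; without the adjustment, mean-square fit statistics
sit visibly below 1 at large n and the flags fire on perfectly fitting
items.

* **Item fit** — outfit (unweighted) and infit (information-weighted)
  mean squares, standardized via the Wilson–Hilferty cube-root transform
  using the exact conditional fourth moments.  `fit_residual` is the
  standardized outfit; |fit_residual| > 2.5 flags misfit.  Noisy or
  unrelated items land far on the positive side, deterministic
  (Guttman-like, over-discriminating) items far on the negative side.
  Items with under 20 observations carry a low-information flag.
* **Local dependence** — Pearson correlations of the standardized
  residuals; a pair is flagged when it exceeds the mean off-diagonal
  correlation by 0.2 (a relative cut, robust to the small negative bias
  Rasch residual correlations have by construction).
* **Dimensionality** — eigendecomposition of the residual correlation
  matrix; items are split by the sign of the first-component loading,
  abilities are re-estimated on each subset, and each person's two
  measures are compared by a z-test at α = 0.05.  Unidimensionality is
  accepted when the Wilson 95% CI for the share of significant
  differences reaches down to 5%.  The split test needs at least 3 items
  per side, otherwise it is skipped with a warning.
* **DIF** — per item and person factor, a two-way ANOVA of standardized
  residuals on factor level × ability class interval (5 equal-count
  strata by default).  The factor main effect is uniform DIF, the
  interaction non-uniform DIF; p-values are Bonferroni-corrected across
  items.  A factor with a single level is rejected (no contrast).

Every cut-off above lives in `DiagnosticSettings` and is echoed into the
diagnostic report, since none of them is fixed by theory.

## The 0–100 metric and environmental adjustment

Abilities are mapped affinely to 0 (least) … 100 (most disability) and
clipped.  The default anchors are the WLE abilities of the minimum and
maximum possible raw score on the calibrated bank — attainable endpoints
that depend only on the item bank, not on the sample at hand.

Performance is then adjusted for environment: a random-forest regression
of the 0–100 performance score on the 0–100 capacity score plus
environmental covariates (assistance, devices, support, attitudes),
500 trees, ⌈p/3⌉ split candidates, minimum leaf 5, fixed seed; the model
predictions are the adjusted scores (clipped to [0, 100]), and the
out-of-bag R² is reported next to that of a capacity-only forest so the
environmental contribution is visible.  The adjustment runs on the
0–100 scale because the severity cut-offs and the reported distribution
operate on the performance metric score.  Ordinal covariates enter as
integers, categorical ones as one-of-K indicators.

## Severity classification

Cut-offs are distribution-based: sample mean M and standard deviation S
of the adjusted performance score (unweighted: n−1 divisor; weighted:
population-style weighted SD — the convention is recorded in the run
metadata).  Levels: no (< M−S, or score exactly 0), mild (M−S … M),
moderate (M … M+S), severe (≥ M+S).  The published rules use strict
inequalities at the two interior boundaries, leaving exact boundary
scores unassigned; here they join the higher-severity side, consistent
with the ≥ that defines severe, and the policy is configurable.
Prevalence is the (optionally weighted) level distribution;
disaggregation reports per-level indicator means with normal CIs and a
configurable small-n flag (default 30).  The histogram tiles [0, 100]
with the three cut-off positions marked.

## Synthetic surveys

The generator draws capacity ability from N(μ, σ²), builds performance
ability as a correlation-ρ mixture plus centred environmental shifts
(performance = μ + ρ(θ<sub>cap</sub>−μ) + σ√(1−ρ²)·z + Σβ<sub>c</sub>(x<sub>c</sub>−E[x<sub>c</sub>])),
and samples responses from the same closed-form PCM used in estimation,
with MCAR missingness.  Defaults emulate the published national
calibrations: 2000 persons; 15 five-category items with difficulties
−2…+2 and symmetric thresholds ±1.5 (threshold locations ≈ −3.5…+3.5,
matching the printed difficulty ranges); ability N(−1, 1.2²), putting the
population below the scale centre as every national table shows; ρ = 0.8
between capacity and performance; 2% missingness.  Environmental
covariates are a mix of binary (assistive devices 25%, personal
assistance 15%) and 5-level ordinal (attitudes, social support)
variables, with default shifts of +0.6 logits per device and +0.25 per
attitude level; an employment indicator with a built-in disability
gradient (logit drop 0.8 per performance logit) supports the
disaggregation stage.

What the generator does **not** emulate: informative missingness,
complex sampling designs (strata/clusters/weights), response styles,
item-level DIF (tests construct DIF data by stacking two generated
groups), or multidimensionality.  Passing tests therefore demonstrate
correctness of the estimation and classification machinery under the
model, not robustness to violations real survey data may carry.

## Numerical choices and degenerate inputs

Category probabilities are computed with a max-subtracted cumulative sum
(no overflow for |θ| up to hundreds of logits).  Person solving uses
damped Newton (steps clipped to 1 logit) with a bracketed root-finder
fallback for any group left unsettled.  Ties in the DIF ability
stratification are broken by first-occurrence ranking, which makes the
strata deterministic.  Constant items are dropped, constant score
vectors make cut-offs undefined (error), a zero-variance measure yields
PSI 0 with a warning, and scores outside [0, 100] are rejected rather
than clipped at classification time.

Problem sizes: the test suite and the acceptance script run at the
generator defaults (n = 2000; 5000 for the reliability-convergence
check; 50 000 for the distributional goodness-of-fit check) with 12
replicates for the DIF power/size study — sizes at which the recovery
targets and power are comfortably estimable on a single CPU.

## Known limitations

* Joint (not conditional/marginal) likelihood estimation: consistent
  behaviour is achieved through the Warm-weighted refinement plus
  (K−1)/K correction, verified by simulation at the default design, not
  by theory; very short scales or very sparse categories may retain
  bias.  Thresholds whose categories have only a handful of respondents
  carry standard errors of several tenths of a logit — their point
  estimates should be read alongside the reported SEs.
* Exact numerical agreement with any particular commercial Rasch
  package's country calibrations is not claimed; estimator details
  (and therefore third decimals) differ between implementations.
* No anchoring/equating across surveys: each calibration is
  sample-specific, so scores from different runs are not directly
  comparable.
* Survey weights affect cut-offs, prevalence, and disaggregation, but
  no design-based variance estimation (linearization/replication) is
  provided; CIs are simple normal approximations.
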