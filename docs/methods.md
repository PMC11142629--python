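# Methods

## The model

For each ordered pair of residents (i, j) co-present in the unit on day
t, and separately for the affirmation and correction networks, the
binary tie outcome is modelled as

    P(y_ijt = 1) = Φ(η_ijt),
    η_ijt = x_ijt'β + a_i + b_j + c_t + m(i, j),

where Φ is the standard normal CDF, x_ijt collects the covariates below,
a_i ~ N(0, σ_a²) and b_j ~ N(0, σ_b²) are sender and receiver random
effects, c_t ~ N(0, σ_c²) is a day random effect, and m(i, j) is a latent
factor term: the multiplicative form u_i·v_j (default) or the distance
form −‖u_i − u_j‖.  The two networks are fitted as two separate models
sharing the same covariate columns; each reports its own intercept and
variance components.

The latent term exists because the logs carry no within-day timing: if
i and j exchange feedback on the same day, neither direction can
condition on the other, so residual dyadic correlation remains after all
lagged covariates.  The latent factor absorbs it.  We treat random
effects and latent positions as nuisance components: only β and the
three variance components are reported.

## Covariates

All history terms are deterministic functions of events strictly before
the observation day (no leakage).  Windowed terms use a sliding recency
window of `recent_window` days; the default is 1 day, i.e. terms respond
to the immediately preceding day.  This default was chosen on variance
grounds: at realistic tie densities (~0.04 ties per dyad-day, 15
potential partners) the probability of having received at least one
affirmation within a multi-week window approaches 1, so longer binary
windows drive the degree indicators toward a constant and their
coefficients become unestimable.  A 1-day binary indicator keeps every
history term informative and matches the one-day resolution of the
logs.  Longer windows and count coding (`use_counts`) remain available,
and which coding an archival analysis used is generally not knowable —
conclusions that depend on the window length should be checked under
several settings.

Definitions (per network, unless noted):

* **Reciprocity** — indicator that j→i occurred in the window.
* **Transitive closure / three cycle** — indicator (count if
  `use_counts`: number of distinct intermediaries) of some k with i→k
  and k→j (transitive) or j→k and k→i (cycle) in the window.
* **Indegree activity / popularity** — receipts of i (resp. j) in the
  window from anyone other than the focal partner; staff-sourced
  receipts included.  Excluding the partner keeps these terms separable
  from reciprocity and same-peer concentration.
* **Outdegree activity** — events sent by i to residents other than j.
* **Out-isolation activity** — 1 iff i has sent nothing in that network
  over the entire prior history (cumulative, not windowed).
* **Same-peer concentration** — indicator that i→j occurred in the window.
* **Staff indegree terms** — staff-sourced subset of the corresponding
  receipts.  Differential coding: a staff receipt counts in both the
  base term and the staff term, so staff coefficients read as
  staff-versus-peer differences.
* **Head-turning (HT) terms** — HT corrections sanction a resident for
  ignoring a correctable peer behaviour.  HT indegree activity: HT
  corrections received by i in the window (staff version: staff-sourced
  subset); whole-unit HT: an HT correction issued to someone other than
  i; HT outdegree popularity: j sent an HT correction; HT reciprocity:
  j sent i an HT correction.
* **Tenure** — indicators for <`tenure_young_days`(30) and
  ≥`tenure_senior_days`(120) days since entry, for sender and receiver;
  the middle tenure band is the reference.
* **Attributes** — white activity/popularity (race indicators), age and
  LSI-R activity/popularity (mean-centred over the full roster),
  race homophily (same-race indicator), age homophily and LSI-R
  similarity (1 − |Δ|/roster range; defined as 1 when the range is
  zero), admission-time homophily max(0, 1 − |Δentry|/60 d).  The 60-day
  scale treats residents admitted within about two months as an entry
  cohort; it is a bounded, unit-free choice, not an estimate.

History terms are binary by default because tie presence, not event
multiplicity, is the modelled outcome and binarisation is robust to
same-day duplicates; the outcome grid itself always binarises same-day
events on a dyad.

## Estimation

Albert–Chib Gibbs sampling: each binary outcome is augmented with a
truncated-normal latent variable z ~ N(η, 1) constrained by the outcome
sign, after which every conditional update is conjugate — multivariate
normal for β (prior N(0, 5²) iid), normal for each sender/receiver/day
effect, inverse-gamma(2, 1) for the variance components, and normal for
the rows of U and V given the other (multiplicative form; positions have
N(0, 1) priors).  The distance form updates positions by per-actor
random-walk Metropolis (step 0.15).  Numerical choices:

* Truncated-normal draws use inverse-CDF sampling with the argument
  clipped to [1e−16, 1−1e−16] for tail safety.
* Sender, receiver, and day effects are re-centred every sweep with the
  mean folded into the intercept (η-preserving), which resolves the
  additive location non-identifiability.
* The multiplicative latent term is identified only up to rotation (the
  distance form up to translation/rotation), so raw positions are never
  reported; invariance is tested to 1e−10.
* Defaults: 1,500 sweeps, 500 burn-in, thinning 2, one chain.  Split-R̂
  and effective sample size are computed per parameter (via arviz), with
  warnings above 1.05 / below 100.  Two runs with the same seed are
  bit-identical.
* Degenerate inputs are refused: all-zero/all-one outcomes, non-finite
  covariates, fewer than 100 retained draws at summary time.

Fixing `fixed_re_variance` near zero with `latent_dim=0` collapses the
model to plain Bayesian probit; the test suite checks agreement with an
independent maximum-likelihood probit fit in that limit.

## The synthetic unit

The generator emulates a 16-bed single-gender unit observed for 611
days.  Roster: the unit starts full; stays are truncated normal
(mean 133.9 d, SD 42.4 d, minimum 1 d) and each departure refills the
bed the same day, so the head-count equals capacity throughout.  At
those defaults a 611-day run turns over ≈ capacity × (1 + 611/133.9) ≈ 89
distinct residents; an always-full unit with these stay lengths
necessarily admits more residents than a unit with partial occupancy
would.  Attributes: age ~ N(33.1, 7.5²) truncated to [18, 70], LSI-R
~ N(25.32, 6.05²) truncated to the observed [13, 40] and rounded, race
white with probability 0.91, matching the reference unit's reported
moments.

Events: staff feedback is exogenous — Poisson daily counts (defaults 2
affirmations, 1 correction per day; unreported for the reference unit
and exposed as configuration, never used as recovery truth) aimed at
uniformly random present residents, with corrections flagged as
head-turning with probability 0.05.  Resident ties are then drawn
dyad-by-dyad from the full model: covariates are computed from history
strictly before the day with the same engine the assembler uses (the
test suite asserts the generation-time and assembly-time design matrices
are identical), random effects use the reference variance components,
latent positions are N(0, 0.3²) per dimension (a modest residual dyadic
correlation), and each tie is Bernoulli(Φ(η)).  Same-day events never
see each other; all of a day's events enter history the next day.

Intercepts are calibrated so that mean simulated event volumes match
targets (the reference unit's 6,108 affirmations and 1,945 corrections,
pro-rated for shorter horizons).  Volumes respond monotonically to the
own-network intercept but the two networks couple through cross-network
covariates, so both intercepts are bisected jointly on shared
common-random-number simulations; a non-bracketed target raises a
diagnostic.  Because unit-level random effects are amplified by the
endogenous feedback terms, full-scale volumes vary by roughly ±15%
across seeds, and the bisection phase is followed by up to two secant
corrections (using the global log-volume/intercept slope) on a larger
seed batch, from which the achieved counts are reported.

What the generator does *not* emulate: free-text content, the
staff/senior-resident legitimacy review, reactive staff behaviour,
readmissions (a returning resident is a new id), dropout-versus-
completion structure, or any behaviour outside the fitted model class.
Passing recovery tests therefore shows the estimator is correct for
data from its own model class at realistic scale — not that the model
is a complete account of real units.

## Recovery experiments and problem sizes

Recovery experiments simulate a unit, assemble the design, refit, and
compare posteriors to the generating coefficients.  The standard runs
use a 16-bed unit over 150 days (null calibration: intercept-only truth,
ten-covariate fit, five replicates) or 300 days (headline recovery:
reference point estimates as truth on a minimal covariate subset
containing the targets, calibrated intercepts, five replicates, fits at
1,200 sweeps / 400 burn-in).  These sizes keep a full run in minutes on
one CPU while leaving each headline coefficient's per-replicate
posterior standard deviation at roughly 0.02–0.09 probit units.

A consequence worth stating plainly: at 300 days (half the reference
horizon) the per-replicate sampling error of a recovered coefficient is
comparable to the *width* of the tightest reference intervals (e.g.
±0.04 for affirmation reciprocity), and replicate-level density
fluctuations are amplified by the endogenous feedback terms.  Median
recovery over five replicates is accurate to a few hundredths, but
individual replicates can land outside a ±0.04 band with appreciable
probability; recovery checks against narrow intervals are inherently
stochastic at this scale.

## Known limitations

* The latent probit sampler mixes slowly for the day-variance component
  on short horizons; the diagnostics table flags this.
* Binary 1-day history coding is one defensible choice among several;
  archival analyses may have used different memory structures, and no
  numerical equivalence to any particular archival fit is claimed —
  only structural equivalence plus recovery of known truths.
* Staff rates and the head-turn share are guesses; covariates involving
  them (staff and HT terms) are simulated at plausible but unverifiable
  base rates.
* Roster turnover at full occupancy fixes co-presence at exactly the bed
  capacity; real units have vacancy gaps, which would thin the risk set.
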