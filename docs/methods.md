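# Methods

This note documents the statistical models, the sampler, the decision and
allocation machinery, the scenario generator, and the numerical and design
choices behind `platformsim`.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Trial structure

A two-arm comparison — medical management (MM, the reference arm, index 0)
versus endovascular thrombectomy plus medical management (EVT, index 1) —
run simultaneously in J mutually exclusive patient subgroups (J = 5 by
default: Large Core Only; Mild Deficit Only; Distal Occlusion Only; Distal
Occlusion + Large core; Distal Occlusion + Mild Deficit).  The endpoint is
binary (favorable 90-day outcome).  Enrollment follows Poisson weekly
accrual (52/week by default) to a fixed total (10,000), with analyses at
cumulative-enrollment milestones (every 2,500).  Participants enrolled
between consecutive milestones form one *analysis period*; at the a-th
analysis the drift model sees T = a periods, so the first interim carries
no drift terms.  The subgroup population mix is a required configuration
input; the shipped default is uniform (0.2 each), a documented placeholder
for a registry-derived mix rather than an empirical estimate.

Outcomes are assumed available at the analysis following enrollment: the
90-day ascertainment lag is deliberately not modeled.  This makes interim
information slightly "fresher" than in a real trial; with enrollment
blocks of 2,500 at ~52/week the lag spans roughly a fifth of a block, so
the simplification mainly matters if response rates change quickly.

## Posterior models

All models treat the favorable-outcome count in a subgroup-arm cell as
binomial with probability `P_jk`.

**Independent logistic.** `logit(P_jk) = β_jk ~ N(0, 1.82²)`,
independently per cell.  The prior SD 1.82 makes the implied distribution
of `P_jk` close to uniform; the equivalence is approximate and is not
enforced anywhere.

**Hierarchical beta-binomial.** `P_jk ~ Beta(m·P_k, m·(1−P_k))` with
`P_k ~ Beta(1, 1)`.  The borrowing strength `m` (> 0; default 30) is the
prior pseudo-sample size of the arm-level mean: `m = 1` is close to no
borrowing, `m = 30` pulls the five subgroup rates strongly toward `P_k`.
Larger `m` buys power in small subgroups at the cost of bias when the
subgroup truly deviates from the arm mean; the shrinkage is verified to be
monotone in `m` by the test suite.

**Hierarchical drift.** Final-period rates `P_jkT` follow the hierarchical
prior; earlier periods satisfy `logit(P_jkt) = logit(P_jkT) + θ_t` with
`θ_T = 0`, a first-order NDLM random walk `θ_{t−1} ~ N(θ_t, τ)`, and
`τ ~ InvGamma(0.25, 0.1)`.  **`τ` is interpreted as the random-walk
*variance***, the conventional reading of an inverse-gamma prior; a
precision or SD parameterization would change the amount of smoothing, so
the choice is stated prominently here.  With T = 1 the model reduces
exactly to the hierarchical model (verified within Monte-Carlo error by
the suite); `τ` is then drawn from its prior, which is what the conjugate
update yields with zero difference terms.

### Sampler

Metropolis-within-Gibbs, pure NumPy, vectorized across cells:

* `P_jk | P_k, data` in the hierarchical model is conjugate —
  `Beta(m·P_k + Y_jk, m(1−P_k) + n_jk − Y_jk)` — and is sampled directly.
* `P_k`, the independent-model `β_jk`, and the drift model's `logit(P_jkT)`
  use adaptive random-walk Metropolis (Robbins–Monro scale adaptation
  toward 0.44 acceptance during burn-in, frozen afterwards).
* `θ_t` uses one-at-a-time random-walk Metropolis on the identity scale;
  `τ | θ` is a conjugate inverse-gamma update.

Likelihoods are evaluated as `y·log p + (n−y)·log(1−p)`, well defined for
the fractional pseudo-counts (`Y = rate × n0`, e.g. 0.25 × 10 = 2.5);
binomial normalizing constants cancel and are omitted.  Default settings:
2 chains × 6,000 iterations with 1,000 burn-in and no thinning (10,000
retained draws).  Simulation sweeps use 1 chain × 1,500/500 (1,000 draws),
which resolves posterior probabilities to 0.001 — adequate for thresholds
up to γ = 0.9975.  Convergence is summarized by split-R̂ on the `P_jk`
draws and reported as a diagnostic flag; it never aborts a run, because a
simulated trial must always produce a decision.

Sampler correctness is established against *independent deterministic
oracles*: 1-D quadrature over the log odds for the independent model, and
a semi-analytic quadrature for the K = 1 hierarchical model that
marginalizes each `P_jk` in closed form (beta-function ratios) and
integrates the single remaining dimension `P_k` on a fine grid.  MCMC
means must agree within 3 Monte-Carlo standard errors (batch-means
estimate).

## Decision rules and allocation

Per analysis and per still-open subgroup, in order:

1. **Superiority** (strict): `P(P_j,EVT > P_j,MM) > γ` or the mirror image.
   Ties among draws count as "not superior", and both directions cannot
   fire simultaneously when γ > 0.5.
2. **Equivalence** (strict): `P(0.8 < OR_j < 1.2) > 0.7`, where
   `OR_j = odds(P_j,MM)/odds(P_j,EVT)`; declares the arms interchangeable
   and sends all future participants to the cheaper MM arm.
3. **Scheme**: fixed 0.5/0.5; RAR weights
   `w_k = sqrt(P(P_jk − P_jk′ > 0) · Var(P_jk)/(n_jk + 1))` normalized to
   1 (0.5/0.5 if both weights vanish); RARCOMP is exactly
   `(V_RAR + 0.5)/2`, hence always within [0.25, 0.75].

Decisions are **terminal**: a locked subgroup is never re-tested and its
one-arm allocation persists.  Reversal is never simulated because the
design never reverses a lock.  RAR probabilities are not epsilon-clipped;
a degenerate (0, 1) allocation is legitimate under pure RAR and RARCOMP
bounds it automatically.

The fixed scheme has no interim analyses; its superiority/equivalence
tests run once, at the final analysis.

**Pseudo-data.** Adaptive schemes prime their *initial* allocation by
fitting the configured model to a pseudo-dataset of `n0 = 10` observations
per cell with fractional successes `rate × n0` built from prior rate
estimates.  The pseudo-data never enter any interim or final analysis and
can never trigger a decision; they exist only so the first 2,500
participants are not randomized blindly at 1:1 under a scheme designed to
adapt.  The RAR weight's `n_jk` uses *real* current enrollment (zero at
the start); since the pseudo sample sizes are equal across arms this
choice does not affect the initial probabilities.

## Scenarios (the synthetic-data layer)

Five canonical scenarios define the truth per subgroup × arm: a null
("Equal", both arms at the pooled rates 0.10/0.70/0.35/0.25/0.75), the
anticipated effect ("Expected"), its mirror ("Reversed"), a larger effect
("ExtremeEVT"), and an effect confined to Large Core Only
("SingleSubgroup").  An optional drift profile adds
`θ = (0.75, 0.50, 0.25, 0)` to the log odds of the four analysis periods,
emulating response rates that start high and settle linearly to the
final-period truth.  Custom rate matrices and θ vectors are supported; the
only shipped profile is the linear one.

What the generator does *not* emulate: covariate-driven outcome
heterogeneity within subgroups, outcome ascertainment lag, missing data,
dropout, noncompliance, or accrual rates that vary over calendar time.
Passing operating-characteristic tests therefore demonstrate the design's
behavior under clean binomial sampling from the stated truths, not
robustness to those real-data complications.

## Operating characteristics and calibration

* **Familywise type-1 error**: the proportion of null-scenario trials with
  *any* superiority declaration — any subgroup, any analysis, either
  direction; one count per trial.  Equivalence declarations do not count
  (they change allocation, not the efficacy claim).  The familywise
  reading reflects the multiplicity over five subgroups and four analyses
  that a single calibrated γ must absorb.
* **Power**: per subgroup with a true difference, the proportion of trials
  declaring the *truly better* arm superior; wrong-direction declarations
  are not credited.  Subgroups with equal truth are type-1 cells and get
  no power value.
* **Patient benefit**: the gap between the proportion of favorable
  outcomes had every participant received the arm with the higher true
  rate *in their enrollment period*, and the observed proportion.  The
  period-specific best rate matters under drift.  Smaller is better.
* **γ calibration**: monotone bisection on an ascending γ grid (default
  0.95 … 0.999), returning the smallest evaluated grid value whose
  estimated familywise type-1 is ≤ the target — a conservative convention.
  Each evaluation simulates an independent batch of null trials.  Every
  reported rate carries the binomial Monte-Carlo SE `sqrt(p(1−p)/n)`.
  Drift-model runs reuse the thresholds calibrated on non-drifted nulls
  (and the RARCOMP-calibrated γ is reused for RAR in the desk-scale
  checks, consistent with adaptive-scheme thresholds calibrating to
  essentially the same value).

### Problem sizes

The full-scale design (10,000 participants, 10,000 simulated trials) is
available but long-running.  The shipped test suite and the acceptance
script use a desk-scale version chosen once: 1,000 participants with
analyses every 250 (preserving the four-analysis structure), 100–300
trials per operating-characteristic estimate, 200 trials per calibration
evaluation, and 1,500-iteration single chains.  Monte-Carlo SEs are
reported alongside every rate so the reduced precision is explicit.

## Reproducibility

All randomness derives from `numpy` `SeedSequence` substreams keyed by
`(master seed, trial id, purpose, analysis/period)`.  Repeated runs are
bit-identical; batches are invariant to execution order; any single trial
from a batch can be replayed in isolation.  Derived child seeds are
reduced modulo 2³¹.

## Known limitations

* Two arms only; no arm addition or dropping, and no K > 2 RARCOMP.
* No futility rule distinct from equivalence; no sample-size
  re-estimation.
* The equivalence→MM rule assumes MM is always the cheaper option.
* Convergence at the short simulation-sweep chain lengths is monitored
  but not enforced; posterior-probability estimates carry ~0.001–0.01
  Monte-Carlo granularity, which the calibrated γ implicitly absorbs.
* The uniform subgroup mix is a placeholder; operating characteristics in
  unequal mixes (where borrowing matters most for small subgroups) should
  be re-simulated with the intended proportions.
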