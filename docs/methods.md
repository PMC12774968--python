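# Methods

This package estimates apparent survival and population size of root
voles (*Microtus oeconomus*) from a robust-design live-trapping
experiment in which avian predators were excluded from half of the
plots, and asks how much the exclusion changed survival.  Everything is
exercised end-to-end on synthetic capture histories with known truth;
the same code accepts field data in the long CSV format.

## Robust-design Huggins model

Trapping follows the robust design: primary sessions (five consecutive
trapping days) separated by roughly two-month intervals.  Within a
session the population is closed; each day an available animal is
caught with probability `p` (capture and recapture equal, `p = c`).
Between sessions the population is open: an animal survives an interval
of `L` days with probability `S^(L/30)`, where `S` is apparent monthly
survival (mortality and permanent emigration are confounded, which is
the estimand the exclusion experiment needs), and is present on the
plot at a given session with probability `1 − γ` independently of its
previous availability (random temporary emigration, `γ′ = γ″`).

The likelihood is Huggins' conditional likelihood: each individual
contributes the probability of its history *after* its first capture,
given that first capture.  This removes abundance from the likelihood
entirely.  Concretely, the remaining days of the first-capture session
are independent Bernoulli(p) trials, and subsequent sessions are
handled by a forward recursion over three latent states — alive and
available, alive but off the plot, dead — with the transition and
emission structure above.  An off-plot or dead animal cannot be seen;
an animal captured in a session must have been available.  The
recursion is validated against brute-force enumeration of all state
sequences on every small instance (machine-precision agreement) and
against an independently coded two-state alive/dead recursion when
`γ = 0`.

Abundance per session, plot and location is recovered afterwards by
Horvitz–Thompson summation over the animals caught in that session,
`N̂ = Σ 1/p*`, with `p* = 1 − Π(1 − p)` the probability of at least one
capture in the session.  `N̂` estimates the animals alive *and
available*, and can never fall below the observed count.

Model structure is declared as terms on the logit of `S` and of `p`:
products of location, treatment, time, body mass, sex, cohort and (for
`p`) the ordinal trapping day within session.  Time enters either
categorically (optionally merging the last two levels, the standard
remedy when the final session leaves survival parameters inestimable)
or as a cubic B-spline basis with 3 or 4 degrees of freedom.  The
netting went up only after the first, pre-experimental session, so
every design row whose interval originates in that session carries a
zero treatment covariate: all plots share "control" parameters there.
At most 11 terms are allowed per model component.

Fitting is quasi-Newton (L-BFGS) from a zero start on the logit scale;
the covariance of the coefficient vector comes from the inverse
numerical Hessian (central differences, relative step 1e-5).  Fits are
flagged — not discarded silently — when the optimizer fails, when any
fitted real-scale probability leaves `[1e-6, 1 − 1e-6]`, or when a
coefficient variance is degenerate (< 1e-10 or > 1e6); flagged fits are
screened out before model ranking, mirroring the estimability screening
of the original analysis.

Choices made where the design was open: logit links throughout (the
field default); survival parameterized directly on the 30-day scale so
the fitted and reported scales coincide; conditioning on the first
capture occasion (occasions before it contribute nothing); `γ` a single
logit intercept, constant over intervals; age excluded from the default
term pool (it appears in no competitive structure) but expressible
through cohort; occasions within a session exchangeable apart from the
linear day covariate.

## Body-mass imputation

Body mass enters survival as an individual covariate and must exist for
every animal at every session, but is observed only at capture.  Vole
mass trajectories follow a small number of temporal patterns (stable
small animals, heavy overwintering adults, fast spring growers), so we
fit a finite Gaussian mixture over sex × session mean trajectories by
EM: class `g` has mean `m̄(g, s, t)` per sex `s` and session `t` and a
class-specific residual sd; each animal gets posterior membership
probabilities `P(c_i = g)`.  This replaces a latent-class linear
mixed-effects formulation with a plain finite mixture: the downstream
consumer needs only class means, memberships, and BIC, all of which the
mixture delivers, and it avoids random-effects machinery that the
deliverables never use.  The EM log-likelihood is non-decreasing by
construction; empty classes are reseeded within the restart budget;
convergence is a relative log-likelihood change below 1e-8 (cap 500
iterations); the best of `n_restarts` random initializations wins.
`BIC = −2 lnL + k ln(n_individuals)` counts mixing proportions,
residual sds, and estimated mean cells.

Two caveats worth knowing.  First, the weighted class mean is the
probability-weighted average `Σ m·P / Σ P` — the natural reading of
"mean weighted by class probabilities".  Second, with fully sex-specific
mean cells and no sex-linked class structure in the data, the
likelihood is invariant to permuting class labels *within one sex*;
class labels are therefore only interpretable per sex, and the recovery
test scores accuracy under the best per-sex label alignment (the
alignment the imputation consumes).

Imputation model-averages across the fitted class counts (3 and 4 by
default) with BIC weights `exp(−ΔBIC/2)`, normalized.  Each animal's
baseline curve is `Σ_g m̄(g, s_i, t) P(c_i = g)`; its imputed series is
the baseline plus the mean difference between observed mass and
baseline over the sessions where it was caught.  The offset has the
sign that makes the imputation pass exactly through a single
observation, and it forces the per-animal mean residual at captured
sessions to zero — both are algebraic identities and are asserted as
such in the tests.  Empty (class, sex, session) mean cells are filled
by linear interpolation across sessions and flagged.

## Model selection and averaging

Candidates are every marginality-respecting subset of the term pools
(an interaction never appears without its margins), expanded over the
allowed time forms.  Mandatory structure: survival always contains
location, time and body mass; capture always contains location × time.
Ranking uses `AICc = −2 lnL + 2k + 2k(k+1)/(n_eff − k − 1)` with
`n_eff` = number of individuals (the exchangeable unit under
per-individual conditioning; configurable).  Models with Akaike weight
above 0.001 are retained.

Averaged predictions are built by simulation rather than by averaging
coefficients: each retained model contributes multivariate-Gaussian
draws at `(β̂, V̂)` in proportion to its weight; the derived quantity —
monthly survival at a covariate profile, a treatment/control survival
ratio, a Horvitz–Thompson abundance — is evaluated per draw and the
pooled draws give the mean, the 2.5/97.5 percentile interval, and a
p-value against a null value: twice the fraction of draws on the null's
side of the mean at least as far from the mean as the null.  The
phrase admits a second reading (distance measured from the null); both
are implemented, the first is the default.  A p-value is never exactly
zero: with an empty tail it is reported at the resolution floor `1/n`.
Predictions plug in the mean observed body mass and sex ratio of the
captures at the prediction point, not grand means.

The default desk-scale candidate pool (20 models) varies the treatment
terms the experiment's question turns on — treatment, treatment × time,
treatment × body mass — over categorical and 3-df spline time forms and
a day effect on capture; the full study-scale pool is available behind
a flag.

## Goodness of fit

Fit is checked by parametric bootstrap: simulate every animal's
post-first-capture history from the fitted real-scale parameters (the
first capture stays where it was observed, matching the conditional
likelihood's support), refit the same structure, and record the
deviance; `p` is the fraction of bootstrap deviances at or above the
observed one and `ĉ` is observed deviance over mean bootstrap deviance.

Deviance is measured against the saturated multinomial over encounter
histories (animals grouped by first-capture occasion, one free
probability per distinct history within a group).  The saturated
reference is load-bearing: the raw maximized −2 lnL of a
Bernoulli-type model depends on the data essentially through total
capture counts — sufficient statistics — and so barely moves under
extra-binomial dispersion.  We verified this directly: under a strong
two-point mixture in `p`, raw-likelihood `ĉ` stayed at 1.00 while the
saturated-relative `ĉ` responds (≈ 1.1 at the default mixture), which
is why the saturated form is used.  Failed refits are dropped and
counted; above 20% failures the result is flagged unreliable.  The
bootstrap replicate count defaults to 100 and is configurable.

## The synthetic-data generator

The generator mirrors the fitted model's state structure plus the
things the model deliberately ignores, so both calibration and
misspecification can be studied.  The default scenario matches the
field study's scale: 3 locations × 2 plots, 7 bimonthly 5-day sessions
(session 1 pre-experimental), 74/65 animals initially per
treatment/control plot, deterministic recruitment of 30 per plot per
interval (deterministic so true abundance is known exactly), monthly
survival ≈ 0.75 for controls with a positive netting effect (≈ 0.90 at
the reference profile, i.e. control survival 15–20% lower), mild
location and body-mass effects on survival, per-day capture probability
0.40, random emigration γ = 0.1, and three mass-trajectory classes with
a 2 g sex effect, 1.5 g between-animal and 1 g within-animal noise,
masses rounded to 0.5 g like field readings.  γ has no field-estimated
generating value; 0.1 is a scenario choice.  All draws are made up
front with config-determined shapes, so a fixed seed is bit-reproducible
and raising a probability under the same seed can only add captures.

What the generator does *not* emulate: spatial structure (home ranges,
edge animals partially exposed to predators outside the netting),
trap-level saturation, behavioural trap response, Markovian emigration,
and individual survival heterogeneity beyond body mass.  Passing
recovery tests therefore demonstrate the estimators are correct under
the model's own assumptions and robust to the specific misspecification
studied (capture heterogeneity), not that field data meet those
assumptions.

## Problem sizes and numerics

Simulation studies use sizes chosen to give informative Monte Carlo
precision on a desk machine: likelihood-oracle checks enumerate ~2000
small instances exactly; survival CI coverage uses 150 replicates at
full study scale (coverage ±1.8% MC error, small against the 90–98%
acceptance band); abundance and relative-survival recovery use 50
replicates; the ĉ calibration uses 10 studies × 50 bootstrap
replicates at a reduced scale (5 sessions × 3 days, ~270 captured
animals) where the intercept-only refit is cheap.  Optimizer
tolerances: L-BFGS defaults, zero start; a likelihood evaluation floors
probabilities at 1e-300 before logging; abundance floors `p*` at 1e-12
(unreachable for captured animals at finite coefficients).  Stage seeds
in the pipeline derive from the master seed by fixed offsets so stages
re-run independently yet reproducibly.

## Known limitations

Temporary emigration is random only; Markovian emigration, dead
recoveries and multi-state extensions are out of scope.  `N̂` has no
closed-form variance — uncertainty comes from the averaging draws.
Quasi-AICc inflation by ĉ is available but off by default.  The
numerical-Hessian covariance can understate uncertainty for models near
estimability boundaries; such fits are screened out rather than
patched.  Bit-compatibility with program MARK is not attempted; the
likelihood itself is validated by enumeration instead.
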