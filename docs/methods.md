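# Methods

## The experimental structure the package models

Two players each control an avatar (a 4-unit object) on an invisible circle
of 600 units. A player's only percept is a binary vibration that is on
while their avatar overlaps one of the three objects they can feel: the
partner's avatar, the partner's *shadow* (an identical object rigidly
offset from the partner by 150 units), and the player's own static object.
Objects are half-open intervals `[x, x+4)` anchored at their left edge, so
touching edges do not count as contact; the shadow offset is applied in the
positive direction by default (the direction is not observable in the data
and is configurable, as is anchoring). Trials last 60 s; each player may
click at most once per trial to claim "I found the other", and afterwards
rates the clarity of the other's presence on the 4-point PAS. A session is
10 dyads × 20 trials by default; unbalanced sessions are supported.

## Click classification

The target of a click is the felt object nearest (torus distance between
anchors) to the clicker's avatar at the click time, interpolated linearly
along the shorter arc between trajectory samples. Anything farther than
`max_assign_distance` (default 8 units = two object lengths; the original
rule's radius is not published) is *unknown*. When the two nearest
candidates differ by less than `ambiguity_margin` (default 2 units) the
click is flagged for human review — this flag deterministically reproduces
the role of the manual trajectory inspection used in the original studies.
Exact ties (measure zero) resolve by the fixed priority avatar > shadow >
static; `radius_sensitivity` reports how all counts move with the radius.

## Outcome definitions

Per trial: a click is *correct* iff assigned to the partner's avatar
(shadow and static are both incorrect); *joint success* means both players
clicked and both were correct; the *inter-click interval* exists only when
both clicked, and the synchrony indicator D is 1 iff the interval is
strictly below the 3-s window (the boundary has measure zero; the strict
convention is fixed and documented). Under the null that both click times
are independent Uniform(0, T), the interval CDF is `1 − ((T−d)/T)²`, so
P(< 3 s) = 0.0975 at T = 60. Empirical interval densities use a Gaussian
KDE with mass reflected at 0 and T (Silverman bandwidth by default; the
original estimation method is unstated, so method and bandwidth are
options), and P(< d) is obtained by trapezoidal integration; a degenerate
all-equal sample is treated as a point mass.

## The hierarchical path model

Observation level (player-trial with a click, plus one joint-success
observation per trial):

* `S ~ Bernoulli(Φ(a_i + b_i (min(t, τS_i) − 1) + λS D))`
* `G ~ Bernoulli(Φ(c_j + λG D))`
* `Y ~ OrdProbit(u_i + v_i (min(t, τP_i) − 1) + γS S + γG G + γD D; κ)`,
  with `P(Y=k) = Φ(κ_k − η) − Φ(κ_{k−1} − η)`, `κ0 = −∞`, `κ4 = +∞`.

The piecewise predictor equals its intercept at trial 1, rises linearly to
the individual breakpoint τ ∈ [1, T], and is constant afterwards
(learning, then consolidation); slopes are constrained non-negative
(learning means improvement). When both dyad members have an observed PAS
in a trial, their latent ordinal residuals are bivariate standard normal
with correlation ρ, and the likelihood term is the rectangle probability
of the bivariate normal (Gauss–Legendre quadrature of the conditional-
normal representation; 32 nodes while sampling, 48 for standalone
likelihood evaluation, matching 2-D adaptive quadrature to well below
1e−6). Missing PAS responses (rare in this paradigm — a handful of clicks
historically received no rating) contribute nothing and are treated as
missing at random; trials without a click contribute no S or Y
observation, while D and G are defined at trial level regardless.

Joint success is modelled with its own probit submodel even though the
recorded G is a deterministic function of the two S values — this
reproduces the path structure in which synchrony acts on joint success
directly (`λG`) and joint success acts on clarity (`γG`). The indirect
synchrony → joint success → clarity pathway is summarised by the
draw-wise product `λG·γG`; an alternative contrast (difference in expected
PAS category under D=1 vs D=0 mediated through G, evaluated at the
population consolidation level of the PAS curve) is available.

### Priors and identification

The supplementary document with the original submodel equations was not
available, so the package declares its own weakly informative defaults
(all overridable): Normal(0, 2.5²) on regression effects and hyper-means
of intercepts; Half-Normal(1) on random-effect SDs; Half-Normal on the
non-negative slopes with Half-Normal(1) hyper-scale; breakpoints
TruncNormal(μτ, στ) on [1, T] with μτ ~ Uniform(1, T) and στ ~
Half-Normal(5); cutpoints Normal(0, 5²) under an ordering constraint; ρ ~
Uniform(−1, 1). Identification of the ordinal submodel is standard: latent
residual SD fixed at 1, hyper-mean of the PAS intercepts u fixed at 0,
three free cutpoints.

### Sampling

No gradient-based PPL is used; the posterior is sampled by an adaptive
random-walk Metropolis-within-Gibbs scheme designed for this model:

* Unit-level parameters are proposed in small blocks — `(a_i, b_i, τS_i)`,
  `(u_i, v_i, τP_i)`, `c_j` — and accepted per unit, **vectorised across
  dyads** (units in different dyads are conditionally independent). The
  PAS-side blocks run in two passes, one per dyad member, because the
  bivariate ρ-terms couple dyad-mates.
* Sampling happens in a **centered-covariate parametrization** (all probit
  covariates mean-centered; an exact reparametrization) which decorrelates
  the effect parameters from cutpoints and intercept fields; snapshots are
  converted back to the standard parametrization.
* Breakpoints mix through complementary moves: the per-unit blocks, a
  joint translation of a whole breakpoint field together with its
  hyper-location, a multiplicative group move rescaling `(τ − 1)` jointly
  with the hyper-location and hyper-scale (with the appropriate Jacobian),
  and an independence refresh from the hierarchical prior whose acceptance
  is the likelihood ratio only — breakpoints of non-learners re-mix
  immediately.
* The breakpoint hyper-parameters `(μτ, στ)` are drawn from their full
  conditionals, which depend on the field only through its sum and sum of
  squares: the conditional is tabulated on a fine grid and used as an
  independence-Metropolis proposal (acceptance ≈ 1), eliminating the
  random-walk bottleneck inside the breakpoint funnel.
* Proposal scales adapt toward 0.44 acceptance (0.30 for blocks) during
  warmup with a decaying Robbins–Monro schedule and are frozen afterwards.

Defaults are 2 chains × 800 warmup + 800 kept sweeps. Convergence is
reported (split R̂ and ESS via arviz) and surfaced as warnings, never
silently: the breakpoint hyper-means μτ are genuinely weakly identified
when many individuals have near-flat learning curves, and their wide HPDIs
and modest ESS reflect that. Fits are reproducible given a seed (each
chain gets an independent child stream). Degenerate data (e.g. all
successes) produce a prior-dominated fit with a warning. Parameters can be
pinned via `McmcConfig.fixed`, which is how the no-learning reduction to a
plain probit is tested against an independent maximum-likelihood fit.

HPDI: the narrowest interval containing the requested mass of the sorted
draws (requires ≥ 100 draws).

### What "average breakpoint" means

On a bounded trial range the *location* parameter μτ of the truncated-
normal breakpoint hierarchy is only weakly identified: a low location with
a large scale and a central location with a moderate scale imply nearly
the same breakpoint distribution on [1, 20] (e.g. TruncN(2.5, 4.8) and
TruncN(5.1, 2.5) both have mean ≈ 5.4). The data inform the breakpoint
*distribution*, not the parametrization, so posteriors for μτ alone can
sit far from the generating location while fitting perfectly — a behaviour
confirmed by an independent implementation of the identical model in a
general-purpose Gibbs sampler, which reproduces this package's posterior.
The identified "average breakpoint" quantity is the **mean of the
truncated breakpoint distribution**, reported as `mean_tau_S` /
`mean_tau_P` (derived per draw from μτ and στ) alongside the raw
locations; calibration studies cover the derived means against the
generator's implied values.

## Synthetic data: what it emulates, and what it does not

The event-level generator draws from the model above with a default truth
chosen to emulate the study's published marginals: 10 dyads × 20 trials ×
60 s; click probability 0.80; PAS missingness 1.3%; intercept hierarchy
giving ≈72% correct clicks at consolidation; breakpoint hyper-means 3.2
(success) and 5.1 (PAS); effects λS = 0.70, λG = 1.01, γS = −0.16,
γG = 0.69, γD = 0.14; ρ = 0; cutpoints (−0.85, 0.55, 1.60) calibrated once
so the marginal PAS distribution is ≈ (6, 30, 33, 31)%. Click times in
both-click trials follow a synchrony mixture: with p_sync = 0.15 the two
clicks are separated by an Exponential(mean 1.5 s) gap, otherwise both are
independent Uniform(0, 60) — p_sync was set so the marginal share of
< 3 s intervals matches the study's; the resulting *conditional* contrast
between joint and non-joint trials has the right sign but is milder than
the study's (0.25 vs 0.14), because here synchrony raises joint success
only through λS.

Two joint-success modes exist by design. `generate_events` derives G as
"both clicked and both correct", so the event files are internally
consistent and the descriptive pipeline recomputes exactly the G that
generated the PAS. `generate_model_data` instead draws G from its own
probit submodel (team intercepts μc = −0.43, σc = 0.4, effect λG) — the
exact generative counterpart of the fitted model, which is what makes
HPDI-coverage calibration of λG well defined. The recovery suite uses the
latter; end-to-end pipeline tests use the former.

The behavioural generator drives the torus simulator with search-and-dwell
controllers (sweep at 35–75 units/s until contact; oscillate locally while
in contact; click with hazard 0.8/s after 0.8 s of sustained contact).
These are stress-test stand-ins, not models of human players: they produce
realistic *geometry* (clicks during contact with a known intended target,
which classification must recover) but none of the contingency-seeking
dynamics of real interaction. Passing tests therefore validate the
pipeline's mechanics on data of known provenance; they do not certify the
behavioural realism of any controller, nor how the model would fit human
data.

## Problem sizes and numerical choices

The recovery calibration refits 10 replicates of 40 dyads × 20 trials
(2 × 700 + 700 sweeps each) and requires each 95% HPDI to cover the
generating value in ≥ 8/10 replicates for γG, λG, λS, γS and the two mean
breakpoints (the identified estimands; see above). The
acceptance script runs the full pipeline at the study's design size
(10 dyads). Interval Monte-Carlo oracles use 10⁶ uniform pairs; HPDI
oracle 10⁶ normal draws; likelihood oracle 2-D adaptive quadrature.
Probabilities are floored at 1e−300 before logs; binary probit terms use
`log Φ` directly for stability; probit tail arguments are clipped at ±9
where the neglected mass is < 1e−18.

## Known limitations

* The sampler trades gradient information for simplicity: effective sample
  sizes on strongly coupled parameters (cutpoints, γS, the breakpoint
  hyper-means) are modest at default settings, and the diagnostics say so.
* The converter for the original study's raw log dialect is a documented
  stub; real data must be exported to the `events.csv` schema first.
* Ambiguity flags reproduce *which* clicks a human would have reviewed,
  not the review outcome itself.
* The KDE-based interval P(< 3 s) depends mildly on bandwidth near the
  0-boundary; the analytic null does not.
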