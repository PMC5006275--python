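# Methods

## Designs

Four design variants are encoded (`tvsmart.design.DesignSpec`). In the
*time-varying* variants, outcome monitoring starts at `t00` and a subject
becomes a responder at the first time `T1 < t10` the responder rule is met
(`absolute_drop`: `Y0 − Y1 ≥ C`; `relative_drop`: `Y1 ≤ (1−f)·Y0`);
non-responders are censored at `t10` (`δ = I(T1 < t10)`). In the *standard*
variants everyone is assessed and re-randomized at `t10`. In `full_rerand`
variants responders are re-randomized between continuing (+1) and reducing
(−1) their first-stage intervention; in `nonresp_rerand` variants responders
always continue (`A2R ≡ 0`). Non-responders are always re-randomized between
intensifying (+1) and augmenting with the other intervention type (−1).
Every subject stays on the second stage for the fixed `Δt`, so `T2 = T1 + Δt`.

Defaults (`t00 = 0.1`, `t10 = 1`, `Δt = 1`, all randomization probabilities
0.5, `C = 9`) are the conditions of the motivating smoking-cessation
example, where one month is the natural time unit for both stages.

An *embedded adaptive intervention* (AI) is a decision rule
`(a1, a2r, a2nr)` — 8 per `full_rerand` design, 4 (`(a1, a2nr)`) per
`nonresp_rerand` design — enumerated in a fixed lexicographic order (−1
before +1) that also serves as the deterministic tie-break everywhere an
extremum over AIs is taken.

## Data generators

**Weibull mechanism** (primary). Per subject: `b ~ N(0, σ_b²)`;
`Y0 = β00 + b + ε0`; `A1` randomized; `T1*` drawn from a Weibull with shape
`k` and scale `exp{γ0 + γ1·A1 + α·m(0)}` left-truncated at `t00` (inverse
CDF of the conditional distribution), where `m(0) = β00 + b` is the latent,
error-free baseline; censoring at `t10` sets `δ`. The intermediate residual
`ε1` is then re-drawn by pure rejection until the responder rule matches
`δ` (cap 10⁶ rounds; hitting it signals an infeasible threshold/variance
combination). `Y2` uses fresh `ε2`. "Scale" is the standard convention
`S(t) = exp{−(t/scale)^k}`.

Two consequences of this mechanism matter for everything downstream:

1. *Endogeneity by construction.* With `α > 0`, high-`b` subjects have long
   response times, so `cov(b, T2) > 0` and a model that treats `T2` as
   exogenous overstates `β32`. This is the phenomenon the package exists to
   study, not a defect.
2. *The stage-1 submodel is deliberately misspecified.* Conditioning `ε1`
   on response status makes the realized `Y1` law a status-dependent
   truncated normal: responders' `Y1` is pulled down by about
   `σ1·√(2/π) ≈ 4` and censored subjects' up by the same amount. Maximum
   likelihood absorbs this into `β01`, `β31`, the variance components, the
   event intercept `γ0`, the association `α` and the Weibull shape — so
   those parameters are *not recoverable* by any estimator, under either
   model. The baseline mean `β00`, the final-outcome block
   (`β02, β12, β22, β23, β32, β41, β42`) and the hazard arm effect `γ1` are
   untouched and recover within Monte-Carlo error (verified at n = 10⁴).
   Replication summaries therefore show near-zero coverage for the stage-1
   block even for a "correct" fit; read them as mechanism artifacts.

**Boundary-crossing mechanism** (alternate). `ε1` is drawn once and `T1*`
solves the linear crossing equation
`β01 + β11·A1 + β31·T1* + b + ε1 = (1−f)·Y0`; crossings before `t00` are
moved to `t00` (responders), trajectories not crossing by `t10` are censored
there. The printed source rule maps late crossings to `t00`, which would
violate `δ = I(T1 < t10)`; we treat that as a typo and censor at `t10`,
keeping the literal rule behind `literal_clamp=True` for auditing. Under
this mechanism `Y1 = (1−f)·Y0` *exactly* for interior crossers, which puts a
`σ1 → 0` ridge into both likelihoods; fitted values on such data sit on that
ridge and should be treated qualitatively. The Weibull mechanism is the
validated path.

## TVMEM estimation

Subject `i`'s outcome vector is trivariate normal with covariance
`σ_b²·J + diag(σ0², σ1², σ2²)`, inverted in closed form (rank-one update).
The mean coefficients are profiled out by GLS at each variance iterate and
the (log-scale) SDs optimized by L-BFGS-B from a method-of-moments start,
with one fallback restart from an even variance split. Standard errors come
from the inverse observed information (numerical Hessian over the full
parameter vector, log-SD scale for variance components; SD-scale SEs by the
delta method, CIs transformed from the log scale). ML, not REML, for
comparability with the joint likelihood. Stage residual variances are free
by default (`shared_resid_var` collapses them); `fix_sigma_b=0` reduces the
fit to per-stage OLS exactly (tested). Columns that the data cannot identify
— the constant `T1`/`T2` of standard-design data, or the all-zero `A2R`
block of `nonresp_rerand` designs — are dropped automatically and reported
in `dropped_terms`. The implementation is verified against `nlme::lme`
(ML, `varIdent` residuals) to full printed precision on a reference dataset.

## Joint model estimation

The joint likelihood per subject integrates
`p(T1, δ | b) · Π_j p(Y_j | b) · p(b)` over `b` with Gauss–Hermite
quadrature (default 15 nodes, log-sum-exp accumulation). Quadrature is
*adaptive*: recentred at each subject's empirical-Bayes posterior from the
longitudinal block, where that posterior is exactly Gaussian — making the
rule exact for the longitudinal factor and accurate for the event factor.
Plain (prior-centred) GH with 15 nodes is not adequate here: with
`σ_b = 5` the posterior (SD ≈ 2.4) can sit many node-spacings from zero.
During optimization the centres are frozen at the warm start so the
objective is smooth; analytic gradients (verified against finite
differences at 1e-6) drive L-BFGS-B, warm-started from the TVMEM fit plus a
censored constant-hazard regression with plug-in `m(0)`. The variance
parameters are box-bounded within `e^±3` of the warm start to keep the
optimizer off the degenerate-generator ridge described above. SEs come from
the inverse observed information, with the Hessian formed by differencing
the analytic gradient; a non-positive-definite Hessian is reported with its
smallest eigenvalue and flags the fit as non-converged.

The hazard is `h(t) = h0(t)·exp{γ1·A1 + α·m(0)}` with `m(0) = β00 + b` —
association through the latent baseline only, keeping the integral
one-dimensional. `h0` is Weibull (shape estimated, log-scale absorbed into
`γ0`) or optionally piecewise-constant with knots at responder-`T1`
quantiles. Left truncation at `t00` is OFF by default — matching how such
models are commonly fitted and empirically reproducing the study's slight
downward bias in `β32` (≈1.8 vs truth 2.0); `truncate_at_t00=True` gives
the conditional likelihood and an unbiased `β32`. Note the parameterization
flip: the generator's *scale* coefficients appear negated (times `k`) on
the fitted proportional-hazards scale, so a correctly specified fit
recovers `γ1 ≈ −0.4`, `α ≈ −0.25` for generating values `0.4, 0.25`.

## Embedded-AI means, power, cost

*Simulated* AI means average `Y2` over all subjects (pooled across
replicates) consistent with the AI — first-stage arm equal, and the
second-stage option received matching what the AI dictates for the
subject's own response status; an AI with no consistent subjects is
reported missing, never zero. *Estimated* (plug-in) AI means average the
fitted final-outcome predictor over the subjects of the AI's arm, with the
second-stage indicators set by the AI and each subject's own response
status and `T2`, and `b = 0`; response-status proportions thus enter at
their empirical per-arm frequencies. Both models' plug-ins agree to ~3
decimals on the same data even where the TVMEM coefficients are biased,
because least-squares-type fits reproduce cell means.

*Power* is the fraction of replicates in which the extremal estimated AI
mean belongs to the truly optimal AI, determined per design from one
oracle simulation of 10⁵ subjects at the generating parameters. The
selection direction is a flag; the default is `maximize` (with these
scenarios both directions give identical selection rates, so the data do
not distinguish them). The time-varying design is analyzed with the joint
model; the standard design — whose event time is constant — with the
TVMEM.

*Cost* is linear: stage 1 charges the arm's unit-time cost (`c1`
medication, `c2` behavioral) for the realized `T1` (time-varying) or for
`t10` (standard pricing, also applicable to the same simulated subjects
for a paired comparison); stage 2 charges `Δt` at the option's rate —
continue `c`, reduce `c/2`, intensify `2c`, augment `c1 + c2`. Since total
cost is linear in `(c1, c2)`, the cost surface over a price grid is
computed from two unit-price evaluations per replicate.

## Reproducibility and problem sizes

Every stochastic routine takes a seeded `numpy` Generator; replicate `k` of
a study uses the stream `SeedSequence(entropy=seed, spawn_key=(k,))`, so any
single replicate can be re-run in isolation and identical seeds give
bit-identical data. The acceptance script runs 100 fitting replicates of
n = 1000 (the study's tables used 500) and 1000 cost replicates; Monte-Carlo
standard errors at those sizes are ~0.02–0.07 for coefficient means, ~3
percentage points for coverage/power, ~1.6 cost units for mean cost.

## Known limitations and discrepancies

* The published Monte-Carlo dispersion for the reference scenario (CI
  length 0.478 for `β12`, i.e. SE ≈ 0.122) lies below the information
  floor `σ2/√n = 0.158` implied by the stated residual SD 5 at n = 1000,
  so the printed CI lengths, estimate SDs, the exact coverage values and
  the 0%-coverage claim for `β32` cannot be produced by any estimator
  under the stated generative parameters. This package reproduces the
  published Monte-Carlo *means* closely (e.g. joint `β12` 0.41 vs 0.407,
  joint `β32` 1.80 vs 1.790, TVMEM `β12` 0.29 vs 0.275, TVMEM `β32` 3.8
  vs 4.07) while its dispersion-dependent quantities differ in the
  direction that analysis predicts (higher TVMEM coverage, nonzero `β32`
  coverage, slightly higher selection power).
* Stage-1 parameters are not identified under the rejection-conditioned
  generator (see above); this is a property of the mechanism, shared by
  any estimator.
* The boundary-crossing generator induces a degenerate likelihood ridge;
  fits on such data are qualitative.
* Baseline covariates `Z`/`W` are plumbed through the model surface but
  default to absent, as in every simulated scenario; weighting schemes,
  >2-stage designs, random slopes and spline baselines are out of scope.
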