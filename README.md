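# tvsmart

Simulation and estimation toolkit for **time-varying SMART designs** —
two-stage sequential multiple assignment randomized trials in which each
responder is re-randomized to second-stage options at their own random
response time `T1` instead of at a fixed interim visit.

## The problem

In a standard two-stage SMART every participant is assessed at a fixed time
`t10`, then re-randomized. If the first-stage intervention is costly or has
side effects (the motivating example is smoking cessation: medication M vs
behavioral intervention B, outcome = cigarettes/day), there is a case for
moving a subject on as soon as a pre-fixed improvement threshold is crossed.
That makes the first-stage duration a subject-specific random variable
(monitored from `t00`, censored at `t10`), and the usual SMART regression
machinery no longer applies: the duration is *endogenous* — slow responders
tend to be subjects with high latent outcome levels.

`tvsmart` implements the two analytic models appropriate for such designs
and the full Monte-Carlo machinery to study them:

* **TVMEM** — a time-varying (piecewise) mixed effects model: three stacked
  Gaussian submodels sharing one subject random intercept
  `b_i ~ N(0, σ_b²)`,

  ```
  Y0 = β00                                               + b + ε0
  Y1 = β01 + β11·A1 + β31·T1                             + b + ε1
  Y2 = β02 + β12·A1 + β22·A2R + β23·A2NR + β32·T2
            [+ β41·A1·A2R + β42·A1·A2NR]                 + b + ε2
  ```

  with `T1`, `T2 = T1 + Δt` treated as known covariates and arm coding
  `A1 = −1` (M) / `+1` (B); `A2R = +1` continue / `−1` reduce (responders),
  `A2NR = +1` intensify / `−1` augment (non-responders), `0` = not
  applicable.

* **Joint model** — the same longitudinal submodels plus a relative-risk
  submodel for the time to response,

  ```
  h_i(t) = h0(t) · exp{ γ1·A1 + α·m_i(0) },   m_i(0) = β00 + b_i ,
  ```

  with Weibull (or piecewise-constant) baseline `h0`, fitted by maximum
  likelihood with the random intercept integrated out by adaptive
  Gauss–Hermite quadrature. Because the hazard shares `b_i` with the
  outcomes, this model de-confounds `β12` and `β32`.

On top of the estimators sit a trial simulator (Weibull event times with a
rejection-sampled responder rule, or a boundary-crossing mechanism),
embedded adaptive-intervention (AI) mean estimation, a replication engine
(bias / MSE / CI coverage / CI length), optimal-AI selection power, and a
linear trial-cost model comparing the time-varying design with its standard
fixed-time analog.

## Worked example

```python
import tvsmart as tv

cfg  = tv.load_scenario("table1")          # shipped scenario preset
data = tv.simulate_trial(cfg.design, cfg.params, 1000, tv.replicate_rng(7, 0))
tvmem = tv.fit_tvmem(data)
joint = tv.fit_joint(data)
```

Running `python examples/02_fit_models.py` (which does exactly this) prints

```
truth: beta12 = 0.4, beta32 = 2.0

TVMEM beta12 =  0.167  beta32 =  4.354 [3.041, 5.668]  (loglik -9315.5, converged=True)
joint beta12 =  0.312  beta32 =  1.866 [0.572, 3.161]  (loglik -9820.4, converged=True)
```

The stacked model, treating the duration as exogenous, estimates the time
effect `β32` at 4.35 — more than double the generating value 2.0 — because
subjects with a high latent level both respond late and smoke more at exit.
The joint model's hazard submodel absorbs that association (its fitted
association is negative: `alpha ≈ −0.20`, higher baseline level → lower
response hazard) and returns `β32 = 1.87` with an interval covering the
truth. The `examples/` directory has one short script per capability
(simulation, fitting, replication study, power, cost), each printing what
its numbers mean.

A thin CLI wraps the same functions:

```bash
tvsmart simulate  --config table1  --seed 3 --out trial.csv
tvsmart fit       --data trial.csv --model joint --out fit.csv
tvsmart replicate --config table1  --R 50 --seed 7 --out summary.csv
tvsmart power     --config table11 --R 50 --seed 7 --out power.csv
tvsmart cost      --config table13 --c1 2 --c2 1 --out costs.csv
```

Scenario presets (`table1`, `table3`, `table5`, `table7`, `table9`,
`table11`, `table12`, `table13`) encode the simulation scenarios of the
underlying study; `tv.load_scenario` also accepts a path to your own YAML
file in the same four-block format (design / params / replication /
evaluation).

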