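"""Fit both analytic models to one simulated trial and compare them.

The stacked mixed model (TVMEM) treats the intervention durations T1/T2 as
known covariates; the joint model adds a Weibull hazard for the time to
response sharing the subject-level random intercept.  Because slow
responders tend to be subjects with high latent smoking levels, the TVMEM's
time coefficient beta32 is confounded upward; the joint model corrects it.
"""

import tvsmart as tv

cfg = tv.load_scenario("table1")
data = tv.simulate_trial(cfg.design, cfg.params, 1000, tv.replicate_rng(7, 0))

tvmem = tv.fit_tvmem(data)
joint = tv.fit_joint(data)

print(f"truth: beta12 = {cfg.params.beta12}, beta32 = {cfg.params.beta32}\n")
for name, fit in (("TVMEM", tvmem), ("joint", joint)):
    b12, b32 = fit.params["beta12"], fit.params["beta32"]
    lo, hi = fit.conf_int.loc["beta32"]
    print(f"{name:5s} beta12 = {b12:6.3f}  beta32 = {b32:6.3f} "
          f"[{lo:.3f}, {hi:.3f}]  (loglik {fit.loglik:.1f}, "
          f"converged={fit.converged})")
print("\nThe joint model's beta32 interval covers the truth; the TVMEM's "
      "typically does not.")
print("Event submodel (proportional-hazards scale):",
      joint.params[["gamma0", "gamma1", "alpha", "weibull_shape"]].round(3).to_dict())
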