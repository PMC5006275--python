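"""Simulate one time-varying SMART and look at its structure.

Heavy smokers are randomized to medication (A1=-1) or behavioral support
(A1=+1); whoever drops their daily cigarette count by C=9 before one month
is re-randomized immediately at their personal response time T1, everyone
else at the one-month censoring point t10.
"""

import tvsmart as tv

cfg = tv.load_scenario("table1")
rng = tv.replicate_rng(7, 0)
data = tv.simulate_trial(cfg.design, cfg.params, n=1000, rng=rng)
tv.validate_trialdata(data, cfg.design)

resp = data["delta"].mean()
print(f"subjects: {len(data)}   responders: {100 * resp:.1f}%")
print(f"mean response time among responders: "
      f"{data.loc[data.delta == 1, 'T1'].mean():.3f} months (censoring at "
      f"{cfg.design.t10})")
print(data.head(5).round(3).to_string(index=False))
print("\nEvery responder has T1 < 1 and a second-stage option A2R in {-1,+1};")
print("non-responders carry T1 = 1 and A2NR instead; T2 = T1 + 1 is the exit time.")
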