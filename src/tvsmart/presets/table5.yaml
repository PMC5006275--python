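# Fig.-2 time-varying SMART (only non-responders re-randomized), no interactions
design:
  variant: nonresp_rerand_timevarying
  p_stage1: 0.6          # P(A1=+1, behavioral); medication gets 0.4
  p_stage2_resp: 0.5     # ignored: responders always continue
  p_stage2_nonresp: 0.45 # P(A2NR=+1, intensify); augment gets 0.55
  t00: 0.1
  t10: 1.0
  delta_t: 1.0
  responder_rule: absolute_drop
  threshold: 9.0
params:
  beta00: 10.0
  beta01: 1.0
  beta11: 0.2
  beta31: 0.1
  beta02: 0.0
  beta12: 0.45
  beta22: 0.0
  beta23: 0.40
  beta32: 2.0
  beta41: 0.0
  beta42: 0.0
  sigma_b: 5.0
  sigma0: 4.0
  sigma1: 5.0
  sigma2: 5.0
  gamma0: -1.5
  gamma1: 0.4
  alpha: 0.25
  weibull_shape: 1.0
replication:
  R: 500
  n: 1000
  seed: 0
  estimators: [tvmem, joint]
  mechanism: weibull
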