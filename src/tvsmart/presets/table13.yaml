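# Cost comparison under the Fig.-1 generative scenario (no fitting needed)
design:
  variant: full_rerand_timevarying
  p_stage1: 0.5
  p_stage2_resp: 0.5
  p_stage2_nonresp: 0.5
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
  beta12: 0.4
  beta22: 0.5
  beta23: 0.5
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
  R: 1000
  n: 1000
  seed: 0
  estimators: []
  mechanism: weibull
evaluation:
  c1: 2.0
  c2: 1.0
  c1_grid: [0.5, 1.0, 1.5, 2.0]
  c2_grid: [0.5, 1.0, 1.5, 2.0]
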