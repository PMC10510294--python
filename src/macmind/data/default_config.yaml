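# Default macmind configuration.
#
# Descriptor values follow the standard hyper-parameter set
# (K=2, L=2, R1=R2=5).  The two sources for the scale weights disagree
# (0.3/0.7 in one place, 0.7/0.3 — also reported as the optimal ratio —
# elsewhere); the library default is alphas = (0.7, 0.3) with the small
# scale weighted more.  Swap the entries to use the other reading.
descriptor:
  L: 2
  R1: 5
  R2: 5
  K: 2
  alphas: [0.7, 0.3]
  Na: 8
  Nr: 2
  Nh: 2
  eps_rel: 1.0e-6

# Loss weights (lambda_sim, lambda_label, lambda_smo).
loss:
  lambda_sim: 20.0
  lambda_label: 2.0
  lambda_smo: 0.5

registration:
  metric: macmind
  levels: [4, 2]
  iterations: [40, 30]
  step: 1.0
  field_sigma: 4.0
  tol: 1.0e-6
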