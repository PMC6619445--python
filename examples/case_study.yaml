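design:
  K: 1
  N2: 100
  alpha: 0.025
  n1:
    0: 27
    1: 53
  sigma2:
    0: 156.75709999999998
    1: 192.0996
    2: 192.0996
epsilon: 0.0
grids:
  priors:
    arm: 1
    means:
    - -10.0
    - -5.0
    - 0.0
    - 5.0
    - 10.0
    variances:
    - 1.0
    - 5.0
    - 10.0
plans:
  add:
    0: 33
    1: 33
    2: 34
  no_add:
    0: 32
    1: 68
priors:
  1:
    mean: 0.0
    variance: 10.0
  2:
    mean: 5.0
    variance: 10.0
simulation:
  n_sims: 20000
  policy: never_add
  seed: 1
  true_means:
    0: 0.0
    1: 0.0
    2: 0.0
stage1:
  0: 5.0
  1: 8.0
utility: count
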