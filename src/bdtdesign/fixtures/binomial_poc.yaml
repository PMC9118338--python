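# Single-arm proof-of-concept trial with a binomial response endpoint
# (objective response rate in non-small-cell lung cancer): H0: theta <= 0.075,
# relevance threshold 0.175.  The sponsor's analysis prior is the RSN
# Beta(0.0811, 1) with mean 0.075; the informative prior Beta(11, 29) encodes
# a historical study with 10 responses out of 38 under a uniform baseline.
name: binomial_poc
model:
  family: binomial
hypotheses:
  theta0: 0.075
  thetaR: 0.175
analysis_priors:
  rsn:
    kind: beta
    a: 0.0811
    b: 1.0
  informative:
    kind: beta
    a: 11.0
    b: 29.0
  robust_mixture:
    kind: mixture
    components:
      - {kind: beta, a: 11.0, b: 29.0}
      - {kind: beta, a: 1.0, b: 1.0}
    weights: [0.5, 0.5]
  eb_power:
    kind: power
    historical: {n0: 38, successes: 10, failures: 28}
    baseline: {kind: beta, a: 1.0, b: 1.0}
    a0: empirical_bayes
sampling:
  prior:
    kind: beta
    a: 11.0
    b: 29.0
  grid:
    kind: beta
    means: [0.1, 0.15, 0.2, 0.25, 0.275, 0.3, 0.35]
    strength: 40.0
costs:
  c0p: 0.05
  c1p: 0.95
  mode: bf_reweighted
goals:
  type1_max: 0.15
  type2_max: 0.2
  indeterminate_max: 0.1
phase3:
  target_power: 0.9
  alpha3: 0.025
  zeta: 0.2
numerics:
  n_grid: {start: 1, stop: 150, step: 1}
  smoothing:
    smooth_sate: true
    smooth_amse: true
    bandwidth_sate: 101
    bandwidth_amse: 15
output:
  directory: results/binomial_poc
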