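# Default prior configuration for MAP inversion of the three-level
# mean-reverting HGF. Means and variances are given in estimation space:
# identity for means/omega, log for variance-like parameters and kappa,
# logit for the AR(1) rates phi2/phi3. Zero variance fixes a parameter.
# The level-3 attractor m3 is tied to mu3_0 (tie_m3), the usual convention
# for mean-reverting configurations where the attractor prior equals the
# initial mean.
parameters:
  mu3_0:    {mean: -2.6, variance: 1.0}
  sigma3_0: {mean: 0.0, variance: 0.0}        # log(1.0)
  mu2_0:    {mean: 0.0, variance: 0.0}
  sigma2_0: {mean: 0.0, variance: 0.0}        # log(1.0)
  kappa:    {mean: -1.6094379124341003, variance: 0.0}   # log(0.2)
  omega:    {mean: -0.5, variance: 0.0}
  theta:    {mean: -2.302585092994046, variance: 0.0}    # log(0.1)
  phi2:     {mean: -2.9444389791664403, variance: 0.0}   # logit(0.05)
  m2:       {mean: 0.0, variance: 0.0}
  phi3:     {mean: -2.9444389791664403, variance: 0.0}   # logit(0.05)
  m3:       {mean: -2.6, variance: 0.0}
options:
  tie_m3: true
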