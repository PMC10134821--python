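# Noisy-prior variant of the equal-leakage inference: every
# literature-estimated kinetic parameter (shared by both strains) gets a
# one-decade log-uniform prior around its default instead of a point mass,
# representing increased parameter uncertainty.  Volumes stay fixed.
name: noisy
statistic_mode: mean
t_statistic: 48.0
k: 2.0
observed:
  mean: 1.14
  sd: 0.235
priors:
  - {name: d, kind: log_uniform, center: 3.88e-5, decades: 1.0}
  - {name: e_leak, kind: log_uniform, low: 1.0e-2, high: 10.0}
  - {name: vmax_glc, kind: log_uniform, center: 10.0, decades: 1.0}   # mmol/(gDW h)
  - {name: km_glc, kind: log_uniform, center: 0.05, decades: 1.0}     # mmol/L
  - {name: vmax_aa, kind: log_uniform, center: 1.0, decades: 1.0}     # mmol/(gDW h)
  - {name: km_aa, kind: log_uniform, center: 0.01, decades: 1.0}      # mmol/L
  - {name: y_glc, kind: log_uniform, center: 0.09, decades: 1.0}      # gDW/mmol
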