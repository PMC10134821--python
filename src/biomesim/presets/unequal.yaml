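# Unequal-leakage inference: lysine and isoleucine leakage sampled
# independently; diffusion fixed at the measured mean rate; a draw is
# accepted only if BOTH strains' statistics fall inside their windows.
name: unequal
statistic_mode: per_strain
t_statistic: 48.0
k: 10.0                       # acceptance half-width, in units of each strain's sd
observed:
  mean: {dLys: 0.925, dIle: 1.35}   # per-strain observed log10 growth ratios
  sd: {dLys: 0.015, dIle: 0.026}
priors:
  # membrane diffusion rate fixed at the measured mean (L/h)
  - {name: d, kind: point, value: 3.88e-5}
  # per-amino-acid leakage stoichiometries (mmol/gDW), three decades each
  - {name: e_lys, kind: log_uniform, low: 1.0e-2, high: 10.0}
  - {name: e_ile, kind: log_uniform, low: 1.0e-2, high: 10.0}
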