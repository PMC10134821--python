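# Equal-leakage inference: both amino acids share one leakage stoichiometry;
# diffusion rate and leakage are free, kinetic parameters stay at defaults.
name: equal
statistic_mode: mean          # single statistic = mean of the two strains' log10 ratios
t_statistic: 48.0             # hours at which yields are compared
k: 2.0                        # acceptance half-width, in units of the observed sd
observed:
  mean: 1.14                  # experimentally observed log10 growth ratio (pooled mean)
  sd: 0.235                   # its standard deviation
priors:
  # membrane diffusion rate (L/h): one decade centered on the measured mean
  - {name: d, kind: log_uniform, center: 3.88e-5, decades: 1.0}
  # leakage stoichiometry (mmol leaked per gDW formed): three decades
  - {name: e_leak, kind: log_uniform, low: 1.0e-2, high: 10.0}
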