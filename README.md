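# biomesim

Modelling and inference toolkit for membrane-separated coculture devices —
transwell-style plates in which pairs of wells exchange metabolites, but not
cells, through a porous membrane. It is written for microbial-ecology and
systems-biology labs that use such devices to quantify cross-feeding: the
running example throughout is a syntrophic pair of *E. coli* amino-acid
auxotrophs (ΔLys, which needs lysine and leaks isoleucine, and ΔIle, which
needs isoleucine and leaks lysine) feeding each other across the membrane.

The package covers the full analysis chain:

1. **Plate-reader I/O and calibration** (`biomesim.plate_io`) — wide kinetic
   CSV tables, blank subtraction, linear OD-to-concentration calibration,
   and the small design formulas (dilution fractions, the amino-acid dose
   that caps growth at a chosen theoretical cell yield).
2. **Membrane diffusion** (`biomesim.diffusion`) — the lumped two-well
   gradient-flux model
   `dN_L/dt = -d (C_L - C_R)`, `dN_R/dt = +d (C_L - C_R)`,
   with the diffusion rate *d* in L/h (membrane area and thickness absorbed
   into the constant). Its solution is a single exponential relaxation to
   equilibrium with rate `k = d (1/V_L + 1/V_R)`; the estimator fits the
   deviation from equilibrium with `a e^{bt}` and returns `d̂ = -b V / 2`
   for equal volumes.
3. **Coculture dynamics** (`biomesim.coculture`) — a minimal dynamic
   flux-balance model: Michaelis–Menten-bounded uptake, Liebig
   minimum-flux Monod growth
   `μ = min(y_glc v_glc C_glc/(K_glc+C_glc), y_aa v_aa C_aa/(K_aa+C_aa))`,
   stoichiometric consumption at `μ/y`, growth-proportional leakage
   `e μ B` of the partner's amino acid, and gradient-driven metabolite
   diffusion between compartments. The summary statistic is
   `S = log10(yield_same(48 h) / yield_separated(48 h))`, the log-ratio of
   same-well (positive control) to membrane-separated growth.
4. **Rejection ABC** (`biomesim.abc`) — likelihood-free inference of the
   leakage stoichiometry *e* (mmol per gDW of biomass formed) and *d* from
   an observed statistic: draw from log-uniform priors, simulate both
   layouts, accept when `|S_sim - m_obs| <= k σ_obs`. Three shipped presets
   (`equal`, `unequal`, `noisy`) mirror the standard study configurations.
5. **Synthetic data** (`biomesim.synth`) — plate-reader-shaped datasets
   (dye diffusion, destructive amino-acid sampling, growth curves) with
   recorded ground truth, so every stage has reproducible inputs and
   parameter-recovery tests without any downloads.

## Worked example

```python
import numpy as np
from biomesim import (gen_dye_experiment, apply_calibration, fit_diffusion_rate,
                      DiffusionSystem, default_strains, paired_statistic,
                      get_preset, run_rejection, posterior_summary)
from biomesim.plate_io import CalibrationCurve

# 1. generate a dye-diffusion plate (72 h / 15 min, 3 replicates per pore
#    size, 400-uM load left, water right) and re-estimate one pair's rate
series, plate, truth = gen_dye_experiment(seed=7)
curve = CalibrationCurve(slope=1.0, intercept=0.05, r_squared=1.0)
conc = apply_calibration(series, curve)
geom = DiffusionSystem(d=0.0, c_left0=0.4, c_right0=0.0)
left, right, pore = plate.pairs[3]
est = fit_diffusion_rate(conc, geom, left_wells=[left], right_wells=[right])
print(f"pore {pore} um: d_hat = {est.d_hat:.3e} L/h "
      f"(truth {truth.params['d_by_pore'][pore]:.3e})")

# 2. the growth-ratio statistic at one parameter point
S = paired_statistic(default_strains(1.0, 1.0), d=3.88e-5)
print(f"growth-ratio statistic S at e=1 mmol/g, d=3.88e-5 L/h: {S:.3f}")

# 3. rejection ABC with the shipped equal-leakage preset
config = get_preset("equal", n_samples=200, seed=7)
post = run_rejection(config)
summary = posterior_summary(post)
print(f"acceptance rate: {summary['acceptance_rate']:.3f}")
print(summary["table"].round(3))
```

prints

```
pore 0.03 um: d_hat = 1.001e-05 L/h (truth 1.000e-05)
growth-ratio statistic S at e=1 mmol/g, d=3.88e-5 L/h: 2.431
acceptance rate: 0.035
           median_log10  q25_log10  q75_log10  q2.5_log10  q97.5_log10
parameter
d                -4.485     -4.772     -4.387      -4.902       -4.041
e_leak            0.159     -0.109      0.307      -0.119        0.394
```

The fitted rate recovers the generating value to 0.1%. `S = 2.43` means
that at leakage 1 mmol/g and the measured membrane rate, same-well growth
at 48 h exceeds membrane-separated growth about 270-fold — the membrane is
the bottleneck of the cross-feeding. The ABC run then accepts only draws
whose simulated statistic lands inside the observed window (1.14 ± 2×0.235
for this preset): the leakage posterior concentrates around
`log10 e ≈ 0.16` (e ≈ 1.4 mmol/g), an order-of-magnitude tightening of the
three-decade prior, while the diffusion posterior stays broad.

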