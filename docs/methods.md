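# Methods

## Two-well membrane diffusion

Each device junction joins two well-mixed compartments (volumes `V_L`,
`V_R`, both 250 µL by default) through a porous membrane. Solute flux is
taken proportional to the concentration difference,

    dN_L/dt = −d (C_L − C_R),      dN_R/dt = +d (C_L − C_R),

with amounts `N` in mmol and `C = N/V` in mmol/L. The proportionality
constant `d` (L/h) lumps membrane area, thickness and open-pore fraction
into one parameter, so the flux carries units of mmol/h. The system relaxes
exponentially to the amount-weighted equilibrium
`C_eq = (V_L C_L0 + V_R C_R0)/(V_L + V_R)` with rate
`k = d (1/V_L + 1/V_R)`; for equal volumes `k = 2d/V`.

**Rate estimation.** The deviation of either well from equilibrium,
`D(t) = C(t) − C_eq`, is a single exponential with the same rate on both
sides, so the estimator fits `D(t) = a e^{bt}` by nonlinear least squares
and reports `d̂ = −b/(1/V_L + 1/V_R)`. `C_eq` comes from the known loaded
doses, not the tail of the data, so incomplete runs are handled correctly.
Fitting choices:

* default `pooled` mode stacks the left deviation and the negated right
  deviation into one regression; `left`/`right` modes reproduce per-side
  analyses (e.g. sequestration asymmetry);
* initialisation is a log-linear regression of `log |D|` on `t` over the
  first half of the series, truncated at the first sign change or collapse
  below 1% of `D(0)` — a loss term can drag the late trace past the
  conservative equilibrium, which would otherwise poison the regression;
* the optimiser stops at relative parameter change `1e-10` (bounded
  function evaluations); a fitted `b > 0` flags the estimate and floors
  `d̂` at 0 rather than reporting a negative rate;
* replicate pairs are fitted one at a time; callers aggregate.

Noise-free recovery is exact to well below 0.1% for `d` spanning
`1e-6`–`1e-3` L/h on the 72-h/15-min schedule; under 0.005-OD Gaussian
reader noise the estimate stays within 10% of truth in ≥95% of replicates
(both verified in the test suite and the acceptance script).

## Coculture model

A minimal dynamic flux-balance model of two auxotrophs in one or two
compartments. Per strain `s` in compartment `w`:

    growth       dB/dt = μ B,
    growth law   μ = min( y_glc v_glc C_glc/(K_glc + C_glc),
                          y_aa  v_aa  C_aa /(K_aa  + C_aa ) ),
    consumption  required metabolite m:  −(μ/y_m) B,
    leakage      partner's amino acid:   +e μ B,
    transport    per metabolite:  ±d (C_other − C_this)   (two wells only).

Uptake is Michaelis–Menten bounded; growth follows the Liebig minimum of
the glucose- and amino-acid-supported biomass fluxes; non-limiting
nutrients are still consumed stoichiometrically at `μ/y` (no luxury uptake
or overflow); leakage is strictly growth-proportional (`e` mmol per gDW
formed — resting cells leak nothing). Biomass does not cross the membrane.
No maintenance, death, or lag terms.

**Default parameters.** Units mmol, gDW, L, h throughout.

| parameter | default | unit | origin |
|---|---|---|---|
| `vmax_glc` | 10 | mmol/(gDW·h) | literature-range glucose uptake |
| `km_glc` | 0.05 | mmol/L | literature-range |
| `vmax_aa` | 1 | mmol/(gDW·h) | literature-range amino-acid uptake |
| `km_aa` | 0.01 | mmol/L | literature-range |
| `y_glc` | 0.09 | gDW/mmol | ≈0.5 g biomass per g glucose |
| `y_aa` (lysine) | 1.533 | gDW/mmol | derived: `N_A·1e-3/aa_per_cell × m_cell` |
| `y_aa` (isoleucine) | 2.248 | gDW/mmol | same, `aa_per_cell = 7.5e7` |
| `e` | free (prior `1e-2`–`10`) | mmol/gDW | inferred |
| `d` | 3.88e-5 | L/h | measured mean for lysine/isoleucine, 0.1-µm pores |
| glucose | 22.2 mmol/L | | 0.4% w/v at MW 180.16 |
| inoculum | 1.25e-7 gDW/well | | OD600 0.001 × 0.5 gDW/L/OD × 250 µL |
| cell dry mass | 2.8e-13 | gDW/cell | used for cell-count conversions |

The amino-acid yields are derived from the per-cell incorporation counts
(`1.1e8` lysine, `7.5e7` isoleucine molecules per cell), which makes the
supplement-dose formula and the model self-consistent: 0.731 mmol/L lysine
in a 250-µL well caps the ΔLys monoculture at 1e9 cells, which the
integrated model reproduces to 0.1%.

**Bootstrap of the cross-feeding loop.** With strictly growth-coupled
leakage, an all-zero amino-acid start is a fixed point: nobody can grow,
so nobody leaks. Each compartment is therefore seeded with the amino acid
its *resident* strain leaks, at `e × inoculum` mmol — the pool the
inoculated biomass would itself have released while being grown up. The
seed (i) vanishes as `e → 0`, so low-leakage negative controls stay flat,
and (ii) sits in the leaking strain's own well, so in separated layouts
the partner's supply still has to cross the membrane.

**Positive control.** The same-well positive control is modelled as the
two wells of a junction pooled into one well-mixed 500-µL compartment:
same glucose concentration, same absolute inocula as the separated layout.
This is exactly the `d → ∞` limit of the separated system, so the
statistic `S` (below) isolates the membrane bottleneck rather than a
resource imbalance; a single 250-µL positive control would carry half the
separated layout's glucose and drive `S → −0.30` at saturation.

**Statistic.** `S_s = log10(yield_same(s, 48 h)/yield_sep(s, 48 h))` per
strain; `mean` mode averages the two strains, `per_strain` keeps both.
Yields are linear interpolations of total strain biomass.

**Criticality.** The cross-feeding loop is autocatalytic with gain
`e_lys e_ile y_lys y_ile`; with the default yields and equal leakage it is
subcritical below `e* = 1/sqrt(y_lys y_ile) ≈ 0.54 mmol/g`. Below `e*`
cultures only convert the seed pool (~1% biomass gain) and `S ≈ 0`; the
statistic is informative about `e` only in the band around `e ≈ 0.6–1.5`
where growth is membrane-limited at 48 h. Parameter-recovery tests
therefore use a generating value inside that band (`e = 1`).

**Integration.** `scipy.integrate.solve_ivp` with LSODA, `rtol 1e-8`,
`atol 1e-12` on amounts, and a hard (unsmoothed) minimum in the growth
law. The default maximum step is 0.0025 h, the setting the model family
was originally validated at; `simulate(..., max_step=None)` lets the
adaptive error control choose steps freely, which agrees with the capped
reference to ~1e-5 on `S` at ~30–50× less cost. The ABC inner loop uses
free stepping for that reason (verified by a dedicated test); regime and
acceptance sweeps keep the 0.0025-h cap. States are floored at zero on
output; an excursion below −1e-9 raises instead of being silently clipped.

## Rejection ABC

Draws are sampled from independent priors (`log_uniform`: `10^U`,
`U ~ Uniform(log10 low, log10 high)`; `point`: Dirac), each draw is run
through the paired same-well/separated simulation, and accepted iff
`|S_sim − m_obs| ≤ k σ_obs` — in per-strain mode the window must hold for
*both* strains simultaneously. All draws are retained with their statistic
and acceptance flag (for parameter-space maps); simulation failures are
recorded as rejected-with-error, never dropped. Identical seed and config
reproduce the run bit-for-bit. Plain rejection only — no sequential Monte
Carlo or regression adjustment.

Shipped presets (YAML under `biomesim/presets/`):

* `equal` — shared leakage `e`, `d` free over one decade centered on
  3.88e-5 L/h (log10 bounds −4.911/−3.911), `e` over `1e-2`–`10` mmol/g;
  observed window 1.14 ± 2×0.235 (mean mode).
* `unequal` — `d` fixed at 3.88e-5; independent `e_lys`, `e_ile`;
  per-strain windows 0.925 ± 10×0.015 (ΔLys) and 1.35 ± 10×0.026 (ΔIle).
* `noisy` — `equal` plus one-decade log-uniform priors on every
  literature-estimated kinetic parameter (`vmax_glc`, `km_glc`, `vmax_aa`,
  `km_aa`, `y_glc`, applied to both strains; volumes stay fixed). The
  amino-acid yields stay tied to the per-cell incorporation counts so the
  dose formula remains consistent.

The observed means/sds are experimental inputs shipped as preset values;
the package does not re-estimate them from raw growth curves.

## Synthetic data

The generators emulate the three bench experiments with known truth:
dye diffusion (72 h/15 min, 289 points, three replicate pairs per pore
size, default rates 0/1e-5/3.88e-5/2e-4/5e-4 L/h for the none/0.03/0.1/
0.2/0.4-µm membranes — zero for the poreless control and monotone in pore
size, with the 0.1-µm value at the measured amino-acid mean); destructive
amino-acid sampling (whole-well harvests at 1.5/3/6/12/24 h, three
independent pairs per timepoint, standards ladders of 100→0 µM lysine in
duplicate and 1000→0 µM isoleucine in triplicate); and growth curves
(96 h/15 min, 385 points, any scenario, biomass converted to OD600 at
0.5 gDW/L per OD unit plus a 0.05 blank offset).

Noise is additive i.i.d. Gaussian on the reading (default sd 0.005 OD),
floored at 0. Real reader noise is heteroscedastic and drifts; neither is
modelled, so recovery rates measured here are upper bounds on real-data
performance. The default dye calibration (0.001 OD/µM, intercept 0.05)
puts the 400-µM load mid-scale. An optional first-order input-well loss
term (default 0) emulates dye sequestration in the membrane; with it on,
the input-side rate estimate exceeds the receiver-side one, reproducing
the qualitative per-side asymmetry seen in such devices. In the same-well
growth table each strain gets its own strain-resolved column
(`A1:dLys`-style ids, as a labelled two-channel readout would give); a
plain OD600 reader would only see the sum, so the end-to-end consistency
check is exact rather than approximate. Every generated artefact is
byte-reproducible from `(params, seed)`.

## Known limitations

* The growth model has no lag, maintenance, death, or contact-dependent
  exchange; it cannot represent crossover/contamination between wells.
* Dye sequestration is emulated in the generator but deliberately absent
  from the estimator's model; per-side estimates bracket the truth instead.
* The equal-leakage statistic is non-monotone in `e` (rises to the
  membrane-limited band, falls back to 0 at saturation), so a single
  observed `S` constrains `e` only up to that bimodality; the shipped
  observed windows sit in the informative band.
* Observed statistic values are inputs; re-deriving them from raw
  experimental exports is out of scope.
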