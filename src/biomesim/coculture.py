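"""Dynamic model of the membrane-separated syntrophic auxotroph coculture.

Two E. coli auxotrophs — a lysine auxotroph (dLys) and an isoleucine
auxotroph (dIle) — grow in one or two well-mixed compartments joined by a
porous membrane.  Each strain takes up glucose and its required amino acid
under Michaelis-Menten bounds, grows at the rate allowed by the most
limiting biosynthetic flux (Liebig minimum rule),

    mu = min( y_glc vmax_glc C_glc/(K_glc + C_glc),
              y_aa  vmax_aa  C_aa /(K_aa  + C_aa ) ),

consumes each required metabolite stoichiometrically at mu/y, and leaks
the partner's amino acid in proportion to the biomass it builds
(flux = e mu B, with e in mmol leaked per gDW formed).  Metabolites — but
not cells — diffuse between compartments with the lumped gradient-driven
rate d (L/h) of the diffusion module.  The model is a minimal dynamic
flux-balance analysis: uptake bounds plus biomass stoichiometry set the
growth rate, with a growth-proportional secretion term and two-compartment
transport.

Amounts are mmol, biomass gDW, volumes L, time h throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .plate_io import N_AVOGADRO, supplement_concentration

METABOLITES = ("glucose", "lysine", "isoleucine")

#: amino-acid molecules incorporated per cell built (from auxotroph yield data)
AA_PER_CELL = {"lysine": 1.1e8, "isoleucine": 7.5e7}
CELL_DRY_MASS_G = 2.8e-13  # gDW per E. coli cell
GLUCOSE_MW = 180.16  # g/mol
#: default medium: 0.4% w/v glucose = 4 g/L
GLUCOSE_MM = 4.0 / GLUCOSE_MW * 1000.0  # ~22.2 mmol/L
GDW_PER_L_PER_OD = 0.5  # biomass density per OD600 unit
WELL_VOLUME_L = 2.5e-4
INOCULUM_OD = 0.001  # OD 0.1 culture diluted 1:100
#: mean measured membrane diffusion rate for lysine/isoleucine, 0.1-um pores
D_DEFAULT = 3.88e-5  # L/h
MAX_STEP_H = 0.0025  # integrator max step (h) matching the reference solver


def aa_yield(amino_acid: str, aa_per_cell: float | None = None) -> float:
    """Biomass yield on an amino acid, gDW per mmol.

    Derived from the per-cell incorporation count: one mmol of amino acid
    builds ``N_A * 1e-3 / aa_per_cell`` cells of ``CELL_DRY_MASS_G`` each.
    """
    per_cell = AA_PER_CELL[amino_acid] if aa_per_cell is None else aa_per_cell
    return N_AVOGADRO * 1e-3 / per_cell * CELL_DRY_MASS_G


@dataclass(frozen=True)
class StrainParams:
    """Kinetic and stoichiometric parameters of one auxotroph.

    vmax in mmol/(gDW h), K in mmol/L, yields in gDW/mmol, e_leak in mmol
    of the partner amino acid leaked per gDW of biomass formed.
    """

    name: str
    required_aa: str
    leaked_aa: str
    vmax_glc: float = 10.0
    km_glc: float = 0.05
    vmax_aa: float = 1.0
    km_aa: float = 0.01
    y_glc: float = 0.09
    y_aa: float | None = None
    e_leak: float = 1.0

    def __post_init__(self) -> None:
        if self.required_aa == self.leaked_aa:
            raise ValueError("required and leaked amino acids must differ")
        if self.required_aa not in METABOLITES or self.leaked_aa not in METABOLITES:
            raise ValueError("amino acids must be model metabolites")
        for attr in ("vmax_glc", "km_glc", "vmax_aa", "km_aa", "y_glc"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        if self.e_leak < 0:
            raise ValueError("e_leak must be >= 0")
        if self.y_aa is None:
            object.__setattr__(self, "y_aa", aa_yield(self.required_aa))


def default_strains(e_lys: float = 1.0, e_ile: float = 1.0) -> tuple[StrainParams, StrainParams]:
    """The (dLys, dIle) pair with default kinetics and given leakage."""
    dlys = StrainParams(
        name="dLys", required_aa="lysine", leaked_aa="isoleucine", e_leak=e_ile
    )
    dile = StrainParams(
        name="dIle", required_aa="isoleucine", leaked_aa="lysine", e_leak=e_lys
    )
    return dlys, dile


@dataclass
class CompartmentState:
    """One well: volume (L), per-strain biomass (gDW), metabolite amounts (mmol)."""

    volume: float
    biomass: dict[str, float] = field(default_factory=dict)
    amounts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if any(v < 0 for v in self.biomass.values()):
            raise ValueError("biomass must be >= 0")
        if any(v < 0 for v in self.amounts.values()):
            raise ValueError("amounts must be >= 0")
        for m in METABOLITES:
            self.amounts.setdefault(m, 0.0)


@dataclass
class CocultureSystem:
    """One- or two-compartment system with its strain parameter set."""

    compartments: list[CompartmentState]
    strains: dict[str, StrainParams]
    d: float | None = None

    def __post_init__(self) -> None:
        if len(self.compartments) not in (1, 2):
            raise ValueError("systems have one or two compartments")
        if len(self.compartments) == 2:
            if self.d is None or self.d < 0:
                raise ValueError("two-compartment systems need d >= 0")
        for comp in self.compartments:
            for s in comp.biomass:
                if s not in self.strains:
                    raise ValueError(f"unknown strain {s!r} in compartment")


@dataclass(frozen=True)
class Trajectory:
    """Integrated time course; ``states[i]`` matches ``labels`` columns."""

    times: np.ndarray
    states: np.ndarray
    labels: tuple[str, ...]
    system: CocultureSystem

    def column(self, label: str) -> np.ndarray:
        return self.states[:, self.labels.index(label)]

    def strain_biomass(self, strain: str) -> np.ndarray:
        """Total biomass of a strain summed over the compartments it occupies."""
        cols = [j for j, lab in enumerate(self.labels) if lab.endswith(f":B:{strain}")]
        if not cols:
            raise KeyError(f"strain {strain!r} not in trajectory")
        return self.states[:, cols].sum(axis=1)


def growth_rate(strain: StrainParams, concentrations: dict[str, float]) -> float:
    """Liebig-minimum Monod growth rate (1/h) at local concentrations (mmol/L)."""
    c_glc = max(concentrations.get("glucose", 0.0), 0.0)
    c_aa = max(concentrations.get(strain.required_aa, 0.0), 0.0)
    mu_glc = strain.y_glc * strain.vmax_glc * c_glc / (strain.km_glc + c_glc)
    mu_aa = strain.y_aa * strain.vmax_aa * c_aa / (strain.km_aa + c_aa)
    return min(mu_glc, mu_aa)


SCENARIOS = (
    "separated_coculture",
    "same_well_positive",
    "mono_supplement_across",
    "mono_no_partner",
    "no_pore_control",
)


def build_experiment(
    scenario: str,
    strains: tuple[StrainParams, StrainParams] | None = None,
    *,
    d: float = D_DEFAULT,
    volume: float = WELL_VOLUME_L,
    glucose_mm: float = GLUCOSE_MM,
    inoculum_od: float = INOCULUM_OD,
    gdw_per_l_per_od: float = GDW_PER_L_PER_OD,
    mono_strain: str = "dLys",
    seed_leak_fraction: float = 1.0,
) -> CocultureSystem:
    """Configure the model for one of the device's experimental layouts.

    separated_coculture — one strain per 250-uL well, glucose on both
    sides, membrane diffusion ``d``; the syntrophy-across-the-membrane
    experiment.  same_well_positive — both strains share a single well
    (positive control).  no_pore_control — the separated layout with a
    poreless membrane (d = 0).  mono_supplement_across — one strain on the
    left, its required amino acid dosed in the right well at the
    1e9-cell-yield concentration.  mono_no_partner — one strain, glucose
    only, no partner and no supplement (negative control).

    Because leakage is strictly growth-coupled, an all-zero amino-acid
    start is a fixed point of the cross-feeding loop.  Each compartment is
    therefore seeded with the amino acid its resident strain leaks, at
    ``seed_leak_fraction * e_leak * inoculum`` mmol — the pool the
    inoculated biomass would itself have released while being grown.  The
    seed vanishes as e_leak -> 0 (negative controls stay flat) and sits in
    the leaking strain's own well, so the partner's supply still has to
    cross the membrane in separated layouts.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; pick from {SCENARIOS}")
    if strains is None:
        strains = default_strains()
    dlys, dile = strains
    by_name = {dlys.name: dlys, dile.name: dile}
    inoc = inoculum_od * gdw_per_l_per_od * volume  # gDW per well
    glc = glucose_mm * volume  # mmol per well

    def comp(biomass: dict[str, float], extra: dict[str, float] | None = None) -> CompartmentState:
        amounts = {"glucose": glc}
        for s, b in biomass.items():
            leaked = by_name[s].leaked_aa
            amounts[leaked] = amounts.get(leaked, 0.0) + (
                seed_leak_fraction * by_name[s].e_leak * b
            )
        if extra:
            amounts.update(extra)
        return CompartmentState(volume=volume, biomass=dict(biomass), amounts=amounts)

    if scenario == "separated_coculture":
        return CocultureSystem(
            compartments=[comp({dlys.name: inoc}), comp({dile.name: inoc})],
            strains=by_name, d=d,
        )
    if scenario == "no_pore_control":
        return CocultureSystem(
            compartments=[comp({dlys.name: inoc}), comp({dile.name: inoc})],
            strains=by_name, d=0.0,
        )
    if scenario == "same_well_positive":
        # Pool the device pair into one well-mixed compartment: double
        # volume, same glucose concentration, same absolute inocula.  This
        # is exactly the d -> infinity limit of the separated layout, so
        # the statistic isolates the membrane bottleneck rather than a
        # resource imbalance between the two setups.
        pooled = CompartmentState(
            volume=2 * volume,
            biomass={dlys.name: inoc, dile.name: inoc},
            amounts={
                "glucose": 2 * glc,
                dlys.leaked_aa: seed_leak_fraction * dlys.e_leak * inoc,
                dile.leaked_aa: seed_leak_fraction * dile.e_leak * inoc,
            },
        )
        return CocultureSystem(compartments=[pooled], strains=by_name, d=None)
    strain = by_name[mono_strain]
    if scenario == "mono_no_partner":
        return CocultureSystem(
            compartments=[comp({strain.name: inoc})],
            strains={strain.name: strain}, d=None,
        )
    # mono_supplement_across: required amino acid dosed in the opposite well
    dose_mm = supplement_concentration(
        AA_PER_CELL[strain.required_aa], 1e9, volume
    ) * 1000.0  # mol/L -> mmol/L
    return CocultureSystem(
        compartments=[
            comp({strain.name: inoc}),
            comp({}, {strain.required_aa: dose_mm * volume}),
        ],
        strains={strain.name: strain}, d=d,
    )


def _state_layout(sys: CocultureSystem) -> tuple[list[str], np.ndarray]:
    strain_names = list(sys.strains)
    labels: list[str] = []
    y0: list[float] = []
    for w, comp in enumerate(sys.compartments):
        for s in strain_names:
            labels.append(f"w{w}:B:{s}")
            y0.append(comp.biomass.get(s, 0.0))
        for m in METABOLITES:
            labels.append(f"w{w}:N:{m}")
            y0.append(comp.amounts.get(m, 0.0))
    return labels, np.asarray(y0, dtype=float)


def _make_rhs(sys: CocultureSystem):
    # Specialized scalar closure: the state is small (<=10 entries) and the
    # integrator calls this tens of thousands of times per run, so plain
    # float arithmetic beats small-array numpy by an order of magnitude.
    strain_names = list(sys.strains)
    ns = len(strain_names)
    block = ns + 3
    ncomp = len(sys.compartments)
    vols = [c.volume for c in sys.compartments]
    d = float(sys.d or 0.0)
    aa_index = {"lysine": ns + 1, "isoleucine": ns + 2}
    sp = []
    for s in strain_names:
        p = sys.strains[s]
        sp.append(
            (
                p.y_glc * p.vmax_glc, p.km_glc,
                p.y_aa * p.vmax_aa, p.km_aa,
                p.y_glc, p.y_aa, p.e_leak,
                aa_index[p.required_aa], aa_index[p.leaked_aa],
            )
        )

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        dy = [0.0] * (ncomp * block)
        for w in range(ncomp):
            off = w * block
            v = vols[w]
            c_glc = y[off + ns] / v
            if c_glc < 0.0:
                c_glc = 0.0
            for i in range(ns):
                b = y[off + i]
                if b <= 0.0:
                    continue
                mug, kg, mua, ka, yg, ya, e, req, leak = sp[i]
                c_aa = y[off + req] / v
                if c_aa < 0.0:
                    c_aa = 0.0
                mu = mug * c_glc / (kg + c_glc)
                mu_a = mua * c_aa / (ka + c_aa)
                if mu_a < mu:
                    mu = mu_a
                g = mu * b
                dy[off + i] += g
                dy[off + ns] -= g / yg
                dy[off + req] -= g / ya
                dy[off + leak] += e * g
        if ncomp == 2 and d > 0.0:
            v0, v1 = vols
            for m in range(3):
                flux = d * (y[ns + m] / v0 - y[block + ns + m] / v1)
                dy[ns + m] -= flux
                dy[block + ns + m] += flux
        return dy

    return rhs


def simulate(
    sys: CocultureSystem,
    t_end: float,
    *,
    t_eval: np.ndarray | None = None,
    max_step: float | None = MAX_STEP_H,
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the coculture ODEs to ``t_end`` hours.

    A stiff-capable adaptive solver with a 0.0025-h max step (the setting
    the hard growth-law minimum was validated at) is the default; pass
    ``max_step=None`` to let the error control choose steps freely.
    States are floored at zero in the returned trajectory; an excursion
    below -1e-9 raises, signalling the step size was too coarse.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    labels, y0 = _state_layout(sys)
    sol = solve_ivp(
        _make_rhs(sys), (0.0, float(t_end)), y0,
        t_eval=t_eval, method=method, rtol=rtol, atol=atol,
        max_step=np.inf if max_step is None else max_step,
    )
    if not sol.success:
        raise RuntimeError(f"coculture solver failed: {sol.message}")
    states = sol.y.T
    if states.min() < -1e-9:
        raise RuntimeError(
            f"negative state excursion {states.min():.3e}: step size too coarse"
        )
    return Trajectory(
        times=sol.t, states=np.maximum(states, 0.0), labels=tuple(labels), system=sys
    )


def yield_at(traj: Trajectory, t: float, strain: str) -> float:
    """Strain biomass (gDW, summed over compartments) at time ``t``, by
    linear interpolation of the stored trajectory."""
    if not (traj.times[0] <= t <= traj.times[-1]):
        raise ValueError(f"t={t} outside trajectory span")
    return float(np.interp(t, traj.times, traj.strain_biomass(strain)))


def growth_ratio_statistic(
    traj_same: Trajectory,
    traj_sep: Trajectory,
    t: float = 48.0,
    mode: str = "mean",
):
    """log10 ratio of same-well to membrane-separated growth at ``t`` hours.

    S_s = log10(yield_same(s, t) / yield_sep(s, t)) per strain; ``mode``
    "mean" averages the two strains' values, "per_strain" returns the dict.
    The statistic is 0 when separation does not impair growth and grows as
    the membrane becomes the bottleneck of the cross-feeding.
    """
    if mode not in ("mean", "per_strain"):
        raise ValueError(f"unknown mode {mode!r}")
    strains = sorted(set(traj_same.system.strains) & set(traj_sep.system.strains))
    if not strains:
        raise ValueError("trajectories share no strains")
    per: dict[str, float] = {}
    for s in strains:
        y_same = yield_at(traj_same, t, s)
        y_sep = yield_at(traj_sep, t, s)
        if y_same <= 0 or y_sep <= 0:
            raise ValueError(f"non-positive yield for {s}: statistic undefined")
        per[s] = math.log10(y_same / y_sep)
    if mode == "per_strain":
        return per
    return sum(per.values()) / len(per)


def paired_statistic(
    strains: tuple[StrainParams, StrainParams],
    *,
    d: float = D_DEFAULT,
    t: float = 48.0,
    mode: str = "mean",
    max_step: float | None = MAX_STEP_H,
    **solver_opts,
):
    """Run the positive-control and membrane-separated simulations for one
    parameter set and return their growth-ratio statistic."""
    t_eval = np.linspace(0.0, t, 97)
    same = simulate(
        build_experiment("same_well_positive", strains),
        t, t_eval=t_eval, max_step=max_step, **solver_opts,
    )
    sep = simulate(
        build_experiment("separated_coculture", strains, d=d),
        t, t_eval=t_eval, max_step=max_step, **solver_opts,
    )
    return growth_ratio_statistic(same, sep, t=t, mode=mode)


def trajectory_frame(traj: Trajectory):
    """Trajectory as a tidy wide DataFrame (time_h + one column per state)."""
    import pandas as pd

    df = pd.DataFrame(traj.states, columns=list(traj.labels))
    df.insert(0, "time_h", traj.times)
    return df
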