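"""Synthetic plate-reader datasets with recorded ground truth.

Every generator emulates one of the device's bench experiments and returns
plate-reader-shaped artefacts (wide kinetic tables, a plate map, standards
ladders) together with a :class:`SyntheticTruth` carrying the exact
parameters and seed used — so each pipeline stage has download-free inputs
and parameter-recovery tests against a known answer.

Emulated designs:

* dye diffusion — a 400-uM load in the left well of each membrane pair,
  water on the right, read at the dye's isosbestic point for 72 h at
  15-min intervals, three replicate pairs per pore size;
* destructive amino-acid sampling — whole-well harvests at 1.5/3/6/12/24 h
  (three independent pairs per timepoint) read against a linear standards
  ladder;
* growth curves — OD600 for 96 h at 15-min intervals, produced by the
  coculture ODE model, a blank offset and additive Gaussian noise.

Noise is i.i.d. Gaussian on the reading (default sd 0.005 OD) with the
result floored at 0; real reader noise (drift, heteroscedasticity) is not
modelled.  In the same-well positive-control growth table each strain gets
its own strain-resolved trace (well ids like ``A1:dLys``), the way a
labelled two-channel readout would; a plain OD600 reader would only see
their sum.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coculture
from .coculture import (
    GDW_PER_L_PER_OD,
    MAX_STEP_H,
    WELL_VOLUME_L,
    build_experiment,
    default_strains,
    growth_ratio_statistic,
    simulate,
    yield_at,
)
from .diffusion import DiffusionSystem, analytic_two_well, simulate_diffusion
from .plate_io import KineticSeries, PlateMap, save_kinetic_table

#: default per-pore-size diffusion rates (L/h) used for dye generation;
#: zero for the poreless control, rising monotonically with pore size,
#: with the 0.1-um value at the measured amino-acid mean
DEFAULT_D_BY_PORE = {
    "none": 0.0,
    "0.03": 1.0e-5,
    "0.1": 3.88e-5,
    "0.2": 2.0e-4,
    "0.4": 5.0e-4,
}

#: default synthetic dye calibration: 0.001 OD per uM (= 1 OD per mmol/L)
#: puts the 400-uM load mid-scale; intercept is the water baseline
DYE_SLOPE_OD_PER_MM = 1.0
DYE_INTERCEPT_OD = 0.05
NOISE_SD_OD = 0.005

AA_SAMPLING_HOURS = (1.5, 3.0, 6.0, 12.0, 24.0)
#: assay standards ladders, mmol/L
STANDARD_LADDERS_MM = {
    "lysine": ([0.1, 0.05, 0.025, 0.0125, 0.00625, 0.0], 2),
    "isoleucine": ([1.0, 0.5, 0.25, 0.125, 0.0625, 0.03125, 0.01563, 0.0], 3),
}


@dataclass
class SyntheticTruth:
    """Ground truth attached to a generated dataset: the full parameter
    record, the seed, and the sampling schedule (hours)."""

    params: dict
    seed: int
    schedule: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"params": self.params, "seed": self.seed, "schedule": list(self.schedule)},
                indent=2,
            )
        )


def _schedule(t_end: float, dt: float) -> np.ndarray:
    return np.round(np.arange(0.0, t_end + dt / 2, dt), 10)


def gen_dye_experiment(
    seed: int = 0,
    *,
    d_by_pore: dict[str, float] | None = None,
    n_reps: int = 3,
    c0_mm: float = 0.4,
    volume_l: float = WELL_VOLUME_L,
    slope: float = DYE_SLOPE_OD_PER_MM,
    intercept: float = DYE_INTERCEPT_OD,
    noise_sd: float = NOISE_SD_OD,
    loss_rate: float = 0.0,
    t_end: float = 72.0,
    dt: float = 0.25,
) -> tuple[KineticSeries, PlateMap, SyntheticTruth]:
    """Dye-diffusion plate: one membrane pair per (pore size, replicate).

    The left well starts at ``c0_mm`` (default 0.4 mmol/L = 400 uM), the
    right at zero; concentrations follow the two-well model and are mapped
    to OD through the linear calibration, plus Gaussian noise.  A non-zero
    ``loss_rate`` (1/h) drains dye from the input well, emulating membrane
    sequestration for per-side asymmetry studies.
    """
    rng = np.random.default_rng(seed)
    d_by_pore = dict(DEFAULT_D_BY_PORE if d_by_pore is None else d_by_pore)
    times = _schedule(t_end, dt)
    wells, cols, pairs, contents = [], [], [], {}
    for i, (pore, d) in enumerate(d_by_pore.items()):
        sysd = DiffusionSystem(d=d, v_left=volume_l, v_right=volume_l,
                               c_left0=c0_mm, c_right0=0.0)
        if loss_rate > 0:
            c_l, c_r = simulate_diffusion(sysd, times, loss_rate=loss_rate)
        else:
            c_l, c_r = analytic_two_well(sysd, times)
        for rep in range(n_reps):
            row = "ABCDEFGH"[rep]
            wl, wr = f"{row}{2 * i + 1}", f"{row}{2 * i + 2}"
            pairs.append((wl, wr, pore))
            contents[wl] = f"dye {c0_mm * 1000:.0f} uM (input)"
            contents[wr] = "water (receiver)"
            for w, c in ((wl, c_l), (wr, c_r)):
                od = intercept + slope * c
                if noise_sd > 0:
                    od = od + rng.normal(0.0, noise_sd, size=od.shape)
                wells.append(w)
                cols.append(np.maximum(od, 0.0))
    blanks = ["H11", "H12"]
    for w in blanks:
        od = np.full_like(times, intercept)
        if noise_sd > 0:
            od = od + rng.normal(0.0, noise_sd, size=od.shape)
        wells.append(w)
        cols.append(np.maximum(od, 0.0))
        contents[w] = "water blank"
    series = KineticSeries(times=times, wells=wells,
                           values=np.column_stack(cols), unit="OD")
    plate = PlateMap(pairs=pairs, contents=contents, blanks=blanks)
    truth = SyntheticTruth(
        params={
            "d_by_pore": d_by_pore, "c0_mm": c0_mm, "volume_l": volume_l,
            "slope_od_per_mm": slope, "intercept_od": intercept,
            "noise_sd_od": noise_sd, "loss_rate_per_h": loss_rate,
            "n_reps": n_reps,
        },
        seed=seed, schedule=list(times),
    )
    return series, plate, truth


def gen_amino_acid_sampling(
    seed: int = 0,
    *,
    amino_acid: str = "lysine",
    d: float = 3.88e-5,
    c0_mm: float = 0.4,
    volume_l: float = WELL_VOLUME_L,
    slope: float = DYE_SLOPE_OD_PER_MM,
    intercept: float = DYE_INTERCEPT_OD,
    noise_sd_mm: float = 0.005,
    n_reps: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Destructive amino-acid diffusion sampling plus a standards ladder.

    The analytic two-well trace is evaluated at 1.5/3/6/12/24 h; each
    (timepoint, side) is sampled in ``n_reps`` independent wells (whole
    volumes are harvested, so replicates are separate pairs, not repeated
    measures of one well).  Returns the sample table, a standards ladder
    on the same linear OD map, and the truth record.
    """
    if amino_acid not in STANDARD_LADDERS_MM:
        raise ValueError(f"no standards ladder for {amino_acid!r}")
    rng = np.random.default_rng(seed)
    sysd = DiffusionSystem(d=d, v_left=volume_l, v_right=volume_l,
                           c_left0=c0_mm, c_right0=0.0)
    times = np.asarray(AA_SAMPLING_HOURS)
    c_l, c_r = analytic_two_well(sysd, times)
    rows = []
    for i, t in enumerate(times):
        for side, c in (("left", c_l[i]), ("right", c_r[i])):
            for rep in range(n_reps):
                noisy = c + (rng.normal(0.0, noise_sd_mm) if noise_sd_mm > 0 else 0.0)
                rows.append(
                    {"time_h": t, "side": side, "replicate": rep + 1,
                     "amino_acid": amino_acid,
                     "concentration_mmol_l": max(noisy, 0.0)}
                )
    samples = pd.DataFrame(rows)
    ladder, n_dup = STANDARD_LADDERS_MM[amino_acid]
    std_rows = [
        {"concentration_mmol_l": c, "od": intercept + slope * c}
        for c in ladder for _ in range(n_dup)
    ]
    standards = pd.DataFrame(std_rows)
    truth = SyntheticTruth(
        params={
            "amino_acid": amino_acid, "d": d, "c0_mm": c0_mm,
            "volume_l": volume_l, "slope_od_per_mm": slope,
            "intercept_od": intercept, "noise_sd_mm": noise_sd_mm,
            "n_reps": n_reps,
        },
        seed=seed, schedule=list(times),
    )
    return samples, standards, truth


def gen_growth_experiment(
    scenarios: list[str],
    seed: int = 0,
    *,
    strains=None,
    d: float = coculture.D_DEFAULT,
    noise_sd: float = NOISE_SD_OD,
    blank_od: float = 0.05,
    gdw_per_l_per_od: float = GDW_PER_L_PER_OD,
    volume_l: float = WELL_VOLUME_L,
    t_end: float = 96.0,
    dt: float = 0.25,
    max_step: float | None = MAX_STEP_H,
) -> tuple[dict[str, KineticSeries], dict[str, PlateMap], SyntheticTruth]:
    """OD600 growth tables, one per scenario, from the coculture model.

    Biomass is converted to OD through ``gdw_per_l_per_od`` and offset by
    ``blank_od`` before noise; each table carries a flat blank well.  The
    same-well positive control emits one strain-resolved trace per strain
    (ids ``A1:<strain>``) so per-strain yields stay recoverable.
    """
    if strains is None:
        strains = default_strains()
    rng = np.random.default_rng(seed)
    times = _schedule(t_end, dt)
    tables: dict[str, KineticSeries] = {}
    maps: dict[str, PlateMap] = {}
    for scenario in scenarios:
        sys = build_experiment(scenario, strains, d=d, volume=volume_l)
        traj = simulate(sys, t_end, t_eval=times, max_step=max_step)
        wells, cols, contents, pairs = [], [], {}, []
        for w, comp in enumerate(sys.compartments):
            present = [s for s in sys.strains if comp.biomass.get(s, 0.0) > 0]
            well_id = f"A{w + 1}"
            if scenario == "same_well_positive":
                for s in present:
                    wid = f"{well_id}:{s}"
                    wells.append(wid)
                    contents[wid] = s
                    cols.append(traj.column(f"w{w}:B:{s}") / volume_l / gdw_per_l_per_od)
            else:
                wells.append(well_id)
                contents[well_id] = present[0] if present else "medium"
                total = sum(
                    traj.column(f"w{w}:B:{s}") for s in sys.strains
                ) if sys.strains else np.zeros_like(times)
                cols.append(total / volume_l / gdw_per_l_per_od)
        if len(sys.compartments) == 2:
            pore = "none" if (sys.d or 0.0) == 0.0 else "0.1"
            pairs.append(("A1", "A2", pore))
        blank = "H1"
        wells.append(blank)
        contents[blank] = "medium blank"
        cols.append(np.zeros_like(times))
        values = np.column_stack(cols) + blank_od
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=values.shape)
        tables[scenario] = KineticSeries(
            times=times, wells=wells, values=np.maximum(values, 0.0),
            unit="OD", wavelength_nm=600,
        )
        maps[scenario] = PlateMap(pairs=pairs, contents=contents, blanks=[blank])
    truth = SyntheticTruth(
        params={
            "scenarios": list(scenarios), "d": d,
            "e_leak": {s.name: s.e_leak for s in strains},
            "noise_sd_od": noise_sd, "blank_od": blank_od,
            "gdw_per_l_per_od": gdw_per_l_per_od, "volume_l": volume_l,
        },
        seed=seed, schedule=list(times),
    )
    return tables, maps, truth


def statistic_from_tables(
    same: KineticSeries,
    sep: KineticSeries,
    map_same: PlateMap,
    map_sep: PlateMap,
    *,
    t: float = 48.0,
    mode: str = "mean",
    blank_od: float = 0.05,
    gdw_per_l_per_od: float = GDW_PER_L_PER_OD,
    volume_l: float = WELL_VOLUME_L,
) -> float | dict[str, float]:
    """Growth-ratio statistic recomputed from kinetic tables alone.

    Inverts the OD conversion (subtracting the known blank offset) to
    per-strain biomass, interpolates each trace at ``t`` hours, and forms
    the same log10 same-well/separated ratio as the trajectory-level
    statistic.  Wells are mapped to strains through the plate-map contents.
    """
    import math

    def strain_yields(series: KineticSeries, plate: PlateMap) -> dict[str, float]:
        yields: dict[str, float] = {}
        for w in series.wells:
            s = plate.contents.get(w)
            if s is None or s not in ("dLys", "dIle"):
                continue
            od = float(np.interp(t, series.times, series.well(w))) - blank_od
            yields[s] = yields.get(s, 0.0) + od * gdw_per_l_per_od * volume_l
        return yields

    y_same = strain_yields(same, map_same)
    y_sep = strain_yields(sep, map_sep)
    per = {}
    for s in sorted(set(y_same) & set(y_sep)):
        if y_same[s] <= 0 or y_sep[s] <= 0:
            raise ValueError(f"non-positive table yield for {s}")
        per[s] = math.log10(y_same[s] / y_sep[s])
    if not per:
        raise ValueError("no strain is resolvable in both tables")
    if mode == "per_strain":
        return per
    return sum(per.values()) / len(per)


def write_dye_dataset(outdir: str | Path, seed: int = 0, **kwargs) -> None:
    """Write the dye experiment as table.csv + plate.yaml + truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series, plate, truth = gen_dye_experiment(seed, **kwargs)
    save_kinetic_table(series, outdir / "dye_table.csv")
    plate.to_yaml(outdir / "dye_plate.yaml")
    truth.to_json(outdir / "dye_truth.json")


def write_aa_dataset(outdir: str | Path, seed: int = 0, **kwargs) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples, standards, truth = gen_amino_acid_sampling(seed, **kwargs)
    samples.to_csv(outdir / "aa_samples.csv", index=False)
    standards.to_csv(outdir / "aa_standards.csv", index=False)
    truth.to_json(outdir / "aa_truth.json")


def write_growth_dataset(
    outdir: str | Path, scenarios: list[str] | None = None, seed: int = 0, **kwargs
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenarios = scenarios or ["same_well_positive", "separated_coculture"]
    tables, maps, truth = gen_growth_experiment(scenarios, seed, **kwargs)
    for scenario, series in tables.items():
        save_kinetic_table(series, outdir / f"growth_{scenario}.csv")
        maps[scenario].to_yaml(outdir / f"growth_{scenario}_plate.yaml")
    truth.to_json(outdir / "growth_truth.json")
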