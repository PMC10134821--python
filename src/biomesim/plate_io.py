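"""Plate-reader kinetic-table I/O, blank correction and linear calibration.

Kinetic plate-reader exports are wide CSV tables: a ``time`` column followed
by one column per well.  Everything downstream works in hours, litres and
mmol/L, so times are canonicalised to hours on load.  Calibration converts
optical density at a dye's isosbestic point (or an assay readout) to
concentration through an ordinary least-squares line fitted to a standards
ladder.  The module also carries the two small experimental-design formulas
used to set up cultures: the dilution fraction that brings a culture to a
target OD, and the supplement concentration that caps a culture at a chosen
theoretical cell yield.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

N_AVOGADRO = 6.022e23  # molecules per mol, at the precision used throughout

#: recognised membrane pore-size labels (track-etch pore diameter, um)
PORE_SIZE_LABELS = ("none", "0.03", "0.1", "0.2", "0.4")

_TIME_FACTORS = {"hours": 1.0, "minutes": 1.0 / 60.0, "seconds": 1.0 / 3600.0}


@dataclass(frozen=True)
class KineticSeries:
    """A time-indexed block of per-well traces.

    Parameters
    ----------
    times : array of float
        Sample times in hours, strictly increasing.
    wells : sequence of str
        Well identifiers; column order is preserved from the source table.
    values : 2-D array
        ``len(times) x len(wells)`` matrix of readings.
    unit : {"OD", "mmol/L"}
        Whether ``values`` holds raw optical density or calibrated
        concentration.
    wavelength_nm : int, optional
        Measurement wavelength, if known.
    """

    times: np.ndarray
    wells: tuple[str, ...]
    values: np.ndarray
    unit: str
    wavelength_nm: int | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "wells", tuple(self.wells))
        object.__setattr__(self, "values", values)
        if times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if values.shape != (len(times), len(self.wells)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(times)} times x {len(self.wells)} wells"
            )
        if self.unit not in ("OD", "mmol/L"):
            raise ValueError(f"unknown unit {self.unit!r}")

    def well(self, name: str) -> np.ndarray:
        """Return the trace of a single well as a 1-D array."""
        try:
            j = self.wells.index(name)
        except ValueError:
            raise KeyError(f"well {name!r} not in series") from None
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame with a ``time`` column, as exported by the reader."""
        df = pd.DataFrame(self.values, columns=list(self.wells))
        df.insert(0, "time", self.times)
        return df


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear OD-vs-concentration fit: ``OD = slope * C + intercept``."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass
class PlateMap:
    """Plate layout: membrane-paired wells, per-well contents and blanks.

    Pairing is a hardware property of the device (which wells share a
    membrane junction and its pore size); it is declared explicitly and
    never inferred from well geometry.
    """

    pairs: list[tuple[str, str, str]] = field(default_factory=list)
    contents: dict[str, str] = field(default_factory=dict)
    blanks: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for left, right, pore in self.pairs:
            for w in (left, right):
                if w in seen:
                    raise ValueError(f"well {w!r} appears in more than one pair")
                seen.add(w)
            if str(pore) not in PORE_SIZE_LABELS:
                raise ValueError(
                    f"pore size label {pore!r} not one of {PORE_SIZE_LABELS}"
                )
        self.pairs = [(l, r, str(p)) for l, r, p in self.pairs]

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "pairs": [list(p) for p in self.pairs],
            "contents": dict(self.contents),
            "blanks": list(self.blanks),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlateMap":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        pairs = [tuple(p) for p in doc.get("pairs", [])]
        return cls(
            pairs=pairs,
            contents=dict(doc.get("contents", {})),
            blanks=list(doc.get("blanks", [])),
        )


def load_kinetic_table(
    path: str | Path, unit: str, time_unit: str = "hours"
) -> KineticSeries:
    """Read a wide kinetic CSV (``time`` column, then one column per well).

    Times are converted to hours; ``time_unit`` declares the unit of the
    file's time column.  A non-monotone time column or any missing cell is a
    hard error (the offending cell is named).
    """
    if time_unit not in _TIME_FACTORS:
        raise ValueError(f"unknown time unit {time_unit!r}")
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("kinetic table needs a time column plus >=1 well")
    time_col = df.columns[0]
    if time_col.strip().lower() != "time":
        raise ValueError(f"first column must be 'time', got {time_col!r}")
    wells = [str(c) for c in df.columns[1:]]
    if df.isna().any().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at row {i + 1} (time={df.iloc[i, 0]!r}), "
            f"column {df.columns[j]!r}"
        )
    times = df[time_col].to_numpy(dtype=float) * _TIME_FACTORS[time_unit]
    if np.any(np.diff(times) <= 0):
        raise ValueError("time column is not strictly increasing")
    return KineticSeries(times=times, wells=wells, values=df.iloc[:, 1:].to_numpy(dtype=float), unit=unit)


def save_kinetic_table(series: KineticSeries, path: str | Path) -> None:
    """Write a series back to the wide CSV layout (times in hours)."""
    series.to_frame().to_csv(path, index=False)


def blank_subtract(series: KineticSeries, blanks: Sequence[str]) -> KineticSeries:
    """Subtract the per-timepoint mean of the blank wells; drop the blanks.

    Per-timepoint (rather than scalar) correction captures baseline drift
    and reduces to a scalar offset when the blanks are flat.
    """
    if len(blanks) == 0:
        raise ValueError("at least one blank well is required")
    missing = [b for b in blanks if b not in series.wells]
    if missing:
        raise ValueError(f"blank wells not in series: {missing}")
    idx = [series.wells.index(b) for b in blanks]
    baseline = series.values[:, idx].mean(axis=1)
    keep = [j for j, w in enumerate(series.wells) if w not in set(blanks)]
    return KineticSeries(
        times=series.times,
        wells=[series.wells[j] for j in keep],
        values=series.values[:, keep] - baseline[:, None],
        unit=series.unit,
        wavelength_nm=series.wavelength_nm,
    )


def fit_calibration(
    standards: Iterable[tuple[float, float]]
) -> CalibrationCurve:
    """Ordinary least squares of OD on concentration for a standards ladder.

    ``standards`` is an iterable of ``(concentration, OD)`` pairs; replicate
    standards are fitted jointly (all points enter the regression).
    """
    pts = np.asarray(list(standards), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need >=2 (concentration, OD) pairs")
    conc, od = pts[:, 0], pts[:, 1]
    if np.ptp(conc) == 0:
        raise ValueError("all concentrations equal: calibration is rank deficient")
    res = stats.linregress(conc, od)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(float(res.rvalue) ** 2, 1.0),
    )


def apply_calibration(
    series: KineticSeries, curve: CalibrationCurve
) -> KineticSeries:
    """Invert the calibration line: ``C = (OD - intercept) / slope``.

    Concentrations are floored at zero — noise near the blank can push the
    inverted value slightly negative, and downstream diffusion fitting
    assumes non-negative concentrations.
    """
    if series.unit != "OD":
        raise ValueError("apply_calibration expects an OD series")
    if curve.slope <= 0:
        raise ValueError("calibration slope must be positive")
    conc = np.maximum((series.values - curve.intercept) / curve.slope, 0.0)
    return dataclasses.replace(series, values=conc, unit="mmol/L")


def dilution_fraction(target_od: float, culture_od: float, blank_od: float) -> float:
    """Fraction of culture in a dilution that hits ``target_od``.

    ``(target - blank) / (culture - blank)``; blank-invariant under a common
    offset on all three readings.
    """
    if culture_od <= blank_od:
        raise ValueError("culture OD must exceed blank OD (no culture signal)")
    if target_od < blank_od:
        raise ValueError("target OD below blank OD")
    frac = (target_od - blank_od) / (culture_od - blank_od)
    if frac > 1.0:
        raise ValueError("culture is already more dilute than the target")
    return frac


def supplement_concentration(
    aa_per_cell: float, target_cells: float, volume_l: float
) -> float:
    """Amino-acid molarity capping growth at a theoretical cell yield.

    ``aa_per_cell * target_cells / (N_A * volume)`` in mol/L: the dose that
    is exactly consumed when ``target_cells`` cells have been built, each
    incorporating ``aa_per_cell`` molecules of the amino acid.
    """
    if aa_per_cell <= 0 or target_cells <= 0 or volume_l <= 0:
        raise ValueError("all arguments must be positive")
    return aa_per_cell * target_cells / (N_AVOGADRO * volume_l)
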