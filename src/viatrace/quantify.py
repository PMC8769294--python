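"""Beer-Lambert calibration and dose arithmetic.

The Beer-Lambert law, A = eps * c * l, links absorbance A to molar
concentration c (mol/m^3 here, so that the molar absorption coefficient
eps carries m^2/mol) and optical path length l (m). Once eps for the
dye at the imaging wavelength is known, a pixel's absorbance converts
to moles of dye in the column of solution imaged by that pixel:

    moles = A * pixel_area / eps

with pixel_area in m^2. Summing over a segmented cell gives moles of
dye per cell; dividing by the cell volume gives intracellular molarity.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidInputError
from .units import M2_PER_UM2, MOL_PER_M3_PER_MOL_PER_L

__all__ = [
    "CalibrationCurve",
    "PixelDoseModel",
    "fit_epsilon",
    "pixel_moles",
    "dilution_concentration",
    "percent_difference",
    "cell_molarity",
]

CALIBRATION_HEADER = ["concentration_mol_per_L", "absorbance", "path_length_m"]


@dataclass
class CalibrationCurve:
    """Dilution series of (concentration, absorbance, path length) records.

    Concentrations are stored in mol/L as supplied; they are converted to
    mol/m^3 inside the fit so that epsilon is reported in m^2/mol.
    """

    records: list[tuple[float, float, float]]  # (c mol/L, A, l m)
    wavelength: float = 610.0  # nm
    epsilon_mean: float | None = field(default=None)
    epsilon_sd: float | None = field(default=None)

    def __post_init__(self):
        for c, A, l in self.records:
            if not c > 0:
                raise InvalidInputError(f"concentration must be > 0, got {c}")
            if not l > 0:
                raise InvalidInputError(f"path length must be > 0, got {l}")
            if A < 0:
                raise InvalidInputError(f"absorbance must be >= 0, got {A}")

    @classmethod
    def from_csv(cls, path: str | Path, wavelength: float = 610.0) -> "CalibrationCurve":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            missing = set(CALIBRATION_HEADER) - set(reader.fieldnames or ())
            if missing:
                raise InvalidInputError(f"calibration CSV missing columns: {sorted(missing)}")
            records = [
                (
                    float(row["concentration_mol_per_L"]),
                    float(row["absorbance"]),
                    float(row["path_length_m"]),
                )
                for row in reader
            ]
        return cls(records, wavelength=wavelength)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(CALIBRATION_HEADER)
            writer.writerows(self.records)


@dataclass(frozen=True)
class PixelDoseModel:
    """Converts a pixel's absorbance to moles of dye under that pixel."""

    epsilon: float  # m^2/mol
    pixel_size: float  # um per pixel

    def __post_init__(self):
        if not self.epsilon > 0:
            raise InvalidInputError(f"epsilon must be > 0, got {self.epsilon}")
        if not self.pixel_size > 0:
            raise InvalidInputError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def pixel_area_m2(self) -> float:
        return self.pixel_size ** 2 * M2_PER_UM2


def fit_epsilon(
    curve: CalibrationCurve, method: str = "per_record"
) -> tuple[float, float]:
    """Estimate the molar absorption coefficient from a dilution series.

    Parameters
    ----------
    curve:
        Calibration records; concentrations in mol/L, path lengths in m.
    method:
        ``"per_record"`` (default) computes eps_i = A_i / (c_i * l_i)
        for each dilution and reports their mean and sample SD, matching
        how dilution-series epsilons are customarily summarized as
        mean +/- SD. ``"slope"`` instead fits a through-origin regression
        of A on c*l and reports the slope and its standard error.

    Returns
    -------
    (epsilon_mean, epsilon_sd) in m^2/mol. SD is 0 for a single record.
    """
    if not curve.records:
        raise InvalidInputError("calibration curve has no records")
    c = np.array([r[0] for r in curve.records]) * MOL_PER_M3_PER_MOL_PER_L  # mol/m^3
    A = np.array([r[1] for r in curve.records])
    l = np.array([r[2] for r in curve.records])
    if method == "per_record":
        eps = A / (c * l)
        mean = float(np.mean(eps))
        sd = float(np.std(eps, ddof=1)) if eps.size > 1 else 0.0
    elif method == "slope":
        x = c * l
        slope = float(np.sum(A * x) / np.sum(x * x))
        if x.size > 1:
            resid = A - slope * x
            se = float(
                np.sqrt(np.sum(resid**2) / (x.size - 1) / np.sum(x * x))
            )
        else:
            se = 0.0
        mean, sd = slope, se
    else:
        raise InvalidInputError(f"unknown method {method!r}")
    curve.epsilon_mean = mean
    curve.epsilon_sd = sd
    return mean, sd


def pixel_moles(A_pixel, model: PixelDoseModel):
    """Moles of dye in the solution column imaged by a pixel.

    Accepts scalars or arrays. Negative absorbance yields negative
    moles, retained so downstream offset corrections stay unbiased.
    """
    A = np.asarray(A_pixel, dtype=np.float64)
    if not np.all(np.isfinite(A)):
        raise InvalidInputError("absorbance input must be finite")
    out = A * model.pixel_area_m2 / model.epsilon
    return float(out) if np.isscalar(A_pixel) or out.ndim == 0 else out


def dilution_concentration(
    stock: float, parts_stock: float, parts_diluent: float
) -> float:
    """Concentration after mixing `parts_stock` of stock with `parts_diluent` of diluent."""
    if parts_stock < 0 or parts_diluent < 0:
        raise InvalidInputError("mixing parts must be non-negative")
    total = parts_stock + parts_diluent
    if total <= 0:
        raise InvalidInputError("at least one mixing part must be positive")
    return stock * parts_stock / total


def percent_difference(x: float, y: float) -> float:
    """Unsigned percent difference with the mean of the two values as denominator:

        100 * |x - y| / ((x + y) / 2)
    """
    mean = (x + y) / 2.0
    if mean == 0:
        raise InvalidInputError("percent difference undefined when the mean is zero")
    return 100.0 * abs(x - y) / abs(mean)


def cell_molarity(moles: float, volume: float) -> float:
    """Intracellular molarity (mol/L) from moles of dye and cell volume in litres."""
    if not volume > 0:
        raise InvalidInputError(f"volume must be > 0 L, got {volume}")
    return moles / volume
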