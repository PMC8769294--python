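"""The three dye-quantification strategies over treatment datasets.

Strategy 1 ("raw") segments and measures cells on the absorbance image
as converted. Strategy 2 ("background subtracted") first removes the
absorbance of the dye-bearing medium, estimated per field of view from
a two-component Gaussian mixture over the pixel histogram. Strategy 3
("background and scattering subtracted") additionally removes the
apparent per-cell dye content caused by light scattering at cell
edges, estimated once per experiment as the Gaussian peak mean of the
per-cell moles of live stained cells (the LT control) after background
subtraction, and subtracts that offset from every cell's moles.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.mixture import GaussianMixture

from .absorbance import AbsorbanceImage
from .errors import InvalidInputError
from .quantify import PixelDoseModel, cell_molarity
from .segment import CellRecord, SegmentationParams, measure_cells, segment_cells

__all__ = [
    "TreatmentDataset",
    "PeakFit",
    "StrategyResult",
    "background_level",
    "subtract_background",
    "scattering_offset",
    "run_strategy",
    "freedman_diaconis_bins",
]

TREATMENT_ROLES = ("LD", "LT", "DD", "DT", "MIXTURE", "UNKNOWN")


@dataclass
class TreatmentDataset:
    """Absorbance fields of one treatment plus the analysis parameters."""

    role: str
    fields: list[AbsorbanceImage]
    params: SegmentationParams
    model: PixelDoseModel

    def __post_init__(self):
        if self.role not in TREATMENT_ROLES:
            raise InvalidInputError(
                f"role must be one of {TREATMENT_ROLES}, got {self.role!r}"
            )
        if not self.fields:
            raise InvalidInputError("a treatment needs at least one field of view")
        sizes = {f.pixel_size for f in self.fields}
        if len(sizes) > 1:
            raise InvalidInputError(f"inconsistent pixel sizes across fields: {sizes}")


@dataclass
class PeakFit:
    """Parameters of a fitted one- or two-peak histogram model."""

    means: list[float]
    sds: list[float]
    weights: list[float]
    fit_kind: str  # gaussian | gaussian_mixture | lorentzian_pair

    def __post_init__(self):
        if any(w < 0 for w in self.weights):
            raise InvalidInputError("peak weights must be non-negative")
        if any(s <= 0 for s in self.sds):
            raise InvalidInputError("peak widths must be positive")


@dataclass
class StrategyResult:
    """Cell records of one strategy run plus the fitted corrections."""

    strategy: int
    records: list[CellRecord]
    background_levels: list[float] = field(default_factory=list)
    scattering_mu: float | None = None
    scattering_sigma: float | None = None

    @property
    def moles(self) -> np.ndarray:
        return np.array([r.moles for r in self.records])

    @property
    def molarities(self) -> np.ndarray:
        return np.array([r.molarity for r in self.records])


def freedman_diaconis_bins(values: np.ndarray, max_bins: int = 2000) -> np.ndarray:
    """Freedman-Diaconis bin edges, with graceful degenerate fallbacks."""
    v = np.asarray(values, dtype=np.float64)
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return np.array([lo - 0.5, lo + 0.5])
    iqr = float(np.subtract(*np.percentile(v, [75, 25])))
    width = 2.0 * iqr / v.size ** (1.0 / 3.0)
    if width <= 0:
        n_bins = int(np.ceil(np.sqrt(v.size)))
    else:
        n_bins = int(np.ceil((hi - lo) / width))
    n_bins = min(max(n_bins, 4), max_bins)
    return np.linspace(lo, hi, n_bins + 1)


def _histogram_mode(values: np.ndarray) -> float:
    edges = freedman_diaconis_bins(values)
    counts, edges = np.histogram(values, bins=edges)
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def background_level(
    img: AbsorbanceImage,
    max_pixels: int = 100_000,
    min_weight: float = 0.05,
) -> float:
    """Mean absorbance of the background (medium) pixels of one field.

    A two-component Gaussian mixture is fitted to the pixel-absorbance
    distribution; the lower-mean component is the medium outside cell
    boundaries, the upper one the cells. The background mean is
    returned. When the two components are not meaningfully distinct
    (means closer than the larger SD, or either weight below
    ``min_weight``) or the EM fit fails, the histogram mode is used
    instead — for sparse fields the mode is the medium level anyway.
    """
    v = img.pixels.ravel()
    if v.size < 10_000:
        raise InvalidInputError(
            f"background fit needs >= 1e4 pixels, got {v.size}"
        )
    if np.ptp(v) == 0:
        return float(v[0])  # constant image: degenerate fallback
    if v.size > max_pixels:
        # deterministic strided subsample keeps the fit cheap
        step = v.size // max_pixels + 1
        v_fit = v[::step]
    else:
        v_fit = v
    try:
        gm = GaussianMixture(
            n_components=2, random_state=0, max_iter=200, n_init=1
        ).fit(v_fit.reshape(-1, 1))
        mu = gm.means_.ravel()
        sd = np.sqrt(gm.covariances_.ravel())
        w = gm.weights_.ravel()
        if abs(mu[0] - mu[1]) < max(sd) or w.min() < min_weight:
            return _histogram_mode(v)
        return float(mu[np.argmin(mu)])
    except Exception as exc:  # EM non-convergence etc.
        warnings.warn(f"background mixture fit failed ({exc}); using histogram mode")
        return _histogram_mode(v)


def subtract_background(img: AbsorbanceImage, level: float) -> AbsorbanceImage:
    """Subtract a constant background absorbance from every pixel."""
    if not np.isfinite(level):
        raise InvalidInputError("background level must be finite")
    return img.shifted(level)


def _gauss(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def scattering_offset(
    lt_cell_values, exclude_above_quantile: float = 0.95
) -> tuple[float, float]:
    """Gaussian peak (mean, SD) of live stained cells' apparent moles.

    Live cells exclude the dye, yet after background subtraction they
    still show a positive apparent dye content from edge scattering.
    A single Gaussian is fitted to the dominant histogram peak; values
    above the 95th percentile are excluded from the fit so the few
    genuinely dead cells present in a healthy culture do not bias it
    (the peak location of a Gaussian is unaffected by truncating its
    far upper tail).
    """
    v = np.asarray(lt_cell_values, dtype=np.float64).ravel()
    if v.size < 50:
        raise InvalidInputError(
            f"scattering fit needs >= 50 cells, got {v.size}"
        )
    cut = np.quantile(v, exclude_above_quantile)
    kept = v[v <= cut]
    mean, sd = float(np.mean(kept)), float(np.std(kept))
    if sd == 0:
        return mean, 0.0
    # fit in rescaled units so fmol-scale magnitudes are well conditioned
    scale = max(np.abs(kept).max(), sd)
    ks = kept / scale
    edges = freedman_diaconis_bins(ks)
    counts, edges = np.histogram(ks, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (float(counts.max()), centers[int(np.argmax(counts))], float(np.std(ks)))
    try:
        popt, _ = curve_fit(
            _gauss,
            centers,
            counts,
            p0=p0,
            bounds=([0, ks.min() - 1, 1e-12], [np.inf, ks.max() + 1, np.inf]),
            maxfev=10_000,
        )
        mu_fit, sd_fit = popt[1] * scale, abs(popt[2]) * scale
        if kept.min() - 3 * sd <= mu_fit <= kept.max() + 3 * sd:
            return float(mu_fit), float(sd_fit)
    except Exception as exc:
        warnings.warn(f"scattering peak fit failed ({exc}); using trimmed moments")
    return mean, sd


def _segment_and_measure(
    img: AbsorbanceImage,
    params: SegmentationParams,
    model: PixelDoseModel,
    strategy: int,
    field_index: int,
) -> list[CellRecord]:
    labels = segment_cells(img, params)
    recs = measure_cells(labels, img, model)
    for r in recs:
        r.strategy = strategy
        r.field_index = field_index
    return recs


def run_strategy(
    ds: TreatmentDataset,
    strategy: int,
    lt_reference: "TreatmentDataset | tuple[float, float] | float | None" = None,
) -> StrategyResult:
    """Run one quantification strategy over a treatment dataset.

    Parameters
    ----------
    ds:
        The treatment to analyse.
    strategy:
        1 raw; 2 per-field background subtraction before segmentation;
        3 as 2, then the scattering offset mu_LT_noBG subtracted from
        every cell's moles, with molarity recomputed from the corrected
        moles.
    lt_reference:
        Required for strategy 3: either an LT TreatmentDataset (the
        offset is estimated from its pooled strategy-2 per-cell moles),
        a precomputed (mu, sigma) pair, or a bare mu in moles.
    """
    if strategy not in (1, 2, 3):
        raise InvalidInputError(f"strategy must be 1, 2 or 3, got {strategy}")

    if strategy == 1:
        records = []
        for i, img in enumerate(ds.fields):
            records.extend(_segment_and_measure(img, ds.params, ds.model, 1, i))
        return StrategyResult(strategy=1, records=records)

    # strategies 2 and 3 share the background-subtraction pass
    records: list[CellRecord] = []
    levels: list[float] = []
    for i, img in enumerate(ds.fields):
        level = background_level(img)
        levels.append(level)
        sub = subtract_background(img, level)
        records.extend(_segment_and_measure(sub, ds.params, ds.model, strategy, i))
    if strategy == 2:
        return StrategyResult(strategy=2, records=records, background_levels=levels)

    if lt_reference is None:
        raise InvalidInputError(
            "strategy 3 needs an LT reference dataset or a precomputed offset"
        )
    if isinstance(lt_reference, TreatmentDataset):
        lt_result = run_strategy(lt_reference, 2)
        mu, sigma = scattering_offset(lt_result.moles)
    elif isinstance(lt_reference, tuple):
        mu, sigma = float(lt_reference[0]), float(lt_reference[1])
    else:
        mu, sigma = float(lt_reference), float("nan")

    for r in records:
        r.moles = r.moles - mu
        r.molarity = cell_molarity(r.moles, r.volume_L)
    return StrategyResult(
        strategy=3,
        records=records,
        background_levels=levels,
        scattering_mu=mu,
        scattering_sigma=sigma,
    )
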