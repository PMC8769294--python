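"""Brightfield intensity to absorbance conversion.

A brightfield micrograph becomes a quantitative absorbance (optical
density) image through the ratiometric relationship

    A = -log10( (I - Imin) / (Imax - Imin) )

where ``I`` is the sample image, ``Imax`` the blank reference (light
path without the sample) and ``Imin`` the dark reference (shutter
closed). Because the ratio is dimensionless, absorbance images taken on
different microscopes with different cameras and settings are directly
comparable, unlike raw pixel intensities.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateReferenceError, InvalidInputError

__all__ = [
    "IntensityImage",
    "AbsorbanceImage",
    "ExposureReport",
    "average_reference_images",
    "to_absorbance",
    "check_exposure",
    "DEFAULT_CAP",
    "DEFAULT_WAVELENGTH_NM",
]

DEFAULT_CAP = 4.0
DEFAULT_WAVELENGTH_NM = 610.0

ROLE_SAMPLE = "sample"
ROLE_BLANK = "blank"
ROLE_DARK = "dark"
_ROLES = (ROLE_SAMPLE, ROLE_BLANK, ROLE_DARK)


@dataclass(frozen=True)
class IntensityImage:
    """A single-channel brightfield frame of raw camera counts.

    ``pixels`` may be real-valued (e.g. after reference averaging); raw
    frames straight off the camera are integer counts in
    ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    bit_depth: int
    pixel_size: float  # um per pixel, isotropic
    role: str = ROLE_SAMPLE

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise InvalidInputError(f"expected a 2-D image, got ndim={px.ndim}")
        if self.bit_depth not in (8, 16):
            raise InvalidInputError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not self.pixel_size > 0:
            raise InvalidInputError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.role not in _ROLES:
            raise InvalidInputError(f"role must be one of {_ROLES}, got {self.role!r}")
        if px.size and (px.min() < 0 or px.max() > self.full_scale):
            raise InvalidInputError(
                f"pixel values must lie in [0, {self.full_scale}] for "
                f"{self.bit_depth}-bit data"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def full_scale(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class AbsorbanceImage:
    """Per-pixel dimensionless absorbance (OD) at a stated wavelength."""

    pixels: np.ndarray
    wavelength: float = DEFAULT_WAVELENGTH_NM  # nm
    pixel_size: float = 1.0  # um per pixel
    cap: float = DEFAULT_CAP

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise InvalidInputError(f"expected a 2-D image, got ndim={px.ndim}")
        if not np.all(np.isfinite(px)):
            raise InvalidInputError("absorbance image contains non-finite values")
        if px.size and px.max() > self.cap + 1e-12:
            raise InvalidInputError("absorbance values exceed the stated cap")
        if not self.pixel_size > 0:
            raise InvalidInputError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def shifted(self, level: float) -> "AbsorbanceImage":
        """Return a copy with ``level`` subtracted from every pixel."""
        return replace(self, pixels=self.pixels - float(level))


def average_reference_images(images: list[IntensityImage]) -> IntensityImage:
    """Average repeated reference frames pixel by pixel.

    Several blank (or dark) frames of different fields of view are
    averaged to suppress shot noise before conversion; the result is
    kept in floating point, not re-quantized to integer counts.
    """
    if not images:
        raise InvalidInputError("cannot average an empty list of images")
    first = images[0]
    for img in images[1:]:
        if img.shape != first.shape:
            raise InvalidInputError(
                f"shape mismatch: {img.shape} vs {first.shape}"
            )
        if img.bit_depth != first.bit_depth:
            raise InvalidInputError(
                f"bit depth mismatch: {img.bit_depth} vs {first.bit_depth}"
            )
        if img.pixel_size != first.pixel_size:
            raise InvalidInputError(
                f"pixel size mismatch: {img.pixel_size} vs {first.pixel_size}"
            )
        if img.role != first.role:
            raise InvalidInputError(f"role mismatch: {img.role} vs {first.role}")
    mean = np.mean([img.pixels for img in images], axis=0)
    return IntensityImage(mean, first.bit_depth, first.pixel_size, first.role)


def to_absorbance(
    I: IntensityImage,
    Imax: IntensityImage,
    Imin: IntensityImage,
    cap: float = DEFAULT_CAP,
    wavelength: float = DEFAULT_WAVELENGTH_NM,
) -> AbsorbanceImage:
    """Convert a sample/blank/dark triplet into an absorbance image.

    Pixels whose transmittance ratio is at or below ``10**-cap``
    (including I <= Imin) are set to ``cap``: they are beyond the
    instrument's dynamic range. Pixels with I > Imax produce negative
    absorbance and are retained as-is, so that background noise remains
    symmetric around zero for downstream distribution fits.
    """
    if not cap > 0:
        raise InvalidInputError(f"cap must be > 0, got {cap}")
    if I.shape != Imax.shape or I.shape != Imin.shape:
        raise InvalidInputError(
            f"image shapes differ: I {I.shape}, Imax {Imax.shape}, Imin {Imin.shape}"
        )
    denom = Imax.pixels - Imin.pixels
    n_bad = int(np.count_nonzero(denom <= 0))
    if n_bad:
        raise DegenerateReferenceError(n_bad)
    ratio = (I.pixels - Imin.pixels) / denom
    floor = 10.0 ** (-cap)
    with np.errstate(divide="ignore", invalid="ignore"):
        A = np.where(ratio <= floor, cap, -np.log10(np.maximum(ratio, floor)))
    return AbsorbanceImage(A, wavelength=wavelength, pixel_size=I.pixel_size, cap=cap)


@dataclass(frozen=True)
class ExposureReport:
    """Summary of under/over-exposure of a raw frame."""

    zero_fraction: float
    top_fraction: float
    saturated_fraction: float  # within saturation_margin of full scale
    flagged: bool
    messages: tuple[str, ...] = field(default_factory=tuple)


def check_exposure(
    img: IntensityImage, saturation_margin: float = 0.01
) -> ExposureReport:
    """Flag frames captured outside the camera's linear range.

    Quantitative absorbance requires intensities in the linear response
    region of the sensor; saturated or all-dark frames violate that.
    A frame is flagged when more than 0.1 % of pixels sit within
    ``saturation_margin`` of full scale, or at zero counts.
    """
    px = img.pixels
    n = px.size
    top = img.full_scale
    zero_frac = float(np.count_nonzero(px <= 0)) / n
    top_frac = float(np.count_nonzero(px >= top)) / n
    sat_frac = float(np.count_nonzero(px >= top * (1.0 - saturation_margin))) / n
    msgs = []
    if sat_frac > 1e-3:
        msgs.append(f"{sat_frac:.2%} of pixels within {saturation_margin:.0%} of full scale")
    if zero_frac > 1e-3:
        msgs.append(f"{zero_frac:.2%} of pixels at zero counts")
    return ExposureReport(
        zero_fraction=zero_frac,
        top_fraction=top_frac,
        saturated_fraction=sat_frac,
        flagged=bool(msgs),
        messages=tuple(msgs),
    )
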