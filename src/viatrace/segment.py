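"""Cell segmentation and per-cell measurement on absorbance images.

Cells are found by a Bradley-style locally adaptive threshold (local
mean via a uniform filter, offset by a sensitivity-controlled fraction
of the image's global absorbance range), followed by hole filling,
8-connected component labelling, border clearing and a size filter on
the equivalent-circle radius. Each surviving object is then measured:
area, min/max Feret diameters, summed absorbance, moles of dye,
ellipsoid volume and molarity.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull

from .absorbance import AbsorbanceImage
from .errors import InvalidInputError
from .quantify import PixelDoseModel, cell_molarity, pixel_moles
from .units import L_PER_UM3

__all__ = [
    "SegmentationParams",
    "CellRecord",
    "segment_cells",
    "measure_cells",
    "ellipsoid_volume",
    "feret_diameters",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the adaptive-threshold segmentation.

    ``sensitivity`` controls the threshold offset: foreground is
    ``A > local_mean + k * global_range`` with ``k = 1 - 2*sensitivity``,
    so 0.5 is a plain local-mean comparison, smaller values demand
    stronger contrast, larger values admit fainter objects. It is meant
    to be set per image/treatment. ``r_min``/``r_max`` bound the
    equivalent-circle radius (um) of accepted objects; the defaults
    bracket Jurkat-sized suspension cells.
    """

    sensitivity: float = 0.5
    r_min: float = 4.0  # um
    r_max: float = 16.0  # um
    connectivity: int = 8
    exclude_border: bool = True
    fill_holes: bool = True
    window: int | None = None  # odd pixels; default ~1/8 of min image dim

    def __post_init__(self):
        if not 0.0 <= self.sensitivity <= 1.0:
            raise InvalidInputError("sensitivity must lie in [0, 1]")
        if not 0 < self.r_min < self.r_max:
            raise InvalidInputError("need 0 < r_min < r_max")
        if self.connectivity not in (4, 8):
            raise InvalidInputError("connectivity must be 4 or 8")


@dataclass
class CellRecord:
    """Geometry and dye content of one segmented cell."""

    label: int
    area_px: int
    area_um2: float
    feret_max_um: float
    feret_min_um: float
    sum_absorbance: float  # OD summed over pixels
    volume_L: float
    moles: float  # mol
    molarity: float  # mol/L
    strategy: int | None = None
    field_index: int | None = None


def _auto_window(shape: tuple[int, int]) -> int:
    w = int(round(min(shape) / 8.0))
    if w % 2 == 0:
        w += 1
    return max(w, 3)


def segment_cells(img: AbsorbanceImage, params: SegmentationParams) -> np.ndarray:
    """Label cells in an absorbance image; returns an int32 label image.

    Labels are consecutive starting at 1. A constant image yields no
    objects (the global range is zero and no pixel strictly exceeds its
    local mean plus offset... with k<=0 a constant image has A equal to
    the local mean everywhere, never strictly above).
    """
    A = img.pixels
    if not np.all(np.isfinite(A)):
        raise InvalidInputError("absorbance image must be finite")
    win = params.window if params.window is not None else _auto_window(A.shape)
    if win > min(A.shape):
        raise InvalidInputError(
            f"threshold window {win} exceeds image dimension {min(A.shape)}"
        )
    local_mean = ndimage.uniform_filter(A, size=win, mode="reflect")
    k = 1.0 - 2.0 * params.sensitivity
    # robust global contrast scale: the 1st-99th percentile spread, so a
    # handful of extreme pixels (hot pixels, one unusually dark cell)
    # cannot inflate the threshold offset for the whole image
    p1, p99 = np.percentile(A, [1.0, 99.0]) if A.size else (0.0, 0.0)
    fg = A > local_mean + k * (p99 - p1)
    if params.fill_holes:
        fg = ndimage.binary_fill_holes(fg)
    structure = (
        np.ones((3, 3), dtype=bool)
        if params.connectivity == 8
        else ndimage.generate_binary_structure(2, 1)
    )
    labels, n = ndimage.label(fg, structure=structure)
    if n == 0:
        return labels.astype(np.int32)

    if params.exclude_border:
        border_labels = np.unique(
            np.concatenate(
                [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
            )
        )
        border_labels = border_labels[border_labels > 0]
    else:
        border_labels = np.array([], dtype=labels.dtype)

    areas_px = np.bincount(labels.ravel(), minlength=n + 1)
    r_eq_um = np.sqrt(areas_px * img.pixel_size**2 / np.pi)
    keep = (r_eq_um >= params.r_min) & (r_eq_um <= params.r_max)
    keep[0] = False
    keep[border_labels] = False

    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, int(keep.sum()) + 1, dtype=np.int32)
    return remap[labels]


def feret_diameters(coords: np.ndarray, pixel_size: float = 1.0) -> tuple[float, float]:
    """Max and min Feret (caliper) diameters of a pixel set.

    The convex hull is taken over the four corner points of every pixel
    rather than pixel centres, so a single pixel has Feret diameters
    (sqrt(2), 1) * pixel_size instead of zero. The maximum Feret is the
    largest pairwise distance between hull vertices; the minimum is the
    rotating-calipers width (smallest distance between parallel
    supporting lines), found as the minimum over hull edges of the
    farthest vertex distance from the edge's line.
    """
    coords = np.asarray(coords)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] == 0:
        raise InvalidInputError("coords must be an (n, 2) array of pixel indices")
    r, c = coords[:, 0], coords[:, 1]
    corners = np.concatenate(
        [
            np.stack([r, c], 1),
            np.stack([r + 1, c], 1),
            np.stack([r, c + 1], 1),
            np.stack([r + 1, c + 1], 1),
        ]
    ).astype(np.float64)
    hull = ConvexHull(corners)
    pts = corners[hull.vertices]  # counter-clockwise

    diffs = pts[:, None, :] - pts[None, :, :]
    feret_max = float(np.sqrt((diffs**2).sum(-1)).max())

    nv = len(pts)
    widths = []
    for i in range(nv):
        p, q = pts[i], pts[(i + 1) % nv]
        edge = q - p
        norm = np.hypot(*edge)
        if norm == 0:
            continue
        # unit normal to the edge; width = max |distance| of hull points
        n_vec = np.array([-edge[1], edge[0]]) / norm
        widths.append(float(np.abs((pts - p) @ n_vec).max()))
    feret_min = min(widths)
    return feret_max * pixel_size, feret_min * pixel_size


def ellipsoid_volume(feret_max: float, feret_min: float) -> float:
    """Cell volume (litres) from a prolate-spheroid model.

    The cell is modelled as an ellipsoid, V = (4/3) pi a b c, with
    semi-axis a = feret_max / 2 and b = c = feret_min / 2 (both in um):
    a suspension cell is assumed rotationally symmetric about its long
    axis, since a single focal plane gives no depth measurement.
    """
    if not (feret_max > 0 and feret_min > 0):
        raise InvalidInputError("Feret diameters must be positive")
    if feret_min > feret_max + 1e-12:
        raise InvalidInputError("feret_min must not exceed feret_max")
    a = feret_max / 2.0
    b = c = feret_min / 2.0
    return (4.0 / 3.0) * np.pi * a * b * c * L_PER_UM3


def measure_cells(
    labels: np.ndarray,
    img: AbsorbanceImage,
    model: PixelDoseModel,
    which: list[int] | None = None,
) -> list[CellRecord]:
    """Measure every labelled object (or the subset ``which``).

    Per object: pixel count and area in um^2, Feret diameters, summed
    absorbance, moles (via the Beer-Lambert pixel dose model applied to
    the absorbance sum), ellipsoid volume and molarity. A requested
    label absent from the image is skipped with a warning.
    """
    labels = np.asarray(labels)
    if labels.shape != img.shape:
        raise InvalidInputError(
            f"label image shape {labels.shape} != absorbance shape {img.shape}"
        )
    present = np.unique(labels)
    present = present[present > 0]
    if which is not None:
        requested = list(which)
        present_set = set(int(v) for v in present)
        for lab in requested:
            if lab not in present_set:
                warnings.warn(f"label {lab} absent from label image; skipped")
        present = [lab for lab in requested if lab in present_set]

    ps = img.pixel_size
    records: list[CellRecord] = []
    objects = ndimage.find_objects(labels.astype(np.intp))
    for lab in present:
        lab = int(lab)
        sl = objects[lab - 1]
        mask = labels[sl] == lab
        coords = np.argwhere(mask)
        coords[:, 0] += sl[0].start
        coords[:, 1] += sl[1].start
        area_px = int(mask.sum())
        sum_A = float(img.pixels[sl][mask].sum())
        fmax, fmin = feret_diameters(coords, pixel_size=ps)
        vol = ellipsoid_volume(fmax, fmin)
        moles = pixel_moles(sum_A, model)
        records.append(
            CellRecord(
                label=lab,
                area_px=area_px,
                area_um2=area_px * ps**2,
                feret_max_um=fmax,
                feret_min_um=fmin,
                sum_absorbance=sum_A,
                volume_L=vol,
                moles=moles,
                molarity=cell_molarity(moles, vol),
            )
        )
    return records
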