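"""Synthetic brightfield phantoms with known ground-truth dye content.

Each phantom field of view is rendered as the camera would see it: a
smooth illumination field (blank), a dark level, and a sample frame
I = dark + illumination * 10**(-OD) with optional Poisson shot noise,
Gaussian read noise and integer quantization. The optical-density map
is built from a dye-bearing medium (uniform OD), elliptical cells whose
intracellular dye is spread uniformly over their footprint, and a
positive-OD ring at each cell boundary standing in for the light
scattering that real cell edges produce. The ring is a phenomenological
stand-in, not a physical-optics model; its integrated apparent dye
content is the controlled quantity.

Treatment roles mirror a dye-exclusion control design: live (L) or
dead (D) cells suspended in plain buffer (D) or dye solution (T), plus
1:1 live:dead mixtures. Every generated cell is recorded in a truth
table, so recovery of counts, moles and classifications can be checked
exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .absorbance import IntensityImage, average_reference_images, to_absorbance
from .errors import GenerationError, InvalidInputError
from .quantify import PixelDoseModel
from .segment import SegmentationParams
from .strategies import TreatmentDataset
from .units import M2_PER_UM2

__all__ = [
    "CellSpec",
    "PhantomSpec",
    "FieldTriplet",
    "SyntheticTreatment",
    "generate_field",
    "generate_experiment",
    "random_cells",
    "treatment_to_dataset",
    "DEFAULT_DEAD_MOLES_MEAN",
    "DEFAULT_DEAD_MOLES_SD",
    "DEFAULT_RING_MOLES_MEAN",
    "DEFAULT_RING_MOLES_SD",
    "DEFAULT_MEDIUM_OD",
]

# Study-condition defaults: dead-cell dye content ~20.6 fmol/cell (SD 3),
# live-cell apparent (scattering) content ~3.3 fmol/cell (SD 1), stained
# medium OD ~0.3. These set the scale of every synthetic experiment.
DEFAULT_DEAD_MOLES_MEAN = 20.6e-15  # mol
DEFAULT_DEAD_MOLES_SD = 3.0e-15
DEFAULT_RING_MOLES_MEAN = 3.3e-15
DEFAULT_RING_MOLES_SD = 1.0e-15
DEFAULT_MEDIUM_OD = 0.3


@dataclass(frozen=True)
class CellSpec:
    """One synthetic cell: geometry plus true dye content."""

    center_um: tuple[float, float]  # (row, col) in um
    semiaxes_um: tuple[float, float]  # (major a, minor b)
    angle: float = 0.0  # radians, major axis vs. column direction
    moles: float = 0.0  # intracellular dye, mol
    ring_moles: float = 0.0  # integrated apparent dye of the scattering ring, mol
    ring_od: float | None = None  # explicit ring amplitude; overrides ring_moles
    ring_width_um: float = 1.0

    def __post_init__(self):
        if self.moles < 0 or self.ring_moles < 0:
            raise InvalidInputError("moles must be non-negative")
        a, b = self.semiaxes_um
        if not (a > 0 and b > 0 and b <= a):
            raise InvalidInputError("need semiaxes a >= b > 0")

    @property
    def outer_radius_um(self) -> float:
        return self.semiaxes_um[0] + self.ring_width_um


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic field of view."""

    shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.65  # um per pixel
    bit_depth: int = 16
    illumination: float = 30000.0  # blank counts at image centre
    gradient_amplitude: float = 0.05  # fractional linear illumination tilt
    dark_level: float = 400.0  # counts
    read_noise_sd: float = 50.0  # counts
    shot_noise: bool = True
    quantize: bool = True
    medium_absorbance: float = 0.0  # OD of the suspension medium
    epsilon: float = 2555.0  # m^2/mol, used to convert moles -> OD
    cells: tuple[CellSpec, ...] = field(default_factory=tuple)
    seed: int = 0

    def noise_free(self) -> "PhantomSpec":
        """Copy with camera noise and quantization switched off."""
        return replace(self, read_noise_sd=0.0, shot_noise=False, quantize=False)

    @property
    def pixel_area_m2(self) -> float:
        return self.pixel_size**2 * M2_PER_UM2


@dataclass
class FieldTriplet:
    """One rendered field: sample, blank and dark frames plus ground truth."""

    I: IntensityImage
    Imax: IntensityImage
    Imin: IntensityImage
    truth: pd.DataFrame


def _illumination(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.shape
    gr = np.linspace(-1.0, 1.0, h)[:, None]
    gc = np.linspace(-1.0, 1.0, w)[None, :]
    tilt = 0.5 * (gr + gc)
    return spec.illumination * (1.0 + spec.gradient_amplitude * tilt)


def _cell_masks(spec: PhantomSpec, cell: CellSpec) -> tuple[np.ndarray, np.ndarray, slice, slice]:
    """Interior and ring boolean masks of a cell within its bounding box."""
    ps = spec.pixel_size
    a, b = cell.semiaxes_um
    w = cell.ring_width_um
    r0, c0 = cell.center_um
    extent = a + w + ps
    rlo = max(int((r0 - extent) / ps), 0)
    rhi = min(int((r0 + extent) / ps) + 2, spec.shape[0])
    clo = max(int((c0 - extent) / ps), 0)
    chi = min(int((c0 + extent) / ps) + 2, spec.shape[1])
    rows = (np.arange(rlo, rhi) + 0.5) * ps - r0
    cols = (np.arange(clo, chi) + 0.5) * ps - c0
    dr = rows[:, None]
    dc = cols[None, :]
    ca, sa = np.cos(cell.angle), np.sin(cell.angle)
    u = dc * ca + dr * sa  # along major axis
    v = -dc * sa + dr * ca
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    outer = (u / (a + w)) ** 2 + (v / (b + w)) ** 2 <= 1.0
    ring = outer & ~inside
    return inside, ring, slice(rlo, rhi), slice(clo, chi)


def _od_map(spec: PhantomSpec) -> tuple[np.ndarray, pd.DataFrame]:
    od = np.full(spec.shape, float(spec.medium_absorbance))
    h_um = spec.shape[0] * spec.pixel_size
    w_um = spec.shape[1] * spec.pixel_size
    rows = []
    for idx, cell in enumerate(spec.cells):
        r0, c0 = cell.center_um
        reach = cell.outer_radius_um
        if not (reach <= r0 <= h_um - reach and reach <= c0 <= w_um - reach):
            raise GenerationError(
                f"cell {idx} at ({r0:.1f}, {c0:.1f}) um extends outside the image"
            )
        inside, ring, rs, cs = _cell_masks(spec, cell)
        n_in = int(inside.sum())
        n_ring = int(ring.sum())
        if n_in == 0:
            raise GenerationError(f"cell {idx} covers no pixels at this pixel size")
        a_in = cell.moles * spec.epsilon / (n_in * spec.pixel_area_m2)
        if cell.ring_od is not None:
            a_ring = cell.ring_od
        elif n_ring > 0:
            a_ring = cell.ring_moles * spec.epsilon / (n_ring * spec.pixel_area_m2)
        else:
            a_ring = 0.0
        block = od[rs, cs]
        if np.any(block[inside | ring] != spec.medium_absorbance):
            raise GenerationError(f"cell {idx} overlaps a previously placed cell")
        block[inside] += a_in
        block[ring] += a_ring
        rows.append(
            {
                "cell_id": idx,
                "row_um": r0,
                "col_um": c0,
                "a_um": cell.semiaxes_um[0],
                "b_um": cell.semiaxes_um[1],
                "angle": cell.angle,
                "moles": cell.moles,
                "ring_moles": n_ring * a_ring * spec.pixel_area_m2 / spec.epsilon,
                "n_pixels": n_in,
                "is_dead": cell.moles > 0,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "cell_id", "row_um", "col_um", "a_um", "b_um", "angle",
            "moles", "ring_moles", "n_pixels", "is_dead",
        ],
    )
    return od, truth


def _render(spec: PhantomSpec, signal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Turn an expected photon-signal map into a (noisy) camera frame."""
    if spec.shot_noise:
        counts = rng.poisson(signal).astype(np.float64)
    else:
        counts = signal.astype(np.float64, copy=True)
    counts += spec.dark_level
    if spec.read_noise_sd > 0:
        counts += rng.normal(0.0, spec.read_noise_sd, size=counts.shape)
    full = 2**spec.bit_depth - 1
    counts = np.clip(counts, 0.0, full)
    if spec.quantize:
        counts = np.rint(counts)
    return counts


def render_blank(spec: PhantomSpec, rng: np.random.Generator) -> IntensityImage:
    frame = _render(spec, _illumination(spec), rng)
    return IntensityImage(frame, spec.bit_depth, spec.pixel_size, role="blank")


def render_dark(spec: PhantomSpec, rng: np.random.Generator) -> IntensityImage:
    frame = _render(spec, np.zeros(spec.shape), rng)
    return IntensityImage(frame, spec.bit_depth, spec.pixel_size, role="dark")


def generate_field(spec: PhantomSpec) -> FieldTriplet:
    """Render one sample/blank/dark triplet with its ground-truth table.

    Rendering is fully reproducible: the same spec (including seed)
    yields bit-identical frames.
    """
    rng = np.random.default_rng(spec.seed)
    od, truth = _od_map(spec)
    illum = _illumination(spec)
    Imax = render_blank(spec, rng)
    Imin = render_dark(spec, rng)
    sample_frame = _render(spec, illum * 10.0 ** (-od), rng)
    I = IntensityImage(sample_frame, spec.bit_depth, spec.pixel_size, role="sample")
    return FieldTriplet(I=I, Imax=Imax, Imin=Imin, truth=truth)


def random_cells(
    rng: np.random.Generator,
    spec: PhantomSpec,
    moles: np.ndarray,
    ring_moles: np.ndarray,
    radius_mean_um: float = 5.5,
    radius_sd_um: float = 0.5,
    min_axis_ratio: float = 0.85,
    ring_width_um: float = 1.0,
    margin_um: float = 1.5,
    max_attempts: int = 500,
) -> tuple[CellSpec, ...]:
    """Place non-overlapping elliptical cells uniformly at random.

    One cell per entry of ``moles``/``ring_moles``. Placement is by
    rejection: a candidate centre is redrawn until the cell (including
    its scattering ring plus ``margin_um``) clears the image border and
    every previously placed cell; exceeding ``max_attempts`` raises.
    """
    moles = np.asarray(moles, dtype=np.float64)
    ring_moles = np.asarray(ring_moles, dtype=np.float64)
    if moles.shape != ring_moles.shape:
        raise InvalidInputError("moles and ring_moles must have equal length")
    h_um = spec.shape[0] * spec.pixel_size
    w_um = spec.shape[1] * spec.pixel_size
    placed: list[CellSpec] = []
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for m, rm in zip(moles, ring_moles):
        a = float(np.clip(rng.normal(radius_mean_um, radius_sd_um), 3.0, 10.0))
        b = a * float(rng.uniform(min_axis_ratio, 1.0))
        angle = float(rng.uniform(0.0, np.pi))
        reach = a + ring_width_um
        for _ in range(max_attempts):
            r0 = rng.uniform(reach + margin_um, h_um - reach - margin_um)
            c0 = rng.uniform(reach + margin_um, w_um - reach - margin_um)
            ok = all(
                np.hypot(r0 - rc, c0 - cc) > reach + rr + margin_um
                for (rc, cc), rr in zip(centers, radii)
            )
            if ok:
                break
        else:
            raise GenerationError(
                f"could not place cell {len(placed)} after {max_attempts} attempts; "
                "field too crowded"
            )
        placed.append(
            CellSpec(
                center_um=(r0, c0),
                semiaxes_um=(a, b),
                angle=angle,
                moles=float(m),
                ring_moles=float(rm),
                ring_width_um=ring_width_um,
            )
        )
        centers.append((r0, c0))
        radii.append(reach)
    return tuple(placed)


@dataclass
class SyntheticTreatment:
    """All frames and ground truth of one synthetic treatment."""

    role: str
    samples: list[IntensityImage]
    blanks: list[IntensityImage]
    darks: list[IntensityImage]
    truth: pd.DataFrame  # per-cell, with a field_index column


def _treatment_conditions(role: str, medium_od: float) -> tuple[float, bool, bool]:
    """(medium OD, cells take up dye?, mixture?) for a treatment role.

    Only dead cells suspended in dye solution (DT, and the dead half of
    MIXTURE) contain intracellular dye: live cells exclude it, and cells
    in plain buffer have none to take up. Unstained treatments still get
    scattering rings — that is exactly the artefact the corrections
    target.
    """
    if role == "LD":
        return 0.0, False, False
    if role == "DD":
        return 0.0, False, False
    if role == "LT":
        return medium_od, False, False
    if role == "DT":
        return medium_od, True, False
    if role == "MIXTURE":
        return medium_od, True, True
    raise InvalidInputError(f"unknown treatment role {role!r}")


def generate_experiment(
    treatments: list[str],
    seed: int,
    template: PhantomSpec | None = None,
    n_fields: int = 10,
    n_blanks: int = 4,
    n_darks: int = 4,
    cells_per_field: int = 100,
    dead_moles_mean: float = DEFAULT_DEAD_MOLES_MEAN,
    dead_moles_sd: float = DEFAULT_DEAD_MOLES_SD,
    ring_moles_mean: float = DEFAULT_RING_MOLES_MEAN,
    ring_moles_sd: float = DEFAULT_RING_MOLES_SD,
    medium_od: float = DEFAULT_MEDIUM_OD,
) -> dict[str, SyntheticTreatment]:
    """Generate a full multi-treatment synthetic experiment.

    Per treatment: ``n_blanks`` blank and ``n_darks`` dark reference
    frames plus ``n_fields`` sample fields. Live treatments (LD, LT)
    get cells with zero intracellular dye but scattering rings; dead
    treatments (DD, DT) draw intracellular content from a truncated
    normal; stained treatments (LT, DT, MIXTURE) add the medium OD;
    MIXTURE fields hold an exact 1:1 live:dead split.
    All randomness flows from ``seed``.
    """
    if template is None:
        template = PhantomSpec()
    root = np.random.default_rng(seed)
    out: dict[str, SyntheticTreatment] = {}
    for role in treatments:
        med, stained, mixture = _treatment_conditions(role, medium_od)
        rng = np.random.default_rng(root.integers(0, 2**31 - 1))
        blanks = [render_blank(template, rng) for _ in range(n_blanks)]
        darks = [render_dark(template, rng) for _ in range(n_darks)]
        samples: list[IntensityImage] = []
        truth_parts: list[pd.DataFrame] = []
        for fi in range(n_fields):
            if mixture:
                n_dead = cells_per_field // 2
                n_live = cells_per_field - n_dead
                moles = np.concatenate(
                    [
                        np.zeros(n_live),
                        np.clip(
                            rng.normal(dead_moles_mean, dead_moles_sd, n_dead),
                            0.0,
                            None,
                        ),
                    ]
                )
            elif stained:
                moles = np.clip(
                    rng.normal(dead_moles_mean, dead_moles_sd, cells_per_field),
                    0.0,
                    None,
                )
            else:
                moles = np.zeros(cells_per_field)
            ring = np.clip(
                rng.normal(ring_moles_mean, ring_moles_sd, cells_per_field),
                0.0,
                None,
            )
            cells = random_cells(rng, template, moles, ring)
            field_spec = replace(
                template,
                medium_absorbance=med,
                cells=cells,
                seed=int(root.integers(0, 2**31 - 1)),
            )
            triplet = generate_field(field_spec)
            samples.append(triplet.I)
            t = triplet.truth.copy()
            t.insert(0, "field_index", fi)
            truth_parts.append(t)
        out[role] = SyntheticTreatment(
            role=role,
            samples=samples,
            blanks=blanks,
            darks=darks,
            truth=pd.concat(truth_parts, ignore_index=True),
        )
    return out


def treatment_to_dataset(
    st: SyntheticTreatment,
    params: SegmentationParams,
    model: PixelDoseModel,
    cap: float = 4.0,
) -> TreatmentDataset:
    """Convert a synthetic treatment's frames into an analysis-ready dataset."""
    Imax = average_reference_images(st.blanks)
    Imin = average_reference_images(st.darks)
    fields = [to_absorbance(I, Imax, Imin, cap=cap) for I in st.samples]
    role = st.role if st.role in ("LD", "LT", "DD", "DT", "MIXTURE") else "UNKNOWN"
    return TreatmentDataset(role=role, fields=fields, params=params, model=model)
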