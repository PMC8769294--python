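"""TIFF and table I/O plus experiment-manifest handling.

Raw frames are single-plane 8- or 16-bit grayscale TIFFs; absorbance
images are written as 32-bit float TIFF. The pixel size always comes
from the manifest/caller — TIFF resolution tags, when present, are only
cross-checked with a warning, since they are too often wrong or absent
to be trusted silently.
"""
from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .absorbance import AbsorbanceImage, IntensityImage
from .errors import InvalidInputError, UnsupportedFormatError
from .segment import CellRecord
from .units import FMOL_PER_MOL, MMOL_PER_MOL, PL_PER_L

__all__ = [
    "load_intensity_image",
    "save_intensity_image",
    "load_absorbance_image",
    "save_absorbance_image",
    "cells_to_dataframe",
    "write_cell_table",
    "load_manifest",
]

_CHANNELS = {"red": 0, "green": 1, "blue": 2}

CELL_TABLE_COLUMNS = [
    "label",
    "area_um2",
    "feret_max_um",
    "feret_min_um",
    "sum_absorbance",
    "volume_pL",
    "moles_fmol",
    "molarity_mmol_per_L",
]


def load_intensity_image(
    path: str | Path,
    pixel_size: float,
    role: str = "sample",
    channel: str | None = None,
) -> IntensityImage:
    """Read a raw camera frame from TIFF.

    Color images are accepted only when ``channel`` names the plane to
    extract ("red", "green" or "blue"; red matches a 610 nm bandpass).
    Bit depth is inferred from the sample format; float or multi-plane
    TIFFs are rejected.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise UnsupportedFormatError(
                f"{path.name}: expected a single-plane TIFF, got {len(tif.pages)} pages"
            )
        arr = tif.pages[0].asarray()
        res = tif.pages[0].resolution  # (x, y) pixels per resolution unit
    if arr.ndim == 3:
        if channel is None:
            raise UnsupportedFormatError(
                f"{path.name}: color image; specify a channel to extract"
            )
        if channel not in _CHANNELS:
            raise InvalidInputError(
                f"channel must be one of {sorted(_CHANNELS)}, got {channel!r}"
            )
        idx = _CHANNELS[channel]
        if arr.shape[-1] <= idx:
            raise UnsupportedFormatError(
                f"{path.name}: image has {arr.shape[-1]} channels, no {channel!r}"
            )
        arr = arr[..., idx]
    if arr.ndim != 2:
        raise UnsupportedFormatError(
            f"{path.name}: expected a 2-D image, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        raise UnsupportedFormatError(
            f"{path.name}: unsupported sample format {arr.dtype}; "
            "expected uint8 or uint16"
        )
    _cross_check_resolution(path, res, pixel_size)
    return IntensityImage(arr, bit_depth=bit_depth, pixel_size=pixel_size, role=role)


def _cross_check_resolution(path: Path, res, pixel_size: float) -> None:
    try:
        xres = float(res[0]) if res else 0.0
    except (TypeError, ValueError):
        return
    if xres <= 1.0:  # absent or default tag
        return
    tag_um = 1e4 / xres  # assume pixels/cm, the common microscopy convention
    if not np.isclose(tag_um, pixel_size, rtol=0.05):
        warnings.warn(
            f"{path.name}: TIFF resolution tag implies {tag_um:.3g} um/px, "
            f"manifest says {pixel_size:.3g} um/px; using the manifest value"
        )


def save_intensity_image(path: str | Path, img: IntensityImage) -> None:
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    px = img.pixels
    if not np.allclose(px, np.rint(px)):
        raise InvalidInputError(
            "refusing to quantize real-valued counts; round explicitly first"
        )
    tifffile.imwrite(Path(path), np.rint(px).astype(dtype))


def save_absorbance_image(path: str | Path, img: AbsorbanceImage) -> None:
    tifffile.imwrite(Path(path), img.pixels.astype(np.float32))


def load_absorbance_image(
    path: str | Path,
    pixel_size: float,
    wavelength: float = 610.0,
    cap: float = 4.0,
) -> AbsorbanceImage:
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise UnsupportedFormatError(f"expected 2-D absorbance image, got {arr.shape}")
    return AbsorbanceImage(
        np.asarray(arr, dtype=np.float64),
        wavelength=wavelength,
        pixel_size=pixel_size,
        cap=cap,
    )


def cells_to_dataframe(records: list[CellRecord]) -> pd.DataFrame:
    """Cell records as a table in presentation units (um, pL, fmol, mmol/L)."""
    rows = [
        {
            "label": r.label,
            "area_um2": r.area_um2,
            "feret_max_um": r.feret_max_um,
            "feret_min_um": r.feret_min_um,
            "sum_absorbance": r.sum_absorbance,
            "volume_pL": r.volume_L * PL_PER_L,
            "moles_fmol": r.moles * FMOL_PER_MOL,
            "molarity_mmol_per_L": r.molarity * MMOL_PER_MOL,
            "strategy": r.strategy,
            "field_index": r.field_index,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS + ["strategy", "field_index"])


def write_cell_table(path: str | Path, records: list[CellRecord]) -> None:
    cells_to_dataframe(records).to_csv(Path(path), index=False, float_format="%.8g")


def load_manifest(path: str | Path) -> dict:
    """Load and validate an experiment manifest (YAML or JSON)."""
    path = Path(path)
    text = path.read_text()
    manifest = (
        json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    )
    if not isinstance(manifest, dict):
        raise InvalidInputError(f"{path.name}: manifest must be a mapping")
    validate_manifest(manifest, base_dir=path.parent)
    return manifest


def validate_manifest(manifest: dict, base_dir: Path | None = None) -> None:
    for key in ("pixel_size_um", "treatments"):
        if key not in manifest:
            raise InvalidInputError(f"manifest missing required key {key!r}")
    has_eps = "epsilon_m2_per_mol" in manifest
    has_table = "calibration_csv" in manifest
    if has_eps == has_table:
        raise InvalidInputError(
            "manifest must provide exactly one of epsilon_m2_per_mol or calibration_csv"
        )
    if not manifest["treatments"]:
        raise InvalidInputError("manifest lists no treatments")
    base = base_dir or Path(".")
    for role, spec in manifest["treatments"].items():
        for kind in ("samples", "blanks", "darks"):
            paths = spec.get(kind, [])
            if not paths:
                raise InvalidInputError(f"treatment {role!r} has no {kind}")
            for p in paths:
                full = (base / p) if not Path(p).is_absolute() else Path(p)
                if not full.exists():
                    raise InvalidInputError(f"treatment {role!r}: missing file {p}")
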