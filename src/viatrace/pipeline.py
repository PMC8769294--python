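"""End-to-end workflow: manifest in, tables/absorbance images/log out.

The pipeline chains conversion, segmentation, the chosen correction
strategy and (optionally) live/dead classification over the treatments
named in an experiment manifest, and writes every output next to a run
log recording the parameters, fitted background levels, the scattering
offset and the classification threshold, so each number in the output
is auditable.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .absorbance import average_reference_images, to_absorbance
from .classify import ClassificationResult, classify_cells, cmin_threshold, three_sigma_cutoff
from .errors import InvalidInputError, PipelineError
from .imgio import (
    load_intensity_image,
    load_manifest,
    save_absorbance_image,
    write_cell_table,
)
from .quantify import CalibrationCurve, PixelDoseModel, fit_epsilon
from .segment import SegmentationParams
from .strategies import StrategyResult, TreatmentDataset, run_strategy
from .units import FMOL_PER_MOL, MMOL_PER_MOL

__all__ = ["run_pipeline"]


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r}: {exc}") from exc
            return False

    return _Ctx()


def _segmentation_params(manifest: dict, role_spec: dict) -> SegmentationParams:
    cfg = dict(manifest.get("segmentation", {}))
    if "sensitivity" in role_spec:
        cfg["sensitivity"] = role_spec["sensitivity"]
    return SegmentationParams(
        sensitivity=cfg.get("sensitivity", 0.5),
        r_min=cfg.get("r_min_um", 4.0),
        r_max=cfg.get("r_max_um", 16.0),
        exclude_border=cfg.get("exclude_border", True),
        fill_holes=cfg.get("fill_holes", True),
        window=cfg.get("window"),
    )


def run_pipeline(manifest: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis described by an experiment manifest.

    Returns a bundle with per-treatment :class:`StrategyResult` objects
    and the classification (if performed); writes absorbance TIFFs,
    per-strategy cell CSVs, ``classification.json`` and
    ``run_log.json`` into the output directory.
    """
    if not isinstance(manifest, dict):
        mpath = Path(manifest)
        manifest = load_manifest(mpath)
        base = mpath.parent
    else:
        base = Path(manifest.get("base_dir", "."))

    if not manifest.get("treatments"):
        raise InvalidInputError("manifest lists no treatments")
    out = Path(out_dir or manifest.get("output_dir", "viatrace_out"))
    out.mkdir(parents=True, exist_ok=True)

    log: dict = {"version": __version__, "parameters": {}, "stages": {}}
    pixel_size = float(manifest["pixel_size_um"])
    wavelength = float(manifest.get("wavelength_nm", 610.0))
    cap = float(manifest.get("cap", 4.0))
    strategy = int(manifest.get("strategy", 3))
    channel = manifest.get("channel")

    with _stage("calibration"):
        if "epsilon_m2_per_mol" in manifest:
            epsilon = float(manifest["epsilon_m2_per_mol"])
            eps_sd = None
        else:
            curve = CalibrationCurve.from_csv(
                _resolve(base, manifest["calibration_csv"]), wavelength=wavelength
            )
            epsilon, eps_sd = fit_epsilon(curve)
        model = PixelDoseModel(epsilon=epsilon, pixel_size=pixel_size)
    log["parameters"].update(
        {
            "pixel_size_um": pixel_size,
            "wavelength_nm": wavelength,
            "cap": cap,
            "strategy": strategy,
            "epsilon_m2_per_mol": epsilon,
            "epsilon_sd_m2_per_mol": eps_sd,
        }
    )

    treatments = manifest["treatments"]
    if not treatments:
        raise InvalidInputError("manifest lists no treatments")

    datasets: dict[str, TreatmentDataset] = {}
    with _stage("conversion"):
        for role, spec in treatments.items():
            blanks = [
                load_intensity_image(_resolve(base, p), pixel_size, "blank", channel)
                for p in spec["blanks"]
            ]
            darks = [
                load_intensity_image(_resolve(base, p), pixel_size, "dark", channel)
                for p in spec["darks"]
            ]
            Imax = average_reference_images(blanks)
            Imin = average_reference_images(darks)
            fields = []
            for i, p in enumerate(spec["samples"]):
                I = load_intensity_image(_resolve(base, p), pixel_size, "sample", channel)
                A = to_absorbance(I, Imax, Imin, cap=cap, wavelength=wavelength)
                save_absorbance_image(out / f"absorbance_{role}_{i:02d}.tif", A)
                fields.append(A)
            params = _segmentation_params(manifest, spec)
            datasets[role] = TreatmentDataset(
                role=role if role in ("LD", "LT", "DD", "DT", "MIXTURE") else "UNKNOWN",
                fields=fields,
                params=params,
                model=model,
            )
            log["stages"].setdefault("segmentation_params", {})[role] = asdict(params)

    results: dict[str, StrategyResult] = {}
    with _stage("strategy"):
        lt_offset: tuple[float, float] | None = None
        if strategy == 3:
            if "LT" not in datasets:
                raise InvalidInputError("strategy 3 requires an LT treatment")
            from .strategies import scattering_offset

            lt_s2 = run_strategy(datasets["LT"], 2)
            mu, sigma = scattering_offset(lt_s2.moles)
            lt_offset = (mu, sigma)
            log["stages"]["scattering_offset_fmol"] = {
                "mu": mu * FMOL_PER_MOL,
                "sigma": sigma * FMOL_PER_MOL,
            }
        for role, ds in datasets.items():
            res = run_strategy(ds, strategy, lt_reference=lt_offset)
            results[role] = res
            write_cell_table(out / f"cells_{role}_strategy{strategy}.csv", res.records)
            log["stages"].setdefault("background_levels", {})[role] = res.background_levels
            log["stages"].setdefault("cell_counts", {})[role] = len(res.records)

    classification: ClassificationResult | None = None
    cls_cfg = manifest.get("classification")
    if cls_cfg:
        with _stage("classification"):
            classification = _classify(results, cls_cfg, log)
            payload = {
                "method": classification.method,
                "unit": classification.unit,
                "threshold": classification.threshold,
                "n_live": classification.n_live,
                "n_dead": classification.n_dead,
                "percent_dead": classification.percent_dead,
            }
            (out / "classification.json").write_text(json.dumps(payload, indent=2))

    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=_jsonable))
    return {
        "results": results,
        "classification": classification,
        "log": log,
        "out_dir": out,
    }


def _classify(results, cfg: dict, log: dict) -> ClassificationResult:
    method = cfg.get("method", "cmin")
    unit = cfg.get("unit", "moles")
    target_role = cfg.get("target", "MIXTURE")
    if target_role not in results:
        raise InvalidInputError(f"classification target {target_role!r} not analysed")
    values = _values(results[target_role], unit)
    if method == "cmin":
        if "LT" not in results or "DT" not in results:
            raise InvalidInputError("cmin classification needs LT and DT treatments")
        thr = cmin_threshold(
            _values(results["LT"], unit), _values(results["DT"], unit), unit=unit
        )
    elif method == "three_sigma":
        if "LT" not in results:
            raise InvalidInputError("three-sigma classification needs an LT treatment")
        thr = three_sigma_cutoff(_values(results["LT"], unit))
    elif method == "manual":
        scale = FMOL_PER_MOL if unit == "moles" else MMOL_PER_MOL
        thr = float(cfg["threshold"]) / scale  # manual thresholds given in fmol / mmol/L
    else:
        raise InvalidInputError(f"unknown classification method {method!r}")
    scale = FMOL_PER_MOL if unit == "moles" else MMOL_PER_MOL
    log["stages"]["classification_threshold"] = {"unit": unit, "value": thr * scale}
    res = classify_cells(values, thr, unit=unit, method=method)
    return res


def _values(result: StrategyResult, unit: str) -> np.ndarray:
    return result.moles if unit == "moles" else result.molarities


def _resolve(base: Path, p: str) -> Path:
    q = Path(p)
    return q if q.is_absolute() else base / q


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
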