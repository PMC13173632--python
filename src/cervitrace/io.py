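"""File I/O: calibrated images (PNG/TIFF + spacing sidecar), binary
masks (0/255 PNG), ground-truth JSON and cohort CSV.

Pixel spacing is mandatory on read — either passed explicitly or found
in a ``<name>.spacing.json`` sidecar — because silently assuming
1 mm/px would corrupt every downstream length.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .images import CanalMask, UltrasoundImage, as_spacing
from .phantoms import GroundTruth, ScreeningCohort

LUMINANCE = (0.2126, 0.7152, 0.0722)  # ITU-R BT.709 weights


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".spacing.json")


def read_image(path, pixel_spacing_mm=None) -> UltrasoundImage:
    """Load a PNG or TIFF image (8/16-bit; RGB collapsed by luminance).

    Spacing comes from the argument or from ``<file>.spacing.json``;
    if neither is available the load fails loudly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = np.tensordot(arr[..., :3].astype(np.float64), LUMINANCE, axes=1)
    if pixel_spacing_mm is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            pixel_spacing_mm = json.loads(sidecar.read_text())["pixel_spacing_mm"]
        else:
            raise ValueError(
                f"no pixel spacing for {path.name}: pass pixel_spacing_mm "
                f"explicitly or provide a sidecar file {sidecar.name}"
            )
    return UltrasoundImage(arr, as_spacing(pixel_spacing_mm), image_id=path.stem)


def write_image(image: UltrasoundImage, path) -> None:
    """Write a 16-bit TIFF (floats in [0,1] scaled to 0..65535) plus a
    spacing sidecar."""
    path = Path(path)
    arr = image.pixels
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.round(np.clip(arr, 0, 1) * 65535).astype(np.uint16)
    tifffile.imwrite(path, arr)
    _sidecar_path(path).write_text(
        json.dumps({"pixel_spacing_mm": list(image.pixel_spacing_mm)})
    )


def write_mask(mask: CanalMask, path) -> None:
    """PNG with {0, 255} encoding plus a spacing sidecar."""
    path = Path(path)
    Image.fromarray((mask.pixels * 255).astype(np.uint8)).save(path)
    _sidecar_path(path).write_text(
        json.dumps({"pixel_spacing_mm": list(mask.pixel_spacing_mm)})
    )


def read_mask(path, pixel_spacing_mm=None) -> CanalMask:
    """Read a 0/255 PNG mask back to 0/1; any other value is an error."""
    path = Path(path)
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        raise ValueError(f"mask {path.name} must be single-channel")
    bad = np.setdiff1d(np.unique(arr), [0, 255])
    if bad.size:
        raise ValueError(
            f"mask {path.name} contains non-binary values {bad.tolist()[:10]}; "
            "expected only 0 and 255"
        )
    if pixel_spacing_mm is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            pixel_spacing_mm = json.loads(sidecar.read_text())["pixel_spacing_mm"]
        else:
            raise ValueError(
                f"no pixel spacing for {path.name}: pass pixel_spacing_mm "
                f"explicitly or provide a sidecar file {sidecar.name}"
            )
    return CanalMask((arr == 255).astype(np.uint8), as_spacing(pixel_spacing_mm),
                     image_id=path.stem)


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps({
        "chord_mm": truth.chord_mm,
        "arc_mm": truth.arc_mm,
        "os_internal_px": list(truth.os_internal_px),
        "os_external_px": list(truth.os_external_px),
        "apex_px": list(truth.apex_px),
    }, indent=2))


def read_ground_truth(path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        chord_mm=d["chord_mm"], arc_mm=d["arc_mm"],
        os_internal_px=tuple(d["os_internal_px"]),
        os_external_px=tuple(d["os_external_px"]),
        apex_px=tuple(d["apex_px"]),
    )


COHORT_COLUMNS = ["subject_id", "ga_weeks", "cl_single_mm", "cl_two_mm",
                  "cl_ai_mm", "outcome"]


def write_cohort(cohort: ScreeningCohort, path) -> None:
    cohort.table.to_csv(path, index=False)


def read_cohort(path) -> ScreeningCohort:
    table = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns {sorted(missing)}")
    return ScreeningCohort(table=table)
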