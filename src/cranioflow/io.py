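"""Reading and writing the cine / mask / table formats.

Cine stacks are stored as NIfTI volumes with the cardiac frame on the
4th axis (one file for velocity, one for magnitude) plus a JSON sidecar
carrying the acquisition metadata the NIfTI header cannot:

    {"venc_cm_s", "cardiac_period_s", "pixel_spacing_mm",
     "slice_thickness_mm", "plane_label", "seeds": {label: {...}}}

ROI masks round-trip as integer-label NIfTI volumes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import nibabel as nib
import numpy as np

from .velocity import CineStack, RoiMask

__all__ = ["write_cine", "read_cine", "write_mask", "read_mask"]

SIDECAR_KEYS = ("venc_cm_s", "cardiac_period_s", "pixel_spacing_mm",
                "slice_thickness_mm", "plane_label")


def _affine(pixel_spacing: float, slice_thickness: float) -> np.ndarray:
    return np.diag([pixel_spacing, pixel_spacing, slice_thickness, 1.0])


def write_cine(
    stack: CineStack,
    prefix: Path | str,
    slice_thickness: float = 5.0,
    seeds: Optional[Mapping[str, Mapping]] = None,
) -> Dict[str, Path]:
    """Write a cine stack as ``<prefix>_vel.nii`` / ``<prefix>_mag.nii``
    plus ``<prefix>.json``.

    ``seeds`` optionally records per-vessel segmentation seeds
    (``{label: {"seed": [row, col], "direction_sign": ±1}}``) so a stored
    acquisition can be re-quantified without the generating scene.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    pixel_spacing = float(np.sqrt(stack.pixel_area))
    aff = _affine(pixel_spacing, slice_thickness)
    paths = {}
    for name, data in (("vel", stack.velocity), ("mag", stack.magnitude)):
        # NIfTI axes: (x, y, z=1, t); internal layout is (t, rows, cols)
        vol = np.transpose(data, (1, 2, 0))[:, :, None, :]
        p = prefix.with_name(prefix.name + f"_{name}.nii")
        nib.save(nib.Nifti1Image(vol.astype(np.float64), aff), p)
        paths[name] = p
    sidecar = {
        "venc_cm_s": stack.venc,
        "cardiac_period_s": stack.cardiac_period,
        "pixel_spacing_mm": pixel_spacing,
        "slice_thickness_mm": slice_thickness,
        "plane_label": stack.plane_label,
        "seeds": {k: dict(v) for k, v in (seeds or {}).items()},
    }
    pj = prefix.with_name(prefix.name + ".json")
    pj.write_text(json.dumps(sidecar, indent=1))
    paths["json"] = pj
    return paths


def read_cine(prefix: Path | str) -> Tuple[CineStack, Dict[str, Dict]]:
    """Read a cine stack written by :func:`write_cine`.

    Returns the stack and the sidecar's seed dictionary (may be empty).

    Raises
    ------
    ValueError
        If the sidecar is missing required metadata keys.
    """
    prefix = Path(prefix)
    pj = prefix.with_name(prefix.name + ".json")
    sidecar = json.loads(pj.read_text())
    missing = [k for k in SIDECAR_KEYS if k not in sidecar]
    if missing:
        raise ValueError(f"sidecar {pj} missing keys: {missing}")

    def _load(name: str) -> np.ndarray:
        vol = np.asarray(
            nib.load(prefix.with_name(prefix.name + f"_{name}.nii")).dataobj, dtype=float
        )
        return np.transpose(vol[:, :, 0, :], (2, 0, 1))

    stack = CineStack(
        velocity=_load("vel"),
        magnitude=_load("mag"),
        venc=float(sidecar["venc_cm_s"]),
        cardiac_period=float(sidecar["cardiac_period_s"]),
        pixel_area=float(sidecar["pixel_spacing_mm"]) ** 2,
        plane_label=sidecar["plane_label"],
    )
    return stack, sidecar.get("seeds", {})


def write_mask(roi: RoiMask, path: Path | str, pixel_spacing: float = 0.55,
               slice_thickness: float = 5.0) -> Path:
    """Write an ROI as an integer-label NIfTI (1 inside, 0 outside)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vol = roi.mask.astype(np.int16)[:, :, None]
    nib.save(nib.Nifti1Image(vol, _affine(pixel_spacing, slice_thickness)), path)
    return path


def read_mask(path: Path | str, label: str = "ROI", direction_sign: int = 1) -> RoiMask:
    vol = np.asarray(nib.load(Path(path)).dataobj)
    return RoiMask(label=label, mask=vol[:, :, 0] > 0, direction_sign=direction_sign)
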