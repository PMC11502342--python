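"""Readers and writers for volumes, masks, boundary maps and reports.

Formats
-------
* OCT volumes: multi-page TIFF (one page per B-scan), quantized to 16-bit,
  with a JSON sidecar (same stem, ``.json``) holding the pixel pitches, the
  dimensions and the intensity scale of the quantization.
* Masks: multi-page 8-bit binary TIFF.
* Boundary maps: CSV grid (slices x columns, um, ``%.6f``) with a JSON header
  sidecar; the round-trip is bit-exact at that precision.
* Phantom truth: ``*.truth.json`` plus companion CSV surface grids.
* Reports: JSON with floats rounded to 6 decimals so reruns are
  byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import tifffile

from .phantom import PhantomTruth
from .types import BoundaryMap, OCTVolume, SegmentationMask

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_boundary",
    "write_boundary",
    "write_truth",
    "read_truth",
    "write_json_report",
]

_QUANT = 65535


def write_volume(volume: OCTVolume, path: str | Path) -> Path:
    """Write a volume as 16-bit multi-page TIFF + JSON sidecar; returns the TIFF path."""
    path = Path(path).with_suffix(".tiff")
    scale = float(volume.data.max()) or 1.0
    stored = np.round(np.clip(volume.data / scale, 0, 1) * _QUANT).astype(np.uint16)
    tifffile.imwrite(path, stored, photometric="minisblack")
    sidecar = {
        "n_slices": volume.n_slices,
        "n_depth": volume.n_depth,
        "n_lateral": volume.n_lateral,
        "axial_pitch_um": volume.axial_pitch,
        "lateral_pitch_um": volume.lateral_pitch,
        "slice_pitch_um": volume.slice_pitch,
        "intensity_scale": scale,
        "quantization": _QUANT,
        "source": volume.meta.get("phantom_spec", volume.meta.get("source", "unspecified")),
        "coordinate_convention": "row 0 = top of image (shallowest); heights increase toward the probe",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))
    return path


def read_volume(path: str | Path) -> OCTVolume:
    """Read a multi-page TIFF volume; the JSON sidecar is required.

    Raises
    ------
    FileNotFoundError
        If the sidecar is missing (with a remediation hint).
    ValueError
        If sidecar dimensions disagree with the TIFF stack.
    """
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"volume sidecar {sidecar_path} not found; every volume TIFF needs a JSON "
            "sidecar with pixel pitches and intensity scale (see write_volume)"
        )
    meta = json.loads(sidecar_path.read_text())
    stored = tifffile.imread(path)
    if stored.ndim == 2:
        stored = stored[None]
    expected = (meta["n_slices"], meta["n_depth"], meta["n_lateral"])
    if stored.shape != expected:
        raise ValueError(f"sidecar declares {expected} but TIFF stack is {stored.shape}")
    data = stored.astype(np.float64) / meta.get("quantization", _QUANT) * meta["intensity_scale"]
    return OCTVolume(
        data=data,
        axial_pitch=meta["axial_pitch_um"],
        lateral_pitch=meta["lateral_pitch_um"],
        slice_pitch=meta["slice_pitch_um"],
        meta={"source": meta.get("source", "unspecified"), "sidecar": str(sidecar_path)},
    )


def write_mask(mask: SegmentationMask, path: str | Path) -> Path:
    path = Path(path).with_suffix(".tiff")
    labels = mask.labels if mask.labels.ndim == 3 else mask.labels[None]
    tifffile.imwrite(path, labels.astype(np.uint8), photometric="minisblack")
    return path


def read_mask(path: str | Path, backend: str = "file") -> SegmentationMask:
    labels = tifffile.imread(Path(path))
    if labels.ndim == 2:
        labels = labels[None]
    return SegmentationMask(labels=labels, backend=backend, provenance={"path": str(path)})


def write_boundary(boundary: BoundaryMap, path: str | Path) -> Path:
    """CSV grid of heights (um) + JSON header; %.6f round-trips bit-exactly."""
    path = Path(path).with_suffix(".csv")
    np.savetxt(path, boundary.heights, fmt="%.6f", delimiter=",")
    header = {
        "state": boundary.state,
        "axial_pitch_um": boundary.axial_pitch,
        "lateral_pitch_um": boundary.lateral_pitch,
        "slice_pitch_um": boundary.slice_pitch,
        "n_slices": int(boundary.heights.shape[0]),
        "n_lateral": int(boundary.heights.shape[1]),
        "missing_count": int(boundary.missing.sum()),
        "missing_rows_cols": np.argwhere(boundary.missing).tolist(),
    }
    path.with_suffix(".hdr.json").write_text(json.dumps(header, indent=2))
    return path


def read_boundary(path: str | Path) -> BoundaryMap:
    path = Path(path)
    header = json.loads(path.with_suffix(".hdr.json").read_text())
    heights = np.loadtxt(path, delimiter=",", ndmin=2)
    missing = np.zeros(heights.shape, dtype=bool)
    for r, c in header.get("missing_rows_cols", []):
        missing[r, c] = True
    return BoundaryMap(
        heights=heights,
        state=header["state"],
        missing=missing,
        axial_pitch=header["axial_pitch_um"],
        lateral_pitch=header["lateral_pitch_um"],
        slice_pitch=header["slice_pitch_um"],
    )


def write_truth(truth: PhantomTruth, stem: str | Path) -> Path:
    """Write ground truth as ``<stem>.truth.json`` + companion surface CSVs."""
    stem = Path(stem)
    surf = stem.parent / (stem.name + ".true_surface.csv")
    curved = stem.parent / (stem.name + ".true_curved_surface.csv")
    np.savetxt(surf, truth.true_surface.heights, fmt="%.6f", delimiter=",")
    np.savetxt(curved, truth.true_curved_surface.heights, fmt="%.6f", delimiter=",")
    payload = {
        "true_Ra_um": round(truth.true_Ra, 9),
        "true_Rz_um": round(truth.true_Rz, 9),
        "epidermis_thickness_um": truth.epidermis_thickness,
        "attenuation_mu_per_mm": truth.attenuation_mu,
        "axial_pitch_um": truth.true_surface.axial_pitch,
        "lateral_pitch_um": truth.true_surface.lateral_pitch,
        "slice_pitch_um": truth.true_surface.slice_pitch,
        "surface_csv": surf.name,
        "curved_surface_csv": curved.name,
    }
    out = stem.parent / (stem.name + ".truth.json")
    out.write_text(json.dumps(payload, indent=2))
    return out


def read_truth(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())


def write_json_report(report: dict[str, Any], path: str | Path) -> Path:
    """Serialize a report dict with sorted keys so reruns are byte-identical."""
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=float) + "\n")
    return path
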