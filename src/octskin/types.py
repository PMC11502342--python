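"""Core in-memory containers shared by all pipeline stages.

Conventions
-----------
* Volumes are indexed ``(slice, depth_row, lateral_column)``; depth row 0 is the
  top of the image (shallowest, closest to the probe).
* Heights are in micrometres and increase *toward* the probe, i.e. a surface
  point at a smaller depth row has a larger height.
* A-scan = one column of a B-scan; B-scan = one slice of the volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "OCTVolume",
    "SegmentationMask",
    "BoundaryMap",
    "RoughnessReport",
    "OpticsReport",
    "DepthProfile",
    "FitModel",
]


@dataclass
class OCTVolume:
    """A 3D OCT intensity volume with its acquisition geometry.

    Parameters
    ----------
    data:
        Float intensities in arbitrary units (nominally [0, 1]),
        shape ``(n_slices, n_depth, n_lateral)``.
    axial_pitch, lateral_pitch, slice_pitch:
        Pixel pitches in micrometres per pixel.
    meta:
        Free-form provenance (phantom spec hash, acquisition note, ...).
    """

    data: np.ndarray
    axial_pitch: float
    lateral_pitch: float
    slice_pitch: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D (slice, depth, lateral); got shape {self.data.shape}")
        for name in ("axial_pitch", "lateral_pitch", "slice_pitch"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def n_depth(self) -> int:
        return self.data.shape[1]

    @property
    def n_lateral(self) -> int:
        return self.data.shape[2]


@dataclass
class SegmentationMask:
    """Binary per-voxel label: 1 = tissue (skin/plate), 0 = background.

    In every valid A-scan column the tissue pixels form one contiguous run
    from the detected surface down to the bottom of the image; columns where
    no surface was found are all-zero and resolved later by boundary
    interpolation.
    """

    labels: np.ndarray
    backend: str = "classical"
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim not in (2, 3):
            raise ValueError("mask must be a 2D B-scan mask or a 3D volume mask")
        self.labels = (self.labels > 0).astype(np.uint8)


@dataclass
class BoundaryMap:
    """Air-skin boundary heights, one per A-scan, in micrometres.

    ``heights`` has shape ``(n_slices, n_lateral)``.  ``state`` is ``"raw"``
    (as extracted, curvature still present) or ``"detrended"`` (per-B-scan
    quadratic removed and global mean subtracted).  ``missing`` flags entries
    that were interpolated rather than detected.
    """

    heights: np.ndarray
    state: str = "raw"
    missing: np.ndarray | None = None
    axial_pitch: float = 1.0
    lateral_pitch: float = 1.0
    slice_pitch: float = 1.0

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if self.heights.ndim != 2:
            raise ValueError("boundary heights must be 2D (slices x lateral columns)")
        if self.state not in ("raw", "detrended"):
            raise ValueError(f"unknown boundary state {self.state!r}")
        if self.missing is None:
            self.missing = np.zeros(self.heights.shape, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.heights.shape:
                raise ValueError("missing flags must match heights shape")

    @property
    def missing_fraction(self) -> float:
        return float(self.missing.mean())


@dataclass
class FitModel:
    """Per-B-scan quadratic surface trend ``z = a*x**2 + b*x + c``.

    ``x`` is the lateral coordinate in micrometres; coefficients carry the
    matching units (a: um^-1, b: dimensionless, c: um).
    """

    a: float
    b: float
    c: float
    residual_rms: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        return self.a * x**2 + self.b * x + self.c


@dataclass
class RoughnessReport:
    """Arithmetic mean roughness Ra and depth of roughness Rz, both in um."""

    Ra: float
    Rz: float
    n_x: int
    n_y: int
    region: dict[str, Any] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "Ra_um": round(float(self.Ra), 6),
            "Rz_um": round(float(self.Rz), 6),
            "n_x": int(self.n_x),
            "n_y": int(self.n_y),
            "region": self.region,
            "provenance": self.provenance,
        }


@dataclass
class DepthProfile:
    """Mean OCT intensity versus depth, surface-aligned.

    ``signal[k]`` is the mean intensity ``k`` axial pixels below the detected
    surface; ``depth_axis`` gives the same axis in micrometres.
    """

    signal: np.ndarray
    depth_axis: np.ndarray
    smoothing: str = "none"
    samples_per_pixel: float = 1.0  # profile samples per native axial pixel

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.depth_axis = np.asarray(self.depth_axis, dtype=np.float64)
        if self.signal.shape != self.depth_axis.shape:
            raise ValueError("signal and depth_axis must have the same shape")

    @property
    def axial_pitch(self) -> float:
        if len(self.depth_axis) < 2:
            return 1.0
        return float(self.depth_axis[1] - self.depth_axis[0])


@dataclass
class OpticsReport:
    """Epidermal thickness (um) and dermal attenuation coefficient (mm^-1)."""

    epidermal_thickness: float
    attenuation_mu: float
    fit_window_um: tuple[float, float]
    fit_r2: float
    raw_slope_per_mm: float = float("nan")

    def to_dict(self) -> dict[str, Any]:
        return {
            "epidermal_thickness_um": round(float(self.epidermal_thickness), 6),
            "attenuation_mu_per_mm": round(float(self.attenuation_mu), 6),
            "fit_window_um": [round(float(v), 6) for v in self.fit_window_um],
            "fit_r2": round(float(self.fit_r2), 6),
            "raw_slope_per_mm": round(float(self.raw_slope_per_mm), 6),
        }
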