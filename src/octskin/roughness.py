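"""Areal surface roughness parameters Ra and Rz.

Both are evaluated on a detrended (zero-mean) boundary height map
``z(x_i, y_j)`` over an ``n_x x n_y`` grid of A-scan positions:

    Ra = (1 / (n_x * n_y)) * sum_i sum_j |z(x_i, y_j)|
    Rz = max(z) - min(z)

Ra is the arithmetic average of absolute heights about the mean line; Rz is
the single peak-to-valley height of the whole evaluation region (not the ISO
five-segment average).  Both scale linearly with the heights and are
invariant to any spatial permutation of grid values.
"""

from __future__ import annotations

import numpy as np

from .types import BoundaryMap, RoughnessReport

__all__ = ["compute_ra", "compute_rz", "roughness_report", "crop_region"]

#: default fraction of columns trimmed at each lateral edge, where the
#: quadratic fit is least constrained
DEFAULT_EDGE_TRIM = 0.05


def _check(surface: BoundaryMap) -> np.ndarray:
    if surface.state != "detrended":
        raise ValueError("roughness requires a detrended boundary map (run flatten first)")
    z = surface.heights
    if not np.isfinite(z).all():
        raise ValueError("boundary map contains non-finite heights")
    return z


def compute_ra(surface: BoundaryMap) -> float:
    """Arithmetic mean roughness in um: mean absolute height about the mean line."""
    return float(np.mean(np.abs(_check(surface))))


def compute_rz(surface: BoundaryMap) -> float:
    """Depth of roughness in um: highest peak minus lowest valley."""
    z = _check(surface)
    return float(z.max() - z.min())


def crop_region(surface: BoundaryMap, edge_trim: float = DEFAULT_EDGE_TRIM) -> BoundaryMap:
    """Trim a fraction of columns at each lateral edge of the evaluation region."""
    if not 0 <= edge_trim < 0.5:
        raise ValueError("edge_trim must be in [0, 0.5)")
    n_lat = surface.heights.shape[1]
    k = int(round(edge_trim * n_lat))
    sl = slice(k, n_lat - k if k else None)
    return BoundaryMap(
        heights=surface.heights[:, sl],
        state=surface.state,
        missing=surface.missing[:, sl],
        axial_pitch=surface.axial_pitch,
        lateral_pitch=surface.lateral_pitch,
        slice_pitch=surface.slice_pitch,
    )


def roughness_report(
    surface: BoundaryMap,
    edge_trim: float = DEFAULT_EDGE_TRIM,
    provenance: dict | None = None,
) -> RoughnessReport:
    """Compute Ra and Rz on the (optionally edge-trimmed) evaluation region."""
    region = crop_region(surface, edge_trim)
    n_y, n_x = region.heights.shape
    return RoughnessReport(
        Ra=compute_ra(region),
        Rz=compute_rz(region),
        n_x=n_x,
        n_y=n_y,
        region={"edge_trim": edge_trim, "n_slices": n_y, "n_columns": n_x},
        provenance=provenance or {},
    )
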