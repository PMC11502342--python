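"""Boundary extraction and curvature flattening.

From a binary mask the air-skin boundary is read off as the topmost tissue
pixel of each A-scan and converted to a height in micrometres.  The natural
curvature of the skin is then removed per B-scan with an ordinary
least-squares quadratic fit; subtracting the fit and then the global mean of
all residuals leaves a zero-mean height *texture* map from which roughness is
computed, following the ISO mean-line convention.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import BoundaryMap, FitModel, OCTVolume, SegmentationMask

__all__ = ["extract_boundary", "fit_curvature", "flatten", "refine_boundary_subpixel"]

logger = logging.getLogger(__name__)


def _interp_missing(row: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Fill flagged entries by 1D linear interpolation (edges: nearest value)."""
    if not missing.any():
        return row
    x = np.arange(row.size)
    valid = ~missing
    return np.interp(x, x[valid], row[valid])


def extract_boundary(
    mask: SegmentationMask,
    axial_pitch: float,
    reference_row: float = 0.0,
    max_missing_fraction: float = 0.5,
) -> BoundaryMap:
    """Read the raw air-skin boundary off a volume mask.

    Per column the boundary is the depth row of the topmost skin pixel,
    converted to height ``(reference_row - row) * axial_pitch`` so that
    heights increase toward the probe.  Columns with no skin are flagged
    missing and filled by linear interpolation from their nearest valid
    neighbours; a B-scan with more than ``max_missing_fraction`` missing
    columns is considered unreliable.
    """
    labels = mask.labels
    if labels.ndim == 2:
        labels = labels[None]
    n_slices, n_depth, n_lat = labels.shape

    heights = np.empty((n_slices, n_lat))
    missing = np.zeros((n_slices, n_lat), dtype=bool)
    for s in range(n_slices):
        any_skin = labels[s].any(axis=0)
        top = labels[s].argmax(axis=0)
        miss = ~any_skin
        if miss.mean() > max_missing_fraction:
            raise ValueError(
                f"unreliable boundary: {miss.mean():.0%} of columns in B-scan {s} have no skin"
            )
        h = (reference_row - top.astype(np.float64)) * axial_pitch
        h[miss] = np.nan
        heights[s] = _interp_missing(h, miss)
        missing[s] = miss
    if missing.any():
        logger.info("interpolated %d missing boundary columns (%.2f%%)",
                    int(missing.sum()), 100 * missing.mean())
    return BoundaryMap(heights=heights, state="raw", missing=missing, axial_pitch=axial_pitch)


def refine_boundary_subpixel(
    boundary: BoundaryMap,
    volume: OCTVolume,
    step_k: int = 3,
    lateral_smooth: int = 5,
) -> BoundaryMap:
    """Sub-pixel boundary refinement from the intensity image.

    The mask-derived boundary is quantized to whole depth rows, which biases
    Ra upward when texture amplitudes are only a few axial pixels.  For each
    column the step matched-filter response (the statistic the classical
    backend maximizes) is interpolated with a parabola through the three rows
    around the integer boundary; the vertex shifts the boundary by at most
    half a pixel.
    """
    from .segmentation import step_response

    if boundary.state != "raw":
        raise ValueError("refine before flattening: expected a raw boundary")
    h = boundary.heights.copy()
    ap = volume.axial_pitch
    cols = np.arange(volume.n_lateral)
    for s in range(volume.n_slices):
        resp = step_response(volume.data[s], step_k, lateral=lateral_smooth)
        rows = np.clip(np.round(-h[s] / ap).astype(int), step_k + 1, volume.n_depth - step_k - 1)
        r0 = resp[rows - 1, cols]
        r1 = resp[rows, cols]
        r2 = resp[rows + 1, cols]
        denom = r0 - 2 * r1 + r2
        shift = np.where(np.abs(denom) > 1e-12,
                         0.5 * (r0 - r2) / np.where(denom == 0, 1, denom), 0.0)
        shift = np.clip(shift, -0.5, 0.5)
        h[s] = -(rows + shift) * ap
    return BoundaryMap(heights=h, state="raw", missing=boundary.missing.copy(),
                       axial_pitch=ap, lateral_pitch=boundary.lateral_pitch,
                       slice_pitch=boundary.slice_pitch)


def fit_curvature(boundary_row: np.ndarray, x_um: np.ndarray | None = None) -> FitModel:
    """Ordinary least-squares quadratic fit to one B-scan's boundary heights.

    Exact (to machine precision) for input that is itself quadratic.

    Parameters
    ----------
    boundary_row:
        1D heights in um; NaN entries are ignored.
    x_um:
        Lateral coordinates in um; defaults to the pixel index.
    """
    z = np.asarray(boundary_row, dtype=np.float64)
    if x_um is None:
        x_um = np.arange(z.size, dtype=np.float64)
    valid = np.isfinite(z)
    if valid.sum() < 3:
        raise ValueError("need at least 3 valid points for a quadratic fit")
    xv, zv = x_um[valid], z[valid]
    if np.ptp(xv) == 0:
        raise ValueError("rank-deficient fit: all lateral coordinates equal")
    coeffs = np.polyfit(xv, zv, 2)
    resid = zv - np.polyval(coeffs, xv)
    return FitModel(a=float(coeffs[0]), b=float(coeffs[1]), c=float(coeffs[2]),
                    residual_rms=float(np.sqrt(np.mean(resid**2))))


def flatten(boundary: BoundaryMap, lateral_pitch: float | None = None) -> BoundaryMap:
    """Remove natural curvature: per-B-scan quadratic detrend + global mean removal.

    Each slice is fitted and its quadratic trend subtracted independently;
    the global mean of all residuals is then removed so the assembled 2D map
    is zero-mean (the ISO mean line of the whole evaluation region).
    Idempotent: flattening a detrended map changes nothing beyond round-off.

    A slice whose fit fails is dropped from the output with a warning.
    """
    lp = lateral_pitch if lateral_pitch is not None else boundary.lateral_pitch
    x_um = np.arange(boundary.heights.shape[1], dtype=np.float64) * lp

    residuals = []
    kept = []
    for s in range(boundary.heights.shape[0]):
        try:
            model = fit_curvature(boundary.heights[s], x_um)
        except ValueError as exc:
            logger.warning("dropping B-scan %d from boundary map: %s", s, exc)
            continue
        residuals.append(boundary.heights[s] - model.predict(x_um))
        kept.append(s)
    if not residuals:
        raise ValueError("no B-scan could be fitted")
    res = np.asarray(residuals)
    res -= res.mean()
    return BoundaryMap(
        heights=res,
        state="detrended",
        missing=boundary.missing[kept],
        axial_pitch=boundary.axial_pitch,
        lateral_pitch=lp,
        slice_pitch=boundary.slice_pitch,
    )
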