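"""Binary skin/background segmentation of OCT B-scans.

Two interchangeable backends produce :class:`~octskin.types.SegmentationMask`
objects with identical guarantees (per-column contiguity from the surface
down):

* a deterministic *classical* backend (this module): per A-scan the air-skin
  interface is located as the strongest upward intensity step, searched
  around a coarse adaptive-threshold crossing, then cleaned up in 2D;
* a trainable *neural* backend (:mod:`octskin.nn`): a small convolutional
  encoder-decoder with skip connections.

Mask quality is scored with mean intersection-over-union (MIoU) on a 0-100
scale, averaged over the two classes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .types import OCTVolume, SegmentationMask

__all__ = [
    "ClassicalParams",
    "segment_classical",
    "segment_volume_classical",
    "miou",
    "polygon_to_mask",
    "smooth_bscan",
    "step_response",
]


@dataclass
class ClassicalParams:
    """Tunables of the classical backend.

    Detection is two-stage.  A *coarse* stage thresholds a smoothed image at
    ``median + k_mad * MAD`` of the noise floor (estimated from the top
    ``noise_rows`` rows, assumed to be air) to find the approximate surface
    per column; the threshold adapts to the intensity scale, so segmentation
    is invariant to global scaling.  A *fine* stage then places the boundary
    at the maximum of a step matched filter (mean of ``step_k`` rows below
    minus mean of ``step_k`` rows above) within ``search_px`` rows of the
    coarse estimate - an unbiased estimator of a step edge that is exact on
    noise-free images.

    Lateral smoothing over ``lateral_smooth`` columns suppresses speckle; it
    is automatically disabled when the noise floor has (near) zero spread,
    i.e. on noise-free images, so those are segmented exactly.
    """

    depth_smooth: int = 7
    lateral_smooth: int = 5
    k_mad: float = 8.0
    noise_rows: int = 8
    step_k: int = 3
    search_px: int = 7
    median_size: int = 3  # 2D median filter applied to the binary mask
    outlier_px: int = 5  # columns whose boundary deviates more than this from
    outlier_window: int = 31  # .. a running median over this many columns are dropped
    boundary_median: int = 3  # median smoothing of the boundary row across columns


def smooth_bscan(img: np.ndarray, p: ClassicalParams, lateral: int | None = None) -> np.ndarray:
    """Speckle-reducing smoothing used by the coarse detection stage.

    The depth window is *trailing* (it averages the current row and the rows
    above it) so that on a noise-free image the first supra-threshold row is
    exactly the first tissue row: no tissue intensity leaks upward.  The
    lateral window is centered.
    """
    ls = p.lateral_smooth if lateral is None else lateral
    sm = ndimage.uniform_filter1d(img, size=ls, axis=1, mode="nearest") if ls > 1 else img
    return ndimage.uniform_filter1d(sm, size=p.depth_smooth, axis=0, mode="nearest",
                                    origin=(p.depth_smooth - 1) // 2)


def step_response(img: np.ndarray, k: int, lateral: int = 1, log: bool = True) -> np.ndarray:
    """Matched-filter response to an upward step edge, per pixel.

    ``R[r, c] = mean(img[r : r+k, c]) - mean(img[r-k : r, c])`` after optional
    lateral averaging; rows without a full window are set to ``-inf``.  For a
    clean step the response peaks exactly at the first row of the upper level.

    By default the filter runs on log intensity: multiplicative speckle then
    becomes additive noise of *constant* variance, so the peak location is
    not biased toward brighter rows and the step's log-contrast dominates the
    noise.
    """
    if log:
        pos = img[img > 0]
        eps = 1e-6 * float(np.median(pos)) if pos.size else 1e-12
        img = np.log(np.maximum(img, eps))
    if lateral > 1:
        img = ndimage.uniform_filter1d(img, size=lateral, axis=1, mode="nearest")
    n = img.shape[0]
    cs = np.vstack([np.zeros((1, img.shape[1])), np.cumsum(img, axis=0)])
    r = np.arange(n)
    resp = np.full(img.shape, -np.inf)
    valid = (r >= k) & (r <= n - k)
    rv = r[valid]
    below = (cs[rv + k] - cs[rv]) / k
    above = (cs[rv] - cs[rv - k]) / k
    resp[valid] = below - above
    return resp


def _first_crossing(smooth: np.ndarray, threshold: float) -> np.ndarray:
    """Row index of the first supra-threshold pixel per column; -1 if none."""
    above = smooth > threshold
    any_above = above.any(axis=0)
    first = above.argmax(axis=0)
    return np.where(any_above, first, -1)


def segment_classical(
    bscan: np.ndarray,
    params: ClassicalParams | None = None,
) -> SegmentationMask:
    """Segment one B-scan (depth x lateral) into skin (1) / background (0).

    Columns where no surface is found are left all-zero and flagged in
    provenance; if *every* column is empty the scan has no detectable
    surface and a ``ValueError`` is raised.
    """
    p = params or ClassicalParams()
    img = np.asarray(bscan, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("B-scan must be a non-empty 2D array")
    if not np.isfinite(img).all():
        raise ValueError("B-scan contains non-finite intensities")

    # --- coarse stage: adaptive threshold on the smoothed image -------------
    smooth = smooth_bscan(img, p)
    noise = smooth[: p.noise_rows]
    med = float(np.median(noise))
    mad = float(np.median(np.abs(noise - med)))
    noiseless = mad <= max(1e-3 * med, 1e-15)
    if noiseless:
        # constant noise floor: no speckle to average; skip lateral smoothing
        smooth = smooth_bscan(img, p, lateral=1)
    threshold = med + p.k_mad * max(mad, 0.05 * med, 1e-12)
    first = _first_crossing(smooth, threshold)
    if (first >= 0).mean() < 0.2:
        # isolated speckle clusters can cross the threshold in a handful of
        # columns even without tissue; a real surface spans most of the scan
        raise ValueError("no surface detected")

    # --- fine stage: unbiased step localization around the coarse estimate --
    n_depth, n_lat = img.shape
    resp = step_response(img, p.step_k, lateral=1 if noiseless else p.lateral_smooth)
    rows = np.arange(n_depth)[:, None]
    coarse = np.where(first >= 0, first, int(np.median(first[first >= 0])))
    allowed = np.abs(rows - coarse[None, :]) <= p.search_px
    fine = np.where(allowed, resp, -np.inf).argmax(axis=0)
    valid = first >= 0

    mask = np.zeros(img.shape, dtype=np.uint8)
    mask[:, valid] = (rows >= fine[valid][None, :]).astype(np.uint8)

    # --- 2D clean-up ---------------------------------------------------------
    if p.median_size > 1 and not noiseless:
        mask = ndimage.median_filter(mask, size=(p.median_size, p.median_size), mode="nearest")
    labels, n_comp = ndimage.label(mask)
    if n_comp > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_comp + 1))
        mask = (labels == (1 + int(np.argmax(sizes)))).astype(np.uint8)
    first2 = _first_crossing(mask.astype(float), 0.5)
    valid2 = first2 >= 0
    if not valid2.any():
        raise ValueError("no surface detected")
    # speckle clusters above the surface can survive the median filter as
    # narrow false runs; reject columns far from the running median of the
    # boundary and let the surface module interpolate them
    bnd = np.where(valid2, first2, int(np.median(first2[valid2]))).astype(float)
    if p.outlier_px > 0:
        running_med = ndimage.median_filter(bnd, size=p.outlier_window, mode="mirror")
        valid2 &= np.abs(bnd - running_med) <= p.outlier_px
    if valid2.any() and not valid2.all():
        # rejected/undetected columns: fill from their valid neighbours so the
        # mask has no hole columns (count kept in provenance for auditing)
        x = np.arange(n_lat)
        bnd = np.interp(x, x[valid2], bnd[valid2])
    if p.boundary_median > 1 and not noiseless:
        bnd = ndimage.median_filter(bnd, size=p.boundary_median, mode="mirror")
    mask = (rows >= np.round(bnd).astype(int)[None, :]).astype(np.uint8)

    return SegmentationMask(
        labels=mask,
        backend="classical",
        provenance={**asdict(p), "threshold": threshold, "noiseless": noiseless,
                    "missing_columns": int((~valid2).sum())},
    )


def segment_volume_classical(
    volume: OCTVolume,
    params: ClassicalParams | None = None,
) -> SegmentationMask:
    """Apply :func:`segment_classical` slice by slice to a full volume."""
    masks = np.empty(volume.data.shape, dtype=np.uint8)
    missing = 0
    thresholds = []
    for s in range(volume.n_slices):
        m = segment_classical(volume.data[s], params)
        masks[s] = m.labels
        missing += int(m.provenance.get("missing_columns", 0))
        thresholds.append(m.provenance["threshold"])
    return SegmentationMask(
        labels=masks,
        backend="classical",
        provenance={**asdict(params or ClassicalParams()), "missing_columns": missing,
                    "threshold": thresholds},
    )


def miou(pred: SegmentationMask | np.ndarray, truth: SegmentationMask | np.ndarray) -> float:
    """Mean intersection-over-union over {background, skin}, on a 0-100 scale.

    A class absent from both masks contributes IoU 1 (perfect agreement on
    its absence).  Symmetric in its arguments; 100 iff the masks are equal.
    """
    a = pred.labels if isinstance(pred, SegmentationMask) else np.asarray(pred)
    b = truth.labels if isinstance(truth, SegmentationMask) else np.asarray(truth)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    a = a > 0
    b = b > 0
    ious = []
    for cls in (False, True):
        pa, ta = a == cls, b == cls
        union = np.logical_or(pa, ta).sum()
        if union == 0:
            ious.append(1.0)
        else:
            ious.append(np.logical_and(pa, ta).sum() / union)
    return float(100.0 * np.mean(ious))


def polygon_to_mask(vertices: np.ndarray, shape: tuple[int, int]) -> SegmentationMask:
    """Rasterize a closed polygon (rows, cols vertices) into a binary mask.

    Convenience for converting hand-annotated boundary polygons into masks.
    """
    from skimage.draw import polygon

    v = np.asarray(vertices, dtype=np.float64)
    rr, cc = polygon(v[:, 0], v[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=np.uint8)
    mask[rr, cc] = 1
    return SegmentationMask(labels=mask, backend="annotation", provenance={"n_vertices": len(v)})
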