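"""Boundary extraction, quadratic curvature fitting and flattening."""

import numpy as np
import pytest

from octskin.segmentation import segment_volume_classical
from octskin.surface import extract_boundary, fit_curvature, flatten
from octskin.types import BoundaryMap, SegmentationMask


def column_mask(tops, n_depth):
    """Build a contiguous-from-top mask from per-column boundary rows (-1 = empty)."""
    n_lat = len(tops)
    m = np.zeros((n_depth, n_lat), dtype=np.uint8)
    for c, t in enumerate(tops):
        if t >= 0:
            m[t:, c] = 1
    return m


class TestExtractBoundary:
    def test_topmost_skin_pixel_defines_boundary(self):
        mask = SegmentationMask(column_mask([3, 4, 5], 10))
        b = extract_boundary(mask, axial_pitch=2.0)
        assert np.allclose(b.heights[0], [-6.0, -8.0, -10.0])
        assert b.state == "raw"

    def test_all_skin_mask_boundary_at_row_zero(self):
        mask = SegmentationMask(np.ones((1, 8, 5)))
        b = extract_boundary(mask, axial_pitch=4.0)
        assert np.all(b.heights == 0.0)

    def test_missing_columns_interpolated_linearly(self):
        mask = SegmentationMask(column_mask([2, -1, 4, -1, -1, 8], 12))
        b = extract_boundary(mask, axial_pitch=1.0)
        assert np.allclose(b.heights[0], [-2, -3, -4, -16 / 3, -20 / 3, -8])
        assert b.missing[0].tolist() == [False, True, False, True, True, False]

    def test_edge_missing_columns_use_nearest_value(self):
        mask = SegmentationMask(column_mask([-1, 5, 6, -1], 10))
        b = extract_boundary(mask, axial_pitch=1.0)
        assert b.heights[0, 0] == -5.0
        assert b.heights[0, 3] == -6.0

    def test_mostly_missing_bscan_rejected(self):
        mask = SegmentationMask(column_mask([3, -1, -1, -1], 8))
        with pytest.raises(ValueError, match="unreliable"):
            extract_boundary(mask, axial_pitch=1.0)

    def test_phantom_mask_boundary_within_quantization(self, skin_speckled):
        # against the rendered truth: quantization is at most one axial pixel,
        # and close to half a pixel once the constant offset is removed (the
        # mean of the fractional parts is only approximately one half)
        vol, truth = skin_speckled
        b = extract_boundary(truth.true_mask, vol.axial_pitch)
        err = b.heights - (-truth.surface_row * vol.axial_pitch)
        assert err.max() - err.min() <= vol.axial_pitch + 1e-9
        err -= err.mean()
        assert np.abs(err).max() <= 0.6 * vol.axial_pitch


class TestFitCurvature:
    def test_exact_quadratic_recovered_to_machine_precision(self):
        x = np.linspace(-3, 3, 41)
        m = fit_curvature(2 * x**2, x)
        assert m.a == pytest.approx(2.0, abs=1e-10)
        assert m.b == pytest.approx(0.0, abs=1e-10)
        assert m.c == pytest.approx(0.0, abs=1e-10)
        assert m.residual_rms == pytest.approx(0.0, abs=1e-10)

    def test_constant_input(self):
        m = fit_curvature(np.full(10, 7.5))
        assert (m.a, m.b) == (pytest.approx(0, abs=1e-12), pytest.approx(0, abs=1e-12))
        assert m.c == pytest.approx(7.5)

    def test_quadratic_plus_sinusoid(self):
        # the quadratic trend is recovered and the residual keeps the texture:
        # residual mean |z| of a sinusoid -> 2A/pi
        x = np.arange(4096, dtype=float)
        A = 4.0
        z = 1e-5 * (x - 2048) ** 2 + A * np.sin(2 * np.pi * x / 64)
        m = fit_curvature(z, x)
        assert m.a == pytest.approx(1e-5, rel=1e-3)
        resid = z - m.predict(x)
        assert np.mean(np.abs(resid - resid.mean())) == pytest.approx(2 * A / np.pi, rel=1e-2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_curvature(np.array([1.0, 2.0]))

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            fit_curvature(np.array([1.0, 2.0, 3.0]), np.zeros(3))


class TestFlatten:
    def test_pure_quadratic_surface_annihilated(self):
        x = np.arange(64, dtype=float)
        rowz = 3e-4 * (x - 32) ** 2 - 0.01 * x + 5
        b = BoundaryMap(np.tile(rowz, (4, 1)), state="raw", lateral_pitch=1.0)
        det = flatten(b)
        assert det.state == "detrended"
        assert np.abs(det.heights).max() < 1e-9

    def test_detrended_map_has_zero_mean(self, plate_speckled):
        vol, _ = plate_speckled
        mask = segment_volume_classical(vol)
        det = flatten(extract_boundary(mask, vol.axial_pitch), vol.lateral_pitch)
        assert abs(det.heights.mean()) < 1e-9

    def test_flatten_is_idempotent(self):
        rng = np.random.default_rng(3)
        x = np.arange(128, dtype=float)
        rows = 2e-4 * (x - 64) ** 2 + rng.normal(0, 2.0, (5, 128))
        once = flatten(BoundaryMap(rows, state="raw", lateral_pitch=1.0))
        twice = flatten(once)
        assert np.allclose(once.heights, twice.heights, atol=1e-9)

    def test_phantom_texture_recovered_after_curvature_removal(self):
        # detrending the true (curved) boundary must return the true texture
        # up to mask quantization (about half an axial pixel) plus fit
        # leakage, which is small for a periodic texture spanning many periods
        from octskin.phantom import PhantomSpec, make_plate_phantom

        spec = PhantomSpec(n_slices=4, n_depth=256, n_lateral=512,
                           curvature_coeff=2e-6, speckle="none")
        vol, truth = make_plate_phantom(6.3, spec)
        b = extract_boundary(truth.true_mask, vol.axial_pitch)
        det = flatten(b, vol.lateral_pitch)
        err = det.heights - truth.true_surface.heights
        assert np.abs(err - err.mean()).max() <= 0.75 * vol.axial_pitch
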