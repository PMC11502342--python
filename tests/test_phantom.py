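"""Phantom generator: analytic surface truth, rendering, determinism."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.stats import pearsonr

from octskin.phantom import (
    PhantomSpec,
    make_cohort,
    make_plate_phantom,
    make_surface,
    render_volume,
)


def brute_force_ra_rz(heights):
    """Independent definition: mean |z| about the mean, and peak-to-valley."""
    z = np.asarray(heights, dtype=float)
    z = z - z.mean()
    return np.abs(z).mean(), z.max() - z.min()


class TestMakeSurface:
    def test_flat_profile_is_identically_zero(self):
        spec = PhantomSpec(n_slices=4, n_lateral=64, surface_profile="flat", amplitude=0)
        s = make_surface(spec)
        assert np.all(s.heights == 0.0)
        ra, rz = brute_force_ra_rz(s.heights)
        assert ra == 0.0 and rz == 0.0

    def test_triangle_matches_continuous_limit(self):
        # peak amplitude A over an exact number of periods: Ra -> A/2, Rz -> 2A
        spec = PhantomSpec(n_slices=2, n_lateral=4096, lateral_pitch=1.0,
                           surface_profile="triangle", amplitude=12.6, period=256.0)
        s = make_surface(spec)
        ra, rz = brute_force_ra_rz(s.heights)
        assert ra == pytest.approx(6.3, rel=1e-2)
        assert rz == pytest.approx(25.2, rel=1e-2)

    def test_sinusoid_ra_converges_to_2A_over_pi(self):
        A = 5.0
        errs = []
        for n in (256, 1024, 4096):
            spec = PhantomSpec(n_slices=1, n_lateral=n, lateral_pitch=1.0,
                               surface_profile="sinusoid", amplitude=A, period=n / 8)
            ra, _ = brute_force_ra_rz(make_surface(spec).heights)
            errs.append(abs(ra - 2 * A / np.pi))
        assert errs[-1] < 1e-4
        assert errs[0] >= errs[-1]

    def test_period_below_nyquist_rejected(self):
        with pytest.raises(ValueError, match="alias"):
            PhantomSpec(surface_profile="sinusoid", period=30.0, lateral_pitch=25.0)

    def test_scale_equivariance(self):
        base = PhantomSpec(n_slices=4, n_lateral=128, surface_profile="filtered-noise",
                           amplitude=5.0, seed=9)
        s1 = make_surface(base)
        s3 = make_surface(replace(base, amplitude=15.0))
        assert np.allclose(3.0 * s1.heights, s3.heights, atol=1e-12)


class TestRenderVolume:
    def test_seeded_render_is_bit_identical(self):
        spec = PhantomSpec(n_slices=3, n_depth=160, n_lateral=64, seed=5)
        v1, t1 = render_volume(spec)
        v2, t2 = render_volume(spec)
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(t1.true_mask.labels, t2.true_mask.labels)
        assert t1.true_Ra == t2.true_Ra

    def test_truth_matches_brute_force_recomputation(self, skin_speckled):
        _, truth = skin_speckled
        ra, rz = brute_force_ra_rz(truth.true_surface.heights)
        assert truth.true_Ra == pytest.approx(ra, abs=1e-9)
        assert truth.true_Rz == pytest.approx(rz, abs=1e-9)
        assert truth.true_Rz >= truth.true_Ra >= 0

    def test_curvature_changes_surface_not_truth(self):
        base = PhantomSpec(n_slices=3, n_depth=256, n_lateral=128,
                           surface_profile="filtered-noise", amplitude=8.0, seed=2)
        _, t0 = render_volume(base)
        _, t1 = render_volume(replace(base, curvature_coeff=2e-6))
        assert t0.true_Ra == t1.true_Ra
        assert t0.true_Rz == t1.true_Rz
        assert not np.allclose(t0.true_curved_surface.heights, t1.true_curved_surface.heights)

    def test_noiseless_dermal_log_slope_is_minus_2mu(self):
        spec = PhantomSpec(n_slices=1, n_depth=300, n_lateral=8, surface_profile="flat",
                           amplitude=0, speckle="none", attenuation_mu=3.0)
        vol, truth = render_volume(spec)
        col = vol.data[0, :, 0]
        surface = int(truth.surface_row[0, 0])
        dej = surface + 2 + int(100 / 4)  # entrance peak offset + epidermis pixels
        window = col[dej + 2: dej + 40]
        z_mm = np.arange(window.size) * 4.0 / 1000.0
        slope = np.polyfit(z_mm, np.log(window), 1)[0]
        assert slope == pytest.approx(-6.0, abs=1e-9)

    def test_layer_stack_deeper_than_volume_rejected(self):
        spec = PhantomSpec(n_slices=1, n_depth=40, n_lateral=32)
        with pytest.raises(ValueError, match="depth"):
            render_volume(spec)


class TestPlatePhantom:
    def test_target_ra_is_grid_exact(self):
        spec = PhantomSpec(n_slices=2, n_depth=256, n_lateral=512, speckle="none")
        _, truth = make_plate_phantom(6.3, spec)
        assert truth.true_Ra == pytest.approx(6.3, abs=1e-9)

    def test_zero_target_gives_flat_plate(self):
        spec = PhantomSpec(n_slices=2, n_depth=256, n_lateral=128, speckle="none")
        _, truth = make_plate_phantom(0.0, spec)
        assert truth.true_Ra == 0.0

    def test_ra_linear_in_amplitude(self):
        spec = PhantomSpec(n_slices=1, n_depth=256, n_lateral=512, speckle="none")
        _, t1 = make_plate_phantom(6.3, spec)
        _, t2 = make_plate_phantom(12.6, spec)
        a1 = np.abs(t1.true_surface.heights).max()
        a2 = np.abs(t2.true_surface.heights).max()
        assert a2 == pytest.approx(2 * a1, rel=1e-12)

    def test_negative_target_rejected(self):
        with pytest.raises(ValueError):
            make_plate_phantom(-1.0)


class TestCohort:
    BASE = PhantomSpec(n_slices=2, n_depth=256, n_lateral=64)

    def test_noise_free_cohort_is_perfectly_correlated(self):
        cohort = make_cohort(6, slope=0.4, noise_sd=0.0, seed=3, base_spec=self.BASE)
        ages = [a for _, _, a in cohort]
        ras = [t.true_Ra for _, t, _ in cohort]
        assert all(np.diff(ras)[np.argsort(ages)[:-1]] > 0) or pearsonr(ages, ras)[0] > 0.999999
        assert pearsonr(ages, ras)[0] == pytest.approx(1.0, abs=1e-9)

    def test_zero_slope_has_no_expected_correlation(self):
        # Monte-Carlo: across seeds the mean r should be ~0
        rs = []
        for seed in range(12):
            cohort = make_cohort(8, slope=0.0, noise_sd=2.0, seed=seed, base_spec=self.BASE)
            ages = [a for _, _, a in cohort]
            ras = [t.true_Ra for _, t, _ in cohort]
            rs.append(pearsonr(ages, ras)[0])
        assert abs(np.mean(rs)) < 3.0 / np.sqrt(len(rs) * 8)

    def test_study_design_sizes(self):
        cohort = make_cohort(16, age_range=(15.0, 45.0), seed=1, base_spec=self.BASE)
        assert len(cohort) == 16
        ages = [a for _, _, a in cohort]
        assert min(ages) >= 15.0 and max(ages) <= 45.0

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_cohort(2, base_spec=self.BASE)
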