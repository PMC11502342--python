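"""Depth-profile optics: epidermal thickness and attenuation coefficient."""

import numpy as np
import pytest

from octskin.optics import (
    attenuation_coefficient,
    epidermal_thickness,
    mean_depth_profile,
    optics_report,
)
from octskin.phantom import PhantomSpec, render_volume
from octskin.segmentation import segment_volume_classical
from octskin.surface import extract_boundary, refine_boundary_subpixel
from octskin.types import BoundaryMap, DepthProfile, OCTVolume


def constructed_profile():
    """Hand-built profile: peak at index 20, valley at index 50, pitch 5 um.

    Brute-force check below confirms those indices are the argmax and the
    argmin-before-the-dermal-rise.
    """
    n = 120
    sig = np.zeros(n)
    idx = np.arange(n)
    sig += 0.9 * np.exp(-0.5 * ((idx - 20) / 4.0) ** 2)  # surface peak
    sig[50:] = 0.0
    sig[20:51] = np.maximum(sig[20:51], np.linspace(sig[20], 0.1, 31))
    sig[51:] = 0.7 * np.exp(-0.01 * (idx[51:] - 51))  # dermal band after the valley
    return DepthProfile(signal=sig, depth_axis=idx * 5.0)


class TestEpidermalThickness:
    def test_constructed_profile_yields_150_um(self):
        prof = constructed_profile()
        assert int(np.argmax(prof.signal)) == 20  # brute-force peak position
        assert int(np.argmin(prof.signal[20:52])) + 20 == 50  # brute-force valley
        assert epidermal_thickness(prof) == pytest.approx(150.0)

    def test_monotone_decay_has_no_epidermal_band(self):
        sig = np.exp(-0.05 * np.arange(100))
        prof = DepthProfile(signal=sig, depth_axis=np.arange(100.0))
        with pytest.raises(ValueError, match="no epidermal band"):
            epidermal_thickness(prof)

    def test_noiseless_phantom_recovery_is_exact(self, flat_noiseless):
        vol, truth = flat_noiseless
        b = extract_boundary(segment_volume_classical(vol), vol.axial_pitch)
        prof = mean_depth_profile(vol, b, smooth_window=1)
        assert epidermal_thickness(prof) == pytest.approx(truth.epidermis_thickness, abs=1e-9)

    def test_speckled_phantom_recovery_within_tolerance(self, skin_speckled):
        vol, truth = skin_speckled
        mask = segment_volume_classical(vol)
        b = refine_boundary_subpixel(extract_boundary(mask, vol.axial_pitch), vol)
        th = epidermal_thickness(mean_depth_profile(vol, b))
        assert abs(th - truth.epidermis_thickness) <= 1.25 * vol.axial_pitch


class TestAttenuation:
    def test_exact_exponential_closed_form(self):
        depth = np.arange(200.0) * 4.0
        sig = 100.0 * np.exp(-6.0 * depth / 1000.0)
        prof = DepthProfile(signal=sig, depth_axis=depth)
        mu, slope, r2, _ = attenuation_coefficient(prof, window_um=(100.0, 600.0))
        assert mu == pytest.approx(3.0, abs=1e-9)
        assert slope == pytest.approx(-6.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_flat_profile_gives_mu_zero(self):
        prof = DepthProfile(signal=np.full(100, 2.0), depth_axis=np.arange(100.0) * 4)
        mu, *_ = attenuation_coefficient(prof, window_um=(0.0, 396.0))
        assert mu == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_global_intensity_scaling(self):
        depth = np.arange(150.0) * 4.0
        sig = np.exp(-2.0 * depth / 1000.0) * (1 + 0.01 * np.sin(depth))
        p1 = DepthProfile(signal=sig, depth_axis=depth)
        p2 = DepthProfile(signal=1234.5 * sig, depth_axis=depth)
        mu1, *_ = attenuation_coefficient(p1, window_um=(40.0, 560.0))
        mu2, *_ = attenuation_coefficient(p2, window_um=(40.0, 560.0))
        assert mu1 == pytest.approx(mu2, rel=1e-12)

    def test_too_few_samples_rejected(self):
        prof = DepthProfile(signal=np.ones(30), depth_axis=np.arange(30.0) * 4)
        with pytest.raises(ValueError, match="samples"):
            attenuation_coefficient(prof, window_um=(0.0, 20.0))

    def test_noiseless_phantom_mu_exact(self, flat_noiseless):
        vol, truth = flat_noiseless
        b = extract_boundary(segment_volume_classical(vol), vol.axial_pitch)
        prof = mean_depth_profile(vol, b, smooth_window=1)
        mu, *_ = attenuation_coefficient(prof)
        assert mu == pytest.approx(truth.attenuation_mu, rel=1e-6)

    def test_speckled_phantom_mu_within_10_percent(self):
        for seed in (11, 12, 13):
            spec = PhantomSpec(n_slices=16, n_depth=320, n_lateral=256,
                               surface_profile="filtered-noise", amplitude=10.0,
                               attenuation_mu=2.0, seed=seed)
            vol, truth = render_volume(spec)
            b = extract_boundary(segment_volume_classical(vol), vol.axial_pitch)
            mu, *_ = attenuation_coefficient(mean_depth_profile(vol, b))
            assert mu == pytest.approx(truth.attenuation_mu, rel=0.10)

    def test_window_shift_stability_on_noiseless_phantom(self, flat_noiseless):
        vol, truth = flat_noiseless
        b = extract_boundary(segment_volume_classical(vol), vol.axial_pitch)
        prof = mean_depth_profile(vol, b, smooth_window=1)
        _, _, _, (lo, hi) = attenuation_coefficient(prof)
        shift = 2 * vol.axial_pitch
        mus = [attenuation_coefficient(prof, window_um=(lo + s, hi + s))[0]
               for s in (-shift, 0, shift)]
        assert max(mus) - min(mus) <= 0.05 * max(mus)


class TestMeanDepthProfile:
    def test_constant_volume_gives_constant_profile(self):
        vol = OCTVolume(np.full((2, 40, 16), 0.5), 4.0, 25.0, 25.0)
        b = BoundaryMap(np.zeros((2, 16)), state="raw", axial_pitch=4.0)
        prof = mean_depth_profile(vol, b, smooth_window=1)
        assert np.allclose(prof.signal, 0.5)

    def test_seeded_profile_reproducible(self, skin_speckled):
        vol, _ = skin_speckled
        b = extract_boundary(segment_volume_classical(vol), vol.axial_pitch)
        p1 = mean_depth_profile(vol, b)
        p2 = mean_depth_profile(vol, b)
        assert np.array_equal(p1.signal, p2.signal)

    def test_shape_mismatch_rejected(self, skin_speckled):
        vol, _ = skin_speckled
        bad = BoundaryMap(np.zeros((2, 7)), state="raw")
        with pytest.raises(ValueError):
            mean_depth_profile(vol, bad)

    def test_optics_report_bundles_both_metrics(self, skin_speckled):
        vol, truth = skin_speckled
        b = extract_boundary(segment_volume_classical(vol), vol.axial_pitch)
        rep = optics_report(vol, b)
        assert rep.epidermal_thickness > 0
        assert 0 <= rep.fit_r2 <= 1
        assert rep.attenuation_mu == pytest.approx(truth.attenuation_mu, rel=0.15)
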