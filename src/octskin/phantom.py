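"""Synthetic OCT skin/plate phantoms with analytically known ground truth.

The simulator renders layered volumes that mimic what a spectral-domain OCT
scanner sees on skin: a rough, possibly curved air-skin interface with a
strong entrance reflection, a moderately bright epidermal band ending in an
intensity valley at the dermal-epidermal junction (DEJ), and a dermal signal
that decays exponentially with depth.  Optional fully developed speckle is
modelled as multiplicative unit-mean exponential noise.  No coherent optics
(PSF, refraction, shadowing) are simulated - the model is intensity layering
plus noise, which is all the downstream measurement chain needs.

Every rendered volume carries a :class:`PhantomTruth` sidecar holding the
exact surface height field, tissue mask, layer depths and attenuation
coefficient, so segmentation, flattening, roughness and optics estimates can
all be checked against construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import sawtooth

from .types import BoundaryMap, OCTVolume, SegmentationMask

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_surface",
    "render_volume",
    "make_plate_phantom",
    "make_cohort",
]

logger = logging.getLogger(__name__)

SURFACE_PROFILES = ("flat", "sinusoid", "triangle", "filtered-noise")
SPECKLE_MODELS = ("none", "multiplicative-exponential")

# Layer intensity anchors (arbitrary units in [0, 1]).  The entrance peak sits
# ENTRANCE_PEAK_PX pixels below the surface so the surface-aligned mean depth
# profile has a proper local maximum followed by the DEJ valley.
I_SURFACE = 0.60  # specular entrance reflection: the dominant intensity step
I_PEAK = 0.90
I_VALLEY = 0.25
I_DERMIS = 0.70
ENTRANCE_PEAK_PX = 2


@dataclass
class PhantomSpec:
    """Geometry, surface texture, layer structure and noise of one phantom.

    Defaults mirror a typical hand-held SD-OCT skin acquisition: 400 B-scans
    at a 25 um beam increment, 25 um lateral pitch and 4 um axial pitch.

    Parameters
    ----------
    surface_profile:
        ``flat``, ``sinusoid`` or ``triangle`` (1D groove profile constant
        across slices, like a roughness standard plate) or ``filtered-noise``
        (2D Gaussian random field, skin-like texture).
    amplitude:
        Peak height of the periodic profiles in um.  For ``filtered-noise``
        it sets the RMS height to ``amplitude / sqrt(2)`` (the RMS a sinusoid
        of the same amplitude would have).
    period:
        Spatial period (periodic profiles) or correlation scale
        (``filtered-noise``) in um.
    curvature_coeff:
        Quadratic sag of the global surface, um per um^2, applied per B-scan
        as ``z += c * (x - x_center)**2``.
    epidermis_thickness:
        Distance in um from the entrance intensity peak to the DEJ valley.
    attenuation_mu:
        Dermal attenuation coefficient in mm^-1; rendered intensity below the
        DEJ decays as ``exp(-2 * mu * depth)`` (round-trip single scattering).
    """

    n_slices: int = 400
    n_depth: int = 256
    n_lateral: int = 512
    axial_pitch: float = 4.0
    lateral_pitch: float = 25.0
    slice_pitch: float = 25.0
    surface_profile: str = "filtered-noise"
    amplitude: float = 15.0
    period: float = 800.0
    curvature_coeff: float = 0.0
    epidermis_thickness: float = 100.0
    attenuation_mu: float = 2.0
    speckle: str = "multiplicative-exponential"
    noise_floor: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.axial_pitch, self.lateral_pitch, self.slice_pitch) <= 0:
            raise ValueError("all pixel pitches must be > 0")
        if min(self.n_slices, self.n_depth, self.n_lateral) < 1:
            raise ValueError("all dimensions must be >= 1")
        if self.surface_profile not in SURFACE_PROFILES:
            raise ValueError(f"surface_profile must be one of {SURFACE_PROFILES}")
        if self.speckle not in SPECKLE_MODELS:
            raise ValueError(f"speckle must be one of {SPECKLE_MODELS}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.attenuation_mu < 0:
            raise ValueError("attenuation_mu must be >= 0")
        if self.surface_profile in ("sinusoid", "triangle") and self.amplitude > 0:
            if self.period < 2 * self.lateral_pitch:
                raise ValueError(
                    f"period {self.period} um is below the 2-pixel Nyquist limit "
                    f"({2 * self.lateral_pitch} um) and would alias"
                )

    def to_dict(self) -> dict[str, Any]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class PhantomTruth:
    """Exact ground truth for one rendered phantom volume.

    ``true_Ra`` / ``true_Rz`` are defined on the discrete sampled grid of
    ``true_surface`` (mean-removed texture, before curvature), so a pipeline
    that recovers the grid exactly scores zero error.
    """

    true_surface: BoundaryMap
    true_curved_surface: BoundaryMap
    true_mask: SegmentationMask
    true_Ra: float
    true_Rz: float
    epidermis_thickness: float
    attenuation_mu: float
    surface_row: np.ndarray | None = None  # float row of the surface per (slice, col)
    meta: dict[str, Any] = field(default_factory=dict)


def _unit_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Surface texture at unit nominal amplitude, shape (n_slices, n_lateral)."""
    x_um = np.arange(spec.n_lateral) * spec.lateral_pitch
    if spec.surface_profile == "flat":
        return np.zeros((spec.n_slices, spec.n_lateral))
    if spec.surface_profile == "sinusoid":
        row = np.sin(2 * np.pi * x_um / spec.period)
        return np.tile(row, (spec.n_slices, 1))
    if spec.surface_profile == "triangle":
        # sawtooth(width=0.5) is a symmetric triangle in [-1, 1]
        row = sawtooth(2 * np.pi * x_um / spec.period, width=0.5)
        return np.tile(row, (spec.n_slices, 1))
    # filtered-noise: correlated Gaussian field, unit RMS after filtering
    sigma_lat = max(spec.period / (4.0 * spec.lateral_pitch), 0.5)
    sigma_sli = max(spec.period / (4.0 * spec.slice_pitch), 0.5)
    raw = rng.standard_normal((spec.n_slices, spec.n_lateral))
    smooth = gaussian_filter(raw, sigma=(sigma_sli, sigma_lat), mode="wrap")
    rms = float(np.sqrt(np.mean(smooth**2)))
    if rms == 0:
        return smooth
    return smooth / rms / np.sqrt(2.0)  # so amplitude scales like a sinusoid's peak


def make_surface(spec: PhantomSpec) -> BoundaryMap:
    """Generate the rough surface height field in um, zero-mean on the grid.

    The returned map is the *texture* only (no curvature applied) and is
    marked ``detrended`` because it is mean-referenced by construction.
    """
    rng = np.random.default_rng(spec.seed)
    z = spec.amplitude * _unit_field(spec, rng)
    z = z - z.mean()
    return BoundaryMap(
        heights=z,
        state="detrended",
        axial_pitch=spec.axial_pitch,
        lateral_pitch=spec.lateral_pitch,
        slice_pitch=spec.slice_pitch,
    )


def _curvature_term(spec: PhantomSpec) -> np.ndarray:
    """Per-B-scan quadratic sag, shape (n_lateral,), in um."""
    x_um = np.arange(spec.n_lateral) * spec.lateral_pitch
    x0 = x_um.mean()
    return spec.curvature_coeff * (x_um - x0) ** 2


def _depth_intensity(d_px: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Noise-free intensity as a function of signed depth below the surface (pixels)."""
    t_px = spec.epidermis_thickness / spec.axial_pitch
    d_valley = ENTRANCE_PEAK_PX + t_px
    axial_mm = spec.axial_pitch / 1000.0

    out = np.full(d_px.shape, spec.noise_floor, dtype=np.float64)
    m = (d_px >= 0) & (d_px < ENTRANCE_PEAK_PX)
    out[m] = I_SURFACE + (I_PEAK - I_SURFACE) * d_px[m] / ENTRANCE_PEAK_PX
    m = (d_px >= ENTRANCE_PEAK_PX) & (d_px <= d_valley)
    out[m] = I_PEAK + (I_VALLEY - I_PEAK) * (d_px[m] - ENTRANCE_PEAK_PX) / t_px
    m = d_px > d_valley
    out[m] = I_DERMIS * np.exp(-2.0 * spec.attenuation_mu * (d_px[m] - d_valley) * axial_mm)
    return out


def render_volume(spec: PhantomSpec) -> tuple[OCTVolume, PhantomTruth]:
    """Render a phantom volume and its exact ground-truth sidecar.

    Raises
    ------
    ValueError
        If the curved surface plus epidermis plus a 20-pixel dermal window
        does not fit inside ``n_depth``.
    """
    texture = make_surface(spec)
    curv = _curvature_term(spec)
    curved = texture.heights + curv[None, :]

    true_ra = float(np.mean(np.abs(texture.heights)))
    true_rz = float(texture.heights.max() - texture.heights.min())

    # Place the surface so its highest point keeps an air margin at the top,
    # mimicking the probe standoff of a real scan (surface ~1/5 into the image).
    margin_px = max(10, round(0.2 * spec.n_depth))
    row0 = margin_px + curved.max() / spec.axial_pitch  # row of height 0
    s_row = row0 - curved / spec.axial_pitch  # float surface row per (slice, col)

    t_px = spec.epidermis_thickness / spec.axial_pitch
    deepest_needed = s_row.max() + ENTRANCE_PEAK_PX + t_px + 20
    if deepest_needed >= spec.n_depth:
        raise ValueError(
            f"layer stack needs {deepest_needed:.0f} depth pixels but volume has "
            f"{spec.n_depth}; increase n_depth or reduce curvature/epidermis"
        )

    rows = np.arange(spec.n_depth, dtype=np.float64)
    vol = np.empty((spec.n_slices, spec.n_depth, spec.n_lateral))
    mask = np.empty((spec.n_slices, spec.n_depth, spec.n_lateral), dtype=np.uint8)
    for s in range(spec.n_slices):
        d = rows[:, None] - s_row[s][None, :]
        vol[s] = _depth_intensity(d, spec)
        mask[s] = (d >= 0).astype(np.uint8)

    if spec.speckle == "multiplicative-exponential":
        # speckle stream is decoupled from the surface stream so the same
        # texture can be rendered under independent noise realizations
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7_0901]))
        vol *= rng.exponential(1.0, size=vol.shape)

    volume = OCTVolume(
        data=vol,
        axial_pitch=spec.axial_pitch,
        lateral_pitch=spec.lateral_pitch,
        slice_pitch=spec.slice_pitch,
        meta={"phantom_spec": spec.to_dict()},
    )
    truth = PhantomTruth(
        true_surface=texture,
        true_curved_surface=BoundaryMap(
            heights=curved,
            state="raw",
            axial_pitch=spec.axial_pitch,
            lateral_pitch=spec.lateral_pitch,
            slice_pitch=spec.slice_pitch,
        ),
        true_mask=SegmentationMask(labels=mask, backend="truth"),
        true_Ra=true_ra,
        true_Rz=true_rz,
        epidermis_thickness=spec.epidermis_thickness,
        attenuation_mu=spec.attenuation_mu,
        surface_row=s_row,
        meta={"spec": spec.to_dict()},
    )
    return volume, truth


def make_plate_phantom(ra_target: float, spec: PhantomSpec | None = None) -> tuple[OCTVolume, PhantomTruth]:
    """Roughness-standard-plate phantom with grid-exact target Ra.

    A periodic triangle groove profile is scaled so that the mean absolute
    height on the sampled grid equals ``ra_target`` exactly, emulating a
    certified reference plate (e.g. the common Ra = 6.3 um comparison
    specimen).

    Parameters
    ----------
    ra_target:
        Desired arithmetic mean roughness in um.  0 yields a flat plate.
    spec:
        Geometry/noise template; profile, amplitude and period are overridden.
    """
    if ra_target < 0:
        raise ValueError("ra_target must be >= 0")
    base = spec if spec is not None else PhantomSpec()
    if ra_target == 0:
        return render_volume(replace(base, surface_profile="flat", amplitude=0.0))
    # period: an exact divisor of the lateral extent keeps the grid mean at zero
    period = 64 * base.lateral_pitch
    if base.n_lateral % 64 != 0:
        period = base.n_lateral // max(base.n_lateral // 64, 1) * base.lateral_pitch
    probe = replace(base, surface_profile="triangle", amplitude=1.0, period=period)
    m_unit = float(np.mean(np.abs(make_surface(probe).heights)))
    spec_out = replace(probe, amplitude=ra_target / m_unit)
    return render_volume(spec_out)


def make_cohort(
    n_subjects: int,
    age_range: tuple[float, float] = (15.0, 45.0),
    slope: float = 0.35,
    noise_sd: float = 1.5,
    seed: int = 0,
    baseline_ra: float = 8.0,
    base_spec: PhantomSpec | None = None,
    curvature_range: tuple[float, float] = (0.0, 2e-6),
) -> list[tuple[OCTVolume, PhantomTruth, float]]:
    """Synthetic aging cohort: per-subject volumes whose true Ra rises with age.

    Each subject's target roughness is
    ``baseline_ra + slope * (age - age_range[0]) + N(0, noise_sd)`` um,
    clamped at a small positive floor, and a skin-like filtered-noise surface
    is scaled so the rendered grid truth matches the target exactly.  Subjects
    also receive a random natural curvature drawn from ``curvature_range``.

    Returns a list of ``(volume, truth, age)`` tuples, deterministic per seed.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    base = base_spec if base_spec is not None else PhantomSpec(n_slices=40, n_depth=256, n_lateral=256)
    rng = np.random.default_rng(seed)
    ages = np.sort(rng.uniform(age_range[0], age_range[1], n_subjects))
    ra_targets = baseline_ra + slope * (ages - age_range[0]) + rng.normal(0.0, noise_sd, n_subjects)
    floor = 0.5
    if np.any(ra_targets < floor):
        logger.warning("clamping %d negative/near-zero cohort Ra targets to %.1f um",
                       int(np.sum(ra_targets < floor)), floor)
        ra_targets = np.maximum(ra_targets, floor)
    curvatures = rng.uniform(curvature_range[0], curvature_range[1], n_subjects)
    sub_seeds = rng.integers(0, 2**31 - 1, n_subjects)

    cohort = []
    for age, ra_t, curv, s in zip(ages, ra_targets, curvatures, sub_seeds):
        probe = replace(base, surface_profile="filtered-noise", amplitude=1.0,
                        curvature_coeff=float(curv), seed=int(s))
        m_unit = float(np.mean(np.abs(make_surface(probe).heights)))
        vol, truth = render_volume(replace(probe, amplitude=float(ra_t) / m_unit))
        cohort.append((vol, truth, float(age)))
    return cohort
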