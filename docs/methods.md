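# Methods

This note documents the models, estimators and numerical choices behind
`octskin`, in the order data flows through the pipeline, and states what the
synthetic phantoms do and do not establish about real OCT data.

## Phantom forward model

A phantom volume is indexed `(slice, depth row, lateral column)` with pixel
pitches in μm (defaults: 4 μm axial, 25 μm lateral, 25 μm slice — the
lateral/slice values match a 25 μm beam-position increment; the axial value
is a typical spectral-domain figure, chosen here, not taken from any
instrument datasheet). The default acquisition geometry is 400 B-scans; the
tests and acceptance runs use fewer slices to keep runs desk-scale, which
only reduces averaging statistics, not the structure of the problem.

**Surface texture.** Four profiles: `flat`; `sinusoid` and `triangle`
(1D groove profiles constant across slices, like manufactured roughness
comparison plates — peak amplitude *A*, period *P*, rejected below the
2-pixel Nyquist limit); and `filtered-noise` (Gaussian random field with
correlation scale *P*/4, unit RMS, scaled by *A*/√2 so *A* compares with a
sinusoid's peak). Heights are made zero-mean on the sampled grid, and the
ground-truth `Ra`/`Rz` are **defined on that discrete grid** (mean |z| and
max − min), so a pipeline recovering the grid exactly scores zero error.
`make_plate_phantom` scales a unit triangle so grid `Ra` equals the target
exactly; `make_cohort` does the same per subject against
`baseline + slope·(age − age_min) + N(0, σ)` targets (clamped at 0.5 μm with
a warning).

**Curvature.** Natural skin curvature is applied per B-scan as
`z += c·(x − x₀)²` (μm per μm²) *after* the truth is recorded — truth
`Ra`/`Rz` are curvature-independent by construction, which is exactly the
property the flattening stage must reproduce. Defaults in tests span
c = 0…3·10⁻⁶ μm⁻¹ (a sag of up to ~120 μm across a 12.8 mm scan).

**Layers and intensity.** Per A-scan, in units where intensities live in
[0, 1]: a noise floor of 0.02 above the surface; a specular entrance
reflection of 0.60 at the surface rising to a peak of 0.90 two pixels below
it; a linear decline to 0.25 at the dermal–epidermal junction (DEJ), placed
so that the **peak-to-valley distance equals `epidermis_thickness`
exactly**; then a dermal band of 0.70 decaying as `exp(−2·μ·depth)`
(μ in mm⁻¹, round-trip single scattering). The surface sits at ~20 % of the
image depth, mimicking probe standoff. Speckle is fully developed:
multiplicative unit-mean exponential noise per voxel, drawn from a stream
seeded independently of the surface stream so textures can be re-rendered
under fresh noise. Rendering is bit-reproducible given the spec and seed.

*Not modelled:* coherent PSF, refraction, shadowing, depth-dependent focus,
detector roll-off, motion. Passing the phantom suite therefore shows the
*measurement chain* is correct and robust to speckle, curvature and
geometry — not that segmentation would survive every artifact of clinical
scans.

## Classical segmentation

Two stages per B-scan, followed by 2D clean-up:

1. **Coarse:** smooth with a lateral boxcar (5 columns) and a *trailing*
   7-row depth boxcar (averaging the current row and the rows above it, so
   no tissue intensity leaks upward — on a noise-free image the first
   supra-threshold row is exactly the first tissue row). Threshold at
   `median + 8·MAD` of the noise floor, estimated from the top 8 rows.
   Because the threshold is relative, segmentation is invariant to global
   intensity scaling. Fewer than 20 % of columns crossing ⇒
   "no surface detected" (isolated speckle clusters can cross anywhere; a
   real surface spans the scan).
2. **Fine:** within ±7 rows of the coarse estimate, place the boundary at
   the maximum of a step matched filter (mean of 3 rows below minus mean of
   3 rows above) computed on **log intensity**. Under multiplicative
   speckle the log transform makes the noise additive with constant
   variance, so the argmax is not biased toward brighter rows; the log
   step at the air–skin interface (≈ log 0.6 − log 0.02 ≈ 3.4) dwarfs the
   per-window noise. On noise-free images the filter peaks exactly at the
   first tissue row, and lateral smoothing is switched off automatically
   (detected via a near-zero noise MAD), so noiseless phantoms are
   segmented exactly.

Clean-up: 3×3 binary median filter, largest-connected-component keep,
rejection of columns whose boundary deviates more than 5 rows from a 31-column
running median (speckle clusters above the surface produce false runs a few
columns wide; the window must be about twice as wide as the widest run it
should reject), a 3-column boundary median, and hole-filling of rejected
columns by linear interpolation from valid neighbours (counted in
provenance). The final mask is contiguous from the boundary down in every
column — the invariant downstream stages rely on, whichever backend
produced the mask.

Residual per-column boundary jitter under default speckle is ≈0.3–0.5 rows
(σ). Jitter inflates `Ra` by roughly σ²·f(0) of the height distribution —
about +2 % on the 6.3 μm plate — and inflates `Rz` (an extreme-value
statistic over ~10⁴–10⁵ columns) far more; `Rz` recovery tolerances are
therefore only asserted on noise-free phantoms.

## Neural segmentation

A reduced U-Net: `depth` = 2 pooling levels, 8 base channels doubling per
level, 3×3 convolutions with ReLU, 2×2 max-pooling, nearest-neighbour
upsampling with skip concatenation, 1×1 output convolution to two-class
logits; pixel-wise cross-entropy; Adam (β₁ = 0.9, β₂ = 0.999). Forward and
backward passes are written out on numpy arrays (single precision); the
backward pass is verified against finite differences in the test suite, and
training is bit-deterministic per seed. Defaults follow the common
biomedical recipe (learning rate 10⁻⁴, batch 8, 100 epochs, 9:1 split);
"iterations" are read as epochs. The scaled-down run used in tests and the
training example (learning rate 10⁻³, 6 epochs, 180 B-scans of 128×128)
reaches a held-out MIoU above 99 on phantom data in about a minute of CPU
time. Splits are stratified **by volume** so adjacent, nearly identical
B-scans cannot leak between train and test. The encoder is deliberately
small; a deeper/wider variant is a constructor argument away but is not
needed to saturate the phantom task. Predicted masks get the same
contiguity post-processing as the classical backend. Model state serializes
to `.npz` weights + a JSON architecture descriptor and reloads bit-exactly.

MIoU is the two-class mean of |A∩B|/|A∪B| on a 0–100 scale; a class absent
from both masks scores 1, so degenerate fixtures behave sensibly.

## Boundary, flattening, roughness

`extract_boundary` takes the topmost skin pixel per column
(height = (reference_row − row)·axial_pitch, increasing toward the probe;
row 0 is the image top), flags and linearly interpolates missing columns
(nearest-value at the edges) and rejects B-scans with >50 % missing.
Optional sub-pixel refinement interpolates the step matched-filter response
with a parabola through the three rows around the integer boundary
(vertex clamped to ±½ pixel). The pipeline enables it by default: with
texture amplitudes of a few axial pixels, whole-pixel quantization measurably
inflates `Ra`.

`flatten` fits `z = a·x² + b·x + c` per B-scan by ordinary least squares
(exact for quadratic input), subtracts the fit, then removes the **global**
mean over all residuals — the mean line of the whole evaluation region, per
the ISO convention — so `Ra`'s |z| is referenced to a single surface-wide
mean. Per-slice mean removal was the alternative; global removal is the
declared choice and is what makes `flatten` idempotent. A slice whose fit
fails (fewer than 3 valid points, rank-deficient abscissa) is dropped with a
warning. Quadratic-fit leakage — texture projecting onto the quadratic — is
negligible for groove plates spanning many periods but grows for textures
whose correlation length approaches the scan width; the roughness report
trims 5 % of columns at each lateral edge by default, where the fit is least
constrained.

`Ra` is the mean absolute height, `Rz` the single global peak-to-valley of
the evaluation region (deliberately not the ISO five-segment average — the
single-region definition is the one implemented throughout). Since `Rz` is
a difference, the mean-reference choice does not affect it. Both statistics
are permutation-invariant and scale-equivariant, which the property tests
assert, and on every phantom the stored truth matches an independent
brute-force recomputation to 10⁻⁹ μm.

## Depth profile, epidermal thickness, attenuation

The mean depth profile aligns every A-scan to its detected surface and
averages. Alignment uses **shift-and-add onto a 4× oversampled depth grid**:
each sample lands in the fine bin nearest its exact sub-pixel depth below
the surface. Integer alignment (or interpolating resampling) would convolve
the profile with a ≥1-pixel kernel; because the profile's landmarks sit on
*asymmetric* kinks, any such symmetric smearing shifts them — the dominant
error mode for thickness estimation. Under-populated fine bins (< 5 % of
the densest bin) are dropped: with integer-valued boundaries only every 4th
bin is dense, and lone samples from interpolated columns would otherwise
inject large speckle noise. Optional boxcar smoothing exists but defaults
to off, for the same landmark-shift reason; the profile is already an
average over every A-scan (typically ≥10³ samples per bin), so additional
smoothing buys little.

**Thickness** is the depth interval from the first prominent peak
(prominence ≥ 2 % of the dynamic range) to the DEJ valley. The valley is
anchored on the **dermal jump** — the largest upward step of the profile
below the peak — and taken as the minimum between peak and jump; anchoring
on "first local minimum" instead proved fragile to residual speckle
micro-extrema. A profile with no prominent peak, or no dermal rise after
it, raises "no epidermal band detected". Recovery on phantoms: exact on
noise-free volumes; −1 axial pixel typical under default speckle (boundary
jitter smears the kinks slightly); the tests assert ≤ 1.25 pixels.

**Attenuation** fits `ln I` vs depth (mm) by ordinary least squares in a
window from 20 μm below the valley (≈5 axial pixels at the default pitch —
starting closer drags in the jitter-smeared DEJ transition and biases μ low
by several percent, measured on phantoms) to 150 μm deeper, clipped to the
profile. μ = −slope/2 (round-trip single scattering); the raw slope is
reported alongside so a single-pass convention (μ = −slope) is one division
away. Non-positive samples are excluded with a warning; fewer than 10 valid
samples is an error. The fit is invariant to global intensity scaling and
exact on noise-free exponentials; under default speckle μ recovers within a
few percent because speckle is unit-mean and averages out of the profile.

## Pipeline, cohort analysis, I/O

`run_pipeline` chains the stages with a single `PipelineConfig` (YAML
round-trip; classical parameters nested) and is a pure function of
(volume, config): reports serialize byte-identically across reruns, floats
at 6 decimals. `cohort_analysis` computes Pearson r of each metric against
age, overall and stratified by sex, flagging r > 0.6 as a strong positive
correlation; zero-variance metrics and undersized strata yield NaN rather
than dropping rows.

Volumes are 16-bit multi-page TIFFs with a JSON sidecar (pitches,
dimensions, intensity scale); the first write quantizes (scale recorded),
after which round-trips are lossless. Boundary maps are CSV grids at
`%.6f` + JSON header, bit-exact on round-trip; phantom truth is a
`*.truth.json` plus companion surface CSVs.

## Problem sizes and known limitations

Tests and the acceptance script use 20–100 slices per volume, 256–320 depth
and 128–512 lateral pixels — sizes chosen so the whole suite runs in a
couple of minutes on one CPU while keeping ≥10⁴ A-scans per roughness
estimate. Known limitations: `Rz` under speckle is biased high by
extreme-value jitter (use noise-free phantoms to validate `Rz` logic);
thickness is resolved only to about one axial pixel; the quadratic flatten
cannot separate texture from shape when their scales coincide; the classical
detector assumes the air region occupies the top rows used for noise
estimation; and the neural backend ships untrained by design.
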