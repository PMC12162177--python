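# Methods

This note documents the models behind `ledhsi`: what is simulated, the
assumptions baked into each stage, the defaults and why they were chosen,
and what the synthetic experiments do and do not demonstrate.

## Instrument model

The instrument is a wavelength-scanning hyperspectral imager: Λ narrowband
LEDs around a monochrome camera, pulsed one at a time so each frame is one
spectral band.

**LED emission.** Each channel is a Gaussian line centered at its nominal
wavelength with FWHM equal to the published spectral half width. Only
FWHM-type data is available for such emitters, and a symmetric Gaussian
keeps every downstream integral analytic; real LED spectra are mildly
asymmetric, which this model ignores. Spectral integrals use a 1 nm
trapezoid grid over 380–1000 nm.

**Illumination footprint.** Each LED throws a radially symmetric Gaussian
irradiance spot on the target plane, centered where the LED's axis meets
the plane (normal incidence is assumed throughout), with FWHM diameter
`2·d·tan(viewing_angle/2)` at working distance `d` and peak equal to the
channel's relative power. This reproduces the key qualitative behavior of
narrow-viewing-angle emitters — strong corner falloff and high spatial
coefficient of variation before calibration — without a cosine-lobe or
ray-traced model, for which no published parameters exist. No lens
distortion, vignetting, or thermal drift of LED output is modeled.

**Timing.** One hypercube costs `Λ·(pw + dt)` frame periods, where `pw`
is the LED pulse width and `dt` the inter-channel guard delay, both in
whole frames. A 120 fps camera with 18 channels and `pw = dt = 1`
sustains 3.33 hypercubes/s; 30 channels at 20 hps with `dt = 0` requires
600 fps. Both operating points are configurations of the same formula; the
guard delay is a free parameter because published descriptions of such
schedules rarely pin it down in frames.

**Link budget.** Throughput in hypercubes/s is
`link bits/s ÷ (rows·cols·Λ·bit_depth)`. The default interpretation of a
megabit is binary (2²⁰ bits), under which a 400 Mbps link carries 21.33
(floor 21) ten-bit 256×256×30 cubes per second; the decimal reading
(20.35) is selectable. The binary reading is the one consistent with the
published "~21 hps" figure for this configuration.

**Geometry.** Pinhole model: the FOV diagonal is `2·d·tan(fov/2)`, split
by the sensor aspect ratio; pixel pitch is extent/pixels. With the
packaged 1280×720, 90° camera this yields the reference operating points
of ~91 mm × 51 mm and 71 μm pitch, and 50 μm for a 2048-pixel reference
system over 102 mm.

## Synthetic scenes and the forward model

**Phantoms.** A scene is a flat dish (reflectance 0.95) carrying
non-overlapping elliptical tissue regions with smooth spectra — a baseline
plus Gaussian bumps of width ≥ 10 nm, clipped to [0, 1] — plus small
saturating glare disks. Four presets ("kidney-like", "tumor-like",
"liver-like", "heart-like") follow the generic shape of soft-tissue
reflectance (low in the blue, rising toward the red/NIR) with
preset-specific features; they are qualitative stand-ins, not fits to any
measured tissue. Stored ground truth per label is the *band-effective*
reflectance: the spectrum averaged over each LED line weighted by emission
× camera response. This, divided by the 0.99 white-reference reflectance,
is exactly what flat-field calibration can recover; a point sample at the
center wavelength differs from it by up to a few percent under the widest
(75 nm) LED line.

**Capture.** Per band,

    counts = full_well · exposure · gain_b · illum(x, y) · r_b(x, y) + dark,

where `gain_b` is the emission-weighted mean camera response of band *b*
and `r_b` the band-effective reflectance of the pixel's material. With
noise enabled, the signal is replaced by a Poisson draw (shot noise), plus
a fixed-pattern Gaussian dark structure (a camera property, constant
across frames) and Gaussian read noise. Counts are rounded half-up and
clipped to the bit depth (default 10). Glare pixels are forced to full
scale in every lit frame — saturation, not a specular BRDF, which is all
the hyperintense-removal segmentation needs to be exercised. In the
shot-noise-only regime a flat field of mean N counts measures
`SNR_dB = 10·log₁₀N`, the closed form used to validate the noise model.

**Scene geometry default.** The simulated dish spans the central 20% of
the camera FOV (at the default 70 mm working distance, a 14 mm square for
a square sensor). This is a design choice: targets sit under the lens
center, and at this extent even the narrowest-angle channels (14°) deliver
more than 5 dark-subtracted counts at the dish corners, so quantization
never dominates the white reference anywhere on the dish. Corner falloff
in those bands still reaches ~40× below peak, preserving the strong
pre-calibration inhomogeneity that makes flat-fielding worth testing.

**Exposure** is a free multiplicative parameter (default 1 = nominal):
practical acquisition protocols range from tens of milliseconds per band
to seconds, and nothing downstream depends on its absolute value.

All randomness flows from explicit integer seeds; noiseless captures are
seed-independent by construction.

## Calibration

`R = (I − I_D)/(I_W − I_D)` per pixel-band. Pixel-bands whose
white-minus-dark denominator is ≤ ε of full scale (ε = 10⁻³ default) are
masked invalid rather than clamped or in-painted — below that the
denominator is quantization/noise-dominated and residual illumination
artifacts should be excluded, not amplified. Values above 1 are preserved:
glare must stay hyperintense for segmentation to find it. Single dark and
white frames are used by default (N-frame averaging is a caller choice).
The gain of each band cancels in the ratio, so calibration is invariant to
any per-band global gain applied jointly to raw and white captures.

## Segmentation, alignment, ROI

**Hyperintense removal.** The per-pixel aggregate is the maximum over
valid bands (glare saturates in some bands only; a mean aggregate is
selectable), clipped at reflectance 1 so saturated glare cannot stretch
the histogram. The threshold is Otsu's criterion computed *exactly* over
the sample values — candidates are midpoints between consecutive distinct
values — because binned implementations can misassign a spike cluster that
shares the argmax bin and place a gap threshold at the gap's edge rather
than its middle. Pixels above threshold (dish + glare) are excluded; a
morphological opening (disk radius 1 by default) removes speckle. A
percentile threshold is selectable.

**Rigid alignment.** Transforms are similarity maps (translation,
rotation, isotropic scale) about the image center; intensities resample
bilinearly, masks nearest-neighbor to stay boolean, and out-of-frame
pixels are flagged invalid. Automatic estimation is a grid search
maximizing normalized cross-correlation with a deterministic tie-break
(smallest |tx|, |ty|, |θ|, |s−1| lexicographically); it is a convenience
for synthetic experiments — in practice cross-system registration of this
kind is often done manually — and it warns when the best NCC falls below a
confidence floor. The common ROI of two systems is the intersection of
their masks after alignment.

## Spectral statistics

Signatures are per-band means and standard deviations over ROI ∩ valid
pixels. Min–max normalization maps each signature to [0, 1] across bands
and is invariant to positive affine rescaling; a flat signature is a
degenerate input and raises.

Group comparison runs a per-band two-sample Student t-test (pooled
variance by default, Welch selectable) on *per-specimen ROI-mean
signatures*, never on pixels: pixels within an ROI are spatially
correlated and pixel-level testing pseudo-replicates (a pixel-level mode
exists for replication attempts, at the caller's risk). Tests are
one-tailed with a direction declared a priori; inferring the direction
from the data is possible but warns, since it inflates the type-I error.
No multiple-testing correction is applied by default (α = 0.05 per band);
Bonferroni and Benjamini–Hochberg are selectable. Bands with zero pooled
variance and equal means report t = 0, p = 0.5.

Monte-Carlo validation (seeded, in the test suite): under the null with
n = 10 signatures per group and 2000 replicates, the mean per-band flag
rate is 0.05 within two binomial standard errors (individual bands within
four — eighteen simultaneous two-SE checks would fail by chance for an
exactly calibrated test); planted 3σ effects at two bands are recovered at
exactly those bands with power above 0.9. Note that min–max normalization
couples bands, so per-band values are not independent across bands; the
t-test remains well calibrated per band because groups stay exchangeable
under the null.

## File formats

ENVI cubes are a plain-text header (`samples/lines/bands`, `interleave =
bsq`, band wavelengths in nm at full float precision, bit depth) plus a
raw band-sequential binary; TIFF cubes are multi-page (pages in band
order) with a JSON sidecar. Calibrated cubes carry their validity mask as
a companion file. Readers verify byte counts and band/wavelength
consistency and fail loudly on truncation or unsupported interleaves.
Session fixtures (dark, white stack, noiseless and noisy phantom cubes,
ground-truth CSV, manifest with SHA-256 hashes) are fully determined by a
seed; manifests store relative paths so equal seeds give byte-identical
sessions.

## Problem sizes

Simulated validation scenes are 64×64×18 (tests also use smaller images
for transform and format checks); the Monte-Carlo calibration of the
per-band tests uses 2000 null replicates and 200 powered replicates.
These sizes were chosen as the smallest at which every property under
test is comfortably resolved — calibration recovery and segmentation are
resolution-independent claims, and the statistical checks depend only on
group size and replicate count.

## Known limitations

- No tissue optics (absorption/scattering), 3-D relief, shadows, or
  non-normal incidence; the calibration-recovery results say nothing about
  geometric confounds in real scenes.
- Glare is forced saturation; real specular highlights vary with band and
  geometry.
- The camera spectral response is a smooth synthetic curve; real sensor
  curves (and their interaction with calibration) are not modeled.
- Preset spectra are qualitative. Synthetic planted-effect recovery shows
  the statistical machinery is calibrated and powered — it does not show
  that any particular real tissue pair separates at particular bands.
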