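"""Synthetic scenes and the forward model of sequential single-LED capture.

A phantom is a flat target plane carrying tissue-like regions of known,
smooth reflectance spectra on a bright white dish, with optional saturating
glare spots.  Each spectral band is captured as one camera frame while a
single LED illuminates the scene:

    counts(x, y) = full_well * exposure * illum(x, y) * r_band(x, y) + dark

where ``r_band`` is the reflectance of the pixel's material averaged over
the LED emission line weighted by the camera's spectral response, and
``illum`` is the LED's Gaussian footprint on the plane.  Optional Poisson
shot noise, Gaussian read noise and a fixed-pattern dark structure are
added before round-half-up quantization to the camera bit depth.  Glare
pixels are forced to full scale in every lit frame.

Because reflectance enters linearly and illumination cancels in flat-field
calibration, the downstream pipeline can be validated against the stored
per-band ground truth exactly (up to quantization).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .instrument import (
    WAVELENGTH_GRID,
    CameraModel,
    GeometryConfig,
    LEDArray,
    LEDChannel,
    TimingConfig,
    default_led_array,
    emission_profile,
    illumination_field,
)

__all__ = [
    "ReflectanceSpectrum",
    "ScenePhantom",
    "RawHypercube",
    "DarkFrame",
    "WhiteStack",
    "SPECTRUM_PRESETS",
    "WHITE_REFERENCE_REFLECTANCE",
    "make_tissue_spectrum",
    "make_contrast_pair",
    "make_phantom",
    "target_plane_coords",
    "band_reflectance",
    "band_gain",
    "capture_frame",
    "acquire_hypercube",
    "acquire_dark",
    "acquire_white",
]

# Near-unity flat reflectance of the simulated Spectralon-like white target.
WHITE_REFERENCE_REFLECTANCE = 0.99

# The white dish the targets sit on: bright but below the white reference.
BACKGROUND_REFLECTANCE = 0.95

# Fraction of the full camera FOV (longest side) occupied by the simulated
# dish; targets sit under the center of the lens, where even the
# narrowest-angle LEDs illuminate the whole dish well above one count of
# dark-subtracted signal, keeping quantization error small everywhere.
SCENE_EXTENT_FACTOR = 0.2


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Smooth reflectance spectrum: baseline plus Gaussian bumps.

    ``bumps`` is a sequence of (center nm, FWHM-like width nm >= 10,
    amplitude) triples; negative amplitudes carve dips.  Evaluated values
    are clipped to [0, 1].
    """

    baseline: float
    bumps: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.baseline <= 1.0):
            raise ValueError("baseline reflectance must lie in [0, 1]")
        for center, width, _amp in self.bumps:
            if width < 10.0:
                raise ValueError("bump widths must be >= 10 nm to keep spectra smooth")
            if not (200.0 < center < 1500.0):
                raise ValueError("bump center outside plausible optical range")

    def __call__(self, wavelengths: Sequence[float] | np.ndarray) -> np.ndarray:
        lam = np.asarray(wavelengths, dtype=float)
        val = np.full_like(lam, self.baseline, dtype=float)
        for center, width, amp in self.bumps:
            sigma = width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            val = val + amp * np.exp(-0.5 * ((lam - center) / sigma) ** 2)
        return np.clip(val, 0.0, 1.0)


# Qualitative stand-ins for soft-tissue signatures: low reflectance in the
# blue rising toward the red/NIR, with preset-specific features.
SPECTRUM_PRESETS: Mapping[str, ReflectanceSpectrum] = {
    "kidney-like": ReflectanceSpectrum(
        baseline=0.15, bumps=((630.0, 70.0, 0.25), (850.0, 140.0, 0.35))
    ),
    "tumor-like": ReflectanceSpectrum(
        baseline=0.15, bumps=((505.0, 40.0, 0.22), (850.0, 140.0, 0.30))
    ),
    "liver-like": ReflectanceSpectrum(
        baseline=0.10, bumps=((700.0, 90.0, 0.20), (900.0, 120.0, 0.25))
    ),
    "heart-like": ReflectanceSpectrum(
        baseline=0.20, bumps=((580.0, 60.0, 0.15), (800.0, 160.0, 0.30))
    ),
}


def make_tissue_spectrum(
    preset: str | None = None,
    *,
    baseline: float | None = None,
    bumps: Sequence[tuple[float, float, float]] | None = None,
    seed: int | None = None,
) -> ReflectanceSpectrum:
    """Build a smooth tissue-like reflectance spectrum.

    Either name a ``preset``, give explicit ``baseline``/``bumps``, or pass
    a ``seed`` for a random (but reproducible) spectrum.
    """
    if preset is not None:
        if preset not in SPECTRUM_PRESETS:
            raise KeyError(f"unknown preset {preset!r}; choose from {sorted(SPECTRUM_PRESETS)}")
        return SPECTRUM_PRESETS[preset]
    if baseline is not None:
        return ReflectanceSpectrum(baseline=baseline, bumps=tuple(bumps or ()))
    if seed is None:
        raise ValueError("give a preset, explicit parameters, or a seed")
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.12, 0.35)
    n_bumps = rng.integers(2, 5)
    bump_list = []
    for _ in range(n_bumps):
        center = rng.uniform(430.0, 930.0)
        width = rng.uniform(40.0, 160.0)
        amp = rng.uniform(0.05, 0.3) * rng.choice([-1.0, 1.0])
        if base + amp < 0.02:
            amp = abs(amp)
        bump_list.append((center, width, amp))
    return ReflectanceSpectrum(baseline=base, bumps=tuple(bump_list))


def make_contrast_pair(
    delta: float, bands: Sequence[float] = (505.0, 660.0), baseline: float = 0.4
) -> tuple[ReflectanceSpectrum, ReflectanceSpectrum]:
    """Two spectra identical except at the given bands, where the second is
    higher by exactly ``delta`` (narrow 12 nm bumps)."""
    if not (0.0 < baseline + delta <= 1.0):
        raise ValueError("baseline + delta must stay within (0, 1]")
    a = ReflectanceSpectrum(baseline=baseline)
    b = ReflectanceSpectrum(
        baseline=baseline, bumps=tuple((float(c), 12.0, delta) for c in bands)
    )
    return a, b


# ---------------------------------------------------------------------------
# scene phantom
# ---------------------------------------------------------------------------


@dataclass
class ScenePhantom:
    """Known-reflectance scene: tissue regions on a bright dish with glare.

    ``label_map`` assigns each pixel a material label; ``background_label``
    (the dish) has flat high reflectance.  ``ground_truth`` stores, per
    label, the band-effective reflectance the instrument can ideally
    recover for each LED channel: the reflectance spectrum averaged over
    the LED emission line weighted by the camera spectral response.
    """

    label_map: np.ndarray
    spectra: dict[int, ReflectanceSpectrum]
    glare_mask: np.ndarray
    background_label: int = 0
    ground_truth: dict[int, np.ndarray] = field(default_factory=dict)
    band_wavelengths: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.label_map.shape != self.glare_mask.shape:
            raise ValueError("label_map and glare_mask shapes differ")
        labels = set(np.unique(self.label_map).tolist())
        missing = labels - set(self.spectra)
        if missing:
            raise ValueError(f"labels without a spectrum: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape

    def tissue_mask(self) -> np.ndarray:
        """True where a tissue (non-background, non-glare) pixel lies."""
        return (self.label_map != self.background_label) & ~self.glare_mask


def make_phantom(
    rows: int,
    cols: int,
    n_tissues: int = 2,
    glare_spots: int = 3,
    seed: int = 0,
    *,
    presets: Sequence[str] | None = None,
    led_array: LEDArray | None = None,
    camera: CameraModel | None = None,
    max_tries: int = 200,
) -> ScenePhantom:
    """Place non-overlapping elliptical tissue regions on the white dish.

    Glare spots are small disks forced to sensor saturation; they may land
    on tissue or background.  Fully reproducible for a fixed seed.
    """
    if n_tissues < 1:
        raise ValueError("n_tissues must be >= 1")
    rng = np.random.default_rng(seed)
    label_map = np.zeros((rows, cols), dtype=np.int32)
    yy, xx = np.mgrid[0:rows, 0:cols]

    names = list(presets) if presets else list(SPECTRUM_PRESETS)
    spectra: dict[int, ReflectanceSpectrum] = {
        0: ReflectanceSpectrum(baseline=BACKGROUND_REFLECTANCE)
    }

    placed = 0
    tries = 0
    min_dim = min(rows, cols)
    while placed < n_tissues:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not fit {n_tissues} tissue regions in a {rows}x{cols} scene"
            )
        a = rng.uniform(0.10, 0.18) * min_dim  # semi-axes in pixels
        b = rng.uniform(0.10, 0.18) * min_dim
        cy = rng.uniform(a + 2, rows - a - 2)
        cx = rng.uniform(b + 2, cols - b - 2)
        ellipse = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
        if np.any(label_map[ellipse] != 0):
            continue
        placed += 1
        label_map[ellipse] = placed
        spectra[placed] = SPECTRUM_PRESETS[names[(placed - 1) % len(names)]]

    glare_mask = np.zeros((rows, cols), dtype=bool)
    for _ in range(glare_spots):
        r = rng.integers(1, max(2, min_dim // 24))
        gy = rng.integers(r, rows - r)
        gx = rng.integers(r, cols - r)
        glare_mask |= (yy - gy) ** 2 + (xx - gx) ** 2 <= r**2

    arr = led_array or default_led_array()
    cam = camera or CameraModel(rows=rows, cols=cols)
    ground_truth = {
        lbl: np.array(
            [band_reflectance(spec, ch, cam) for ch in arr.channels], dtype=float
        )
        for lbl, spec in spectra.items()
    }
    return ScenePhantom(
        label_map=label_map,
        spectra=spectra,
        glare_mask=glare_mask,
        ground_truth=ground_truth,
        band_wavelengths=arr.wavelengths,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# captured data containers
# ---------------------------------------------------------------------------


@dataclass
class RawHypercube:
    """Uncalibrated counts, shape (rows, cols, bands), with band metadata."""

    data: np.ndarray
    band_wavelengths: np.ndarray
    bit_depth: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("hypercube data must be 3-D (rows, cols, bands)")
        if self.data.shape[2] != len(self.band_wavelengths):
            raise ValueError("band count does not match wavelength list")
        full = 2**self.bit_depth - 1
        if self.data.min() < 0 or self.data.max() > full:
            raise ValueError("counts exceed the sensor bit depth")


@dataclass
class DarkFrame:
    """Sensor counts with all LEDs off."""

    data: np.ndarray
    metadata: dict = field(default_factory=dict)


@dataclass
class WhiteStack:
    """Per-band counts of the near-unity flat white reference."""

    data: np.ndarray
    band_wavelengths: np.ndarray
    bit_depth: int
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def target_plane_coords(
    shape: tuple[int, int],
    geometry: GeometryConfig,
    extent_factor: float = SCENE_EXTENT_FACTOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Physical (x, y) mm coordinates of pixel centers on the target plane.

    The longest image side spans ``extent_factor * working_distance`` mm,
    centered on the optical axis; pixel (0, 0) is the top-left corner.
    """
    rows, cols = shape
    extent = extent_factor * geometry.working_distance
    pitch = extent / max(rows, cols)
    x = (np.arange(cols) - (cols - 1) / 2.0) * pitch
    y = (np.arange(rows) - (rows - 1) / 2.0) * pitch
    return np.meshgrid(x, y)


def band_reflectance(
    spectrum: ReflectanceSpectrum, channel: LEDChannel, camera: CameraModel
) -> float:
    """Band-effective reflectance: the weighted mean of the spectrum over
    the LED emission line, weighted by emission x camera response.

    This is the quantity flat-field calibration ideally recovers (divided
    by the white-reference reflectance), since the per-band gain cancels.
    """
    em = emission_profile(channel, WAVELENGTH_GRID)
    qe = np.asarray(camera.qe(WAVELENGTH_GRID), dtype=float)
    w = em * qe
    return float(
        np.trapezoid(w * spectrum(WAVELENGTH_GRID), WAVELENGTH_GRID)
        / np.trapezoid(w, WAVELENGTH_GRID)
    )


def band_gain(channel: LEDChannel, camera: CameraModel) -> float:
    """Per-band sensitivity: emission-weighted mean camera response."""
    em = emission_profile(channel, WAVELENGTH_GRID)
    qe = np.asarray(camera.qe(WAVELENGTH_GRID), dtype=float)
    return float(np.trapezoid(em * qe, WAVELENGTH_GRID) / np.trapezoid(em, WAVELENGTH_GRID))


def _quantize(values: np.ndarray, bit_depth: int) -> np.ndarray:
    """Round half up, then clip to the sensor range."""
    full = 2**bit_depth - 1
    return np.clip(np.floor(values + 0.5), 0, full).astype(np.uint16)


def _fixed_pattern(camera: CameraModel, shape: tuple[int, int]) -> np.ndarray:
    rng = np.random.default_rng(camera.fpn_seed)
    return rng.normal(0.0, camera.dark_sigma, size=shape)


def capture_frame(
    target: ScenePhantom | float | None,
    channel: LEDChannel | None,
    camera: CameraModel,
    geometry: GeometryConfig,
    *,
    exposure: float = 1.0,
    noise_on: bool = True,
    rng: np.random.Generator | None = None,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Capture one frame: a single LED lit (or none, for a dark frame).

    ``target`` is a phantom, a flat reflectance value (white reference),
    or None together with ``channel=None`` for a dark frame.  Returns
    quantized counts of dtype uint16.
    """
    if exposure <= 0 and channel is not None:
        raise ValueError("exposure must be positive for a lit frame")
    if isinstance(target, ScenePhantom):
        frame_shape = target.shape
    elif shape is not None:
        frame_shape = shape
    else:
        frame_shape = (camera.rows, camera.cols)
    if rng is None:
        rng = np.random.default_rng()

    if channel is None:
        signal = np.zeros(frame_shape, dtype=float)
    else:
        xg, yg = target_plane_coords(frame_shape, geometry)
        illum = illumination_field(channel, geometry, xg, yg)
        if isinstance(target, ScenePhantom):
            refl = np.zeros(frame_shape, dtype=float)
            for lbl, spec in target.spectra.items():
                refl[target.label_map == lbl] = band_reflectance(spec, channel, camera)
        elif target is None:
            refl = np.zeros(frame_shape, dtype=float)
        else:
            refl = np.full(frame_shape, band_reflectance(
                ReflectanceSpectrum(baseline=float(target)), channel, camera))
        gain = band_gain(channel, camera)
        signal = camera.full_well_scale * exposure * gain * illum * refl

    if noise_on:
        counts = (
            rng.poisson(signal).astype(float)
            + camera.dark_mean
            + _fixed_pattern(camera, frame_shape)
            + rng.normal(0.0, camera.read_sigma, size=frame_shape)
        )
    else:
        counts = signal + camera.dark_mean

    out = _quantize(counts, camera.bit_depth)
    if channel is not None and isinstance(target, ScenePhantom):
        out[target.glare_mask] = camera.full_scale
    return out


def _timestamps(n_bands: int, fps: float, timing: TimingConfig) -> dict:
    period = timing.frames_per_channel / fps
    starts = np.arange(n_bands) * period
    return {
        "band_start_s": starts.tolist(),
        "cube_duration_s": n_bands * period,
        "fps": fps,
    }


def acquire_hypercube(
    phantom: ScenePhantom,
    led_array: LEDArray | None = None,
    camera: CameraModel | None = None,
    geometry: GeometryConfig | None = None,
    timing: TimingConfig | None = None,
    *,
    exposure: float = 1.0,
    noise_on: bool = True,
    seed: int = 0,
) -> RawHypercube:
    """Scan all LED channels over the phantom: one band per frame."""
    arr = led_array or default_led_array()
    cam = camera or CameraModel(rows=phantom.shape[0], cols=phantom.shape[1])
    geo = geometry or GeometryConfig()
    tim = timing or TimingConfig()
    rng = np.random.default_rng(seed)
    bands = [
        capture_frame(phantom, ch, cam, geo, exposure=exposure, noise_on=noise_on, rng=rng)
        for ch in arr.channels
    ]
    meta = {
        "exposure": exposure,
        "noise_on": noise_on,
        "seed": seed,
        **_timestamps(arr.n_channels, cam.fps_max, tim),
    }
    return RawHypercube(
        data=np.stack(bands, axis=2),
        band_wavelengths=arr.wavelengths,
        bit_depth=cam.bit_depth,
        metadata=meta,
    )


def acquire_dark(
    camera: CameraModel,
    *,
    shape: tuple[int, int] | None = None,
    noise_on: bool = True,
    seed: int = 0,
) -> DarkFrame:
    """Capture the dark-current frame (all LEDs off)."""
    rng = np.random.default_rng(seed)
    geo = GeometryConfig()
    data = capture_frame(None, None, camera, geo, noise_on=noise_on, rng=rng, shape=shape)
    return DarkFrame(data=data, metadata={"noise_on": noise_on, "seed": seed})


def acquire_white(
    led_array: LEDArray | None = None,
    camera: CameraModel | None = None,
    geometry: GeometryConfig | None = None,
    *,
    shape: tuple[int, int] | None = None,
    exposure: float = 1.0,
    noise_on: bool = True,
    seed: int = 0,
    reflectance: float = WHITE_REFERENCE_REFLECTANCE,
) -> WhiteStack:
    """Capture the per-band white-reference stack (flat 0.99 reflectance)."""
    arr = led_array or default_led_array()
    cam = camera or CameraModel()
    geo = geometry or GeometryConfig()
    rng = np.random.default_rng(seed)
    bands = [
        capture_frame(
            reflectance, ch, cam, geo, exposure=exposure, noise_on=noise_on, rng=rng, shape=shape
        )
        for ch in arr.channels
    ]
    meta = {"exposure": exposure, "noise_on": noise_on, "seed": seed,
            "reflectance": reflectance}
    return WhiteStack(
        data=np.stack(bands, axis=2),
        band_wavelengths=arr.wavelengths,
        bit_depth=cam.bit_depth,
        metadata=meta,
    )
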