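"""Parametric models of the acquisition hardware.

The instrument is a wavelength-scanning hyperspectral imager: a ring of
narrowband LEDs around a monochrome camera, switched on one at a time so
that each camera frame records one spectral band.  This module holds the
closed-form descriptions of that hardware — per-channel LED emission and
illumination footprints, the camera, the sequential-illumination timing
budget, the data-link throughput, and the pinhole imaging geometry.

All calculators are pure functions of their configuration objects; nothing
here touches image data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "LEDChannel",
    "LEDArray",
    "CameraModel",
    "TimingConfig",
    "LinkConfig",
    "GeometryConfig",
    "DEFAULT_LED_TABLE",
    "default_led_array",
    "default_camera",
    "emission_profile",
    "illumination_field",
    "hypercube_rate",
    "required_fps",
    "transfer_rate",
    "pixel_pitch",
    "fov_extent",
    "WAVELENGTH_GRID",
]

# Integration grid for spectral quantities: 1 nm steps, 380-1000 nm.
WAVELENGTH_GRID = np.arange(380.0, 1000.0 + 1.0, 1.0)

# Default 18-channel LED array: (center wavelength nm, spectral half
# width / FWHM nm, full viewing angle deg) for each emitter.
DEFAULT_LED_TABLE: tuple[tuple[float, float, float], ...] = (
    (405, 19, 102),
    (420, 16, 26),
    (450, 20, 40),
    (470, 25, 80),
    (505, 30, 86),
    (525, 30, 18),
    (555, 25, 40),
    (590, 13, 64),
    (610, 15, 30),
    (630, 15, 60),
    (660, 18, 80),
    (700, 21, 80),
    (770, 26, 14),
    (800, 29, 88),
    (830, 35, 14),
    (850, 40, 26),
    (890, 75, 40),
    (910, 47, 30),
)

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class LEDChannel:
    """One narrowband emitter.

    Parameters
    ----------
    center_wavelength : float
        Peak emission wavelength, nm.
    half_width : float
        FWHM of the spectral emission line, nm.
    viewing_angle : float
        Full emission cone angle, degrees.  Narrow angles concentrate
        light near the optical axis and darken the image corners.
    position : tuple of float
        (x, y) offset of the LED from the lens axis on the array plane, mm.
    relative_power : float
        Peak irradiance scale relative to the brightest channel, in (0, 1].
    """

    center_wavelength: float
    half_width: float
    viewing_angle: float
    position: tuple[float, float] = (0.0, 0.0)
    relative_power: float = 1.0

    def __post_init__(self) -> None:
        if not (350.0 <= self.center_wavelength <= 1100.0):
            raise ValueError(
                f"center_wavelength {self.center_wavelength} nm outside [350, 1100]"
            )
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if not (0.0 < self.viewing_angle < 180.0):
            raise ValueError("viewing_angle must lie in (0, 180) degrees")
        if self.relative_power <= 0:
            raise ValueError("relative_power must be positive")


@dataclass(frozen=True)
class LEDArray:
    """Ordered set of LED channels; band order of every hypercube."""

    channels: tuple[LEDChannel, ...]

    def __post_init__(self) -> None:
        if len(self.channels) < 1:
            raise ValueError("LEDArray needs at least one channel")
        wl = [c.center_wavelength for c in self.channels]
        if any(b <= a for a, b in zip(wl, wl[1:])):
            raise ValueError("channel center wavelengths must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def wavelengths(self) -> np.ndarray:
        return np.array([c.center_wavelength for c in self.channels], dtype=float)


def _default_qe(wavelengths: np.ndarray | float) -> np.ndarray | float:
    """Smooth monochrome-CMOS-like spectral response (IR filter removed):
    peaks near 550 nm and rolls off gently into the NIR."""
    lam = np.asarray(wavelengths, dtype=float)
    qe = 0.75 * np.exp(-0.5 * ((lam - 560.0) / 220.0) ** 2)
    return np.clip(qe, 0.0, 1.0)


@dataclass(frozen=True)
class CameraModel:
    """Monochrome camera: geometry, rate, noise and spectral response.

    ``full_well_scale`` is the dark-subtracted count level produced by a
    unit-reflectance target under nominal exposure, peak illumination and
    unit quantum efficiency; it anchors the photon budget of the forward
    model.
    """

    rows: int = 720
    cols: int = 1280
    bit_depth: int = 10
    fps_max: float = 120.0
    angular_fov: float = 90.0
    dark_mean: float = 64.0
    dark_sigma: float = 2.0
    read_sigma: float = 2.0
    qe: Callable[[np.ndarray], np.ndarray] = _default_qe
    full_well_scale: float = 900.0
    fpn_seed: int = 20240405  # fixed-pattern dark structure, a camera property

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("sensor dimensions must be >= 1")
        if self.bit_depth not in (8, 10, 12, 16):
            raise ValueError("bit_depth must be one of 8, 10, 12, 16")
        if self.fps_max <= 0:
            raise ValueError("fps_max must be positive")

    @property
    def full_scale(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class TimingConfig:
    """Sequential illumination schedule in whole frame periods.

    ``pw_frames`` is the LED pulse width PW (frames the LED stays on and
    the camera exposes); ``dt_frames`` is the dark guard delay DT between
    channels.  One hypercube costs ``n_channels * (pw + dt)`` frames.
    """

    pw_frames: int = 1
    dt_frames: int = 1

    def __post_init__(self) -> None:
        if self.pw_frames < 1:
            raise ValueError("pw_frames must be >= 1")
        if self.dt_frames < 0:
            raise ValueError("dt_frames must be >= 0")

    @property
    def frames_per_channel(self) -> int:
        return self.pw_frames + self.dt_frames


@dataclass(frozen=True)
class LinkConfig:
    """Wireless data link. ``unit`` selects what one megabit means:
    'binary' = 2**20 bits, 'decimal' = 10**6 bits."""

    rate_mbps: float = 400.0
    unit: str = "binary"

    def __post_init__(self) -> None:
        if self.rate_mbps <= 0:
            raise ValueError("rate_mbps must be positive")
        if self.unit not in ("binary", "decimal"):
            raise ValueError("unit must be 'binary' or 'decimal'")

    @property
    def bits_per_second(self) -> float:
        mbit = 2.0**20 if self.unit == "binary" else 1.0e6
        return self.rate_mbps * mbit


@dataclass(frozen=True)
class GeometryConfig:
    """Imaging geometry: target plane normal to the optical axis at the
    working distance, normal LED incidence."""

    working_distance: float = 70.0  # mm

    def __post_init__(self) -> None:
        if self.working_distance <= 0:
            raise ValueError("working_distance must be positive")


def default_led_array(ring_radius: float = 6.0) -> LEDArray:
    """The packaged 18-channel array (405-910 nm).

    LEDs are placed on a ring of ``ring_radius`` mm around the lens axis,
    mirroring a board where the emitters surround the camera.
    """
    n = len(DEFAULT_LED_TABLE)
    channels = []
    for i, (wl, hw, va) in enumerate(DEFAULT_LED_TABLE):
        ang = 2.0 * math.pi * i / n
        pos = (ring_radius * math.cos(ang), ring_radius * math.sin(ang))
        channels.append(
            LEDChannel(
                center_wavelength=wl,
                half_width=hw,
                viewing_angle=va,
                position=pos,
                relative_power=1.0,
            )
        )
    return LEDArray(channels=tuple(channels))


def default_camera(rows: int = 720, cols: int = 1280) -> CameraModel:
    """The packaged monochrome camera (1280x720, 120 fps, 90 deg FOV)."""
    return CameraModel(rows=rows, cols=cols)


# ---------------------------------------------------------------------------
# spectral / spatial emission models
# ---------------------------------------------------------------------------


def emission_profile(channel: LEDChannel, wavelengths: Sequence[float] | np.ndarray) -> np.ndarray:
    """Relative spectral emission of one LED on a wavelength grid.

    Modeled as a Gaussian line centered at ``center_wavelength`` with
    FWHM equal to the channel's spectral half width; the peak value is 1.
    """
    grid = np.asarray(wavelengths, dtype=float)
    if grid.size == 0:
        raise ValueError("wavelength grid is empty")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    sigma = channel.half_width * _FWHM_TO_SIGMA
    return np.exp(-0.5 * ((grid - channel.center_wavelength) / sigma) ** 2)


def footprint_fwhm(channel: LEDChannel, geometry: GeometryConfig) -> float:
    """FWHM diameter (mm) of the illumination footprint on the target plane:
    2 * d * tan(viewing_angle / 2)."""
    if channel.viewing_angle >= 180.0:
        raise ValueError("viewing_angle must be < 180 degrees")
    half = math.radians(channel.viewing_angle) / 2.0
    return 2.0 * geometry.working_distance * math.tan(half)


def illumination_field(
    channel: LEDChannel,
    geometry: GeometryConfig,
    x_mm: np.ndarray,
    y_mm: np.ndarray,
) -> np.ndarray:
    """Irradiance map of one LED on the target plane (unitless).

    A radially symmetric Gaussian footprint centered where the LED axis
    (normal incidence) meets the plane, i.e. at the LED's own (x, y)
    offset; the footprint FWHM diameter is ``2 d tan(viewing_angle/2)``,
    so narrow-angle emitters produce stronger corner falloff.  Peak value
    equals the channel's ``relative_power``.

    ``x_mm`` / ``y_mm`` are broadcastable coordinate arrays on the plane.
    """
    fwhm = footprint_fwhm(channel, geometry)
    dx = np.asarray(x_mm, dtype=float) - channel.position[0]
    dy = np.asarray(y_mm, dtype=float) - channel.position[1]
    r2 = dx * dx + dy * dy
    return channel.relative_power * np.exp(-4.0 * math.log(2.0) * r2 / fwhm**2)


# ---------------------------------------------------------------------------
# timing / throughput / geometry calculators
# ---------------------------------------------------------------------------


def hypercube_rate(fps: float, n_channels: int, timing: TimingConfig) -> float:
    """Hypercubes per second achievable at a camera frame rate.

    One cube consumes ``n_channels * (pw + dt)`` frame periods, so the
    rate is ``fps / (n_channels * (pw + dt))``.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    return fps / (n_channels * timing.frames_per_channel)


def required_fps(n_channels: int, target_hps: float, timing: TimingConfig) -> float:
    """Camera frame rate needed to sustain ``target_hps`` hypercubes/s."""
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if target_hps <= 0:
        raise ValueError("target_hps must be positive")
    return n_channels * timing.frames_per_channel * target_hps


def transfer_rate(
    link: LinkConfig, rows: int, cols: int, n_channels: int, bit_depth: int
) -> tuple[float, int]:
    """Hypercubes per second the data link can carry.

    Returns ``(raw, floor)``: the exact ratio link_bits_per_second /
    bits_per_cube, and its integer floor.
    """
    if min(rows, cols, n_channels, bit_depth) < 1:
        raise ValueError("all cube dimensions must be >= 1")
    bits_per_cube = rows * cols * n_channels * bit_depth
    raw = link.bits_per_second / bits_per_cube
    return raw, math.floor(raw)


def pixel_pitch(fov_extent_mm: float, n_pixels: int) -> float:
    """Physical size of one pixel on the target plane, in micrometers."""
    if fov_extent_mm <= 0 or n_pixels <= 0:
        raise ValueError("fov extent and pixel count must be positive")
    return fov_extent_mm / n_pixels * 1000.0


def fov_extent(
    angular_fov: float, working_distance: float, aspect: tuple[float, float] = (1.0, 1.0)
) -> tuple[float, float]:
    """(width, height) in mm of the field of view at the working distance.

    Pinhole model: the diagonal extent is ``2 d tan(angular_fov/2)`` and
    is split according to the sensor aspect ratio.
    """
    if not (0.0 < angular_fov < 180.0):
        raise ValueError("angular_fov must lie in (0, 180) degrees")
    if working_distance <= 0:
        raise ValueError("working_distance must be positive")
    aw, ah = aspect
    if aw <= 0 or ah <= 0:
        raise ValueError("aspect components must be positive")
    diag = 2.0 * working_distance * math.tan(math.radians(angular_fov) / 2.0)
    norm = math.hypot(aw, ah)
    return diag * aw / norm, diag * ah / norm
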