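"""Flat-field calibration of raw hypercubes.

Per pixel and band the calibrated reflectance is

    R(x, y, b) = (I(x, y, b) - D(x, y)) / (W(x, y, b) - D(x, y))

with I the raw cube, D the dark-current frame and W the white-reference
stack.  The division cancels both the spatial inhomogeneity of each LED's
illumination footprint and the per-band differences in LED power and
sensor sensitivity.  Pixel-bands whose white-minus-dark denominator is at
or below a small fraction of full scale are unilluminated and are masked
invalid rather than clamped or in-painted; values above 1 (glare, or
targets brighter than the white reference) are preserved so that
hyperintense segmentation can find them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import DarkFrame, RawHypercube, WhiteStack

__all__ = ["CalibratedCube", "flat_field_calibrate", "calibration_report", "DEFAULT_EPSILON"]

log = logging.getLogger(__name__)

# Denominator floor as a fraction of sensor full scale; below this the
# white reference is noise-dominated and the pixel-band is masked.
DEFAULT_EPSILON = 1e-3


@dataclass
class CalibratedCube:
    """Reflectance cube with a per-pixel-band validity mask."""

    data: np.ndarray
    validity_mask: np.ndarray
    band_wavelengths: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.shape != self.validity_mask.shape:
            raise ValueError("data and validity_mask shapes differ")
        if self.data.shape[2] != len(self.band_wavelengths):
            raise ValueError("band count does not match wavelength list")
        if not np.all(np.isfinite(self.data[self.validity_mask])):
            raise ValueError("non-finite reflectance inside the valid region")

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


def flat_field_calibrate(
    raw: RawHypercube,
    dark: DarkFrame,
    white: WhiteStack,
    epsilon: float = DEFAULT_EPSILON,
) -> CalibratedCube:
    """Dark-subtract and divide by the white reference, band by band."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if raw.data.shape != white.data.shape:
        raise ValueError(
            f"raw {raw.data.shape} and white {white.data.shape} shapes differ"
        )
    if dark.data.shape != raw.data.shape[:2]:
        raise ValueError("dark frame shape does not match cube bands")
    if not np.array_equal(raw.band_wavelengths, white.band_wavelengths):
        raise ValueError("raw and white band wavelengths differ")

    full_scale = 2**raw.bit_depth - 1
    num = raw.data.astype(np.float64) - dark.data.astype(np.float64)[..., None]
    den = white.data.astype(np.float64) - dark.data.astype(np.float64)[..., None]
    valid = den > epsilon * full_scale

    data = np.full(raw.data.shape, np.nan, dtype=np.float64)
    np.divide(num, den, out=data, where=valid)

    for b in range(raw.data.shape[2]):
        if not valid[:, :, b].any():
            log.warning(
                "band %d (%.0f nm): white reference entirely below the validity "
                "floor; band retained but fully masked",
                b,
                raw.band_wavelengths[b],
            )
    n_over = int((data[valid] > 1.0).sum())
    if n_over:
        log.info("%d valid pixel-bands exceed reflectance 1 (glare or bright target)", n_over)

    return CalibratedCube(
        data=data,
        validity_mask=valid,
        band_wavelengths=np.asarray(raw.band_wavelengths, dtype=float),
        metadata={"epsilon": epsilon, "bit_depth": raw.bit_depth, **raw.metadata},
    )


def calibration_report(cal: CalibratedCube) -> pd.DataFrame:
    """Per-band summary: mean, std, % invalid, % above reflectance 1.

    Means and stds are over valid pixel-bands only.
    """
    rows = []
    n_pix = cal.data.shape[0] * cal.data.shape[1]
    for b in range(cal.n_bands):
        band = cal.data[:, :, b]
        valid = cal.validity_mask[:, :, b]
        vals = band[valid]
        rows.append(
            {
                "band": b,
                "wavelength_nm": cal.band_wavelengths[b],
                "mean": float(vals.mean()) if vals.size else np.nan,
                "std": float(vals.std()) if vals.size else np.nan,
                "pct_invalid": 100.0 * (1.0 - valid.sum() / n_pix),
                "pct_over_one": 100.0 * float((vals > 1.0).sum()) / n_pix,
            }
        )
    return pd.DataFrame(rows)
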