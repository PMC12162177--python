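"""Spectral signatures, normalization, SNR and per-band group comparison.

A spectral signature is the per-band mean reflectance over an ROI, here
with its per-band standard deviation and pixel count.  Signatures are
min-max normalized across bands,

    S_hat(b) = (S(b) - S_min) / (S_max - S_min),

before comparison between instruments or tissue groups.  Image quality is
summarized as SNR_dB = 20 log10(mean / std) over a flat ROI.  Group
differences are tested band-by-band with a two-sample Student t-test
(pooled variance by default, Welch selectable), one-tailed in a direction
declared a priori; the sampling unit is one specimen's ROI-mean signature,
never individual pixels, to avoid pseudo-replication.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CalibratedCube
from .spatial import ROIMask

__all__ = [
    "SpectralSignature",
    "BandComparison",
    "extract_signature",
    "normalize_signature",
    "snr_db",
    "compare_groups",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpectralSignature:
    """Per-band ROI statistics of one specimen/cube."""

    band_wavelengths: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    n_pixels: np.ndarray
    normalized: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        n = len(self.band_wavelengths)
        for name in ("mean", "std", "n_pixels"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match band count")
        if self.normalized is not None and len(self.normalized) != n:
            raise ValueError("normalized length does not match band count")

    def to_frame(self) -> pd.DataFrame:
        d = {
            "wavelength_nm": self.band_wavelengths,
            "mean": self.mean,
            "std": self.std,
            "n_pixels": self.n_pixels,
        }
        if self.normalized is not None:
            d["normalized"] = self.normalized
        return pd.DataFrame(d)


@dataclass(frozen=True)
class BandComparison:
    """Per-band two-group test results."""

    band_wavelengths: np.ndarray
    mean_a: np.ndarray
    mean_b: np.ndarray
    t_statistic: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    alpha: float
    direction: str
    correction: str = "none"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavelength_nm": self.band_wavelengths,
                "mean_a": self.mean_a,
                "mean_b": self.mean_b,
                "t": self.t_statistic,
                "p": self.p_value,
                "significant": self.significant,
            }
        )


def extract_signature(
    cal: CalibratedCube, roi: ROIMask, label: str = ""
) -> SpectralSignature:
    """Per-band mean/std of reflectance over ROI ∩ valid pixels."""
    if roi.mask.shape != cal.data.shape[:2]:
        raise ValueError("ROI shape does not match cube")
    if not roi.mask.any():
        raise ValueError("ROI is empty")
    n_bands = cal.n_bands
    mean = np.empty(n_bands)
    std = np.empty(n_bands)
    n_pix = np.empty(n_bands, dtype=int)
    for b in range(n_bands):
        sel = roi.mask & cal.validity_mask[:, :, b]
        vals = cal.data[:, :, b][sel]
        n_pix[b] = vals.size
        mean[b] = vals.mean() if vals.size else np.nan
        std[b] = vals.std() if vals.size else np.nan
    return SpectralSignature(
        band_wavelengths=np.asarray(cal.band_wavelengths, dtype=float),
        mean=mean,
        std=std,
        n_pixels=n_pix,
        label=label,
    )


def normalize_signature(sig: SpectralSignature) -> SpectralSignature:
    """Min-max normalize the signature across bands to [0, 1]."""
    if len(sig.mean) < 2:
        raise ValueError("need at least 2 bands to normalize")
    finite = np.isfinite(sig.mean)
    if not finite.any():
        raise ValueError("signature has no finite band values")
    smin = np.nanmin(sig.mean)
    smax = np.nanmax(sig.mean)
    if smax == smin:
        raise ValueError("degenerate flat signature: Smax equals Smin")
    norm = (sig.mean - smin) / (smax - smin)
    return replace(sig, normalized=norm)


def snr_db(values: np.ndarray) -> float:
    """Signal-to-noise ratio of a flat region: 20 log10(mean / std), dB."""
    vals = np.asarray(values, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need at least 2 finite values")
    mu = vals.mean()
    sigma = vals.std()
    if sigma == 0:
        raise ValueError("zero standard deviation: SNR is infinite")
    if mu <= 0:
        raise ValueError("non-positive mean: SNR undefined")
    return float(20.0 * np.log10(mu / sigma))


def _group_matrix(group: Sequence[SpectralSignature], use_normalized: bool) -> np.ndarray:
    rows = []
    for sig in group:
        if use_normalized:
            sig = sig if sig.normalized is not None else normalize_signature(sig)
            rows.append(sig.normalized)
        else:
            rows.append(sig.mean)
    return np.vstack(rows)


def compare_groups(
    group_a: Sequence[SpectralSignature],
    group_b: Sequence[SpectralSignature],
    direction: str | None = "greater",
    alpha: float = 0.05,
    *,
    use_normalized: bool = True,
    equal_var: bool = True,
    correction: str = "none",
) -> BandComparison:
    """Band-wise one-tailed two-sample t-test between signature groups.

    ``direction='greater'`` tests whether group_a exceeds group_b (and
    'less' the reverse) — it must be declared a priori; pass
    ``direction='auto'`` to infer it from the data, at the cost of an
    inflated type-I error (a warning is emitted).  Each signature is one
    sampling unit (one specimen's ROI mean).  ``correction`` in
    {'none', 'bonferroni', 'fdr_bh'} adjusts across bands.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 signatures")
    if direction is None:
        raise ValueError("one-tailed testing requires a declared direction")
    if direction not in ("greater", "less", "auto"):
        raise ValueError("direction must be 'greater', 'less', or 'auto'")

    wl = group_a[0].band_wavelengths
    for sig in list(group_a) + list(group_b):
        if not np.array_equal(sig.band_wavelengths, wl):
            raise ValueError("signatures have mismatched band wavelengths")

    a = _group_matrix(group_a, use_normalized)
    b = _group_matrix(group_b, use_normalized)

    if direction == "auto":
        warnings.warn(
            "direction inferred from the data inflates the one-tailed "
            "type-I error; declare it a priori when possible",
            stacklevel=2,
        )
        direction = "greater" if a.mean() >= b.mean() else "less"

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # bands with (near-)zero pooled variance are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p = stats.ttest_ind(
            a, b, axis=0, equal_var=equal_var, alternative=direction
        )
    # zero pooled variance with equal means: no evidence either way
    degenerate = ~np.isfinite(t_stat)
    t_stat = np.where(degenerate, 0.0, t_stat)
    p = np.where(degenerate, 0.5, p)

    if correction == "none":
        p_adj = p
    else:
        from statsmodels.stats.multitest import multipletests

        method = {"bonferroni": "bonferroni", "fdr_bh": "fdr_bh"}[correction]
        p_adj = multipletests(p, alpha=alpha, method=method)[1]

    return BandComparison(
        band_wavelengths=wl,
        mean_a=a.mean(axis=0),
        mean_b=b.mean(axis=0),
        t_statistic=t_stat,
        p_value=p_adj,
        significant=p_adj < alpha,
        alpha=alpha,
        direction=direction,
        correction=correction,
    )
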