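"""Signature and comparison plots (PNG/SVG)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .spectral import BandComparison, SpectralSignature

__all__ = ["plot_signatures"]


def plot_signatures(
    signatures: Sequence[SpectralSignature],
    path: str | Path,
    comparison: BandComparison | None = None,
    normalized: bool = True,
) -> Path:
    """Plot signature curves with a shaded std band; significant bands from
    an optional comparison are marked with asterisks."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for sig in signatures:
        y = sig.normalized if (normalized and sig.normalized is not None) else sig.mean
        ax.plot(sig.band_wavelengths, y, marker="o", label=sig.label or None)
        if not normalized or sig.normalized is None:
            ax.fill_between(sig.band_wavelengths, y - sig.std, y + sig.std, alpha=0.2)
    if comparison is not None:
        top = ax.get_ylim()[1]
        for wl, flag in zip(comparison.band_wavelengths, comparison.significant):
            if flag:
                ax.annotate("*", (wl, top), ha="center", fontsize=14)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("normalized reflectance" if normalized else "reflectance")
    if any(s.label for s in signatures):
        ax.legend()
    out = Path(path)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
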