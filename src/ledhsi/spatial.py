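"""Hyperintense segmentation, rigid alignment, and ROI construction.

Imaging targets sit on a bright white dish, so the background — and any
specular glare — appears hyperintense in the calibrated reflectance cube.
Tissue pixels are recovered by thresholding a per-pixel aggregate (default:
maximum over valid bands, since glare saturates in some bands only) with a
histogram method (default Otsu), followed by a small morphological opening.

When two instruments image the same scene, their cubes are aligned with a
rigid similarity transform (translation, rotation about the image center,
isotropic scale), masks are resampled nearest-neighbor, and the common ROI
is the intersection of the two segmentation masks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from skimage import morphology
from skimage.transform import SimilarityTransform, warp

from .calibration import CalibratedCube

__all__ = [
    "ROIMask",
    "RigidTransform",
    "segment_hyperintense",
    "apply_rigid",
    "estimate_rigid",
    "mask_overlap",
]

log = logging.getLogger(__name__)


@dataclass
class ROIMask:
    """Boolean region-of-interest mask with provenance."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not self.mask.any():
            self.provenance.setdefault("empty", True)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class RigidTransform:
    """Similarity transform: rotate by ``theta_deg`` and scale by ``scale``
    about the image center, then translate by (tx, ty) pixels (x = column,
    y = row)."""

    tx: float = 0.0
    ty: float = 0.0
    theta_deg: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def inverse(self) -> "RigidTransform":
        s = 1.0 / self.scale
        th = -np.deg2rad(self.theta_deg)
        # invert p' = sR(p - c) + c + t about the same center
        tx = -s * (np.cos(th) * self.tx - np.sin(th) * self.ty)
        ty = -s * (np.sin(th) * self.tx + np.cos(th) * self.ty)
        return RigidTransform(tx=tx, ty=ty, theta_deg=-self.theta_deg, scale=s)

    def matrix(self, shape: tuple[int, int]) -> SimilarityTransform:
        """Forward pixel-coordinate map for an image of the given shape."""
        rows, cols = shape
        cx, cy = (cols - 1) / 2.0, (rows - 1) / 2.0
        to_center = SimilarityTransform(translation=(-cx, -cy))
        sr = SimilarityTransform(scale=self.scale, rotation=np.deg2rad(self.theta_deg))
        back = SimilarityTransform(translation=(cx + self.tx, cy + self.ty))
        return to_center + sr + back


def apply_rigid(
    image: np.ndarray, transform: RigidTransform, interpolation: str = "bilinear"
) -> tuple[np.ndarray, np.ndarray]:
    """Resample an image (or mask) under a rigid transform.

    Returns ``(warped, valid)`` where ``valid`` flags pixels whose value
    came entirely from inside the input frame.  Boolean masks are
    resampled nearest-neighbor regardless of ``interpolation``.
    """
    img = np.asarray(image)
    is_mask = img.dtype == bool
    order = 0 if (is_mask or interpolation == "nearest") else 1
    tform = transform.matrix(img.shape[:2])
    warped = warp(
        img.astype(float), inverse_map=tform.inverse, order=order, cval=0.0,
        preserve_range=True,
    )
    support = warp(
        np.ones(img.shape[:2]), inverse_map=tform.inverse, order=order, cval=0.0,
        preserve_range=True,
    )
    valid = support > 0.999
    if is_mask:
        warped = warped > 0.5
    return warped, valid


def segment_hyperintense(
    cube: CalibratedCube,
    method: str = "otsu",
    cleanup_radius: int = 1,
    aggregate: str = "max",
    percentile: float = 75.0,
) -> ROIMask:
    """Segment tissue by excluding hyperintense background and glare.

    The per-pixel aggregate over valid bands (default: maximum) is
    thresholded; pixels above the threshold — the white dish and glare,
    both hyperintense — are excluded.  A morphological opening with a
    disk of ``cleanup_radius`` pixels removes speckle.
    """
    if not cube.validity_mask.any():
        raise ValueError("cube has no valid band")
    any_valid = cube.validity_mask.any(axis=2)
    filled = np.where(cube.validity_mask, cube.data, -np.inf)
    if aggregate == "max":
        agg = filled.max(axis=2)
    elif aggregate == "mean":
        s = np.where(cube.validity_mask, cube.data, 0.0).sum(axis=2)
        n = cube.validity_mask.sum(axis=2)
        agg = np.divide(s, n, out=np.full(s.shape, -np.inf), where=n > 0)
    else:
        raise ValueError("aggregate must be 'max' or 'mean'")

    # saturated glare can reach reflectance >> 1 and would stretch the
    # histogram until the threshold lands above the dish; reflectance is
    # physically bounded, so cap the aggregate at 1 before thresholding
    agg = np.minimum(agg, 1.0)
    vals = agg[any_valid]
    if vals.size == 0 or np.ptp(vals) == 0:
        raise ValueError("no histogram separation: aggregate image is constant")

    if method == "otsu":
        thr = _otsu_exact(vals)
    elif method == "percentile":
        thr = float(np.percentile(vals, percentile))
    else:
        raise ValueError("method must be 'otsu' or 'percentile'")

    mask = any_valid & (agg <= thr)
    if cleanup_radius > 0:
        mask = morphology.opening(mask, morphology.disk(cleanup_radius))
    if not mask.any():
        log.warning("segmentation produced an empty ROI (threshold %.4f)", thr)
    return ROIMask(
        mask=mask,
        provenance={"method": method, "threshold": thr, "aggregate": aggregate,
                    "cleanup_radius": cleanup_radius},
    )


def _otsu_exact(vals: np.ndarray) -> float:
    """Otsu's threshold computed exactly over the sample values.

    Candidate thresholds are midpoints between consecutive distinct
    values, so spike-shaped histograms are split exactly and a threshold
    inside an empty gap lands at the gap midpoint (binned implementations
    can misassign the cluster sharing the argmax bin).
    """
    u, counts = np.unique(vals, return_counts=True)
    if u.size < 2:
        raise ValueError("no histogram separation: aggregate image is constant")
    w = np.cumsum(counts)[:-1]
    total = counts.sum()
    csum = np.cumsum(counts * u)[:-1]
    mu0 = csum / w
    mu1 = (csum[-1] + counts[-1] * u[-1] - csum) / (total - w)
    bcv = (w / total) * (1 - w / total) * (mu0 - mu1) ** 2
    i = int(np.argmax(bcv))
    return float(0.5 * (u[i] + u[i + 1]))


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def estimate_rigid(
    moving: np.ndarray,
    fixed: np.ndarray,
    search_grid: dict | None = None,
    min_ncc: float = 0.2,
) -> tuple[RigidTransform, float]:
    """Grid-search rigid registration maximizing normalized cross-correlation.

    Convenience for synthetic experiments (alignment between instruments is
    often done manually in practice).  Returns the best transform and its
    NCC score; raises if either image is flat, and logs a warning when the
    best score falls below ``min_ncc``.  Ties break toward the smallest
    (|tx|, |ty|, |theta|, |scale-1|) lexicographically.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.std() == 0 or fixed.std() == 0:
        raise ValueError("cannot register flat images")
    grid = {
        "tx": np.arange(-4.0, 4.5, 1.0),
        "ty": np.arange(-4.0, 4.5, 1.0),
        "theta": np.arange(-10.0, 10.5, 5.0),
        "scale": np.array([1.0]),
    }
    if search_grid:
        grid.update({k: np.asarray(v, dtype=float) for k, v in search_grid.items()})

    best: tuple | None = None
    for s, th, ty, tx in product(grid["scale"], grid["theta"], grid["ty"], grid["tx"]):
        t = RigidTransform(tx=tx, ty=ty, theta_deg=th, scale=s)
        warped, valid = apply_rigid(moving, t)
        if valid.sum() < 16:
            continue
        score = _ncc(warped[valid], fixed[valid])
        key = (-score, abs(tx), abs(ty), abs(th), abs(s - 1.0))
        if best is None or key < best[0]:
            best = (key, t, score)
    if best is None:
        raise ValueError("search grid produced no overlapping candidates")
    _, t, score = best
    if score < min_ncc:
        log.warning("registration confidence low: best NCC %.3f < %.3f", score, min_ncc)
    return t, score


def mask_overlap(a: ROIMask, b: ROIMask) -> ROIMask:
    """Common ROI of two (already aligned) masks: logical intersection."""
    if a.mask.shape != b.mask.shape:
        raise ValueError(f"mask shapes differ: {a.mask.shape} vs {b.mask.shape}")
    inter = a.mask & b.mask
    prov = {"op": "overlap", "a": a.provenance, "b": b.provenance}
    if not inter.any():
        log.warning("mask overlap is empty")
        prov["empty"] = True
    return ROIMask(mask=inter, provenance=prov)
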