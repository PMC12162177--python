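"""Readers and writers for cubes, masks, signatures, transforms and sessions.

Hypercubes are stored either as ENVI (a plain-text ``.hdr`` describing a
raw band-sequential ``.img``, with band wavelengths in the header) or as
multi-page TIFF with a JSON sidecar carrying wavelengths and bit depth.
Calibrated cubes additionally carry a validity mask, stored as a companion
single-band file.  All write→read round-trips are bit-exact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .calibration import CalibratedCube
from .instrument import (
    CameraModel,
    GeometryConfig,
    LEDArray,
    LEDChannel,
    LinkConfig,
    TimingConfig,
    default_led_array,
)
from .simulate import (
    RawHypercube,
    WhiteStack,
    acquire_dark,
    acquire_hypercube,
    acquire_white,
    make_phantom,
)
from .spatial import RigidTransform, ROIMask
from .spectral import SpectralSignature

__all__ = [
    "read_cube",
    "write_cube",
    "write_mask",
    "read_mask",
    "write_signature",
    "read_signature",
    "write_transform",
    "read_transform",
    "load_instrument_config",
    "default_instrument_config",
    "SessionManifest",
    "generate_fixtures",
    "load_manifest",
]

log = logging.getLogger(__name__)

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _envi_header_text(shape: tuple[int, int, int], dtype: np.dtype,
                      wavelengths: np.ndarray, bit_depth: int, kind: str) -> str:
    rows, cols, bands = shape
    wl = ", ".join(repr(float(w)) for w in wavelengths)  # full precision
    return (
        "ENVI\n"
        f"description = {{ledhsi {kind} cube}}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[np.dtype(dtype)]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
        f"bit depth = {bit_depth}\n"
    )


def _parse_envi_header(path: Path) -> dict:
    text = path.read_text()
    if not text.lstrip().startswith("ENVI"):
        raise ValueError(f"{path} is not an ENVI header")
    # join brace-delimited multi-line values, then split on '='
    fields: dict[str, str] = {}
    buf = ""
    for line in text.splitlines()[1:]:
        buf += line.strip()
        if buf.count("{") > buf.count("}"):
            buf += " "
            continue
        if "=" in buf:
            key, val = buf.split("=", 1)
            fields[key.strip().lower()] = val.strip()
        buf = ""
    return fields


def _write_envi(path: Path, data: np.ndarray, wavelengths: np.ndarray,
                bit_depth: int, kind: str) -> None:
    img = path.with_suffix(".img")
    hdr = path.with_suffix(".hdr")
    bsq = np.ascontiguousarray(np.moveaxis(data, 2, 0))  # (bands, rows, cols)
    img.write_bytes(bsq.tobytes())
    hdr.write_text(_envi_header_text(data.shape, data.dtype, wavelengths, bit_depth, kind))


def _read_envi(path: Path) -> tuple[np.ndarray, np.ndarray, int]:
    hdr = path.with_suffix(".hdr")
    img = path.with_suffix(".img")
    if not hdr.exists() or not img.exists():
        raise FileNotFoundError(f"missing ENVI pair for {path}")
    fields = _parse_envi_header(hdr)
    interleave = fields.get("interleave", "bsq").lower()
    if interleave != "bsq":
        raise ValueError(f"unsupported ENVI interleave {interleave!r}; only bsq")
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type {code}")
    dtype = np.dtype(_ENVI_DTYPES[code])
    raw = img.read_bytes()
    expected = rows * cols * bands * dtype.itemsize
    if len(raw) != expected:
        raise ValueError(
            f"{img}: expected {expected} bytes, found {len(raw)} (truncated or corrupt)"
        )
    data = np.frombuffer(raw, dtype=dtype).reshape(bands, rows, cols)
    data = np.moveaxis(data, 0, 2).copy()
    wl_field = fields.get("wavelength", "{}").strip("{} ")
    wavelengths = np.array([float(w) for w in wl_field.split(",") if w.strip()])
    if len(wavelengths) != bands:
        raise ValueError("ENVI wavelength list does not match band count")
    bit_depth = int(fields.get("bit depth", 16))
    return data, wavelengths, bit_depth


def _write_tiff(path: Path, data: np.ndarray, wavelengths: np.ndarray,
                bit_depth: int, kind: str) -> None:
    tif = path.with_suffix(".tif")
    pages = np.moveaxis(data, 2, 0)
    tifffile.imwrite(tif, pages)
    sidecar = {
        "kind": kind,
        "band_wavelengths": [float(w) for w in wavelengths],
        "bit_depth": int(bit_depth),
        "dtype": str(data.dtype),
        "shape": list(data.shape),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def _read_tiff(path: Path) -> tuple[np.ndarray, np.ndarray, int]:
    tif = path.with_suffix(".tif")
    sidecar_path = path.with_suffix(".json")
    if not tif.exists() or not sidecar_path.exists():
        raise FileNotFoundError(f"missing TIFF/JSON pair for {path}")
    meta = json.loads(sidecar_path.read_text())
    pages = tifffile.imread(tif)
    data = np.moveaxis(np.atleast_3d(pages.reshape((-1,) + tuple(pages.shape[-2:]))), 0, 2)
    if list(data.shape) != meta["shape"]:
        raise ValueError(f"{tif}: shape {data.shape} does not match sidecar {meta['shape']}")
    wavelengths = np.asarray(meta["band_wavelengths"], dtype=float)
    if len(wavelengths) != data.shape[2]:
        raise ValueError("sidecar wavelength list does not match band count")
    return data, wavelengths, int(meta["bit_depth"])


def write_cube(cube: RawHypercube | WhiteStack | CalibratedCube, path: str | Path,
               fmt: str = "envi") -> Path:
    """Write a cube to disk; returns the base path (without extension).

    ``fmt`` is 'envi' (hdr + raw BSQ) or 'tiff' (multi-page + JSON
    sidecar).  Calibrated cubes also write a ``<base>.mask`` companion.
    """
    base = Path(path)
    if base.suffix in (".img", ".hdr", ".tif", ".json"):
        base = base.with_suffix("")
    if isinstance(cube, CalibratedCube):
        kind, data, bit_depth = "calibrated", cube.data, cube.metadata.get("bit_depth", 16)
    elif isinstance(cube, (RawHypercube, WhiteStack)):
        kind, data, bit_depth = "raw", cube.data, cube.bit_depth
    else:
        raise TypeError(f"cannot write object of type {type(cube).__name__}")
    writer = {"envi": _write_envi, "tiff": _write_tiff}.get(fmt)
    if writer is None:
        raise ValueError("fmt must be 'envi' or 'tiff'")
    writer(base, data, cube.band_wavelengths, bit_depth, kind)
    if isinstance(cube, CalibratedCube):
        mask_base = base.parent / (base.name + "_mask")
        writer(mask_base, cube.validity_mask.astype(np.uint8),
               cube.band_wavelengths, 8, "mask")
    return base


def read_cube(path: str | Path, fmt: str | None = None) -> RawHypercube | CalibratedCube:
    """Read a cube written by :func:`write_cube` (format auto-detected)."""
    base = Path(path)
    if base.suffix in (".img", ".hdr", ".tif", ".json"):
        base = base.with_suffix("")
    if fmt is None:
        fmt = "envi" if base.with_suffix(".hdr").exists() else "tiff"
    reader = {"envi": _read_envi, "tiff": _read_tiff}[fmt]
    data, wavelengths, bit_depth = reader(base)
    mask_base = base.parent / (base.name + "_mask")
    has_mask = (mask_base.with_suffix(".hdr").exists()
                or mask_base.with_suffix(".json").exists())
    if np.issubdtype(data.dtype, np.floating) or has_mask:
        if has_mask:
            mask, _, _ = reader(mask_base)
            mask = mask.astype(bool)
        else:
            mask = np.isfinite(data)
        return CalibratedCube(
            data=data.astype(np.float64),
            validity_mask=mask,
            band_wavelengths=wavelengths,
            metadata={"bit_depth": bit_depth},
        )
    return RawHypercube(data=data, band_wavelengths=wavelengths, bit_depth=bit_depth)


def write_mask(mask: ROIMask | np.ndarray, path: str | Path) -> Path:
    """Write a boolean mask as a single-band 8-bit TIFF (+ provenance JSON)."""
    p = Path(path).with_suffix(".tif")
    arr = mask.mask if isinstance(mask, ROIMask) else np.asarray(mask, dtype=bool)
    tifffile.imwrite(p, arr.astype(np.uint8) * 255)
    if isinstance(mask, ROIMask):
        p.with_suffix(".json").write_text(json.dumps(mask.provenance, default=str, indent=1))
    return p


def read_mask(path: str | Path) -> ROIMask:
    p = Path(path).with_suffix(".tif")
    arr = tifffile.imread(p) > 0
    prov_path = p.with_suffix(".json")
    prov = json.loads(prov_path.read_text()) if prov_path.exists() else {}
    return ROIMask(mask=arr, provenance=prov)


def write_signature(sig: SpectralSignature, path: str | Path) -> Path:
    p = Path(path)
    sig.to_frame().to_csv(p, index=False)
    return p


def read_signature(path: str | Path, label: str = "") -> SpectralSignature:
    df = pd.read_csv(path)
    return SpectralSignature(
        band_wavelengths=df["wavelength_nm"].to_numpy(float),
        mean=df["mean"].to_numpy(float),
        std=df["std"].to_numpy(float),
        n_pixels=df["n_pixels"].to_numpy(int),
        normalized=df["normalized"].to_numpy(float) if "normalized" in df else None,
        label=label or Path(path).stem,
    )


def write_transform(t: RigidTransform, path: str | Path) -> Path:
    p = Path(path)
    payload = {**asdict(t), "convention": "rotate/scale about image center, xy pixels"}
    p.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return p


def read_transform(path: str | Path) -> RigidTransform:
    d = json.loads(Path(path).read_text())
    return RigidTransform(tx=d["tx"], ty=d["ty"], theta_deg=d["theta_deg"], scale=d["scale"])


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def default_instrument_config() -> Path:
    """Path of the packaged default instrument description."""
    return Path(__file__).parent / "data" / "default_instrument.yaml"


def load_instrument_config(path: str | Path | None = None) -> dict:
    """Load an instrument description from YAML.

    Returns a dict with keys ``led_array``, ``camera``, ``timing``,
    ``link``, ``geometry``.  The packaged default reproduces the
    18-channel 405-910 nm array and the 1280x720 / 120 fps / 90 deg
    camera.
    """
    cfg_path = Path(path) if path else default_instrument_config()
    cfg = yaml.safe_load(cfg_path.read_text())
    leds = cfg.get("leds")
    if leds:
        ring = float(cfg.get("led_ring_radius_mm", 6.0))
        n = len(leds)
        channels = []
        for i, row in enumerate(leds):
            ang = 2.0 * np.pi * i / n
            channels.append(
                LEDChannel(
                    center_wavelength=float(row["wavelength_nm"]),
                    half_width=float(row["half_width_nm"]),
                    viewing_angle=float(row["viewing_angle_deg"]),
                    position=(ring * np.cos(ang), ring * np.sin(ang)),
                    relative_power=float(row.get("relative_power", 1.0)),
                )
            )
        led_array = LEDArray(channels=tuple(channels))
    else:
        led_array = default_led_array()
    cam_cfg = cfg.get("camera", {})
    camera = CameraModel(**cam_cfg) if cam_cfg else CameraModel()
    timing = TimingConfig(**cfg.get("timing", {}))
    link = LinkConfig(**cfg.get("link", {}))
    geometry = GeometryConfig(**cfg.get("geometry", {}))
    return {
        "led_array": led_array,
        "camera": camera,
        "timing": timing,
        "link": link,
        "geometry": geometry,
    }


# ---------------------------------------------------------------------------
# session fixtures
# ---------------------------------------------------------------------------


@dataclass
class SessionManifest:
    """Index of one simulated acquisition session on disk."""

    root: str
    seed: int
    band_wavelengths: list[float]
    files: dict[str, str] = field(default_factory=dict)
    hashes: dict[str, str] = field(default_factory=dict)

    def path(self, key: str) -> Path:
        return Path(self.root) / self.files[key]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate_fixtures(
    output_dir: str | Path,
    seed: int = 0,
    *,
    rows: int = 64,
    cols: int = 64,
    n_tissues: int = 2,
    glare_spots: int = 3,
    fmt: str = "envi",
) -> SessionManifest:
    """Write a complete small acquisition session for testing.

    Contents: dark frame, white-reference stack, a two-tissue phantom cube
    in noiseless and noisy variants, the ground-truth spectra as CSV, and
    a JSON manifest.  Fully determined by ``seed``.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    camera = CameraModel(rows=rows, cols=cols)
    geometry = GeometryConfig()
    led_array = default_led_array()
    phantom = make_phantom(rows, cols, n_tissues=n_tissues, glare_spots=glare_spots,
                           seed=seed, led_array=led_array, camera=camera)

    dark = acquire_dark(camera, shape=(rows, cols), noise_on=False, seed=seed)
    white = acquire_white(led_array, camera, geometry, shape=(rows, cols),
                          noise_on=False, seed=seed)
    raw_clean = acquire_hypercube(phantom, led_array, camera, geometry,
                                  noise_on=False, seed=seed)
    raw_noisy = acquire_hypercube(phantom, led_array, camera, geometry,
                                  noise_on=True, seed=seed + 1)

    ext = ".img" if fmt == "envi" else ".tif"
    files: dict[str, str] = {}

    dark_cube = RawHypercube(data=dark.data[..., None],
                             band_wavelengths=np.array([0.0]),
                             bit_depth=camera.bit_depth)
    write_cube(dark_cube, out / "dark", fmt=fmt)
    files["dark"] = "dark" + ext
    write_cube(WhiteStack(data=white.data, band_wavelengths=white.band_wavelengths,
                          bit_depth=white.bit_depth), out / "white", fmt=fmt)
    files["white"] = "white" + ext
    write_cube(raw_clean, out / "phantom_noiseless", fmt=fmt)
    files["phantom_noiseless"] = "phantom_noiseless" + ext
    write_cube(raw_noisy, out / "phantom_noisy", fmt=fmt)
    files["phantom_noisy"] = "phantom_noisy" + ext

    gt_rows = []
    for lbl, refl in sorted(phantom.ground_truth.items()):
        for wl, r in zip(phantom.band_wavelengths, refl):
            gt_rows.append({"label": lbl, "wavelength_nm": wl, "reflectance": r})
    gt_path = out / "ground_truth.csv"
    pd.DataFrame(gt_rows).to_csv(gt_path, index=False)
    files["ground_truth"] = "ground_truth.csv"

    tifffile.imwrite(out / "labels.tif", phantom.label_map.astype(np.int32))
    files["labels"] = "labels.tif"
    tifffile.imwrite(out / "glare.tif", phantom.glare_mask.astype(np.uint8))
    files["glare"] = "glare.tif"

    manifest = SessionManifest(
        root=str(out),
        seed=seed,
        band_wavelengths=[float(w) for w in led_array.wavelengths],
        files=files,
        hashes={k: _sha256(out / v) for k, v in files.items()},
    )
    # root is stored relative so identical seeds give byte-identical sessions
    (out / "manifest.json").write_text(
        json.dumps({**asdict(manifest), "root": "."}, indent=1, sort_keys=True)
    )
    log.info("session fixtures written to %s (seed %d)", out, seed)
    return manifest


def load_manifest(path: str | Path) -> SessionManifest:
    """Load and validate a session manifest (all referenced files exist)."""
    p = Path(path)
    if p.is_dir():
        p = p / "manifest.json"
    d = json.loads(p.read_text())
    manifest = SessionManifest(**d)
    manifest.root = str(p.parent)
    for key, rel in manifest.files.items():
        if not (p.parent / rel).exists():
            raise FileNotFoundError(f"manifest entry {key!r}: missing file {rel}")
    return manifest
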