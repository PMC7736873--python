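"""Image interchange: 16-bit PGM + JSON sidecar, and DICOM planar reading.

The canonical fixture format is a binary 16-bit PGM (P5, maxval 65535,
big-endian) with a JSON sidecar of the same stem carrying pixel size,
acquisition context and provenance (tool version, seed, config hash).
PGM keeps fixtures bit-exact and dependency-light; DICOM planar files
are supported read-only.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
from PIL import Image

from .phantom import ActivityMap
from .simulate import CountImage


def _config_hash(meta: dict) -> str:
    blob = json.dumps(meta, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(meta: dict, seed=None) -> dict:
    from . import __version__

    return {
        "tool": "mibgcal",
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(meta),
    }


def write_pgm16(path, array: np.ndarray) -> None:
    """Write a 2D non-negative integer array as binary 16-bit PGM."""
    arr = np.asarray(array)
    if arr.ndim != 2:
        raise ValueError("PGM image must be 2D")
    if arr.min() < 0 or arr.max() > 65535:
        raise ValueError("PGM values must lie in [0, 65535]")
    h, w = arr.shape
    with open(path, "wb") as fh:
        fh.write(f"P5\n{w} {h}\n65535\n".encode())
        fh.write(arr.astype(">u2").tobytes())


def read_pgm16(path) -> np.ndarray:
    """Read a PGM image into an integer array (via Pillow)."""
    with Image.open(path) as img:
        return np.asarray(img).astype(np.int64)


def _sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def save_count_image(image: CountImage, path, seed=None) -> None:
    """Write a count image as PGM plus JSON sidecar with provenance."""
    meta: dict = {"kind": "count_image", "pixel_size_mm": image.pixel_size_mm}
    if image.settings is not None:
        s = image.settings
        meta["settings"] = {
            "window": str(s.window),
            "matrix": s.matrix,
            "duration_s": s.duration_s,
            "distance_mm": s.distance_mm,
            "activity_mbq": s.activity_mbq,
            "seed": s.seed,
        }
        if seed is None:
            seed = s.seed
    if image.collimator is not None:
        c = image.collimator
        meta["collimator"] = {
            "name": c.name,
            "hole_diameter_mm": c.hole_diameter_mm,
            "septal_thickness_mm": c.septal_thickness_mm,
            "length_mm": c.length_mm,
            "group": c.group,
        }
    meta.update(image.provenance)
    meta["provenance"] = _provenance(meta, seed=seed)
    write_pgm16(path, image.counts)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, default=str))


def load_count_image(path) -> CountImage:
    """Read a PGM count image; pixel size comes from the sidecar."""
    counts = read_pgm16(path)
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    pixel = float(meta.get("pixel_size_mm", 1.0))
    return CountImage(counts, pixel, provenance={"source": str(path), **meta})


def save_activity_map(activity: ActivityMap, path) -> None:
    """Quantize an activity map to 16 bits and write PGM + sidecar."""
    values = np.asarray(activity.values, dtype=float)
    peak = values.max()
    scale = 65535.0 / peak if peak > 0 else 1.0
    write_pgm16(path, np.rint(values * scale).astype(np.int64))
    meta = {
        "kind": "activity_map",
        "view": activity.view,
        "pixel_size_mm": activity.pixel_size_mm,
        "densities": activity.densities,
        "quantization_scale": scale,
    }
    meta["provenance"] = _provenance(meta)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_dicom_planar(path) -> CountImage:
    """Read a planar DICOM file into a CountImage (requires pydicom).

    Extracts the pixel array, pixel spacing and — when present — the
    actual frame duration (ms) as the acquisition time.
    """
    import pydicom

    ds = pydicom.dcmread(path)
    counts = np.asarray(ds.pixel_array)
    if counts.ndim == 3:  # multi-frame planar: take the first frame
        counts = counts[0]
    spacing = getattr(ds, "PixelSpacing", None)
    pixel = float(spacing[0]) if spacing else 1.0
    meta = {"source": str(path), "format": "DICOM"}
    duration = getattr(ds, "ActualFrameDuration", None)
    if duration is not None:
        meta["duration_s"] = float(duration) / 1000.0
    return CountImage(counts.astype(np.int64), pixel, provenance=meta)
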