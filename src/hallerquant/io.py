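"""Reading and writing: images, metadata sidecars, metric tables, QC overlays.

Images are 8-bit grayscale PNG/BMP/TIFF.  Per-image metadata (eye side,
pixel scale, CCT, fovea, group) travels in a JSON sidecar named
``<image stem>.json`` next to the image; explicit keyword overrides win over
the sidecar.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image as PILImage

from .enface import EnFaceError, EnFaceImage, EyeMetrics, PIXEL_SIZE_MM_DEFAULT
from .symmetry import SegmentDecomposition, VesselSegment

SIDECAR_KEYS = {"eye_side", "pixel_size_mm", "cct_um", "fovea_xy", "group", "eye_id"}

METRICS_COLUMNS = ["eye_id", "group", "eye_side", "vessel_area_mm2",
                   "vessel_length_mm", "mean_diameter_mm", "symmetry_index_pct",
                   "cct_um", "valid"]


def sidecar_path(image_path: Path) -> Path:
    return Path(image_path).with_suffix(".json")


def read_sidecar(image_path: Path) -> dict:
    """Load the JSON sidecar for an image; unknown keys are rejected."""
    p = sidecar_path(image_path)
    if not p.exists():
        return {}
    meta = json.loads(p.read_text())
    unknown = set(meta) - SIDECAR_KEYS
    if unknown:
        raise EnFaceError(f"unknown sidecar keys in {p}: {sorted(unknown)}")
    return meta


def load_enface(image_path, **overrides) -> EnFaceImage:
    """Read an 8-bit grayscale image plus sidecar metadata as an EnFaceImage."""
    image_path = Path(image_path)
    with PILImage.open(image_path) as im:
        arr = np.asarray(im.convert("L"))
    meta = read_sidecar(image_path)
    meta.update({k: v for k, v in overrides.items() if v is not None})
    meta.pop("group", None)
    eye_id = meta.pop("eye_id", None)
    fovea = meta.get("fovea_xy")
    if fovea is not None:
        meta["fovea_xy"] = tuple(fovea)
    img = EnFaceImage(
        arr,
        pixel_size_mm=meta.get("pixel_size_mm", PIXEL_SIZE_MM_DEFAULT),
        eye_side=meta.get("eye_side", "OD"),
        fovea_xy=meta.get("fovea_xy"),
        cct_um=meta.get("cct_um"),
    )
    return img


def save_enface(pixels: np.ndarray, image_path, metadata: Optional[dict] = None) -> None:
    """Write an 8-bit grayscale image and (optionally) its JSON sidecar."""
    image_path = Path(image_path)
    PILImage.fromarray(np.asarray(pixels, dtype=np.uint8), mode="L").save(image_path)
    if metadata:
        unknown = set(metadata) - SIDECAR_KEYS
        if unknown:
            raise EnFaceError(f"unknown sidecar keys: {sorted(unknown)}")
        sidecar_path(image_path).write_text(json.dumps(metadata, indent=2) + "\n")


def metrics_to_dict(m: EyeMetrics) -> dict:
    d = dataclasses.asdict(m)
    return {k: d[k] for k in METRICS_COLUMNS}


def metrics_to_frame(records: Iterable[EyeMetrics]) -> pd.DataFrame:
    return pd.DataFrame([metrics_to_dict(m) for m in records], columns=METRICS_COLUMNS)


def write_metrics_csv(records: Iterable[EyeMetrics], path) -> None:
    metrics_to_frame(records).to_csv(path, index=False, float_format="%.6f")


def write_metrics_json(m: EyeMetrics, path) -> None:
    d = metrics_to_dict(m)
    clean = {k: (None if isinstance(v, float) and math.isnan(v) else v)
             for k, v in d.items()}
    Path(path).write_text(json.dumps(clean, indent=2) + "\n")


def segments_to_frame(segments: Sequence[VesselSegment]) -> pd.DataFrame:
    rows = []
    for s in segments:
        (r0, c0), (r1, c1) = s.endpoints
        rows.append({
            "end0_row": r0, "end0_col": c0, "end1_row": r1, "end1_col": c1,
            "n_pixels": s.n_pixels,
            "length_mm": s.length_mm,
            "orientation_deg": s.orientation_deg,
            "hemifield": s.hemifield,
            "natural_oblique": s.natural_oblique,
        })
    return pd.DataFrame(rows, columns=["end0_row", "end0_col", "end1_row", "end1_col",
                                       "n_pixels", "length_mm", "orientation_deg",
                                       "hemifield", "natural_oblique"])


def write_segment_csv(segments: Sequence[VesselSegment], path) -> None:
    segments_to_frame(segments).to_csv(path, index=False, float_format="%.6f")


def qc_overlay(image: EnFaceImage, decomp: SegmentDecomposition) -> np.ndarray:
    """RGB image: dimmed scan with segments colored by class.

    Natural oblique segments green, other segments red, branch pixels blue.
    Segment coordinates are in the normalized (OD) frame, so the backdrop is
    laterality-normalized too.
    """
    from .symmetry import normalize_laterality

    base = normalize_laterality(image, image.eye_side)
    gray = (base.pixels.astype(float) * 0.5).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)
    for seg in decomp.segments:
        rr, cc = seg.pixel_path[:, 0], seg.pixel_path[:, 1]
        rgb[rr, cc] = (0, 220, 0) if seg.natural_oblique else (230, 0, 0)
    return rgb


def save_qc_overlay(rgb: np.ndarray, path) -> None:
    PILImage.fromarray(rgb, mode="RGB").save(path)
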