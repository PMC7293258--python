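"""Domain types for en face choroidal slab analysis.

The analyzed input is a coronal (en face) slice through the top quarter of
Haller's layer, reconstructed from a macula-centered OCT volume after
flattening to Bruch's membrane.  Images are 8-bit grayscale rasters in which
the large choroidal vessels appear *dark*; row 0 is the superior edge of the
scan and, for a right eye (OD), increasing column index runs nasal→temporal.
The default scan geometry is a 7 × 7 mm field sampled at 512 × 512 pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

#: mm per pixel edge for the default 7 x 7 mm / 512 x 512 px scan mode.
PIXEL_SIZE_MM_DEFAULT = 7.0 / 512.0

MIN_IMAGE_SIDE_PX = 64

EYE_SIDES = ("OD", "OS")


class EnFaceError(ValueError):
    """Base class for domain validation errors."""


class ImageSizeError(EnFaceError):
    """Image too small for the requested operation (e.g. threshold window)."""


class UndefinedDiameterError(EnFaceError):
    """Mean diameter requested for a zero-length skeleton."""


class UndefinedIndexError(EnFaceError):
    """Symmetry index requested with no retained segments."""


def _validate_grid(pixels: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise EnFaceError(f"{name} must be a 2-D array, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class EnFaceImage:
    """Grayscale en face slab image with scan metadata.

    Parameters
    ----------
    pixels : (H, W) array of 8-bit intensities, row 0 = superior edge.
    pixel_size_mm : physical edge length of one pixel in mm.
    eye_side : "OD" (right) or "OS" (left); drives laterality normalization.
    fovea_xy : (x=column, y=row) pixel position of the fovea; ``None`` means
        the image center (macula-centered scans).
    cct_um : optional subfoveal central choroidal thickness in micrometers.
    """

    pixels: np.ndarray
    pixel_size_mm: float = PIXEL_SIZE_MM_DEFAULT
    eye_side: str = "OD"
    fovea_xy: Optional[Tuple[float, float]] = None
    cct_um: Optional[float] = None

    def __post_init__(self) -> None:
        arr = _validate_grid(self.pixels, "EnFaceImage.pixels")
        if arr.shape[0] < MIN_IMAGE_SIDE_PX or arr.shape[1] < MIN_IMAGE_SIDE_PX:
            raise ImageSizeError(
                f"en face image must be at least {MIN_IMAGE_SIDE_PX} px per side, "
                f"got {arr.shape[1]}x{arr.shape[0]}"
            )
        if arr.dtype != np.uint8:
            if np.nanmin(arr) < 0 or np.nanmax(arr) > 255:
                raise EnFaceError("intensities must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        object.__setattr__(self, "pixels", arr)
        if not (self.pixel_size_mm > 0):
            raise EnFaceError(f"pixel_size_mm must be > 0, got {self.pixel_size_mm}")
        if self.eye_side not in EYE_SIDES:
            raise EnFaceError(f"eye_side must be one of {EYE_SIDES}, got {self.eye_side!r}")
        if self.fovea_xy is not None:
            x, y = self.fovea_xy
            if not (0 <= x < self.width_px and 0 <= y < self.height_px):
                raise EnFaceError(f"fovea_xy {self.fovea_xy} outside image bounds")
        if self.cct_um is not None and not (self.cct_um > 0):
            raise EnFaceError("cct_um must be positive when given")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def fovea(self) -> Tuple[float, float]:
        """Resolved fovea position (x=column, y=row)."""
        if self.fovea_xy is not None:
            return tuple(self.fovea_xy)
        return ((self.width_px - 1) / 2.0, (self.height_px - 1) / 2.0)

    def with_pixels(self, pixels: np.ndarray) -> "EnFaceImage":
        return replace(self, pixels=pixels)


@dataclass(frozen=True)
class VesselMask:
    """Binary vessel segmentation; foreground (True) = dark vessel phase."""

    pixels: np.ndarray
    pixel_size_mm: float = PIXEL_SIZE_MM_DEFAULT

    def __post_init__(self) -> None:
        arr = _validate_grid(self.pixels, "VesselMask.pixels")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 1))):
                raise EnFaceError("mask values must be binary (0/1)")
            arr = arr.astype(bool)
        object.__setattr__(self, "pixels", arr)
        if not (self.pixel_size_mm > 0):
            raise EnFaceError("pixel_size_mm must be > 0")

    @property
    def n_foreground(self) -> int:
        return int(self.pixels.sum())

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class Skeleton:
    """One-pixel-wide vessel centerlines (subset of the mask foreground)."""

    pixels: np.ndarray
    pixel_size_mm: float = PIXEL_SIZE_MM_DEFAULT

    def __post_init__(self) -> None:
        arr = _validate_grid(self.pixels, "Skeleton.pixels")
        if arr.dtype != bool:
            arr = arr.astype(bool)
        object.__setattr__(self, "pixels", arr)
        if not (self.pixel_size_mm > 0):
            raise EnFaceError("pixel_size_mm must be > 0")

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinarizationConfig:
    """Local-mean (Niblack-style) thresholding plus size-filter de-noising.

    ``offset`` is subtracted from the local mean before comparison; ``None``
    resolves to 0.1 x the image-wide intensity SD at run time, which adapts
    the margin to scan contrast.  Components smaller than ``min_component_px``
    are dropped and enclosed holes smaller than ``min_hole_px`` are filled.
    ``smooth_px`` is the radius of a median boundary-smoothing filter applied
    between thresholding and the size filters; without it, noise-ragged mask
    edges sprout skeleton spurs that inflate vessel length (0 disables).
    """

    window_px: int = 51
    offset: Optional[float] = None
    min_component_px: int = 100
    min_hole_px: int = 100
    smooth_px: int = 1

    def __post_init__(self) -> None:
        if self.window_px < 3 or self.window_px % 2 == 0:
            raise EnFaceError(f"window_px must be odd and >= 3, got {self.window_px}")
        if self.min_component_px < 0 or self.min_hole_px < 0:
            raise EnFaceError("de-noising size thresholds must be >= 0")
        if self.smooth_px < 0:
            raise EnFaceError("smooth_px must be >= 0")


@dataclass(frozen=True)
class EyeMetrics:
    """Per-eye vessel-structure record.

    ``mean_diameter_mm`` is vessel area / vessel length, the caliber of an
    equivalent uniform-width vessel network.  ``valid`` is False when the
    segmentation produced no vessels (or no usable segments), in which case
    the numeric fields are NaN rather than misleading zeros.
    """

    vessel_area_mm2: float
    vessel_length_mm: float
    mean_diameter_mm: float
    symmetry_index_pct: float
    cct_um: Optional[float] = None
    group: Optional[str] = None
    eye_side: str = "OD"
    eye_id: Optional[str] = None
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid:
            for name in ("vessel_area_mm2", "vessel_length_mm", "mean_diameter_mm"):
                v = getattr(self, name)
                if not (v >= 0):
                    raise EnFaceError(f"{name} must be nonnegative, got {v}")
            if not (0.0 <= self.symmetry_index_pct <= 100.0):
                raise EnFaceError(
                    f"symmetry_index_pct must lie in [0, 100], got {self.symmetry_index_pct}"
                )
            if self.vessel_length_mm > 0:
                prod = self.mean_diameter_mm * self.vessel_length_mm
                if not math.isclose(prod, self.vessel_area_mm2, rel_tol=1e-9, abs_tol=1e-12):
                    raise EnFaceError("mean_diameter_mm x vessel_length_mm != vessel_area_mm2")

    @classmethod
    def invalid(cls, eye_side: str = "OD", eye_id: Optional[str] = None,
                group: Optional[str] = None, cct_um: Optional[float] = None) -> "EyeMetrics":
        nan = float("nan")
        return cls(nan, nan, nan, nan, cct_um=cct_um, group=group,
                   eye_side=eye_side, eye_id=eye_id, valid=False)
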