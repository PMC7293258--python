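"""Running-pattern symmetry of Haller's-layer vessels.

The large choroidal vessels of a healthy macula drain obliquely away from the
fovea toward the upper-temporal and lower-temporal vortex veins, mirror-wise
about the horizontal fovea line.  This module quantifies that: the thinned
vessel map is cut into branch-free segments at branch points, each segment's
endpoint-to-endpoint angle to the horizontal is measured in a
laterality-normalized frame (temporal = +x, superior = +y), and a segment is
a "natural oblique vessel" when it points into its hemifield's temporal-ward
quadrant.  The symmetry index is the percentage of total segment length that
is natural oblique; a high index implies a subfoveal watershed zone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from .enface import (
    EYE_SIDES,
    EnFaceError,
    EnFaceImage,
    Skeleton,
    UndefinedIndexError,
    VesselMask,
)
from .vessels import skeleton_length_px

SUPERIOR = "superior"
INFERIOR = "inferior"

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=int)
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class VesselSegment:
    """A branch-free piece of the skeleton, in the normalized frame.

    ``pixel_path`` is ordered endpoint-to-endpoint as (row, col) pairs;
    ``orientation_deg`` is the undirected angle in (-90, 90] between the
    endpoint chord and the horizontal, positive = temporal-and-superior.
    """

    pixel_path: np.ndarray
    length_mm: float
    orientation_deg: float
    hemifield: str
    natural_oblique: bool = False

    @property
    def endpoints(self) -> Tuple[Tuple[int, int], Tuple[int, int]]:
        return (tuple(self.pixel_path[0]), tuple(self.pixel_path[-1]))

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_path)

    @property
    def midpoint(self) -> Tuple[int, int]:
        return tuple(self.pixel_path[len(self.pixel_path) // 2])


@dataclass(frozen=True)
class SegmentDecomposition:
    """Segments plus the pixel bookkeeping of the decomposition."""

    segments: Tuple[VesselSegment, ...]
    n_branch_px: int
    n_discarded: int          # components dropped (loops + too short)
    n_discarded_px: int
    n_loops: int
    n_skeleton_px: int

    def pixel_accounting_ok(self) -> bool:
        seg_px = sum(s.n_pixels for s in self.segments)
        return seg_px + self.n_branch_px + self.n_discarded_px == self.n_skeleton_px


@dataclass(frozen=True)
class SymmetryResult:
    symmetry_index_pct: float
    natural_length_mm: float
    total_length_mm: float
    n_segments: int
    n_discarded: int = 0


MaskLike = Union[np.ndarray, VesselMask, Skeleton, EnFaceImage]


def normalize_laterality(obj: MaskLike, eye_side: str) -> MaskLike:
    """Mirror left-eye (OS) rasters horizontally so temporal is always +x.

    Right-eye (OD) inputs are returned unchanged.  For an ``EnFaceImage`` the
    fovea x coordinate is mirrored along with the pixels.
    """
    if eye_side not in EYE_SIDES:
        raise EnFaceError(f"eye_side must be one of {EYE_SIDES}, got {eye_side!r}")
    if eye_side == "OD":
        return obj
    if isinstance(obj, EnFaceImage):
        fovea = obj.fovea_xy
        if fovea is not None:
            fovea = (obj.width_px - 1 - fovea[0], fovea[1])
        return replace(obj, pixels=np.fliplr(obj.pixels), fovea_xy=fovea)
    if isinstance(obj, (VesselMask, Skeleton)):
        return replace(obj, pixels=np.fliplr(obj.pixels))
    return np.fliplr(np.asarray(obj))


def mirror_fovea_x(fovea_xy: Tuple[float, float], width_px: int,
                   eye_side: str) -> Tuple[float, float]:
    """Fovea coordinates in the laterality-normalized frame."""
    if eye_side == "OD":
        return tuple(fovea_xy)
    return (width_px - 1 - fovea_xy[0], fovea_xy[1])


def _neighbor_counts(sk: np.ndarray) -> np.ndarray:
    return ndimage.convolve(sk.astype(int), _NEIGHBOR_KERNEL, mode="constant", cval=0)


def find_branch_points(skel: Union[Skeleton, np.ndarray]) -> np.ndarray:
    """Skeleton pixels with >= 3 skeleton neighbors (8-connectivity).

    Returns an (N, 2) array of (row, col) coordinates.  A single anatomical
    junction generally shows up as a small 8-connected *cluster* of such
    pixels (even an ideal one-pixel cross has five); use
    :func:`count_branch_points` for a per-junction count.
    """
    sk = skel.pixels if isinstance(skel, Skeleton) else np.asarray(skel, dtype=bool)
    branch = sk & (_neighbor_counts(sk) >= 3)
    return np.argwhere(branch)


def count_branch_points(skel: Union[Skeleton, np.ndarray]) -> int:
    """Number of junctions: 8-connected clusters of branch pixels."""
    sk = skel.pixels if isinstance(skel, Skeleton) else np.asarray(skel, dtype=bool)
    branch = sk & (_neighbor_counts(sk) >= 3)
    _, n = ndimage.label(branch, structure=_STRUCT8)
    return int(n)


def segment_orientation(p0: Sequence[float], p1: Sequence[float]) -> float:
    """Undirected angle of the chord p0→p1 to the horizontal, in (-90, 90].

    Points are (row, col) in the normalized raster (row 0 superior, +col
    temporal); the angle is computed in the anatomical frame where superior
    is +y, so a vessel running temporal-and-superior has a positive angle.
    """
    (r0, c0), (r1, c1) = p0, p1
    dx = float(c1) - float(c0)
    dy = float(r0) - float(r1)  # superior = decreasing row
    if dx == 0.0 and dy == 0.0:
        raise EnFaceError("segment endpoints coincide; orientation undefined")
    ang = math.degrees(math.atan2(dy, dx))
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    return ang


def classify_natural_oblique(orientation_deg: float, hemifield: str,
                             inclusive: bool = False) -> bool:
    """Is a segment oriented toward its hemifield's temporal vortex vein?

    Superior hemifield: natural when the angle lies in the open interval
    (0°, 90°); inferior hemifield: (-90°, 0°).  Exactly horizontal or
    vertical segments are not natural unless ``inclusive`` is set.
    """
    if hemifield == SUPERIOR:
        lo, hi = 0.0, 90.0
    elif hemifield == INFERIOR:
        lo, hi = -90.0, 0.0
    else:
        raise EnFaceError(f"unknown hemifield {hemifield!r}")
    if inclusive:
        return lo <= orientation_deg <= hi
    return lo < orientation_deg < hi


def _trace_path(coords: np.ndarray) -> np.ndarray:
    """Order the pixels of a branch-free component from one endpoint."""
    coord_set = {tuple(p) for p in coords}
    degree = {}
    for p in coord_set:
        r, c = p
        degree[p] = sum(
            (r + dr, c + dc) in coord_set
            for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
        )
    ends = [p for p, d in degree.items() if d <= 1]
    start = min(ends) if ends else min(coord_set)
    path = [start]
    visited = {start}
    cur = start
    while len(visited) < len(coord_set):
        r, c = cur
        nxt = None
        for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, 1), (-1, -1)):
            q = (r + dr, c + dc)
            if q in coord_set and q not in visited:
                nxt = q
                break
        if nxt is None:  # should not happen for a simple path
            break
        path.append(nxt)
        visited.add(nxt)
        cur = nxt
    return np.array(path, dtype=int)


def decompose_segments(skel: Skeleton,
                       fovea_xy: Optional[Tuple[float, float]] = None,
                       min_segment_px: int = 5,
                       inclusive_band: bool = False) -> SegmentDecomposition:
    """Cut the skeleton into branch-free segments and classify each.

    Branch pixels (>= 3 neighbors) are removed; every remaining 8-connected
    component with two endpoints and at least ``min_segment_px`` pixels
    becomes one :class:`VesselSegment`.  Closed loops and sub-threshold
    fragments are discarded but counted, so that segment pixels + branch
    pixels + discarded pixels always equal the skeleton pixel total.

    The skeleton must already be in the laterality-normalized frame;
    hemifield is assigned by the segment midpoint's side of the horizontal
    fovea line (on-line midpoints count as inferior).
    """
    sk = skel.pixels
    n_total = int(sk.sum())
    if fovea_xy is None:
        fovea_xy = ((sk.shape[1] - 1) / 2.0, (sk.shape[0] - 1) / 2.0)
    fovea_y = float(fovea_xy[1])

    branch = sk & (_neighbor_counts(sk) >= 3)
    remaining = sk & ~branch
    n_branch_px = int(branch.sum())

    labels, n_comp = ndimage.label(remaining, structure=_STRUCT8)
    slices = ndimage.find_objects(labels)
    segments: List[VesselSegment] = []
    n_discarded = n_loops = n_discarded_px = 0
    for idx in range(1, n_comp + 1):
        sl = slices[idx - 1]
        comp = labels[sl] == idx
        n_px = int(comp.sum())
        if n_px < max(min_segment_px, 2):
            n_discarded += 1
            n_discarded_px += n_px
            continue
        # a loop has no endpoint: every pixel keeps 2 within-component neighbors
        deg = _neighbor_counts(comp)[comp]
        if int((deg <= 1).sum()) == 0:
            n_discarded += 1
            n_loops += 1
            n_discarded_px += n_px
            continue
        offset = np.array([sl[0].start, sl[1].start])
        path = _trace_path(np.argwhere(comp)) + offset
        p0, p1 = path[0], path[-1]
        orientation = segment_orientation(p0, p1)
        mid = path[len(path) // 2]
        hemifield = SUPERIOR if mid[0] < fovea_y else INFERIOR
        length_mm = skeleton_length_px(comp) * skel.pixel_size_mm
        segments.append(VesselSegment(
            pixel_path=path,
            length_mm=length_mm,
            orientation_deg=orientation,
            hemifield=hemifield,
            natural_oblique=classify_natural_oblique(orientation, hemifield,
                                                     inclusive=inclusive_band),
        ))
    return SegmentDecomposition(
        segments=tuple(segments),
        n_branch_px=n_branch_px,
        n_discarded=n_discarded,
        n_discarded_px=n_discarded_px,
        n_loops=n_loops,
        n_skeleton_px=n_total,
    )


def symmetry_index(segments: Iterable[VesselSegment], n_discarded: int = 0) -> SymmetryResult:
    """Percentage of total segment length classified natural oblique."""
    segments = list(segments)
    total = sum(s.length_mm for s in segments)
    if not segments or total <= 0:
        raise UndefinedIndexError("no retained segments; symmetry index undefined")
    natural = sum(s.length_mm for s in segments if s.natural_oblique)
    if natural >= total:
        pct = 100.0
    else:
        pct = min(100.0, max(0.0, 100.0 * natural / total))
    return SymmetryResult(
        symmetry_index_pct=pct,
        natural_length_mm=natural,
        total_length_mm=total,
        n_segments=len(segments),
        n_discarded=n_discarded,
    )


def compute_symmetry(skel: Skeleton, eye_side: str = "OD",
                     fovea_xy: Optional[Tuple[float, float]] = None,
                     min_segment_px: int = 5,
                     inclusive_band: bool = False) -> SymmetryResult:
    """Laterality-normalize, decompose, classify, and compute the index."""
    norm = normalize_laterality(skel, eye_side)
    if fovea_xy is not None:
        fovea_xy = mirror_fovea_x(fovea_xy, skel.shape[1], eye_side)
    decomp = decompose_segments(norm, fovea_xy=fovea_xy,
                                min_segment_px=min_segment_px,
                                inclusive_band=inclusive_band)
    return symmetry_index(decomp.segments, n_discarded=decomp.n_discarded)
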