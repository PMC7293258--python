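"""Segment decomposition, orientation classification, and the symmetry index."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hallerquant import (
    EnFaceError,
    EnFaceImage,
    Skeleton,
    UndefinedIndexError,
    VesselMask,
)
from hallerquant.symmetry import (
    INFERIOR,
    SUPERIOR,
    VesselSegment,
    classify_natural_oblique,
    compute_symmetry,
    count_branch_points,
    decompose_segments,
    find_branch_points,
    mirror_fovea_x,
    normalize_laterality,
    segment_orientation,
    symmetry_index,
)
from hallerquant.vessels import compute_eye_metrics, skeletonize_mask
from hallerquant.simulate import VesselSceneParams, generate_vessel_image

from conftest import skeleton_from_coords


def _segment(length_mm, orientation_deg, hemifield, natural):
    path = np.array([[0, 0], [0, 1], [0, 2]])
    return VesselSegment(pixel_path=path, length_mm=length_mm,
                         orientation_deg=orientation_deg, hemifield=hemifield,
                         natural_oblique=natural)


class TestNormalizeLaterality:
    def test_od_is_identity(self):
        arr = np.random.default_rng(0).random((64, 64)) > 0.5
        out = normalize_laterality(arr, "OD")
        assert out is arr

    def test_os_is_involution(self):
        arr = np.random.default_rng(1).random((64, 64)) > 0.5
        out = normalize_laterality(normalize_laterality(arr, "OS"), "OS")
        assert np.array_equal(out, arr)

    def test_os_flips_orientation_sign(self):
        # +30-degree line (rising temporally) in a left eye becomes -30 after
        # normalization mirrors the temporal direction
        coords = [(50 - round(i * math.tan(math.radians(30))), 10 + i) for i in range(60)]
        skel = skeleton_from_coords(coords, (100, 100))
        norm = normalize_laterality(skel, "OS")
        decomp = decompose_segments(norm, fovea_xy=(49.5, 90.0))
        assert len(decomp.segments) == 1
        assert decomp.segments[0].orientation_deg == pytest.approx(-30, abs=1.5)

    def test_unknown_eye_side_rejected(self):
        with pytest.raises(EnFaceError):
            normalize_laterality(np.zeros((64, 64), dtype=bool), "LEFT")

    def test_fovea_mirroring(self):
        assert mirror_fovea_x((10.0, 20.0), 512, "OS") == (501.0, 20.0)
        assert mirror_fovea_x((10.0, 20.0), 512, "OD") == (10.0, 20.0)


class TestBranchPoints:
    def test_straight_line_has_none(self):
        skel = skeleton_from_coords([(10, c) for c in range(5, 50)], (64, 64))
        assert len(find_branch_points(skel)) == 0

    def test_t_shape_has_one_junction(self):
        coords = [(10, c) for c in range(40)] + [(r, 20) for r in range(11, 30)]
        skel = skeleton_from_coords(coords, (64, 64))
        assert count_branch_points(skel) == 1
        assert len(find_branch_points(skel)) >= 1

    def test_plus_shape_has_one_junction(self):
        coords = [(20, c) for c in range(40)] + [(r, 20) for r in range(40) if r != 20]
        skel = skeleton_from_coords(coords, (64, 64))
        assert count_branch_points(skel) == 1


class TestDecomposeSegments:
    def test_straight_line_single_horizontal_segment(self):
        skel = skeleton_from_coords([(10, c) for c in range(100)], (128, 128))
        decomp = decompose_segments(skel)
        assert len(decomp.segments) == 1
        assert decomp.segments[0].orientation_deg == pytest.approx(0.0)
        assert decomp.n_discarded == 0

    def test_t_shape_yields_three_segments(self):
        coords = [(60, c) for c in range(10, 110)] + [(r, 60) for r in range(61, 111)]
        skel = skeleton_from_coords(coords, (128, 128))
        decomp = decompose_segments(skel, min_segment_px=5)
        assert len(decomp.segments) == 3
        assert decomp.pixel_accounting_ok()

    def test_closed_ring_is_discarded_as_loop(self):
        from skimage.draw import circle_perimeter
        arr = np.zeros((64, 64), dtype=bool)
        rr, cc = circle_perimeter(30, 30, 10)
        arr[rr, cc] = True
        decomp = decompose_segments(Skeleton(arr), min_segment_px=5)
        assert len(decomp.segments) == 0
        assert decomp.n_discarded == 1
        assert decomp.n_loops == 1

    def test_mass_conservation_on_generated_scene(self, default_scene):
        _, image, truth, _ = default_scene
        skel = skeletonize_mask(truth)
        decomp = decompose_segments(skel)
        seg_px = sum(s.n_pixels for s in decomp.segments)
        assert seg_px + decomp.n_branch_px + decomp.n_discarded_px == decomp.n_skeleton_px
        assert len(decomp.segments) > 10


class TestOrientation:
    @pytest.mark.parametrize("p0,p1,expected", [
        ((10, 0), (10, 10), 0.0),     # horizontal
        ((10, 0), (0, 10), 45.0),     # up-temporal diagonal
        ((10, 5), (0, 5), 90.0),      # vertical, either endpoint order
        ((0, 5), (10, 5), 90.0),
    ])
    def test_chord_angles(self, p0, p1, expected):
        assert segment_orientation(p0, p1) == pytest.approx(expected)

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(EnFaceError):
            segment_orientation((3, 3), (3, 3))

    @given(st.integers(-50, 50), st.integers(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_angle_range_and_undirectedness(self, dr, dc):
        if dr == 0 and dc == 0:
            return
        a = segment_orientation((0, 0), (dr, dc))
        b = segment_orientation((dr, dc), (0, 0))
        assert -90 < a <= 90
        assert a == pytest.approx(b)


class TestClassifyNaturalOblique:
    @pytest.mark.parametrize("angle,hemifield,expected", [
        (37.0, SUPERIOR, True),
        (-37.0, SUPERIOR, False),
        (-37.0, INFERIOR, True),
        (37.0, INFERIOR, False),
        (0.0, SUPERIOR, False),
        (90.0, SUPERIOR, False),
        (0.0, INFERIOR, False),
    ])
    def test_quadrant_rule(self, angle, hemifield, expected):
        assert classify_natural_oblique(angle, hemifield) is expected

    def test_inclusive_bounds_option(self):
        assert classify_natural_oblique(0.0, SUPERIOR, inclusive=True)
        assert classify_natural_oblique(90.0, SUPERIOR, inclusive=True)


class TestSymmetryIndex:
    def test_all_natural_scores_100(self):
        segs = [_segment(1.0, 30, SUPERIOR, True), _segment(2.0, -40, INFERIOR, True)]
        assert symmetry_index(segs).symmetry_index_pct == 100.0

    def test_none_natural_scores_0(self):
        segs = [_segment(1.0, -30, SUPERIOR, False)]
        assert symmetry_index(segs).symmetry_index_pct == 0.0

    def test_length_weighted_ratio(self):
        segs = [_segment(3.0, 30, SUPERIOR, True), _segment(1.0, -30, SUPERIOR, False)]
        res = symmetry_index(segs)
        assert res.symmetry_index_pct == pytest.approx(75.0)
        assert res.natural_length_mm == pytest.approx(3.0)
        assert res.total_length_mm == pytest.approx(4.0)

    def test_no_segments_rejected(self):
        with pytest.raises(UndefinedIndexError):
            symmetry_index([])


class TestPipelineInvariants:
    def test_mirror_pair_gives_identical_index(self, default_scene):
        """An OD image and its horizontal mirror labelled OS are the same eye;
        the pipeline must return bit-identical metrics for both."""
        _, image, _, _ = default_scene
        mirrored = EnFaceImage(np.fliplr(image.pixels),
                               pixel_size_mm=image.pixel_size_mm, eye_side="OS")
        m_od = compute_eye_metrics(image)
        m_os = compute_eye_metrics(mirrored)
        assert m_od.symmetry_index_pct == m_os.symmetry_index_pct
        assert m_od.vessel_area_mm2 == m_os.vessel_area_mm2
        assert m_od.vessel_length_mm == m_os.vessel_length_mm

    @staticmethod
    def _mirror_symmetric_pattern(sign: int):
        """±45° lines, mirror-wise about the horizontal midline.

        ``sign=+1`` runs every superior line up-temporal and every inferior
        line down-temporal (the natural drainage pattern); ``sign=-1`` turns
        each line 90° in place, producing the fully unnatural pattern.
        """
        coords = []
        for c0 in (10, 60, 110):
            for i in range(100):
                coords.append((120 - i, c0 + i) if sign > 0 else (21 + i, c0 + i))
                coords.append((136 + i, c0 + i) if sign > 0 else (235 - i, c0 + i))
        return skeleton_from_coords(coords, (256, 256))

    def test_ideal_symmetric_pattern_scores_100_rotated_scores_0(self):
        res = compute_symmetry(self._mirror_symmetric_pattern(+1))
        assert res.symmetry_index_pct == 100.0
        # same line positions with every running direction turned 90 degrees
        res_rot = compute_symmetry(self._mirror_symmetric_pattern(-1))
        assert res_rot.symmetry_index_pct == 0.0

    def test_index_bounded_on_random_skeletons(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            arr = rng.random((96, 96)) > 0.9
            skel = skeletonize_mask(VesselMask(arr))
            try:
                res = compute_symmetry(skel, min_segment_px=3)
            except UndefinedIndexError:
                continue
            assert 0.0 <= res.symmetry_index_pct <= 100.0

    @pytest.mark.parametrize("s", [0.0, 0.5, 1.0])
    def test_generator_symmetry_recovery(self, s):
        params = VesselSceneParams(symmetry_fraction=s, seed=11)
        image, _, _ = generate_vessel_image(params)
        m = compute_eye_metrics(image)
        assert abs(m.symmetry_index_pct / 100.0 - s) <= 0.1
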