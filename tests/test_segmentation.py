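"""Per-slice segmentation: MSER detection, LV selection, hull, rays, RV, trabeculae."""

import math
from dataclasses import replace

import numpy as np
import pytest
from skimage.measure import label as cc_label

from lvtrab.phantom import PhantomSpec, generate_phantom
from lvtrab.segmentation import (
    RayCastConfig,
    Region,
    SegmentationConfig,
    SegmentationError,
    cast_external_layer,
    convex_hull_region,
    detect_msers,
    detect_rv,
    detect_trabeculae,
    polygon_area,
    polygon_coverage_area,
    polygon_mask,
    refine_hull,
    segment_slice,
    select_lv_cavity,
)
from lvtrab.studyio import SliceImage


def region_from_mask(mask, spacing=(1.0, 1.0)):
    return Region.from_mask(mask, spacing)


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(yy - center[0], xx - center[1]) < radius


# ---------------------------------------------------------------------------
# MSER


class TestDetectMsers:
    def test_uniform_image_yields_nothing(self):
        img = SliceImage(np.full((128, 128), 500.0), (1.0, 1.0), 1)
        assert detect_msers(img, 0.5) == []

    def test_phantom_pool_found_near_center(self, default_phantom):
        stack, truth = default_phantom
        s = stack.slices[-1]  # basal
        regions = detect_msers(s, 0.5)
        assert regions
        # independent oracle: connected component of the midpoint threshold
        spec = PhantomSpec()
        mid = 0.5 * (spec.intensity_blood + spec.intensity_myocardium)
        comp = cc_label(s.pixels > mid, connectivity=2)
        c = (s.pixels.shape[0] - 1) / 2.0
        pool_lbl = comp[int(c), int(c)]
        rows, cols = np.nonzero(comp == pool_lbl)
        oracle_centroid = (rows.mean(), cols.mean())
        best = min(
            regions,
            key=lambda r: math.hypot(
                r.centroid_px[0] - oracle_centroid[0],
                r.centroid_px[1] - oracle_centroid[1],
            ),
        )
        assert math.hypot(
            best.centroid_px[0] - oracle_centroid[0],
            best.centroid_px[1] - oracle_centroid[1],
        ) <= 2.0

    def test_rv_crescent_outside_roi_excluded(self, default_phantom):
        # ROI chosen so the crescent (inner radius 33 mm, spanning 150-250 deg,
        # nearest Chebyshev distance 33/sqrt(2) ~ 23 px) lies entirely outside
        # the centered box, while the LV pool is inside
        stack, truth = default_phantom
        s = stack.slices[-1]
        regions = detect_msers(s, 0.18)
        rv = truth.rv_mask[-1]
        for r in regions:
            assert not rv[r.pixels[:, 0], r.pixels[:, 1]].any()

    def test_roi_fraction_validated(self, default_phantom):
        stack, _ = default_phantom
        with pytest.raises(ValueError, match="roi_fraction"):
            detect_msers(stack.slices[0], 0.0)


# ---------------------------------------------------------------------------
# LV selection


class TestSelectLv:
    def make_image(self, shape=(128, 128)):
        return SliceImage(np.zeros(shape), (1.0, 1.0), 1)

    def test_single_region_returned(self):
        disk = region_from_mask(disk_mask((128, 128), (64, 64), 15))
        assert select_lv_cavity([disk], self.make_image()) is disk

    def test_disk_beats_crescent_at_equal_distance(self):
        shape = (128, 128)
        disk = region_from_mask(disk_mask(shape, (40, 64), 12))
        ring = disk_mask(shape, (88, 64), 16) & ~disk_mask(shape, (88, 64), 10)
        crescent = region_from_mask(ring & (np.mgrid[0:128, 0:128][0] < 88))
        img = self.make_image(shape)
        assert disk.circularity > crescent.circularity
        assert select_lv_cavity([disk, crescent], img) is disk

    def test_centered_disk_beats_corner_disk(self):
        shape = (128, 128)
        center = region_from_mask(disk_mask(shape, (64, 64), 12))
        corner = region_from_mask(disk_mask(shape, (16, 16), 12))
        assert select_lv_cavity([center, corner], self.make_image(shape)) is center

    def test_empty_candidates_error(self):
        with pytest.raises(SegmentationError):
            select_lv_cavity([], self.make_image())

    def test_score_formula_explicit(self):
        # recompute the declared score by hand for two candidates
        shape = (128, 128)
        a = region_from_mask(disk_mask(shape, (64, 64), 10))
        b = region_from_mask(disk_mask(shape, (30, 30), 14))
        img = self.make_image(shape)
        half_diag = math.hypot(*shape) / 2
        center = ((shape[0] - 1) / 2, (shape[1] - 1) / 2)

        def score(r):
            d = math.hypot(r.centroid_px[0] - center[0], r.centroid_px[1] - center[1])
            return r.circularity - 0.5 * d / half_diag

        expect = a if score(a) >= score(b) else b
        assert select_lv_cavity([a, b], img) is expect


# ---------------------------------------------------------------------------
# Convex hull


def brute_force_hull(points):
    """O(n^3) hull: a point is a vertex iff some pair-line has it extreme."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    verts = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            cross = d[0] * (pts[:, 1] - pts[i, 1]) - d[1] * (pts[:, 0] - pts[i, 0])
            if (cross >= -1e-9).all() or (cross <= 1e-9).all():
                verts.add(tuple(pts[i]))
                verts.add(tuple(pts[j]))
    return verts


class TestConvexHull:
    def test_disk_hull_area_close_to_region_area(self):
        disk = region_from_mask(disk_mask((128, 128), (64, 64), 20))
        hull = convex_hull_region(disk)
        assert polygon_coverage_area(hull) == pytest.approx(disk.area_px, rel=0.02)
        assert polygon_coverage_area(hull) >= disk.area_px

    def test_star_cavity_hull_exceeds_area_and_matches_brute_force(self, default_phantom):
        stack, truth = default_phantom
        cav = region_from_mask(truth.cavity_mask[-1])
        hull = convex_hull_region(cav)
        assert polygon_area(hull) > cav.area_px
        # oracle over boundary pixels only (<= 200 points)
        mask = cav.mask()
        from scipy.ndimage import binary_erosion

        boundary = mask & ~binary_erosion(mask, np.ones((3, 3), bool))
        rows, cols = np.nonzero(boundary)
        pts = np.column_stack([rows, cols])
        rng = np.random.default_rng(0)
        if len(pts) > 200:
            pts = pts[rng.choice(len(pts), 200, replace=False)]
        oracle = brute_force_hull(pts)
        fast = convex_hull_region(region_from_mask(_mask_from_points(pts, mask.shape)))
        assert {tuple(v) for v in fast} == _extreme_only(oracle)

    def test_hull_idempotent(self):
        disk = region_from_mask(disk_mask((128, 128), (64, 64), 20))
        hull1 = convex_hull_region(disk)
        pts = np.round(hull1).astype(int)
        hull2 = convex_hull_region(region_from_mask(_mask_from_points(pts, (128, 128))))
        assert polygon_area(hull2) == pytest.approx(polygon_area(hull1), rel=0.02)

    def test_collinear_region_rejected(self):
        mask = np.zeros((128, 128), bool)
        mask[64, 10:100] = True
        with pytest.raises(SegmentationError, match="degenerate"):
            convex_hull_region(region_from_mask(mask))


def _mask_from_points(pts, shape):
    m = np.zeros(shape, bool)
    m[pts[:, 0], pts[:, 1]] = True
    return m


def _extreme_only(vertex_set):
    """Drop collinear mid-edge points from the brute-force vertex set."""
    pts = np.array(sorted(vertex_set))
    from scipy.spatial import ConvexHull

    h = ConvexHull(pts)
    return {tuple(pts[i]) for i in h.vertices}


# ---------------------------------------------------------------------------
# External layer ray casting


class TestCastExternal:
    def test_clean_annulus_recovered_within_1_5_px(self, clean_annulus):
        spec, stack, truth = clean_annulus
        s = stack.slices[0]
        hull = refine_hull(s, convex_hull_region(region_from_mask(truth.cavity_mask[0])))
        poly = cast_external_layer(s, hull)
        c = (spec.image_size - 1) / 2.0
        radii = np.hypot(poly[:, 0] - c, poly[:, 1] - c)
        r_out = spec.cavity_radius + spec.wall_thickness
        assert np.abs(radii - r_out).max() <= 1.5

    def test_elliptical_annulus_within_2_px(self):
        size = 224
        c = (size - 1) / 2.0
        yy, xx = np.mgrid[0:size, 0:size]
        a_i, b_i, a_o, b_o = 25.0, 18.0, 33.0, 26.0
        inner = ((xx - c) / a_i) ** 2 + ((yy - c) / b_i) ** 2 < 1.0
        outer = ((xx - c) / a_o) ** 2 + ((yy - c) / b_o) ** 2 < 1.0
        img = np.full((size, size), 60.0)
        img[outer] = 300.0
        img[inner] = 800.0
        s = SliceImage(img, (1.0, 1.0), 1)
        hull = convex_hull_region(region_from_mask(inner))
        poly = cast_external_layer(s, hull)
        ang = np.arctan2(poly[:, 0] - c, poly[:, 1] - c)
        r_meas = np.hypot(poly[:, 0] - c, poly[:, 1] - c)
        r_true = (a_o * b_o) / np.sqrt(
            (b_o * np.cos(ang)) ** 2 + (a_o * np.sin(ang)) ** 2
        )
        assert np.abs(r_meas - r_true).max() <= 2.0

    def test_short_reach_raises_with_hint(self):
        spec = PhantomSpec(
            cavity_radius=15.0, wall_thickness=22.0, n_trabeculae=0,
            trabecula_depth=0.0, rv_present=False, noise_sd=0.0, n_slices=1,
        )
        stack, truth = generate_phantom(spec)
        s = stack.slices[0]
        hull = convex_hull_region(region_from_mask(truth.cavity_mask[0]))
        with pytest.raises(SegmentationError, match="d_expand"):
            cast_external_layer(s, hull, RayCastConfig(d_expand=1.2))

    def test_config_validation(self):
        with pytest.raises(ValueError, match="n_rays"):
            RayCastConfig(n_rays=10)
        with pytest.raises(ValueError, match="d_expand"):
            RayCastConfig(d_expand=0.9)


# ---------------------------------------------------------------------------
# RV detection


class TestDetectRv:
    def test_absent_when_no_rv(self, zero_phantom_segs):
        stack, truth, segs = zero_phantom_segs
        spec = PhantomSpec(n_trabeculae=0, rv_present=False, n_slices=1)
        st, tr = generate_phantom(spec)
        res = segment_slice(st.slices[0])
        assert res.rv_cavity is None

    def test_detected_inside_truth_mask(self, default_phantom, default_segs):
        stack, truth = default_phantom
        seg = default_segs[-1]
        assert seg.rv_cavity is not None
        r, c = (int(round(v)) for v in seg.rv_cavity.centroid_px)
        assert truth.rv_mask[-1][r, c]

    @pytest.mark.parametrize("angle", [20.0, 110.0, 305.0])
    def test_location_invariance(self, angle):
        spec = PhantomSpec(rv_angle=angle, n_slices=1)
        stack, truth = generate_phantom(spec)
        seg = segment_slice(stack.slices[0])
        assert seg.rv_cavity is not None
        r, c = (int(round(v)) for v in seg.rv_cavity.centroid_px)
        assert truth.rv_mask[0][r, c]


# ---------------------------------------------------------------------------
# Trabecular / compact split


class TestDetectTrabeculae:
    def test_no_strands_no_trabecular_mask(self, zero_phantom_segs):
        _, _, segs = zero_phantom_segs
        assert all(s.trabecular_mask.sum() == 0 for s in segs)

    def test_known_strands_high_dice(self, default_phantom, default_segs):
        stack, truth = default_phantom
        for i in (0, 4, 8):
            got = default_segs[i].trabecular_mask
            want = truth.trabecular_mask[i]
            dice = 2 * (got & want).sum() / (got.sum() + want.sum())
            assert dice >= 0.85

    def test_inverted_containment_rejected(self, default_phantom):
        stack, _ = default_phantom
        s = stack.slices[-1]
        big = convex_hull_region(region_from_mask(disk_mask(s.pixels.shape, (111.5, 111.5), 40)))
        small = convex_hull_region(region_from_mask(disk_mask(s.pixels.shape, (111.5, 111.5), 20)))
        with pytest.raises(SegmentationError, match="geometry"):
            detect_trabeculae(s, hull=big, external=small)


# ---------------------------------------------------------------------------
# Whole-slice invariants


def test_containment_and_disjointness_on_sweep(sweep_segs):
    for frac, stack, truth, segs in sweep_segs:
        for seg in segs:
            seg.validate()  # containment chain + disjointness + RV exclusion


def test_measured_trabecular_area_strictly_increases(sweep_segs):
    totals = []
    for frac, stack, truth, segs in sweep_segs:
        totals.append(sum(s.trabecular_mask.sum() for s in segs))
    assert totals == sorted(totals)
    assert len(set(totals)) == len(totals)


def test_rotation_equivariance_of_areas(default_phantom):
    stack, _ = default_phantom
    s = stack.slices[-1]
    seg = segment_slice(s)
    rot = SliceImage(np.rot90(s.pixels).copy(), s.pixel_spacing, s.instance_index)
    seg_rot = segment_slice(rot)
    for attr in ("trabecular_mask", "compact_mask"):
        a = getattr(seg, attr).sum()
        b = getattr(seg_rot, attr).sum()
        assert b == pytest.approx(a, rel=0.02)
    assert seg_rot.lv_cavity.area_px == pytest.approx(seg.lv_cavity.area_px, rel=0.02)


def test_region_circularity_of_disk_high():
    for radius in (10, 20, 40):
        disk = region_from_mask(disk_mask((128, 128), (64, 64), radius))
        assert disk.circularity >= 0.85
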