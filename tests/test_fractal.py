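"""Endocardial border extraction and box-counting fractal dimension."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from lvtrab.fractal import (
    FractalError,
    LVNC,
    NON_LVNC,
    ThirdsPartition,
    box_count_fd,
    box_counts,
    box_sizes,
    classify_fd_global,
    extract_border,
    fd_profile,
    koch_curve_mask,
    split_thirds,
)
from lvtrab.phantom import PhantomSpec, generate_phantom
from lvtrab.segmentation import (
    Region,
    convex_hull_region,
    polygon_coverage_area,
    segment_slice,
)

KOCH_DIM = math.log(4) / math.log(3)


# ---------------------------------------------------------------------------
# Border extraction


class TestExtractBorder:
    def test_disk_border_length_close_to_circumference(self, zero_phantom_segs):
        stack, truth, segs = zero_phantom_segs
        spec = PhantomSpec(n_trabeculae=0)
        seg = segs[-1]  # basal, cavity radius 26 px
        border = extract_border(seg)
        # 8-connected circle raster has between 2*pi*r and 8r/sqrt(2) pixels
        assert border.sum() == pytest.approx(2 * math.pi * 26, rel=0.10)

    def test_trabeculated_border_longer_than_hull_perimeter(self, default_segs):
        seg = default_segs[-1]
        border = extract_border(seg)
        hull = convex_hull_region(seg.lv_cavity)
        d = np.diff(np.vstack([hull, hull[:1]]), axis=0)
        hull_perimeter = np.hypot(d[:, 0], d[:, 1]).sum()
        assert border.sum() > hull_perimeter

    def test_border_closed_8_connected(self, default_segs):
        border = extract_border(default_segs[-1])
        rows, cols = np.nonzero(border)
        for r, c in zip(rows, cols):
            patch = border[max(0, r - 1) : r + 2, max(0, c - 1) : c + 2]
            assert patch.sum() >= 3  # itself plus at least two neighbors

    def test_empty_cavity_rejected(self, default_segs):
        seg = default_segs[0]
        empty = Region(
            pixels=np.array([[1, 1]]), shape=(64, 64), pixel_spacing=(1.0, 1.0)
        )
        from dataclasses import replace as dc_replace

        bad = dc_replace(seg, lv_cavity=empty)
        bad.lv_cavity.pixels = np.empty((0, 2), dtype=int)
        with pytest.raises((FractalError, ValueError)):
            extract_border(bad)


# ---------------------------------------------------------------------------
# Box counting


class TestBoxCountFd:
    def test_straight_line_dimension_one(self):
        m = np.zeros((256, 256), bool)
        m[128, :] = True
        assert 0.95 <= box_count_fd(m) <= 1.05

    def test_koch_curve_recovers_log4_log3(self):
        fd = box_count_fd(koch_curve_mask(depth=5, base_px=729))
        assert fd == pytest.approx(KOCH_DIM, abs=0.06)

    def test_koch_triadic_oracle(self):
        # independent check: counting at the curve's own triadic scales gives
        # the similarity dimension almost exactly
        k = koch_curve_mask(depth=5, base_px=729)
        sizes = [3, 9, 27, 81]
        counts = box_counts(k, sizes)
        slope = -np.polyfit(np.log(sizes), np.log(counts), 1)[0]
        assert slope == pytest.approx(KOCH_DIM, abs=0.06)

    def test_single_pixel_dimension_zero(self):
        m = np.zeros((256, 256), bool)
        m[100, 100] = True
        assert abs(box_count_fd(m)) <= 0.1

    def test_too_small_image_rejected(self):
        m = np.ones((16, 16), bool)
        with pytest.raises(FractalError, match="too small"):
            box_count_fd(m)

    def test_scale_robustness_on_grid_commensurate_doubling(self):
        fd1 = box_count_fd(koch_curve_mask(depth=5, base_px=512))
        fd2 = box_count_fd(koch_curve_mask(depth=5, base_px=1024))
        assert abs(fd1 - fd2) < 0.03

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(42)
        mask = rng.random((128, 128)) < 0.05
        sizes = box_sizes(mask.shape)
        fast = box_counts(mask, sizes)
        for s, n_fast in zip(sizes, fast):
            n_slow = 0
            for r0 in range(0, 128, s):
                for c0 in range(0, 128, s):
                    if mask[r0 : r0 + s, c0 : c0 + s].any():
                        n_slow += 1
            assert n_fast == n_slow

    @given(
        mask=hnp.arrays(bool, (32, 32)),
    )
    def test_counts_match_brute_force_property(self, mask):
        if not mask.any():
            return
        for s in (2, 4, 8):
            n_slow = sum(
                mask[r : r + s, c : c + s].any()
                for r in range(0, 32, s)
                for c in range(0, 32, s)
            )
            assert box_counts(mask, [s])[0] == n_slow


def test_fd_nondecreasing_with_trabeculation(sweep_segs, zero_phantom_segs):
    _, _, zero_segs = zero_phantom_segs
    means = [np.mean([box_count_fd(extract_border(s)) for s in zero_segs])]
    for frac, stack, truth, segs in sweep_segs[:3]:  # 0.1, 0.2, 0.3
        means.append(np.mean([box_count_fd(extract_border(s)) for s in segs]))
    assert means == sorted(means)


# ---------------------------------------------------------------------------
# Profile over a stack


class TestFdProfile:
    P4 = (1.08, 1.17, 1.32, 1.27, 1.21, 1.31, 1.11)  # B1 B2 B3 M1 A1 A2 A3
    P4_THIRDS = ThirdsPartition(basal=(0, 1, 2), mid=(3,), apical=(4, 5, 6))

    def test_seven_slice_worked_example(self):
        prof = fd_profile(list(self.P4), self.P4_THIRDS)
        assert prof.global_fd == pytest.approx(1.21, abs=0.005)
        assert prof.max_fd_basal == 1.32
        assert prof.max_fd_mid == 1.27
        assert prof.max_fd_apical == 1.31
        assert prof.third_labels == (LVNC, NON_LVNC, LVNC)
        assert prof.global_label == NON_LVNC  # 1.21 < 1.26

    def test_apical_max_from_nine_slices(self):
        fds = (1.10, 1.14, 1.20, 1.20, 1.13, 1.19, 1.31, 1.27, 1.44)
        thirds = ThirdsPartition(basal=(0, 1, 2), mid=(3, 4, 5), apical=(6, 7, 8))
        prof = fd_profile(list(fds), thirds)
        assert prof.max_fd_apical == 1.44
        assert prof.third_labels[2] == LVNC

    def test_identical_values(self):
        thirds = split_thirds(6, apical_first=False)
        prof = fd_profile([1.2] * 6, thirds)
        assert prof.global_fd == pytest.approx(1.2)
        assert prof.max_fd_basal == prof.max_fd_mid == prof.max_fd_apical == 1.2

    def test_absent_slices_skipped_and_empty_third_non_lvnc(self):
        thirds = ThirdsPartition(basal=(0, 1), mid=(2, 3), apical=(4, 5))
        prof = fd_profile([1.4, None, None, None, 1.2, None], thirds)
        assert prof.global_fd == pytest.approx(1.3)
        assert prof.max_fd_mid is None
        assert prof.third_labels[1] == NON_LVNC

    def test_all_absent_rejected(self):
        thirds = ThirdsPartition(basal=(0,), mid=(1,), apical=(2,))
        with pytest.raises(FractalError):
            fd_profile([None, None, None], thirds)


class TestSplitThirds:
    @given(n=st.integers(1, 60))
    def test_partition_properties(self, n):
        t = split_thirds(n)
        all_idx = list(t.basal) + list(t.mid) + list(t.apical)
        assert sorted(all_idx) == list(range(n))
        counts = sorted([len(t.basal), len(t.mid), len(t.apical)])
        assert counts[-1] - counts[0] <= 1

    def test_remainder_goes_basal_first(self):
        t = split_thirds(7, apical_first=False)
        assert len(t.basal) == 3 and len(t.mid) == 2 and len(t.apical) == 2
        t = split_thirds(8, apical_first=False)
        assert len(t.basal) == 3 and len(t.mid) == 3 and len(t.apical) == 2


class TestClassifyGlobal:
    @pytest.mark.parametrize(
        "fd, label",
        [
            (1.26, LVNC),  # inclusive threshold
            (1.37, LVNC),
            (1.21, NON_LVNC),
            (1.2599, NON_LVNC),
        ],
    )
    def test_threshold(self, fd, label):
        assert classify_fd_global(fd) == label

    def test_out_of_range(self):
        with pytest.raises(FractalError):
            classify_fd_global(2.5)
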