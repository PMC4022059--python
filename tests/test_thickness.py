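"""Boundary-distance map, medial axis and wall-thickness sampling."""

import numpy as np
import pytest

import _helpers
from wallmorph.core import BinaryMask, DegenerateImageError
from wallmorph.synthetic import LatticeTruth, make_cell_lattice
from wallmorph.thickness import (
    distance_map,
    medial_axis,
    sample_thickness,
    summarize_thickness,
)


def strip_mask(width, length=80, pad=10, l=1.0):
    m = np.zeros((width + 2 * pad, length), bool)
    m[pad : pad + width, :] = True
    return BinaryMask(m, l)


class TestDistanceMap:
    def test_one_px_line_has_unit_distance(self):
        dm = distance_map(strip_mask(1))
        vals = dm.values[dm.values > 0]
        np.testing.assert_allclose(vals, 1.0)

    def test_four_px_strip_interior_rows(self):
        dm = distance_map(strip_mask(4))
        assert dm.values[11, 40] == pytest.approx(2.0)
        assert dm.values[12, 40] == pytest.approx(2.0)
        assert dm.values[10, 40] == pytest.approx(1.0)

    def test_matches_brute_force_oracle_on_random_masks(self, rng):
        for _ in range(40):
            m = rng.random((20, 20)) < 0.5
            if not m.any() or m.all():
                continue
            dm = distance_map(BinaryMask(m, 1.0))
            np.testing.assert_allclose(dm.values, _helpers.brute_force_distance(m))

    def test_degenerate_masks_rejected(self):
        with pytest.raises(DegenerateImageError):
            distance_map(BinaryMask(np.ones((5, 5), bool), 1.0))
        with pytest.raises(DegenerateImageError):
            distance_map(BinaryMask(np.zeros((5, 5), bool), 1.0))

    def test_lipschitz_between_neighbors(self, rng):
        m = rng.random((40, 40)) < 0.6
        m[0, 0] = False
        dm = distance_map(BinaryMask(m, 1.0))
        v = dm.values
        assert np.all(np.abs(np.diff(v, axis=0)) <= 1.0 + 1e-9)
        assert np.all(np.abs(np.diff(v, axis=1)) <= 1.0 + 1e-9)

    def test_scale_equivariance(self, rng):
        m = rng.random((30, 30)) < 0.5
        m[0, :] = False
        m[5, 5] = True
        d1 = distance_map(BinaryMask(m, 1.0)).values
        d3 = distance_map(BinaryMask(m, 3.0)).values
        np.testing.assert_allclose(d3, 3.0 * d1)


class TestMedialAxis:
    def test_odd_strip_skeleton_is_center_row(self):
        skel = medial_axis(strip_mask(5))
        rows = np.unique(np.argwhere(skel.pixels)[:, 0])
        assert rows.tolist() == [12]  # pad 10 + center of width 5

    def test_disk_skeleton_collapses_to_center(self):
        from skimage.draw import disk as sk_disk

        m = np.zeros((40, 40), bool)
        rr, cc = sk_disk((20, 20), 10)
        m[rr, cc] = True
        skel = medial_axis(BinaryMask(m, 1.0), prune_spurs_px=6)
        pts = np.argwhere(skel.pixels)
        assert len(pts) >= 1
        assert np.abs(pts - 20).max() <= 2

    def test_skeleton_is_subset_and_topology_preserving(self):
        truth = LatticeTruth(wall_thickness_px=5, cell_diameter_px=30, n_cells=9)
        _, mask = make_cell_lattice(truth, seed=3)
        skel = medial_axis(mask)
        assert not (skel.pixels & ~mask.pixels).any()
        assert skel.pixels.sum() <= mask.pixels.sum()
        from scipy import ndimage as ndi

        s8 = np.ones((3, 3))
        assert ndi.label(skel.pixels, s8)[1] == ndi.label(mask.pixels, s8)[1]

    def test_pruning_never_erases_a_component(self):
        m = np.zeros((20, 20), bool)
        m[5, 5] = True  # single-pixel component
        m[10:12, 2:18] = True
        skel = medial_axis(BinaryMask(m, 1.0), prune_spurs_px=5)
        from scipy import ndimage as ndi

        assert ndi.label(skel.pixels, np.ones((3, 3)))[1] == 2


class TestSampleThickness:
    def test_strip_raw_and_doubled_conventions(self):
        mask = strip_mask(4)
        dm = distance_map(mask)
        skel = medial_axis(mask)
        raw = sample_thickness(dm, skel, "raw")
        np.testing.assert_allclose(raw.values, 2.0)
        doubled = sample_thickness(dm, skel, "disjoined-doubled")
        np.testing.assert_allclose(doubled.values, 4.0)

    def test_disk_max_sample_near_radius(self):
        from skimage.draw import disk as sk_disk

        m = np.zeros((50, 50), bool)
        rr, cc = sk_disk((25, 25), 12)
        m[rr, cc] = True
        mask = BinaryMask(m, 0.5)
        samples = sample_thickness(distance_map(mask), medial_axis(mask, prune_spurs_px=8))
        assert samples.values.max() == pytest.approx(12 * 0.5, abs=1.0)

    def test_empty_skeleton_rejected(self):
        mask = strip_mask(4)
        dm = distance_map(mask)
        empty = BinaryMask(np.zeros(mask.shape, bool), 1.0)
        with pytest.raises(ValueError):
            sample_thickness(dm, empty)

    @pytest.mark.parametrize("w", range(3, 16))
    def test_strip_identity_half_width(self, w):
        mask = strip_mask(w)
        samples = sample_thickness(distance_map(mask), medial_axis(mask))
        assert abs(samples.values.mean() - w / 2) <= 0.5

    def test_scale_equivariance_of_cwt(self):
        m1 = strip_mask(6, l=1.0)
        m2 = strip_mask(6, l=2.5)
        s1 = sample_thickness(distance_map(m1), medial_axis(m1))
        s2 = sample_thickness(distance_map(m2), medial_axis(m2))
        np.testing.assert_allclose(s2.values, 2.5 * s1.values)


class TestSummarize:
    def test_constant_and_two_point_samples(self):
        mask = strip_mask(4, l=1.0)
        s = sample_thickness(distance_map(mask), medial_axis(mask))
        df = summarize_thickness(s)
        assert df.iloc[0]["mean"] == pytest.approx(2.0)
        assert df.iloc[0]["sd"] == pytest.approx(0.0)
        assert df.iloc[0]["n"] == s.n

    def test_lattice_recovery_adjoined_walls(self):
        # shared wall of 6 px at l=0.5 um: each cell's own wall is 3 px = 1.5 um
        truth = LatticeTruth(wall_thickness_px=6, cell_diameter_px=40, n_cells=9)
        img, mask = make_cell_lattice(truth, pixel_length=0.5, seed=1)
        samples = sample_thickness(distance_map(mask), medial_axis(mask))
        df = summarize_thickness(samples)
        assert abs(df.iloc[0]["mean"] - 1.5) <= 0.5 * 0.5

    def test_per_group_summary(self):
        mask = strip_mask(4)
        s = sample_thickness(distance_map(mask), medial_axis(mask))
        groups = np.zeros(mask.shape, int)
        groups[:, :40] = 1
        groups[:, 40:] = 2
        df = summarize_thickness(s, groups=groups)
        assert set(df["group"]) == {"all", "1", "2"}
        assert df[df["group"] == "all"]["n"].iloc[0] == s.n
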