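"""Geometric polarity measurements: oracles, equivariances, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ependypol as ep
from ependypol.synthetic_scene import sample_von_mises

from .conftest import random_convex_polygon
from .oracles import feret_all_pairs, rasterized_centroid


def rotate_xy(points, theta_deg, center=(0.0, 0.0)):
    """Rigid rotation in the y-up sense applied to image coordinates."""
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    p = np.asarray(points, dtype=float) - center
    # y-up rotation expressed in y-down image coordinates
    return np.column_stack([p[:, 0] * c + p[:, 1] * s,
                            -p[:, 0] * s + p[:, 1] * c]) + center


class TestPolygonCentroid:
    def test_square(self):
        assert ep.polygon_centroid([(0, 0), (2, 0), (2, 2), (0, 2)]) == \
            pytest.approx((1.0, 1.0))

    def test_triangle_vertex_mean(self):
        assert ep.polygon_centroid([(0, 0), (3, 0), (0, 3)]) == \
            pytest.approx((1.0, 1.0))

    def test_orientation_independent(self):
        poly = [(0, 0), (4, 1), (5, 4), (1, 3)]
        assert ep.polygon_centroid(poly) == \
            pytest.approx(ep.polygon_centroid(poly[::-1]))

    def test_degenerate_polygon_raises(self):
        with pytest.raises(ep.GeometryError):
            ep.polygon_centroid([(0, 0), (1, 1), (2, 2)])

    def test_matches_dense_rasterization(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            poly = random_convex_polygon(rng)
            cx, cy = ep.polygon_centroid(poly)
            ox, oy = rasterized_centroid(poly, h=0.02)
            assert np.hypot(cx - ox, cy - oy) < 0.01


class TestTranslationalDistance:
    def test_identity(self):
        assert ep.translational_distance((3, 4), (3, 4)) == 0.0

    def test_three_four_five(self):
        assert ep.translational_distance((0, 0), (3, 4)) == pytest.approx(5.0)

    def test_near_degenerate(self):
        assert ep.translational_distance((1, 1), (1, 1 + 1e-9)) == \
            pytest.approx(1e-9, rel=1e-6)

    def test_symmetric(self):
        assert ep.translational_distance((1, 2), (5, -3)) == \
            ep.translational_distance((5, -3), (1, 2))


class TestBBPatchAngle:
    def test_plus_x_axis(self):
        assert ep.bb_patch_angle((0, 0), (1, 0)) == 0.0

    def test_image_down_is_270(self):
        # +y in image coordinates points down, i.e. 270 deg in y-up frame
        assert ep.bb_patch_angle((0, 0), (0, 1)) == 270.0

    def test_coincident_points_flagged_nan(self):
        assert np.isnan(ep.bb_patch_angle((2, 2), (2, 2)))

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            c = rng.uniform(-10, 10, 2)
            bc = c + rng.uniform(-5, 5, 2)
            if np.allclose(c, bc):
                continue
            ta = ep.bb_patch_angle(tuple(c), tuple(bc))
            bc_rot = rotate_xy([bc], 30.0, center=c)[0]
            ta_rot = ep.bb_patch_angle(tuple(c), tuple(bc_rot))
            assert ta_rot == pytest.approx((ta + 30.0) % 360.0, abs=1e-6)


class TestFeret:
    def test_horizontal_segment_dominates(self):
        ld, fa = ep.ferets_angle([(0, 0), (4, 0), (2, 0.5)])
        assert ld == pytest.approx(4.0) and fa == pytest.approx(0.0)

    def test_vertical_pair(self):
        ld, fa = ep.ferets_angle([(0, 0), (0, 3)])
        assert ld == pytest.approx(3.0) and fa == pytest.approx(90.0)

    def test_tie_broken_by_smallest_angle(self):
        # unit square: two diagonals tie at sqrt(2); axial 45 and 135
        ld, fa = ep.ferets_angle([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert ld == pytest.approx(np.sqrt(2.0))
        assert fa == pytest.approx(45.0)

    def test_fewer_than_two_distinct_points_raises(self):
        with pytest.raises(ep.GeometryError):
            ep.ferets_angle([(1, 1), (1, 1)])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_all_pairs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 50, size=(40, 2))
        ld, fa = ep.ferets_angle(pts)
        old, ofa = feret_all_pairs(pts)
        assert ld == pytest.approx(old, rel=1e-12)
        assert fa == pytest.approx(ofa, abs=1e-9)


class TestInvariances:
    """Translation, rotation and scale behavior of TD, TA, FA, LD."""

    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_translation_invariance(self, dx, dy):
        rng = np.random.default_rng(17)
        pts = rng.uniform(0, 20, size=(12, 2))
        c, bc = (1.0, 2.0), (4.0, -1.0)
        shift = np.array([dx, dy])
        assert ep.translational_distance(c, bc) == pytest.approx(
            ep.translational_distance(tuple(c + shift), tuple(bc + shift)),
            abs=1e-9)
        ld0, fa0 = ep.ferets_angle(pts)
        ld1, fa1 = ep.ferets_angle(pts + shift)
        assert ld0 == pytest.approx(ld1, abs=1e-9)
        assert fa0 == pytest.approx(fa1, abs=1e-6)

    @given(st.floats(1, 179))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_rotation_equivariance(self, theta):
        rng = np.random.default_rng(19)
        pts = rng.uniform(0, 20, size=(12, 2))
        ld0, fa0 = ep.ferets_angle(pts)
        ld1, fa1 = ep.ferets_angle(rotate_xy(pts, theta))
        assert ld1 == pytest.approx(ld0, rel=1e-9)
        assert fa1 == pytest.approx((fa0 + theta) % 180.0, abs=1e-6)

    @given(st.floats(0.1, 10))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_scale_equivariance(self, s):
        rng = np.random.default_rng(23)
        pts = rng.uniform(0, 20, size=(10, 2))
        c, bc = (2.0, 3.0), (7.0, 1.0)
        assert ep.translational_distance(
            tuple(np.array(c) * s), tuple(np.array(bc) * s)) == \
            pytest.approx(s * ep.translational_distance(c, bc), rel=1e-9)
        ld0, _ = ep.ferets_angle(pts)
        ld1, _ = ep.ferets_angle(pts * s)
        assert ld1 == pytest.approx(s * ld0, rel=1e-9)


class TestRotationalVectors:
    def test_single_pair(self):
        vecs, unmatched = ep.rotational_vectors([(0, 0)], [(1, 0)],
                                                max_gate=5.0)
        assert len(vecs) == 1 and not unmatched
        assert vecs[0].angle == pytest.approx(0.0)
        assert vecs[0].length == pytest.approx(1.0)

    def test_gate_excludes_distant_pair(self):
        vecs, unmatched = ep.rotational_vectors([(0, 0)], [(10, 0)],
                                                max_gate=5.0)
        assert not vecs and unmatched == [0]

    def test_one_to_one_assignment(self):
        # two feet near one bb: only one may claim it
        vecs, unmatched = ep.rotational_vectors(
            [(0, 0), (0.1, 0)], [(1, 0)], max_gate=5.0)
        assert len(vecs) == 1 and len(unmatched) == 1

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            ep.rotational_vectors([], [(0, 0)])

    def test_recovers_generator_truth(self):
        """Feet placed 2 px from their parents at vonMises(90, kappa=1e8)
        all match their true parent; circular mean within 0.5 deg."""
        rng = np.random.default_rng(31)
        bbs = rng.uniform(0, 100, size=(30, 2))
        # enforce generous bb spacing so parentage is unambiguous
        bbs = bbs[np.argsort(bbs[:, 0])]
        bbs[:, 0] = np.linspace(0, 290, 30)
        angles = sample_von_mises(90, 1e8, 30, rng)
        t = np.deg2rad(angles)
        feet = bbs - 2.0 * np.column_stack([np.cos(t), -np.sin(t)])
        vecs, unmatched = ep.rotational_vectors(feet, bbs, max_gate=4.0)
        assert len(vecs) == 30 and not unmatched
        for v, bb in zip(sorted(vecs, key=lambda v: v.foot_point[0]),
                         bbs[np.argsort(feet[:, 0])]):
            assert v.bb_point == pytest.approx(tuple(bb))
        mean, _ = ep.circular_mean_R(
            ep.AngleSample("r", np.array([v.angle for v in vecs])))
        assert abs((mean - 90.0 + 180) % 360 - 180) < 0.5


class TestSummaries:
    @staticmethod
    def _frame(td_values, group):
        return pd.DataFrame({
            "cell_id": np.arange(len(td_values)),
            "TD": td_values,
            "TD_norm": np.asarray(td_values) / 10.0,
            "TA": np.linspace(10, 80, len(td_values)),
            "FA": np.linspace(5, 40, len(td_values)),
            "LD": 5.0, "n_bb": 10, "touches_border": False,
            "group": group})

    def test_identical_groups_give_t_zero_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        df = pd.concat([self._frame(vals, "a"), self._frame(vals, "b")])
        s = ep.summarize_cells(df)
        assert s["t_test"]["t"] == pytest.approx(0.0, abs=1e-12)
        assert s["t_test"]["p"] == pytest.approx(1.0)

    def test_sem_closed_form(self):
        vals = [2.0, 4.0, 6.0, 8.0]
        s = ep.summarize_cells(self._frame(vals, "g"))
        expected_sem = np.std(vals, ddof=1) / np.sqrt(4)
        assert s["groups"]["g"]["TD_sem"] == pytest.approx(expected_sem)
        assert s["groups"]["g"]["TD_mean"] == pytest.approx(5.0)

    def test_tiny_group_flagged(self):
        s = ep.summarize_cells(self._frame([1.0], "solo"))
        assert not s["groups"]["solo"]["statistics_available"]

    def test_offset_contrast_detected(self):
        """Groups generated with offset 0.35 vs 0.10 of the cell radius
        separate at p < 0.001, in the direction of reduced polarity."""
        rng = np.random.default_rng(47)
        r_eq = 20.0
        big = rng.normal(0.35 * r_eq, 1.0, 200)
        small = rng.normal(0.10 * r_eq, 1.0, 200)
        df = pd.concat([self._frame(big, "wt"), self._frame(small, "mut")])
        s = ep.summarize_cells(df)
        assert s["t_test"]["p"] < 1e-3
        assert s["groups"]["mut"]["TD_mean"] < s["groups"]["wt"]["TD_mean"]


class TestMeasureCells:
    def test_label_image_round_trip(self, wt_mosaic):
        cfg, labels, bb, feet, truth = wt_mosaic
        cells = ep.cells_from_label_image(labels)
        assert len(cells) == cfg.n_cells
        m = ep.measure_cells(cells, bb)
        assert set(m.columns) >= {"cell_id", "TD", "TD_norm", "TA", "FA",
                                  "LD", "n_bb"}
        assert (m.n_bb == cfg.bb_per_patch).all()

    def test_parameter_recovery(self, wt_mosaic):
        """Measured TA circular mean within 5 deg of the generative
        direction; mean TD_norm within 0.05 of the generative offset."""
        cfg, labels, bb, feet, truth = wt_mosaic
        m = ep.measure_cells(ep.cells_from_label_image(labels), bb)
        m = m[~m.touches_border]
        mean, _ = ep.circular_mean_R(
            ep.AngleSample("ta", m.TA.dropna().to_numpy()))
        assert abs((mean - cfg.mu_global + 180) % 360 - 180) < 5.0
        assert abs(m.TD_norm.mean() - cfg.offset_frac) < 0.05
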