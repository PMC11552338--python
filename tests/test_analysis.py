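"""Trajectory statistics: angles, proximity null, selection, scoring."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thrombotaxis import analysis, io as tio, walker
from thrombotaxis.errors import DataError
from thrombotaxis.params import WalkerParams

from conftest import make_disc_mask


def traj(pts, cell_id="a", dt=1.0):
    pts = np.asarray(pts, dtype=float)
    return tio.Trajectory(cell_id, np.arange(len(pts)) * dt, pts[:, 0], pts[:, 1])


class TestStepAngles:
    def test_straight_with_flow(self):
        th = analysis.step_angles(traj([(0, 0), (1, 0), (2, 0)]))
        np.testing.assert_allclose(th, 0.0)

    def test_straight_counter_flow(self):
        th = analysis.step_angles(traj([(2, 0), (1, 0), (0, 0)]))
        np.testing.assert_allclose(th, math.pi)

    def test_l_shaped(self):
        th = analysis.step_angles(traj([(0, 0), (1, 0), (1, 1)]))
        np.testing.assert_allclose(th, [0.0, math.pi / 2])

    def test_zero_steps_skipped(self):
        th = analysis.step_angles(traj([(0, 0), (0, 0), (1, 0)]))
        np.testing.assert_allclose(th, [0.0])

    def test_all_static_warns_empty(self):
        with pytest.warns(UserWarning):
            th = analysis.step_angles(traj([(1, 1), (1, 1), (1, 1)]))
        assert th.size == 0

    def test_flow_direction_offset(self):
        th = analysis.step_angles(traj([(0, 0), (0, 1)]),
                                  flow_direction=math.pi / 2)
        np.testing.assert_allclose(th, 0.0, atol=1e-12)

    def test_isotropic_walk_resultant_vanishes(self):
        """Mean resultant length of uniform step angles decays as 1/sqrt(n)."""
        rng = np.random.default_rng(0)
        n = 10_000
        phi = rng.uniform(-np.pi, np.pi, n)
        pts = np.cumsum(np.column_stack([np.cos(phi), np.sin(phi)]), axis=0)
        dist = analysis.angle_distribution(
            analysis.step_angles(traj(np.vstack([[0, 0], pts]))))
        assert dist.resultant_length <= 3.0 / math.sqrt(n)
        assert dist.counts.sum() == n


class TestResample:
    def test_short_track_dropped(self):
        out = analysis.resample_min_duration([traj([(0, 0)] * 101)],  # 100 s
                                             min_T=250.0)
        assert out == []

    def test_ragged_track_on_uniform_grid(self):
        t = np.sort(np.random.default_rng(1).uniform(0, 300, 80))
        t[0], t[-1] = 0.0, 300.0
        tr = tio.Trajectory("a", t, np.linspace(0, 10, 80), np.zeros(80))
        (out,) = analysis.resample_min_duration([tr], min_T=250.0,
                                                dt_resample=5.0)
        np.testing.assert_allclose(np.diff(out.t), 5.0)
        assert out.t[0] == 0.0 and out.t[-1] == 300.0

    def test_empty_input(self):
        assert analysis.resample_min_duration([]) == []


class TestDistanceToThrombus:
    def test_known_distance_from_disc_edge(self):
        mask = make_disc_mask(n=100, centre=(50.0, 50.0), radius=10.0)
        tr = traj([(70, 50), (70, 50.5)])
        d = analysis.distance_to_thrombus(tr, mask)
        assert d[0] == pytest.approx(10.0, abs=mask.grid.dx)

    def test_point_inside_is_zero(self):
        mask = make_disc_mask(n=100, centre=(50.0, 50.0), radius=10.0)
        d = analysis.distance_to_thrombus(traj([(50, 50), (51, 50)]), mask)
        assert d[0] == 0.0

    def test_two_thrombi_takes_minimum(self):
        n = 100
        vals = np.zeros((n, n))
        vals[50, 20] = 1.0
        vals[50, 80] = 1.0
        mask = tio.ThrombusMask(tio.FieldGrid(vals, 1.0))
        d = analysis.distance_to_thrombus(traj([(45, 50), (45, 50.5)]), mask)
        assert d[0] == pytest.approx(25.0, abs=1.5)

    def test_empty_mask_rejected(self):
        mask = tio.ThrombusMask(tio.FieldGrid(np.zeros((16, 16)), 1.0))
        with pytest.raises(DataError):
            analysis.distance_to_thrombus(traj([(5, 5), (6, 6)]), mask)


class TestRandomTrajectory:
    def test_step_lengths_preserved_exactly(self):
        ref = traj([(0, 0), (1, 0), (3, 0), (6, 0)])
        rng = np.random.default_rng(0)
        null = analysis.random_trajectory(ref, (0, 100, 0, 100), rng)
        np.testing.assert_allclose(null.step_lengths(), [1.0, 2.0, 3.0])
        assert null.path_length() == pytest.approx(ref.path_length())

    def test_stays_in_bounds(self):
        rng = np.random.default_rng(1)
        ref = traj(np.cumsum(np.ones((60, 2)), axis=0))
        null = analysis.random_trajectory(ref, (0, 30, 0, 30), rng)
        assert null.x.min() >= 0 and null.x.max() <= 30
        assert null.y.min() >= 0 and null.y.max() <= 30

    def test_single_point_reference_rejected(self):
        with pytest.raises(DataError):
            analysis.random_trajectory(
                tio.Trajectory("a", [0.0], [1.0], [1.0]),
                (0, 10, 0, 10), np.random.default_rng(0))

    def test_null_ensemble_matches_field_average_distance(self):
        """Monte-Carlo mean null distance equals the areal mean of the
        distance map (the null explores the field uniformly)."""
        mask = make_disc_mask(n=120, centre=(20.0, 20.0), radius=8.0)
        dmap = analysis._distance_map(mask)
        rng = np.random.default_rng(2)
        ref = traj([(0, 0), (0.5, 0)])  # two points, tiny step
        means = []
        for _ in range(10_000):
            null = analysis.random_trajectory(ref, mask.grid.bounds, rng)
            means.append(analysis.distance_to_thrombus(null, mask,
                                                       _dmap=dmap).mean())
        assert np.mean(means) == pytest.approx(dmap.values.mean(), rel=0.02)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.lists(st.floats(0.1, 5.0), min_size=1, max_size=12),
       st.integers(0, 10_000))
def test_random_trajectory_length_preservation_property(lengths, seed):
    """Step lengths survive the null construction for arbitrary profiles."""
    pts = np.zeros((len(lengths) + 1, 2))
    pts[1:, 0] = np.cumsum(lengths)
    ref = traj(pts)
    null = analysis.random_trajectory(ref, (0, 50, 0, 50),
                                      np.random.default_rng(seed))
    np.testing.assert_allclose(null.step_lengths(), lengths, rtol=1e-9)


class TestProximityTest:
    def test_null_vs_null_is_unbiased(self):
        """Tracks built exactly like their nulls give a non-significant,
        near-zero mean difference."""
        mask = make_disc_mask(n=150, centre=(40.0, 75.0), radius=10.0)
        rng = np.random.default_rng(3)
        ref = traj(np.cumsum(np.full((50, 2), 0.3), axis=0))
        trajs = [analysis.random_trajectory(ref, mask.grid.bounds, rng)
                 for _ in range(15)]
        res = analysis.proximity_test(trajs, mask, rng=rng)
        assert res.pvalue > 0.01
        diff = res.cell_mean_exp.mean() - res.cell_mean_rand.mean()
        assert abs(diff) < 0.25 * res.cell_mean_rand.mean()

    def test_chemotactic_walkers_closer_than_null(self, disc_field, disc_mask):
        """Walkers attracted to the source end up significantly closer to
        the thrombus than matched random trajectories."""
        wp = WalkerParams(k=20_000.0, v_avg=0.25)
        rng = np.random.default_rng(4)
        trajs = []
        for i in range(16):
            sim = walker.simulate((rng.uniform(90, 125), rng.uniform(92, 108)),
                                  250, disc_field, wp, rng_seed=100 + i,
                                  mask=disc_mask)
            trajs.append(sim.traj)
        res = analysis.proximity_test(trajs, disc_mask, rng=rng)
        assert res.cell_mean_exp.mean() < res.cell_mean_rand.mean()
        assert res.pvalue < 0.01

    def test_single_point_trajectories_well_defined(self):
        mask = make_disc_mask(n=100, centre=(50.0, 50.0), radius=10.0)
        trajs = [tio.Trajectory(f"p{i}", [0.0], [30.0 + i], [50.0])
                 for i in range(3)]
        res = analysis.proximity_test(trajs, mask,
                                      rng=np.random.default_rng(5))
        assert 0.0 <= res.pvalue <= 1.0
        assert res.r_exp.size == 3 and res.r_rand.size == 3

    def test_pooled_reduction_available(self):
        mask = make_disc_mask(n=100, centre=(50.0, 50.0), radius=10.0)
        ref = traj(np.cumsum(np.full((20, 2), 0.5), axis=0) + 30.0)
        res = analysis.proximity_test([ref], mask,
                                      rng=np.random.default_rng(6),
                                      reduction="points")
        assert res.r_exp.size == 20


class TestMeanSpeed:
    def test_path_over_duration(self):
        tr = tio.Trajectory("a", [0, 500], [0, 100], [0, 0])
        assert analysis.mean_speed(tr) == pytest.approx(0.2)

    def test_stationary_is_zero(self):
        tr = tio.Trajectory("a", [0, 10], [5, 5], [5, 5])
        assert analysis.mean_speed(tr) == 0.0

    def test_two_segment_path(self):
        tr = tio.Trajectory("a", [0, 5, 10], [0, 3, 3], [0, 0, 4])
        assert analysis.mean_speed(tr) == pytest.approx(0.7)


class TestSelectModelCells:
    BOUNDS = (0.0, 200.0, 0.0, 200.0)

    def test_lone_slow_crawler_kept(self):
        tr = traj(np.cumsum(np.full((30, 2), 0.1), axis=0) + 100.0)
        assert analysis.select_model_cells([tr], self.BOUNDS) == [tr]

    def test_edge_hugger_dropped(self):
        tr = traj([(5.0, 100.0), (5.5, 100.0), (6.0, 100.0)])
        assert analysis.select_model_cells([tr], self.BOUNDS) == []

    def test_fast_along_flow_glider_dropped(self):
        pts = np.column_stack([np.arange(30) * 2.0 + 50.0, np.full(30, 100.0)])
        tr = traj(pts)  # 2 um/s straight along +x: rolling
        assert analysis.select_model_cells([tr], self.BOUNDS) == []

    def test_upstream_neighbor_excludes(self):
        focal = traj(np.cumsum(np.full((20, 2), 0.1), axis=0) + 100.0)
        # neighbour sits 5 um upstream (-x) of the focal cell's start
        neigh = traj(np.cumsum(np.full((20, 2), 0.1), axis=0)
                     + [95.0, 100.0], cell_id="b")
        kept = analysis.select_model_cells([focal, neigh], self.BOUNDS)
        assert focal not in kept

    def test_downstream_neighbor_allowed(self):
        focal = traj(np.full((20, 2), 100.0) +
                     np.cumsum(np.full((20, 2), 0.1), axis=0))
        neigh = traj(np.full((20, 2), [108.0, 100.0]) +
                     np.cumsum(np.full((20, 2), 0.1), axis=0), cell_id="b")
        kept = analysis.select_model_cells([focal, neigh], self.BOUNDS)
        assert focal in kept


class TestScoreRun:
    def test_identical_is_zero(self):
        tr = traj(np.cumsum(np.ones((40, 2)), axis=0))
        assert analysis.score_run(tr, tr) == 0.0

    def test_static_offset_is_pythagoras(self):
        a = tio.Trajectory("a", [0, 10, 20], [0, 0, 0], [0, 0, 0])
        b = tio.Trajectory("b", [0, 10, 20], [3, 3, 3], [4, 4, 4])
        assert analysis.score_run(a, b) == pytest.approx(5.0)

    def test_uniform_shift(self):
        t = np.arange(0.0, 50.0, 1.0)
        a = tio.Trajectory("a", t, t * 0.2, np.zeros_like(t))
        b = tio.Trajectory("b", t, t * 0.2 + 10.0, np.zeros_like(t))
        assert analysis.score_run(a, b) == pytest.approx(10.0)

    def test_no_overlap_rejected(self):
        a = tio.Trajectory("a", [0, 10], [0, 1], [0, 1])
        b = tio.Trajectory("b", [20, 30], [0, 1], [0, 1])
        with pytest.raises(DataError):
            analysis.score_run(a, b)

    def test_pseudometric_properties(self):
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 100.0, 5.0)
        trs = [tio.Trajectory(f"t{i}", t,
                              np.cumsum(rng.normal(0, 1, t.size)),
                              np.cumsum(rng.normal(0, 1, t.size)))
               for i in range(3)]
        ab = analysis.score_run(trs[0], trs[1])
        ba = analysis.score_run(trs[1], trs[0])
        assert ab == pytest.approx(ba)
        bc = analysis.score_run(trs[1], trs[2])
        ac = analysis.score_run(trs[0], trs[2])
        assert ac <= ab + bc + 1e-9


class TestClassifyAndArea:
    @pytest.mark.parametrize("score,ell,expect", [
        (0.0, 15.0, True),
        (15.0, 15.0, True),   # boundary inclusive
        (150.0, 15.0, False),
    ])
    def test_success_threshold(self, score, ell, expect):
        assert analysis.classify_success(score, ell) is expect

    def test_area_fraction(self):
        vals = np.zeros((10, 10))
        vals[0, 0] = 1.0
        mask = tio.ThrombusMask(tio.FieldGrid(vals, 1.0))
        assert analysis.thrombus_area_fraction(mask) == pytest.approx(1.0)

    def test_half_covered(self):
        vals = np.zeros((10, 10))
        vals[:5] = 1.0
        mask = tio.ThrombusMask(tio.FieldGrid(vals, 1.0))
        assert analysis.thrombus_area_fraction(mask) == pytest.approx(50.0)

    def test_negative_score_rejected(self):
        with pytest.raises(DataError):
            analysis.EnsembleResult("c", [], np.array([-1.0]),
                                    np.array([False]))
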