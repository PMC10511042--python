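"""Displacement-direction correlation r and its aggregation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spheromet import correlation as C
from spheromet.types import Calibration, TrajectorySet

vec3 = st.tuples(*[st.floats(-10, 10) for _ in range(3)]).map(np.array)


def tracks_from(positions):
    return TrajectorySet.from_positions(np.asarray(positions, dtype=float))


class TestDisplacementVectors:
    def test_stationary_cell_has_zero_vector(self):
        tr = tracks_from([[[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]]])
        v = C.displacement_vectors(tr, 1)
        assert np.allclose(v.to_numpy(), 0.0)

    def test_programmed_drift_recovered(self):
        tr = tracks_from([[[0.0, 0.0, 0.0]], [[1.0, 0.0, 0.0]], [[2.0, 0.0, 0.0]]])
        v = C.displacement_vectors(tr, 2)
        assert np.allclose(v.to_numpy(), [[1.0, 0.0, 0.0]])

    def test_anisotropy_correction_applied(self):
        tr = TrajectorySet(
            pd.DataFrame({"track_id": [0, 0], "frame": [0, 1],
                          "z": [0.0, 1.0], "y": [0.0, 0.0], "x": [0.0, 0.0]}),
            calibration=Calibration(px_um=0.5, z_um=1.5))
        v = C.displacement_vectors(tr, 1)
        assert v["vz"].iloc[0] == pytest.approx(3.0)

    def test_absent_cell_excluded_and_counted(self):
        table = pd.DataFrame({"track_id": [0, 0, 1], "frame": [0, 1, 1],
                              "z": 0.0, "y": 0.0, "x": [0.0, 1.0, 5.0]})
        v = C.displacement_vectors(TrajectorySet(table), 1)
        assert list(v.index) == [0]
        assert v.attrs["n_excluded"] == 1


class TestNeighborPairs:
    def test_two_close_cells_pair(self):
        pos = pd.DataFrame({"z": [0.0, 0.0], "y": [0.0, 0.0], "x": [0.0, 3.0]})
        assert C.neighbor_pairs(pos, C.NeighborRule("radius", radius=5.0)) == {(0, 1)}

    def test_all_far_cells_give_empty_graph(self):
        pos = pd.DataFrame({"z": [0.0] * 3, "y": [0.0] * 3, "x": [0.0, 50.0, 100.0]})
        assert C.neighbor_pairs(pos, C.NeighborRule("radius", radius=5.0)) == set()

    def test_single_cell_gives_empty_set(self):
        pos = pd.DataFrame({"z": [0.0], "y": [0.0], "x": [0.0]})
        assert C.neighbor_pairs(pos) == set()

    def test_grid_matches_brute_force_oracle(self):
        # 5x5 grid, spacing d: adaptive radius = 1.5*d, so diagonals at
        # d*sqrt(2) ~ 1.41*d are included. Oracle: brute-force all pairs.
        d = 10.0
        yy, xx = np.mgrid[0:5, 0:5].astype(float) * d
        pos = pd.DataFrame({"z": 0.0, "y": yy.ravel(), "x": xx.ravel()})
        got = C.neighbor_pairs(pos, C.NeighborRule("adaptive_radius", alpha=1.5))
        pts = pos[["z", "y", "x"]].to_numpy()
        expected = {(i, j) for i in range(25) for j in range(i + 1, 25)
                    if np.linalg.norm(pts[i] - pts[j]) <= 1.5 * d}
        assert got == expected
        assert len(got) > 2 * 20  # axial plus diagonal adjacencies


class TestDirectionCorrelation:
    def test_parallel_is_plus_one(self):
        v = np.array([1.0, 2.0, 3.0])
        assert C.direction_correlation(v, 2 * v) == pytest.approx(1.0)

    def test_antiparallel_is_minus_one(self):
        v = np.array([1.0, 2.0, 3.0])
        assert C.direction_correlation(v, -v) == pytest.approx(-1.0)

    def test_orthogonal_is_zero(self):
        assert C.direction_correlation(np.array([1.0, 0.0, 0.0]),
                                       np.array([0.0, 1.0, 0.0])) == pytest.approx(0.0)

    def test_subthreshold_motion_is_undefined(self):
        assert np.isnan(C.direction_correlation(np.array([0.01, 0.0, 0.0]),
                                                np.array([1.0, 0.0, 0.0])))

    @given(v_a=vec3, v_b=vec3, s=st.floats(0.1, 50.0))
    @settings(deadline=None, max_examples=100)
    def test_symmetry_and_scale_invariance(self, v_a, v_b, s):
        r_ab = C.direction_correlation(v_a, v_b, eps_motion=1.0)
        r_ba = C.direction_correlation(v_b, v_a, eps_motion=1.0)
        if np.isnan(r_ab):
            assert np.isnan(r_ba)
        else:
            assert r_ab == pytest.approx(r_ba, abs=1e-12)
            assert -1.0 - 1e-12 <= r_ab <= 1.0 + 1e-12
            r_scaled = C.direction_correlation(s * v_a, v_b, eps_motion=1e-9)
            assert r_scaled == pytest.approx(r_ab, abs=1e-9)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(3)
        from scipy.spatial.transform import Rotation
        for _ in range(20):
            v_a, v_b = rng.normal(size=(2, 3))
            R = Rotation.random(rng=rng).as_matrix()
            r0 = C.direction_correlation(v_a, v_b, eps_motion=1e-9)
            r1 = C.direction_correlation(R @ v_a, R @ v_b, eps_motion=1e-9)
            assert r1 == pytest.approx(r0, abs=1e-9)

    def test_isotropic_directions_give_uniform_r(self):
        # cos(angle) between isotropic 3D directions is uniform on [-1, 1]
        rng = np.random.default_rng(42)
        v = rng.standard_normal((10000, 2, 3))
        rs = np.array([C.direction_correlation(a, b, eps_motion=1e-9)
                       for a, b in v])
        assert abs(rs.mean()) < 0.03
        hist, _ = np.histogram(rs, bins=10, range=(-1, 1))
        assert np.all(np.abs(hist - 1000) < 5 * np.sqrt(1000 * 0.9))


class TestAggregation:
    def _mixture_table(self, n=2000, w=0.5, seed=0):
        rng = np.random.default_rng(seed)
        coh = rng.random(n) < w
        rs = np.where(coh, 1.0, rng.uniform(-1, 1, n))
        return pd.DataFrame({"frame": 1, "time_h": np.linspace(0, 10, n),
                             "id_a": 0, "id_b": 1, "r": rs,
                             "speed_a": 1.0, "speed_b": 1.0})

    def test_fraction_above_for_perfect_coherence(self):
        tab = self._mixture_table(w=1.0)
        assert C.fraction_above(tab, 0.8) == 1.0

    def test_fraction_above_for_uniform_r(self):
        tab = self._mixture_table(n=10000, w=0.0, seed=1)
        # uniform r: P(r > 0.8) = 0.1; 95% binomial CI at n=10000
        assert C.fraction_above(tab, 0.8) == pytest.approx(0.1, abs=2 * 0.003)

    def test_fraction_above_for_half_mixture(self):
        tab = self._mixture_table(n=10000, w=0.5, seed=2)
        assert C.fraction_above(tab, 0.8) == pytest.approx(0.55, abs=0.02)

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            C.fraction_above(self._mixture_table(), 0.8, window=(100.0, 200.0))

    def test_density_column_normalization_contract(self):
        tab = self._mixture_table(n=3000, w=0.5, seed=3)
        dens, t_edges, r_edges = C.correlation_density_over_time(tab, 20, 10)
        assert dens.shape == (10, 20)
        col_max = dens.max(axis=1)
        assert np.allclose(col_max[col_max > 0], 1.0)

    def test_density_all_coherent_mass_in_top_bin(self):
        tab = self._mixture_table(w=1.0)
        dens, _, _ = C.correlation_density_over_time(tab, 20, 5)
        assert np.allclose(dens[:, :-1], 0.0)
        assert np.allclose(dens[:, -1], 1.0)

    def test_density_bimodal_for_mixture(self):
        tab = self._mixture_table(n=20000, w=0.5, seed=4)
        dens, _, r_edges = C.correlation_density_over_time(tab, 20, 4,
                                                           normalization="global")
        marginal = dens.sum(axis=0)
        top = marginal[-1]          # r in (0.9, 1]
        background = marginal[:-1].mean()
        assert top > 5 * background


class TestPipelineTable:
    def test_mixture_movie_truth_pipeline(self):
        from spheromet.synthetic import MotionModel, simulate_trajectories
        model = MotionModel(mode="mixture", n_cells=30, mixture_weight=0.5,
                            step_scale=1.5, seed=17)
        pos, info = simulate_trajectories(model, (28, 180, 180), frames=10,
                                          margin=(3.0, 8.0, 8.0), min_sep=10.8)
        tracks = TrajectorySet.from_positions(pos)
        tab = C.pair_correlation_table(tracks, interval_h=1.0)
        assert ((tab["r"] >= -1) & (tab["r"] <= 1)).all()
        # coherent pairs dominate the r > 0.99 rows
        frac = C.fraction_above(tab, 0.8)
        w_real = np.mean(info["coherent_pair"])
        expected = w_real + (1 - w_real) * 0.1
        assert frac == pytest.approx(expected, abs=0.12)

    def test_coordinated_fraction_monotone_in_coherence(self):
        from spheromet.synthetic import MotionModel, simulate_trajectories
        fracs = []
        for coh in (0.0, 0.5, 1.0):
            model = MotionModel(mode="coherent_groups", n_cells=30, n_groups=1,
                                coherence=coh, step_scale=1.5, seed=19)
            pos, _ = simulate_trajectories(model, (28, 200, 200), frames=20,
                                           margin=(3.0, 8.0, 8.0), min_sep=10.8)
            tab = C.pair_correlation_table(TrajectorySet.from_positions(pos),
                                           interval_h=1.0)
            fracs.append(C.fraction_above(tab, 0.8))
        assert fracs[0] <= fracs[1] <= fracs[2]
        assert fracs[2] == 1.0  # perfect coherence: every pair parallel
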