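"""Generator contracts: determinism, analytic ground truth, error handling."""
import math

import numpy as np
import pytest

from spheromet import morphometry as M
from spheromet.correlation import direction_correlation
from spheromet.synthetic import (MotionModel, RoundingKinetics,
                                 aspect_to_circularity, doublet_geometry,
                                 generate_fusion_movie, generate_junction_image,
                                 generate_nuclei_movie, generate_rounding_movie,
                                 hexagonal_edges, simulate_trajectories,
                                 stadium_circularity, stadium_elongation)


class TestStadiumFamily:
    def test_disc_has_unit_circularity(self):
        assert stadium_circularity(0.0) == pytest.approx(1.0)

    def test_elongation_inverts_circularity(self):
        for u in (0.0, 0.5, 2.0, 4.0, 10.0):
            assert stadium_elongation(stadium_circularity(u)) == pytest.approx(u, abs=1e-9)

    def test_aspect_three_to_one(self):
        # rounded 3:1 rectangle: l = 4*rho, A = rho^2*(pi+8), P = rho*(2pi+8)
        expected = 4 * math.pi * (math.pi + 8) / (2 * math.pi + 8) ** 2
        assert aspect_to_circularity(3.0) == pytest.approx(expected)


class TestRoundingKinetics:
    def test_curve_is_monotone_and_hits_endpoints(self):
        kin = RoundingKinetics(c_inf=0.95, t_latent=5, t_static=18, c0=0.6)
        t = np.linspace(0, 24, 97)
        c = kin.curve(t)
        assert np.all(np.diff(c) >= -1e-12)
        assert c[0] == pytest.approx(0.6)
        assert c[-1] == pytest.approx(0.95)

    def test_jump_appears_as_step_of_programmed_size(self):
        kin = RoundingKinetics(c_inf=0.95, t_latent=5, t_static=18, c0=0.6,
                               jumps=[(10.0, 0.15)])
        t = np.arange(25.0)
        c = kin.curve(t)
        step = c[10] - c[9]
        assert step >= 0.15
        assert c[-1] == pytest.approx(0.95)

    @pytest.mark.parametrize("bad", [
        dict(c_inf=1.2), dict(t_latent=10, t_static=5),
        dict(c0=0.99, c_inf=0.9), dict(jumps=[(3.0, 0.1)]),
    ])
    def test_invalid_parameters_rejected(self, bad):
        kwargs = dict(c_inf=0.95, t_latent=5, t_static=18)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            RoundingKinetics(**kwargs)


class TestRoundingMovie:
    def test_identity_kinetics_gives_constant_near_circular_movie(self):
        c1 = aspect_to_circularity(1.0)
        kin = RoundingKinetics(c_inf=c1, t_latent=1, t_static=2, c0=None)
        movie, truth = generate_rounding_movie(1.0, kin, frames=5, seed=0)
        ser = M.circularity_timeseries(movie)
        assert np.allclose(truth.true_circularity, 1.0)
        assert np.all(np.abs(ser.values - 1.0) < 0.02)
        assert np.ptp(ser.values) < 1e-6  # identical frames

    def test_programmed_curve_nondecreasing_from_analytic_c0(self, rounding_dataset):
        _, truth = rounding_dataset
        c = truth.true_circularity
        assert c[0] == pytest.approx(aspect_to_circularity(3.0))
        assert np.all(np.diff(c) >= -1e-12)
        assert c[-1] == pytest.approx(0.95)

    def test_same_seed_is_bit_identical(self):
        kin = RoundingKinetics()
        a, _ = generate_rounding_movie(2.0, kin, frames=6, seed=7)
        b, _ = generate_rounding_movie(2.0, kin, frames=6, seed=7)
        assert np.array_equal(a.data, b.data)

    def test_invalid_inputs_rejected(self):
        kin = RoundingKinetics()
        with pytest.raises(ValueError):
            generate_rounding_movie(0.5, kin, frames=5, seed=0)
        with pytest.raises(ValueError):
            generate_rounding_movie(2.0, kin, frames=1, seed=0)


class TestNucleiMovie:
    def test_single_cell_centroid_matches_truth_without_noise(self):
        model = MotionModel(mode="independent_walk", n_cells=1, step_scale=1.0, seed=5)
        movie, truth = generate_nuclei_movie(model, (16, 48, 48), frames=4, snr=np.inf)
        for f in range(4):
            vol = movie[f]
            w = vol / vol.sum()
            com = np.array([(w.sum(axis=(1, 2)) * np.arange(16)).sum(),
                            (w.sum(axis=(0, 2)) * np.arange(48)).sum(),
                            (w.sum(axis=(0, 1)) * np.arange(48)).sum()])
            assert np.linalg.norm(com - truth.true_positions[f, 0]) < 0.5

    def test_perfect_coherence_gives_identical_displacements(self):
        model = MotionModel(mode="coherent_groups", n_cells=6, coherence=1.0,
                            n_groups=1, step_scale=1.5, seed=6)
        pos, _ = simulate_trajectories(model, (24, 80, 80), frames=8,
                                       margin=8.0, min_sep=10.0)
        steps = np.diff(pos, axis=0)
        for f in range(steps.shape[0]):
            assert np.allclose(steps[f], steps[f, 0], atol=1e-9)

    def test_mixture_truth_is_bimodal_and_recovers_weight(self):
        model = MotionModel(mode="mixture", n_cells=40, mixture_weight=0.5,
                            step_scale=1.5, seed=8)
        movie, truth = generate_nuclei_movie(model, (28, 200, 200), frames=12,
                                             snr=np.inf)
        pair_of = np.asarray(truth.params["pair_of"])
        coherent = np.asarray(truth.params["coherent_pair"])
        # oracle: r computed directly from true positions, per programmed pair
        steps = np.diff(truth.true_positions, axis=0)
        rs = []
        for p in range(20):
            a, b = np.flatnonzero(pair_of == p)
            for f in range(steps.shape[0]):
                rs.append((p, direction_correlation(steps[f, a], steps[f, b],
                                                    eps_motion=1e-9)))
        rs = np.array([(p, r) for p, r in rs])
        for p in range(20):
            mean_r = rs[rs[:, 0] == p, 1].mean()
            assert (mean_r > 0.999) == bool(coherent[p])
        # coherent fraction ~ Binomial(20, 0.5): within 4 sigma
        k = coherent.sum()
        assert abs(k - 10) <= 4 * math.sqrt(20 * 0.25)

    def test_conservation_of_identities(self, nuclei_dataset):
        _, truth = nuclei_dataset
        assert truth.true_positions.shape[1] == len(truth.true_identities)
        assert np.all(np.isfinite(truth.true_positions))

    def test_seed_determinism(self):
        model = MotionModel(n_cells=5, seed=9)
        a, _ = generate_nuclei_movie(model, (16, 48, 48), frames=3, snr=5.0)
        b, _ = generate_nuclei_movie(model, (16, 48, 48), frames=3, snr=5.0)
        assert np.array_equal(a.data, b.data)

    def test_overcrowded_placement_rejected(self):
        model = MotionModel(n_cells=200, seed=1)
        with pytest.raises(ValueError, match="separation"):
            generate_nuclei_movie(model, (12, 32, 32), frames=2)

    def test_initial_separation_honored(self, nuclei_dataset):
        _, truth = nuclei_dataset
        p0 = truth.true_positions[0]
        d = np.linalg.norm(p0[:, None] - p0[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= truth.params["min_separation"] - 1e-9


class TestJunctionImage:
    def test_two_cells_share_one_straight_border(self):
        chans, truth = generate_junction_image(2, pa_spec=(0, 10.0), seed=3,
                                               shape=(200, 200))
        (y0, x0), (y1, x1) = truth.params["edges"][0]
        L = math.hypot(y1 - y0, x1 - x0)
        assert truth.true_tj_length == pytest.approx(L)
        assert len(truth.params["edges"]) == 1

    def test_hexagonal_truth_is_edge_count_times_side(self):
        edges, n_cells = hexagonal_edges((300, 300), side=40.0)
        total = sum(math.hypot(b[0] - a[0], b[1] - a[1]) for a, b in edges)
        assert total == pytest.approx(len(edges) * 40.0, rel=1e-4)
        assert n_cells >= 2

    def test_degenerate_pa_distribution_gives_fixed_lengths(self):
        _, truth = generate_junction_image(12, pa_spec=(8, 10.0), seed=4)
        assert np.allclose(truth.true_pa_lengths, 10.0)

    def test_seed_determinism(self):
        a, _ = generate_junction_image(10, pa_spec=(5, 9.0), seed=6)
        b, _ = generate_junction_image(10, pa_spec=(5, 9.0), seed=6)
        for k in a:
            assert np.array_equal(a[k], b[k])

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            generate_junction_image(1, seed=0)


class TestFusionMovie:
    def test_tangent_discs_geometry(self):
        d, ln = doublet_geometry(30.0, 30.0, 0.0)
        assert d == pytest.approx(60.0)
        assert ln == pytest.approx(120.0)

    def test_full_coalescence_is_near_circular(self):
        movie, _ = generate_fusion_movie((35.0, 35.0), lambda t: 35.0, frames=2)
        c = M.circularity(M.extract_contour(movie[0]))
        assert abs(c - 1.0) < 0.02

    def test_neck_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            _, truth = generate_fusion_movie((20.0, 30.0), lambda t: 100.0, frames=2)
        assert truth.true_contact_length.max() <= 2 * 20.0 + 1e-9

    def test_programmed_monotonicities(self):
        _, truth = generate_fusion_movie((40.0, 40.0), lambda t: 5.0 * t, frames=10)
        assert np.all(np.diff(truth.true_contact_length) >= 0)
        assert np.all(np.diff(truth.true_doublet_length) <= 0)

    def test_seed_and_shape_determinism(self):
        a, _ = generate_fusion_movie((25.0, 30.0), lambda t: 2 * t, frames=4, seed=1)
        b, _ = generate_fusion_movie((25.0, 30.0), lambda t: 2 * t, frames=4, seed=1)
        assert np.array_equal(a.data, b.data)

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            generate_fusion_movie((0.0, 10.0), lambda t: 0.0, frames=3)
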