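"""Neighbourhood suitability and quota-constrained spatial allocation."""

import numpy as np
import pytest

from esvland import (
    CAParams,
    LandCoverGrid,
    TransitionProbabilityMatrix,
    allocate,
    kappa_agreement,
    largest_remainder_quotas,
    neighborhood_suitability,
    project_areas,
    run_prediction,
    tabulate_areas,
)
from esvland.synthetic_data import SyntheticLandscapeSpec, evolve, generate_initial


def _persistence_matrix(n, diag):
    A = np.full((n, n), (1 - diag) / (n - 1))
    np.fill_diagonal(A, diag)
    return A


class TestNeighborhoodSuitability:
    def test_uniform_grid_is_degenerate(self, scheme):
        g = LandCoverGrid(np.full((6, 6), 3), 30.0, scheme)
        suit = neighborhood_suitability(g, CAParams(kernel_radius=1))
        np.testing.assert_allclose(suit.layers[2], 1.0)  # cropland layer
        assert suit.layers[[0, 1, 3, 4, 5]].max() == 0.0

    def test_center_fraction_counted_by_hand(self, scheme):
        values = np.array([[1, 2, 1], [2, 1, 2], [1, 2, 1]])
        g = LandCoverGrid(values, 30.0, scheme)
        suit = neighborhood_suitability(g, CAParams(kernel_radius=1))
        assert suit.layers[1][1, 1] == pytest.approx(4 / 9)  # grassland
        assert suit.layers[0][1, 1] == pytest.approx(5 / 9)

    def test_layers_partition_to_one(self, random_grid):
        suit = neighborhood_suitability(random_grid, CAParams(kernel_radius=2))
        np.testing.assert_allclose(suit.layers.sum(axis=0), 1.0, atol=1e-12)

    def test_edge_truncation(self, scheme):
        g = LandCoverGrid(np.array([[1, 2], [2, 2]]), 30.0, scheme)
        suit = neighborhood_suitability(g, CAParams(kernel_radius=1))
        # corner windows hold 4 pixels
        assert suit.layers[0][0, 0] == pytest.approx(1 / 4)

    def test_raising_neighbourhood_density_never_lowers_score(self, scheme):
        """Conversion score is monotone in the neighbourhood density of the
        target class (all else fixed)."""
        base = np.full((5, 5), 2)
        denser = base.copy()
        denser[0, 0] = 1  # add a forest pixel far from the centre
        params = CAParams(kernel_radius=2)
        s0 = neighborhood_suitability(LandCoverGrid(base, 30.0, scheme), params)
        s1 = neighborhood_suitability(LandCoverGrid(denser, 30.0, scheme), params)
        assert s1.layers[0][2, 2] >= s0.layers[0][2, 2]


class TestLargestRemainderQuotas:
    def test_counts_sum_to_landscape(self):
        quotas = largest_remainder_quotas(np.array([1.2, 2.5, 6.3]), 100)
        assert quotas.sum() == 100

    def test_exact_targets_pass_through(self):
        np.testing.assert_array_equal(
            largest_remainder_quotas(np.array([10.0, 30.0, 60.0]), 10), [1, 3, 6]
        )

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            largest_remainder_quotas(np.zeros(3), 10)


class TestAllocate:
    def test_identity_dynamics_fix_the_map(self, random_grid, scheme):
        A = TransitionProbabilityMatrix(np.eye(6), scheme=scheme, period_years=5.0)
        out = allocate(random_grid, A, steps=1, params=CAParams(seed=5))
        np.testing.assert_array_equal(out.values, random_grid.values)

    def test_realized_counts_equal_quotas_exactly(self, scheme):
        rng = np.random.default_rng(11)
        g = LandCoverGrid(rng.choice(scheme.codes, size=(100, 100)), 30.0, scheme)
        M = rng.random((6, 6)) + 0.2
        M /= M.sum(axis=1, keepdims=True)
        A = TransitionProbabilityMatrix(M, scheme=scheme, period_years=5.0)
        out = allocate(g, A, steps=1, params=CAParams(seed=1, quota_tolerance=0.0))
        target = project_areas(tabulate_areas(g).as_vector(), A, 1)
        quotas = largest_remainder_quotas(target, 100 * 100)
        np.testing.assert_array_equal(out.class_counts(), quotas)

    def test_fixed_seed_is_pixel_identical_and_seeds_share_areas(self, scheme):
        rng = np.random.default_rng(2)
        g = LandCoverGrid(rng.choice(scheme.codes, size=(60, 60)), 30.0, scheme)
        A = TransitionProbabilityMatrix(
            _persistence_matrix(6, 0.8), scheme=scheme, period_years=5.0
        )
        out1 = allocate(g, A, params=CAParams(seed=9))
        out2 = allocate(g, A, params=CAParams(seed=9))
        out3 = allocate(g, A, params=CAParams(seed=10))
        np.testing.assert_array_equal(out1.values, out2.values)
        np.testing.assert_array_equal(out1.class_counts(), out3.class_counts())

    def test_nodata_pixels_untouched(self, scheme):
        rng = np.random.default_rng(4)
        values = rng.choice(scheme.codes, size=(40, 40))
        values[:5, :5] = scheme.nodata_code
        g = LandCoverGrid(values, 30.0, scheme)
        A = TransitionProbabilityMatrix(
            _persistence_matrix(6, 0.9), scheme=scheme, period_years=5.0
        )
        out = allocate(g, A, params=CAParams(seed=0))
        assert (out.values[:5, :5] == scheme.nodata_code).all()
        assert (out.values[5:, :] != scheme.nodata_code).all()


class TestRunPrediction:
    def test_identical_calibration_pair_freezes_horizons(self, random_grid):
        _, maps = run_prediction(
            random_grid, random_grid, (2000, 2005), [2010, 2015], CAParams(seed=3)
        )
        for _, g in maps:
            np.testing.assert_array_equal(g.values, random_grid.values)

    def test_misaligned_horizon_rejected(self, random_grid):
        with pytest.raises(ValueError, match="aligned"):
            run_prediction(random_grid, random_grid, (2000, 2005), [2012], CAParams())
        with pytest.raises(ValueError, match="after"):
            run_prediction(random_grid, random_grid, (2000, 2005), [2003], CAParams())

    def test_first_horizon_areas_follow_markov_projection(self, scheme):
        spec = SyntheticLandscapeSpec(shape=(100, 100), autocorrelation=1, seed=21)
        A_true = _persistence_matrix(6, 0.9)
        g0 = generate_initial(spec)
        g1 = evolve(g0, A_true, steps=1, seed=22)
        A_est, maps = run_prediction(g0, g1, (2000, 2005), [2010], CAParams(seed=23))
        target = project_areas(tabulate_areas(g1).as_vector(), A_est, 1)
        quotas = largest_remainder_quotas(target, 100 * 100)
        np.testing.assert_array_equal(maps[0][1].class_counts(), quotas)

    def test_simulation_beats_random_map_with_same_marginals(self, scheme):
        """Under strong persistence the simulated map should agree with the
        held-out truth far better than chance (permutation baseline)."""
        spec = SyntheticLandscapeSpec(shape=(100, 100), autocorrelation=1, seed=31)
        A_true = _persistence_matrix(6, 0.95)
        g0 = generate_initial(spec)
        g1 = evolve(g0, A_true, steps=1, seed=32)
        truth = evolve(g1, A_true, steps=1, seed=33)
        _, maps = run_prediction(g0, g1, (2000, 2005), [2010], CAParams(seed=34))
        sim = maps[0][1]
        kappa_sim = kappa_agreement(truth, sim).kappa
        rng = np.random.default_rng(35)
        baseline = []
        for _ in range(10):
            perm = sim.values.ravel().copy()
            rng.shuffle(perm)
            shuffled = LandCoverGrid(perm.reshape(sim.shape), sim.cell_size, scheme)
            baseline.append(kappa_agreement(truth, shuffled).kappa)
        assert kappa_sim > max(baseline)
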