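"""Growth-rate solver: layer matrices, projection, root finding, simulation oracle."""

import math

import numpy as np
import pytest

from lifecycles import (
    GameParams,
    ReproductiveStrategy,
    SizeSchedule,
    enumerate_strategies_upto,
    layer_matrix,
    monte_carlo_growth_rate,
    newborn_return_matrix,
    solve_growth_rate,
    spectral_radius,
)


class TestLayerMatrix:
    def test_undiscounted_rows_are_stochastic(self, default_params, neutral_schedule):
        for n in (1, 3, 6):
            L = layer_matrix(n, 0.0, default_params, neutral_schedule)
            assert L.shape == (n + 1, n + 2)
            np.testing.assert_allclose(L.sum(axis=1), 1.0, atol=1e-12)

    def test_single_cell_entry_is_discounted_doubling(self):
        p = GameParams(w=0.0, m=0.0)
        sch = SizeSchedule(chi={1: 0.7})
        for lam in (0.5, 1.0, 2.0):
            L = layer_matrix(1, lam, p, sch)
            # (1,0) -> (2,0) is the only outcome for an all-A single cell
            assert L[0, 0] == pytest.approx(math.exp(-lam * 0.7 * math.log(2)))
            assert L[0, 1:].sum() == 0.0

    def test_entries_strictly_decrease_with_lambda(self, default_params, neutral_schedule):
        L1 = layer_matrix(2, 0.5, default_params, neutral_schedule)
        L2 = layer_matrix(2, 1.5, default_params, neutral_schedule)
        mask = L1 > 0
        assert np.all(L2[mask] < L1[mask])


class TestNewbornReturnMatrix:
    def test_binary_fission_is_diagonal_without_switching(self):
        p = GameParams(w=0.0, m=0.0)
        sch = SizeSchedule(chi={1: 0.5})
        for lam in (0.0, 1.0, 2.0):
            proj = newborn_return_matrix(ReproductiveStrategy((1, 1)), lam, p, sch)
            expected = 2 * math.exp(-lam * 0.5 * math.log(2))
            np.testing.assert_allclose(proj.matrix, expected * np.eye(2), atol=1e-12)

    @pytest.mark.parametrize("text", ["2+1", "4+4", "3+2+1", "1+1+1+1"])
    def test_undiscounted_row_sums_equal_offspring_count(self, text, default_params):
        s = ReproductiveStrategy.from_string(text)
        proj = newborn_return_matrix(s, 0.0, default_params, SizeSchedule(chi={2: 1.3}))
        np.testing.assert_allclose(proj.matrix.sum(axis=1), s.M, atol=1e-10)

    def test_spectral_radius_decreases_with_lambda(self, default_params, neutral_schedule):
        s = ReproductiveStrategy.from_string("3+2")
        rhos = [
            spectral_radius(newborn_return_matrix(s, lam, default_params, neutral_schedule))
            for lam in np.linspace(0.0, 3.0, 13)
        ]
        assert all(a > b for a, b in zip(rhos, rhos[1:]))


class TestSpectralRadius:
    def test_trivial_one_by_one(self):
        assert spectral_radius(np.array([[0.7]])) == pytest.approx(0.7)

    def test_matches_power_iteration(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            A = rng.uniform(size=(5, 5))
            v = np.ones(5)
            for _ in range(2000):
                v = A @ v
                v /= np.linalg.norm(v)
            assert spectral_radius(A) == pytest.approx(v @ A @ v, rel=1e-8)

    def test_rejects_non_square(self):
        with pytest.raises(ValueError):
            spectral_radius(np.ones((2, 3)))


class TestSolveGrowthRate:
    def test_neutral_condition_gives_unit_rate(self, neutral_params, neutral_schedule):
        for s in enumerate_strategies_upto(6):
            res = solve_growth_rate(s, neutral_params, neutral_schedule)
            assert res.lam == pytest.approx(1.0, abs=1e-8)
            assert res.residual <= 1e-8

    def test_binary_fission_closed_form(self, neutral_params):
        # 2 e^{-lam * chi_1 ln 2} = 1  =>  lam = 1 / chi_1
        res = solve_growth_rate(
            ReproductiveStrategy((1, 1)), neutral_params, SizeSchedule(chi={1: 0.5})
        )
        assert res.lam == pytest.approx(2.0, abs=1e-9)

    def test_size_lumped_and_matrix_routes_agree(self):
        # the w=0 reduction must match the full composition-resolved matrix,
        # including at high switching probability
        sch = SizeSchedule(chi={1: 0.8, 3: 1.4, 5: 0.6})
        for m in (0.0, 0.01, 0.5):
            p = GameParams(w=0.0, m=m)
            for text in ("2+1", "4+4", "3+2+1", "5+2"):
                s = ReproductiveStrategy.from_string(text)
                fast = solve_growth_rate(s, p, sch)
                full = solve_growth_rate(s, p, sch, method="matrix")
                assert fast.method == "size-lumped" and full.method == "matrix"
                assert fast.lam == pytest.approx(full.lam, abs=1e-8)

    def test_rate_invariant_to_game_parameters_without_selection(self):
        # w=0: composition never affects time, so b, c, k, m are inert
        s = ReproductiveStrategy.from_string("3+2")
        sch = SizeSchedule(chi={2: 0.7})
        base = solve_growth_rate(s, GameParams(w=0.0, m=0.01), sch, method="matrix").lam
        for p in (GameParams(w=0.0, m=0.5, b=3, c=0.1, k=1),
                  GameParams(w=0.0, m=0.0, b=20, c=5, k=4)):
            assert solve_growth_rate(s, p, sch, method="matrix").lam == \
                pytest.approx(base, abs=1e-8)

    def test_time_scale_covariance(self, default_params):
        # multiplying gamma by s divides the growth rate by s
        s = ReproductiveStrategy.from_string("4+3")
        base = solve_growth_rate(s, default_params, SizeSchedule()).lam
        for scale in (0.5, 2.0):
            res = solve_growth_rate(s, default_params, SizeSchedule(gamma=scale))
            assert res.lam == pytest.approx(base / scale, rel=1e-8)

    def test_result_diagnostics(self, default_params, neutral_schedule):
        res = solve_growth_rate(ReproductiveStrategy((2, 1)), default_params, neutral_schedule)
        lo, hi = res.bracket
        assert lo <= res.lam <= hi
        assert res.iterations > 0
        assert res.residual < 1e-8


class TestMonteCarlo:
    def test_neutral_rate_recovered(self, neutral_params, neutral_schedule):
        mc = monte_carlo_growth_rate(
            ReproductiveStrategy((2, 1)), neutral_params, neutral_schedule,
            seed=11, horizon=10.0, max_pop=800, replicates=4,
        )
        assert abs(mc.lam - 1.0) <= 2 * mc.stderr

    def test_reproducible_given_seed(self, neutral_params, neutral_schedule):
        kwargs = dict(seed=5, horizon=6.0, max_pop=300, replicates=3)
        a = monte_carlo_growth_rate(
            ReproductiveStrategy((1, 1)), neutral_params, neutral_schedule, **kwargs
        )
        b = monte_carlo_growth_rate(
            ReproductiveStrategy((1, 1)), neutral_params, neutral_schedule, **kwargs
        )
        assert a.replicates == b.replicates
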