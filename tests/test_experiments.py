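"""Parameter scans: perturbations, thresholds, combined effects, classification."""

from dataclasses import replace

import pytest

from lifecycles import (
    GameParams,
    OptimalityRecord,
    ReproductiveStrategy,
    SizeSchedule,
    classify_category,
    find_optimal,
    sample_random_schedules,
    scan_benefit_cost,
    scan_combined,
    scan_single_size_perturbations,
    scan_switching,
    scan_threshold,
)


def _record(optimal: list[str]) -> OptimalityRecord:
    strategies = [ReproductiveStrategy.from_string(s) for s in optimal]
    return OptimalityRecord(
        point={}, lambda_by_strategy={}, optimal_set=strategies,
        category="", max_lambda=1.0, tie_tol=1e-6,
    )


class TestClassifyCategory:
    def test_symmetric_binary(self):
        assert classify_category(_record(["4+4"]), N=8, k=3) == "symmetric-binary"
        assert classify_category(_record(["4+3"]), N=7, k=2) == "symmetric-binary"

    def test_asymmetric_binary(self):
        assert classify_category(_record(["5+3"]), N=8, k=5) == "asymmetric-binary"
        assert classify_category(_record(["7+1"]), N=8, k=7) == "asymmetric-binary"

    def test_multiple_optima(self):
        assert classify_category(_record(["1+1", "2+1"]), N=8, k=1) == "multiple-optima"

    def test_no_benefit_when_threshold_unreachable(self):
        assert classify_category(_record(["1+1"]), N=8, k=8) == "no-benefit"

    def test_other(self):
        assert classify_category(_record(["3+1"]), N=8, k=2) == "other"


class TestFindOptimal:
    def test_fully_neutral_everything_ties(self):
        rec = find_optimal(8, GameParams(w=0.0), SizeSchedule())
        assert len(rec.optimal_set) == 58
        assert rec.category == "multiple-optima"
        assert rec.max_lambda == pytest.approx(1.0, abs=1e-8)

    def test_advantageous_perturbation_selects_n_plus_one(self):
        rec = find_optimal(8, GameParams(w=0.0), SizeSchedule(chi={3: 0.4}))
        assert [str(s) for s in rec.optimal_set] == ["3+1"]

    def test_rejects_nonpositive_tie_tolerance(self):
        with pytest.raises(ValueError):
            find_optimal(4, GameParams(w=0.0), SizeSchedule(), tie_tol=0.0)


class TestSizePerturbationScan:
    def test_only_strategies_through_perturbed_size_deviate(self):
        recs = scan_single_size_perturbations([3], [0.4, 1.0, 1.5], N_max=8)
        for chi in (0.4, 1.5):
            rec = recs[(3, chi)]
            for name, lam in rec.lambda_by_strategy.items():
                s = ReproductiveStrategy.from_string(name)
                passes = s.parts[-1] <= 3 <= s.N - 1  # size 3 visited during growth
                if passes:
                    assert (lam > 1 + 1e-9) if chi < 1 else (lam < 1 - 1e-9)
                else:
                    assert lam == pytest.approx(1.0, abs=1e-8)
        # fully neutral column
        assert all(
            lam == pytest.approx(1.0, abs=1e-8)
            for lam in recs[(3, 1.0)].lambda_by_strategy.values()
        )

    def test_adverse_perturbation_hits_n_plus_one_hardest(self):
        rec = scan_single_size_perturbations([3], [1.5], N_max=8)[(3, 1.5)]
        affected = {
            name: lam for name, lam in rec.lambda_by_strategy.items()
            if abs(lam - 1) > 1e-8
        }
        assert min(affected, key=affected.get) == "3+1"


class TestRandomSchedules:
    def test_unique_optima_are_binary_and_one_plus_one_leads(self):
        scan = sample_random_schedules(150, seed=3, N_max=8)
        unique = scan.table[scan.table.optimum != "tie"]
        assert len(unique) > 0
        assert (unique.M == 2).all()
        assert max(scan.counts, key=scan.counts.get) == "1+1"

    def test_winners_of_three_plus_one_prefer_small_chi3(self):
        scan = sample_random_schedules(400, seed=4, N_max=8)
        t = scan.table
        winners = t[t.optimum == "3+1"]
        assert len(winners) > 0
        assert winners.chi_3.mean() < t.chi_3.mean()

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            sample_random_schedules(10, low=1.5, high=0.5)


class TestThresholdScan:
    def test_max_rate_monotone_decreasing_in_k(self, default_params):
        recs = scan_threshold(range(1, 7), [6], default_params)
        rates = [recs[(k, 6)].max_lambda for k in range(1, 7)]
        assert all(a >= b - 1e-12 for a, b in zip(rates, rates[1:]))

    def test_max_rate_monotone_increasing_in_N_at_low_k(self, default_params):
        recs = scan_threshold([2], [4, 5, 6], default_params)
        rates = [recs[(2, N)].max_lambda for N in (4, 5, 6)]
        assert all(b >= a - 1e-12 for a, b in zip(rates, rates[1:]))

    def test_records_carry_pool_convention(self, default_params):
        recs = scan_threshold([2], [5], default_params)
        assert "maturity size <= 5" in recs[(2, 5)].point["strategy_pool"]


class TestCombinedScan:
    def test_adverse_perturbation_shifts_optimum_to_unaffected_split(self, default_params):
        # 3+3 avoids size 7 entirely; 4+4 must grow through it
        recs = scan_combined([(7, 1.5)], [2], default_params, N_max=8)
        rec = recs[((7, 1.5), 2)]
        assert rec.lam("3+3") > rec.lam("4+4")
        assert rec.point["new_unique_optimum"] in (True, False)

    def test_beneficial_perturbation_recovers_n_plus_one_at_extreme_thresholds(
        self, default_params
    ):
        # n+1 wins at small and large k; intermediate k trades off size
        # against threshold and promotes other binary splits
        recs = scan_combined([(5, 0.4)], [1, 2, 7], default_params, N_max=8)
        assert str(recs[((5, 0.4), 1)].unique_optimum) == "5+1"
        assert str(recs[((5, 0.4), 7)].unique_optimum) == "5+1"
        mid = recs[((5, 0.4), 2)]
        assert str(mid.unique_optimum) == "5+2"
        assert mid.point["new_unique_optimum"]


class TestBenefitCostScan:
    def test_growth_rate_non_decreasing_in_ratio(self, default_params):
        p = replace(default_params, k=3)
        df = scan_benefit_cost(
            [2, 5, 10, 20], p, [ReproductiveStrategy((4, 4))]
        )
        lams = df.sort_values("ratio").lam.to_numpy()
        assert all(b >= a - 1e-10 for a, b in zip(lams, lams[1:]))

    def test_zero_net_benefit_rejected(self, default_params):
        with pytest.raises(ValueError):
            scan_benefit_cost([1.0], default_params, [ReproductiveStrategy((4, 4))])


class TestSwitchingScan:
    def test_optimum_stays_binary_at_maximum_maturity(self, default_params):
        recs = scan_switching([0.01, 0.2], replace(default_params, k=3), N_max=8)
        for rec in recs.values():
            assert rec.point["binary_max_N"]

    def test_growth_rate_decreases_with_switching(self, default_params):
        recs = scan_switching([0.01, 0.1, 0.3], replace(default_params, k=3), N_max=8)
        lams = [recs[m].lam("4+4") for m in (0.01, 0.1, 0.3)]
        assert lams[0] > lams[1] > lams[2]
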