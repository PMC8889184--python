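"""Parameter scans and optimality classification.

The optimal reproductive strategy at a parameter point maximizes the
population growth rate.  These scans reproduce the model's core
experiments: single size perturbations, random size schedules, threshold
(volunteer's dilemma) scans over ``(k, N)``, combined size+threshold
scans, benefit/cost curves, and switching-probability scans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .growth import GameParams, SizeSchedule
from .solver import solve_growth_rate
from .strategies import ReproductiveStrategy, enumerate_strategies_upto

__all__ = [
    "OptimalityRecord",
    "RandomScheduleScan",
    "find_optimal",
    "classify_category",
    "scan_single_size_perturbations",
    "sample_random_schedules",
    "scan_threshold",
    "scan_combined",
    "scan_benefit_cost",
    "scan_switching",
]


@dataclass
class OptimalityRecord:
    """Growth rates of all competing strategies at one parameter point."""

    point: dict
    lambda_by_strategy: dict[str, float]
    optimal_set: list[ReproductiveStrategy]
    category: str
    max_lambda: float
    tie_tol: float

    def lam(self, strategy: ReproductiveStrategy | str) -> float:
        return self.lambda_by_strategy[str(strategy)]

    @property
    def unique_optimum(self) -> ReproductiveStrategy | None:
        return self.optimal_set[0] if len(self.optimal_set) == 1 else None


@lru_cache(maxsize=None)
def _growth_rate(
    strategy: ReproductiveStrategy, params: GameParams, schedule: SizeSchedule
) -> float:
    return solve_growth_rate(strategy, params, schedule).lam


def classify_category(record: OptimalityRecord, N: int, k: int) -> str:
    """Label the optimality pattern at maturity size ``N`` and threshold ``k``.

    Categories: ``no-benefit`` (k >= N: the threshold can never be met
    before maturity), ``multiple-optima``, ``symmetric-binary``
    (N/2 + N/2, or the near-even split for odd N), ``asymmetric-binary``
    ((N-k) + k), and ``other``.
    """
    if k >= N:
        return "no-benefit"
    if len(record.optimal_set) != 1:
        return "multiple-optima"
    s = record.optimal_set[0]
    if s.M == 2 and s.N == N:
        if set(s.parts) == {math.ceil(N / 2), math.floor(N / 2)}:
            return "symmetric-binary"
        if sorted(s.parts) == sorted((N - k, k)):
            return "asymmetric-binary"
    return "other"


def find_optimal(
    N_max: int,
    params: GameParams | None = None,
    schedule: SizeSchedule | None = None,
    tie_tol: float = 1e-6,
    strategies: Sequence[ReproductiveStrategy] | None = None,
) -> OptimalityRecord:
    """Growth rates and optimal set over all strategies with maturity <= N_max.

    Strategies within relative growth-rate gap ``tie_tol`` of the maximum
    are declared co-optimal; the record keeps all raw rates so ties can
    be audited at any tolerance.
    """
    params = params or GameParams()
    schedule = schedule or SizeSchedule()
    if tie_tol <= 0:
        raise ValueError("tie_tol must be positive")
    pool = list(strategies) if strategies is not None else enumerate_strategies_upto(N_max)
    lam = {s: _growth_rate(s, params, schedule) for s in pool}
    mx = max(lam.values())
    optimal = [s for s in pool if lam[s] >= mx * (1.0 - tie_tol)]
    record = OptimalityRecord(
        point={
            "N_max": N_max,
            "k": params.k, "w": params.w, "b": params.b, "c": params.c,
            "m": params.m, "gamma": schedule.gamma, "chi": schedule.chi_dict(),
        },
        lambda_by_strategy={str(s): lam[s] for s in pool},
        optimal_set=optimal,
        category="",
        max_lambda=mx,
        tie_tol=tie_tol,
    )
    record.category = classify_category(record, N_max, params.k)
    return record


def scan_single_size_perturbations(
    n_values: Iterable[int],
    chi_values: Iterable[float],
    params: GameParams | None = None,
    N_max: int = 8,
    tie_tol: float = 1e-6,
) -> dict[tuple[int, float], OptimalityRecord]:
    """Optimality under one perturbed size multiplier at a time.

    For each ``(n, chi)`` the schedule is ``chi_n = chi`` with every other
    size neutral.  With ``w = 0`` only strategies whose organisms pass
    through size ``n`` during growth deviate from the neutral rate 1.
    """
    params = params or GameParams(w=0.0)
    out: dict[tuple[int, float], OptimalityRecord] = {}
    for n in n_values:
        for chi in chi_values:
            rec = find_optimal(
                N_max, params, SizeSchedule(chi={n: chi}), tie_tol=tie_tol
            )
            rec.point["perturbed_n"] = n
            rec.point["perturbed_chi"] = chi
            out[(n, chi)] = rec
    return out


@dataclass
class RandomScheduleScan:
    """Optimal strategies under i.i.d. uniform random size schedules."""

    table: pd.DataFrame  # chi_1..chi_{N-1}, optimum ("tie" if not unique), M
    counts: dict[str, int]  # unique-optimum frequencies
    n_samples: int
    seed: int
    low: float
    high: float


def sample_random_schedules(
    n_samples: int = 10_000,
    low: float = 0.5,
    high: float = 1.5,
    seed: int = 0,
    N_max: int = 8,
    tie_tol: float = 1e-6,
) -> RandomScheduleScan:
    """Draw ``chi_1..chi_{N_max-1} ~ U(low, high)`` and record the optimum.

    Selection is off (``w = 0``); only size effects act.  The returned
    table keeps every sampled schedule together with its winner, so
    conditional summaries (e.g. the chi_3 distribution among schedules
    promoting 3+1) can be computed downstream.
    """
    if not low < high:
        raise ValueError("need low < high")
    rng = np.random.default_rng(seed)
    params = GameParams(w=0.0)
    strategies = enumerate_strategies_upto(N_max)
    sizes = list(range(1, N_max))
    rows = []
    counts: dict[str, int] = {}
    for _ in range(n_samples):
        chi = {n: float(v) for n, v in zip(sizes, rng.uniform(low, high, len(sizes)))}
        schedule = SizeSchedule(chi=chi)
        lam = {s: solve_growth_rate(s, params, schedule).lam for s in strategies}
        mx = max(lam.values())
        optimal = [s for s in strategies if lam[s] >= mx * (1.0 - tie_tol)]
        if len(optimal) == 1:
            winner = str(optimal[0])
            counts[winner] = counts.get(winner, 0) + 1
            M = optimal[0].M
        else:
            winner, M = "tie", 0
        rows.append({**{f"chi_{n}": chi[n] for n in sizes},
                     "optimum": winner, "M": M, "max_lambda": mx})
    return RandomScheduleScan(
        table=pd.DataFrame(rows), counts=counts,
        n_samples=n_samples, seed=seed, low=low, high=high,
    )


def scan_threshold(
    k_values: Iterable[int],
    N_values: Iterable[int] | None = None,
    params: GameParams | None = None,
    tie_tol: float = 1e-6,
) -> dict[tuple[int, int], OptimalityRecord]:
    """Optimality map over contribution threshold ``k`` and maturity bound ``N``.

    The size schedule is neutral.  Each column ``N`` admits every strategy
    with maturity size <= N (the convention is recorded in each record's
    metadata).
    """
    params = params or GameParams()
    if N_values is None:
        N_values = [8]
    out: dict[tuple[int, int], OptimalityRecord] = {}
    for N in N_values:
        for k in k_values:
            rec = find_optimal(N, replace(params, k=int(k)), SizeSchedule(), tie_tol)
            rec.point["strategy_pool"] = f"all strategies with maturity size <= {N}"
            out[(int(k), N)] = rec
    return out


def scan_combined(
    perturbations: Iterable[tuple[int, float]],
    k_values: Iterable[int],
    params: GameParams | None = None,
    N_max: int = 8,
    tie_tol: float = 1e-6,
) -> dict[tuple[tuple[int, float], int], OptimalityRecord]:
    """Optimality under a single size perturbation combined with a threshold.

    Each record is flagged with ``new_unique_optimum``: a unique optimum
    that is unique neither in the size-only scan (same perturbation,
    ``w = 0``) nor in the threshold-only scan (neutral schedule, same k).
    """
    params = params or GameParams()
    perturbations = list(perturbations)
    k_values = [int(k) for k in k_values]

    size_only: dict[tuple[int, float], str | None] = {}
    for n, chi in perturbations:
        rec = find_optimal(N_max, GameParams(w=0.0), SizeSchedule(chi={n: chi}), tie_tol)
        size_only[(n, chi)] = str(rec.unique_optimum) if rec.unique_optimum else None
    thr_only: dict[int, str | None] = {}
    for k in k_values:
        rec = find_optimal(N_max, replace(params, k=k), SizeSchedule(), tie_tol)
        thr_only[k] = str(rec.unique_optimum) if rec.unique_optimum else None

    out: dict[tuple[tuple[int, float], int], OptimalityRecord] = {}
    for n, chi in perturbations:
        schedule = SizeSchedule(chi={n: chi})
        for k in k_values:
            rec = find_optimal(N_max, replace(params, k=k), schedule, tie_tol)
            rec.point["perturbed_n"] = n
            rec.point["perturbed_chi"] = chi
            uniq = rec.unique_optimum
            rec.point["new_unique_optimum"] = bool(
                uniq is not None
                and str(uniq) != size_only[(n, chi)]
                and str(uniq) != thr_only[k]
            )
            out[((n, chi), k)] = rec
    return out


def scan_benefit_cost(
    ratios: Iterable[float],
    params: GameParams | None = None,
    strategy_set: Sequence[ReproductiveStrategy] | None = None,
    schedule: SizeSchedule | None = None,
) -> pd.DataFrame:
    """Growth rates across benefit-to-cost ratios (cost held fixed).

    Returns a tidy frame with one row per (ratio, strategy).  Growth
    rates are non-decreasing in the ratio.
    """
    params = params or GameParams()
    schedule = schedule or SizeSchedule()
    if strategy_set is None:
        strategy_set = [ReproductiveStrategy((4, 4))]
    rows = []
    for ratio in ratios:
        p = replace(params, b=float(ratio) * params.c)
        for s in strategy_set:
            rows.append({
                "ratio": float(ratio), "strategy": str(s),
                "lam": _growth_rate(s, p, schedule),
            })
    return pd.DataFrame(rows)


def scan_switching(
    m_values: Iterable[float],
    params: GameParams | None = None,
    N_max: int = 8,
    tie_tol: float = 1e-6,
) -> dict[float, OptimalityRecord]:
    """Optimality as the cell-type switching probability ``m`` varies.

    Each record is flagged with ``binary_max_N``: whether every optimal
    strategy is a binary split at the maximum admitted maturity size.
    """
    params = params or GameParams()
    out: dict[float, OptimalityRecord] = {}
    for m in m_values:
        rec = find_optimal(N_max, replace(params, m=float(m)), SizeSchedule(), tie_tol)
        rec.point["binary_max_N"] = all(
            s.M == 2 and s.N == N_max for s in rec.optimal_set
        )
        out[float(m)] = rec
    return out
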