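"""Per-step organism growth law.

Organisms grow one cell at a time.  The time to grow from size ``n`` to
``n + 1`` factorises into a size component and a threshold component,

    t_n = t_sn * t_gn,

where ``t_sn = chi_n * gamma * ln((n+1)/n)`` depends only on size (under
the neutral schedule ``chi_n = 1`` the size-doubling time is
size-independent) and ``t_gn`` is the inverse mean fitness of the
organism under a volunteer's dilemma: if the number of type-B cells
reaches the contribution threshold ``k``, every cell receives benefit
``b``; each B cell always pays an individual cost ``c``.  Payoffs enter
through exponential weights ``e^{w P}`` with selection intensity ``w``.

At each increment one cell is chosen to divide (probability proportional
to its type's exponential payoff weight); it is replaced by two daughter
cells, each of which independently switches phenotype with probability
``m``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .strategies import Composition

__all__ = [
    "GameParams",
    "SizeSchedule",
    "payoffs",
    "division_probabilities",
    "threshold_time_component",
    "size_time_component",
    "step_time",
    "division_step_distribution",
]


@dataclass(frozen=True)
class GameParams:
    """Volunteer's-dilemma and cell-level parameters.

    Attributes
    ----------
    b, c
        Benefit to every cell when the organism has at least ``k`` type-B
        cells, and the individual cost each B cell always pays.  When
        selection is active (``w > 0``) the model requires ``b - c > 0``.
    k
        Contribution threshold (minimum number of B cells for the benefit).
    w
        Intensity of selection (w = 0 switches threshold effects off).
    m
        Per-daughter-cell phenotype switching probability at division.
    """

    b: float = 10.0
    c: float = 1.0
    k: int = 3
    w: float = 0.1
    m: float = 0.01

    def __post_init__(self) -> None:
        if not (isinstance(self.k, int) or float(self.k).is_integer()):
            raise ValueError(f"k must be an integer, got {self.k!r}")
        object.__setattr__(self, "k", int(self.k))
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"m must be a probability, got {self.m}")
        if self.w < 0:
            raise ValueError(f"w must be >= 0, got {self.w}")
        if self.w > 0 and not self.b - self.c > 0:
            raise ValueError(
                f"b - c must be positive when selection is active (w > 0); "
                f"got b={self.b}, c={self.c}"
            )


@dataclass(frozen=True)
class SizeSchedule:
    """Size-dependent growth-time multipliers.

    ``chi`` maps a size ``n`` to the normalized cell-increment component
    ``chi_n = t_sn / t_sn0``; sizes not listed default to 1 (the neutral
    condition), so schedules are sparse perturbation dictionaries.
    ``gamma`` is the overall time-scale constant (default 1).
    """

    gamma: float = 1.0
    chi: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        items: Mapping[int, float] | tuple
        items = dict(self.chi) if not isinstance(self.chi, Mapping) else self.chi
        norm = []
        for n, v in sorted(items.items()):
            n = int(n)
            v = float(v)
            if n < 1:
                raise ValueError(f"chi is indexed by sizes n >= 1, got {n}")
            if v <= 0:
                raise ValueError(f"chi_{n} must be > 0, got {v}")
            if v != 1.0:
                norm.append((n, v))
        object.__setattr__(self, "chi", tuple(norm))

    def chi_at(self, n: int) -> float:
        """Multiplier ``chi_n`` (1 unless perturbed)."""
        for size, value in self.chi:
            if size == n:
                return value
        return 1.0

    def chi_dict(self) -> dict[int, float]:
        return dict(self.chi)


def payoffs(comp: Composition, params: GameParams) -> tuple[float, float]:
    """Volunteer's-dilemma payoffs ``(P_A, P_B)`` of the two cell types.

    Every cell gets ``b`` if the organism has at least ``k`` B cells;
    B cells additionally pay ``c`` regardless.
    """
    P_A = params.b if comp.n_B >= params.k else 0.0
    return P_A, P_A - params.c


def _fitness_weights(comp: Composition, params: GameParams) -> tuple[float, float]:
    P_A, P_B = payoffs(comp, params)
    return (
        comp.n_A * math.exp(params.w * P_A),
        comp.n_B * math.exp(params.w * P_B),
    )


def division_probabilities(comp: Composition, params: GameParams) -> tuple[float, float]:
    """Probability that the dividing cell is of type A resp. B.

    Exponential payoff weighting: ``p_A = n_A e^{wP_A} / (n_A e^{wP_A} +
    n_B e^{wP_B})`` and ``p_B = 1 - p_A``.  At ``w = 0`` these reduce to
    the cell-type frequencies.
    """
    f_A, f_B = _fitness_weights(comp, params)
    total = f_A + f_B
    if total <= 0:
        raise ValueError(f"empty organism {comp}: no cell can divide")
    p_A = f_A / total
    return p_A, 1.0 - p_A


def threshold_time_component(comp: Composition, params: GameParams) -> float:
    """Threshold component ``t_gn``: inverse mean fitness of the organism."""
    f_A, f_B = _fitness_weights(comp, params)
    return comp.n / (f_A + f_B)


def size_time_component(n: int, schedule: SizeSchedule) -> float:
    """Size component ``t_sn = chi_n * gamma * ln((n+1)/n)``."""
    if n < 1:
        raise ValueError(f"size must be >= 1, got {n}")
    return schedule.chi_at(n) * schedule.gamma * math.log((n + 1) / n)


def step_time(comp: Composition, schedule: SizeSchedule, params: GameParams) -> float:
    """Time for an organism of composition ``comp`` to grow by one cell."""
    return size_time_component(comp.n, schedule) * threshold_time_component(comp, params)


def division_step_distribution(
    comp: Composition, params: GameParams
) -> dict[Composition, float]:
    """Distribution of the composition after one cell increment.

    A cell of type A (B) is selected to divide with probability ``p_A``
    (``p_B``); the parent is replaced by two daughter cells, each of which
    independently keeps the parental phenotype with probability ``1 - m``
    and switches with probability ``m``.  Outcomes of total size
    ``comp.n + 1`` are merged; zero-probability outcomes are dropped.
    """
    p_A, p_B = division_probabilities(comp, params)
    m = params.m
    a, b = comp.n_A, comp.n_B
    out: dict[Composition, float] = {}

    def add(n_A: int, n_B: int, p: float) -> None:
        if p > 0.0:
            key = Composition(n_A, n_B)
            out[key] = out.get(key, 0.0) + p

    if p_A > 0.0:
        # A divides: daughters AA / AB / BB
        add(a + 1, b, p_A * (1 - m) ** 2)
        add(a, b + 1, p_A * 2 * m * (1 - m))
        add(a - 1, b + 2, p_A * m * m)
    if p_B > 0.0:
        # B divides: daughters BB / AB / AA
        add(a, b + 1, p_B * (1 - m) ** 2)
        add(a + 1, b, p_B * 2 * m * (1 - m))
        add(a + 2, b - 1, p_B * m * m)
    return out
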