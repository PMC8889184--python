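"""Random fragmentation of a mature organism into its offspring units.

When an organism of composition ``(n_A, n_B)`` reaches maturity it splits
instantaneously into parts of the sizes prescribed by its strategy, with
the ``N`` cells assigned to the parts uniformly at random without
replacement.  The composition of a single part of size ``s`` therefore
follows a hypergeometric law, and the joint law over all parts is
multivariate hypergeometric.  Probabilities are exact rationals
(`fractions.Fraction`), which makes the conservation identities exact.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

from .strategies import Composition, ReproductiveStrategy

__all__ = [
    "part_composition_pmf",
    "expected_offspring",
    "joint_fragment_distribution",
]


def part_composition_pmf(
    mature: Composition, part_size: int
) -> dict[Composition, Fraction]:
    """Composition distribution of one offspring unit of size ``part_size``.

    Hypergeometric: ``P[(a, s-a)] = C(n_A, a) C(n_B, s-a) / C(n, s)``.
    """
    if part_size < 1:
        raise ValueError(f"part size must be >= 1, got {part_size}")
    if part_size > mature.n:
        raise ValueError(
            f"part size {part_size} exceeds the mature organism size {mature.n}"
        )
    total = comb(mature.n, part_size)
    pmf: dict[Composition, Fraction] = {}
    a_lo = max(0, part_size - mature.n_B)
    a_hi = min(mature.n_A, part_size)
    for a in range(a_lo, a_hi + 1):
        ways = comb(mature.n_A, a) * comb(mature.n_B, part_size - a)
        pmf[Composition(a, part_size - a)] = Fraction(ways, total)
    return pmf


def expected_offspring(
    mature: Composition, strategy: ReproductiveStrategy
) -> dict[Composition, Fraction]:
    """Expected number of newborn organisms of each composition.

    Sum of the per-part hypergeometric marginals.  Expectations are all
    the growth-rate computation needs (means of a branching process are
    linear); the full joint law is in :func:`joint_fragment_distribution`.
    Conservation holds exactly: the expected A (B) cells summed over
    offspring equal the parent's counts, and total expected organisms
    equal the number of parts.
    """
    if mature.n != strategy.N:
        raise ValueError(
            f"mature organism has {mature.n} cells but strategy {strategy} "
            f"requires maturity size {strategy.N}"
        )
    expectation: dict[Composition, Fraction] = {}
    for part in strategy.parts:
        for comp, p in part_composition_pmf(mature, part).items():
            expectation[comp] = expectation.get(comp, Fraction(0)) + p
    return expectation


def joint_fragment_distribution(
    mature: Composition, strategy: ReproductiveStrategy
) -> dict[tuple[Composition, ...], Fraction]:
    """Joint law of the whole brood, as multisets of compositions.

    Cells are assigned to the parts uniformly without replacement
    (multivariate hypergeometric); outcomes that differ only by the order
    of equal-sized parts are merged.  Keys are sorted tuples of
    compositions; values sum to 1.
    """
    if mature.n != strategy.N:
        raise ValueError(
            f"mature organism has {mature.n} cells but strategy {strategy} "
            f"requires maturity size {strategy.N}"
        )
    joint: dict[tuple[Composition, ...], Fraction] = {}

    def recurse(
        remaining: Composition, parts: tuple[int, ...],
        brood: tuple[Composition, ...], prob: Fraction,
    ) -> None:
        if not parts:
            key = tuple(sorted(brood))
            joint[key] = joint.get(key, Fraction(0)) + prob
            return
        for comp, p in part_composition_pmf(remaining, parts[0]).items():
            left = Composition(remaining.n_A - comp.n_A, remaining.n_B - comp.n_B)
            recurse(left, parts[1:], (*brood, comp), prob * p)

    recurse(mature, strategy.parts, (), Fraction(1))
    return joint
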