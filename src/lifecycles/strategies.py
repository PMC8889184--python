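"""Reproductive strategies and organism compositions.

A reproductive strategy is a fixed fragmentation mode of a multicellular
organism: when an organism reaches its maturity size ``N`` it splits into
offspring units of sizes ``n_1 >= n_2 >= ... >= n_M`` with
``sum(n_i) = N`` and ``M >= 2``.  Strategies are therefore the integer
partitions of ``N`` into at least two parts; the trivial "partition"
consisting of the whole organism is not a reproductive event and is
excluded everywhere.

Organisms consist of two cell phenotypes, ``A`` and ``B``; the state of an
organism is its composition ``(n_A, n_B)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple


class Composition(NamedTuple):
    """Cell-type composition of an organism: ``n_A`` type-A and ``n_B`` type-B cells."""

    n_A: int
    n_B: int

    @property
    def n(self) -> int:
        """Total cell number of the organism."""
        return self.n_A + self.n_B

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"({self.n_A}, {self.n_B})"


@dataclass(frozen=True)
class ReproductiveStrategy:
    """A fragmentation mode ``n_1 + n_2 + ... + n_M`` of a mature organism.

    Parameters
    ----------
    parts
        Offspring sizes, sorted non-increasing, each >= 1, at least two of
        them.  The maturity size ``N`` is their sum.
    """

    parts: tuple[int, ...]

    def __post_init__(self) -> None:
        parts = tuple(int(p) for p in self.parts)
        object.__setattr__(self, "parts", parts)
        if len(parts) < 2:
            raise ValueError(
                f"a reproductive strategy needs at least two offspring units, got {parts!r}"
            )
        if any(p < 1 for p in parts):
            raise ValueError(f"offspring sizes must be positive integers, got {parts!r}")
        if any(a < b for a, b in zip(parts, parts[1:])):
            raise ValueError(f"offspring sizes must be sorted non-increasing, got {parts!r}")

    @property
    def N(self) -> int:
        """Maturity size: the cell count at which the organism fragments."""
        return sum(self.parts)

    @property
    def M(self) -> int:
        """Number of offspring units produced per reproduction event."""
        return len(self.parts)

    @classmethod
    def from_string(cls, text: str) -> "ReproductiveStrategy":
        """Parse the canonical rendering, e.g. ``"4+3+1"``."""
        try:
            parts = tuple(int(tok) for tok in text.replace(" ", "").split("+"))
        except ValueError as exc:
            raise ValueError(f"cannot parse strategy {text!r}") from exc
        return cls(parts)

    def __str__(self) -> str:
        return "+".join(str(p) for p in self.parts)

    def __repr__(self) -> str:
        return f"ReproductiveStrategy({self})"


def _partitions_desc(n: int, max_part: int) -> Iterator[tuple[int, ...]]:
    """Integer partitions of ``n`` with parts <= max_part, descending-lex order."""
    if n == 0:
        yield ()
        return
    for first in range(min(n, max_part), 0, -1):
        for rest in _partitions_desc(n - first, first):
            yield (first, *rest)


def enumerate_strategies(N: int) -> list[ReproductiveStrategy]:
    """All reproductive strategies of maturity size ``N``.

    These are the integer partitions of ``N`` with at least two parts, in
    descending-lexicographic order (``p(N) - 1`` of them, with ``p`` the
    partition function).  E.g. for a 10-celled organism there are 41, for
    a 20-celled organism 626.
    """
    if N < 2:
        raise ValueError(f"no reproductive strategy exists for N={N}; need N >= 2")
    return [
        ReproductiveStrategy(parts)
        for parts in _partitions_desc(N, N)
        if len(parts) >= 2
    ]


def enumerate_strategies_upto(N_max: int) -> list[ReproductiveStrategy]:
    """All strategies with maturity size ``2 <= N <= N_max``, grouped by N."""
    if N_max < 2:
        raise ValueError(f"no reproductive strategy exists for N_max={N_max}; need N_max >= 2")
    out: list[ReproductiveStrategy] = []
    for N in range(2, N_max + 1):
        out.extend(enumerate_strategies(N))
    return out


def newborn_compositions(strategy: ReproductiveStrategy) -> list[Composition]:
    """Every composition a newborn organism of this strategy can have.

    For each distinct offspring size ``s`` all ``s + 1`` compositions
    ``(a, s - a)`` are possible.  Ordered by size ascending, then by
    ``n_A`` descending; the list is duplicate-free and serves as the index
    of the newborn-to-newborn projection matrix.
    """
    out: list[Composition] = []
    for s in sorted(set(strategy.parts)):
        out.extend(Composition(a, s - a) for a in range(s, -1, -1))
    return out


def composition_states(N: int) -> list[list[Composition]]:
    """Layered state space of growing organisms up to size ``N``.

    Layer ``n`` (1-based, returned at index ``n - 1``) holds the ``n + 1``
    compositions of total size ``n``, ordered by ``n_A`` descending.  All
    growth matrices use this ordering.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    return [
        [Composition(a, n - a) for a in range(n, -1, -1)]
        for n in range(1, N + 1)
    ]
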