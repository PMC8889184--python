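"""Enumerate reproductive strategies and newborn compositions.

A reproductive strategy is an integer partition of the maturity size N
into at least two offspring units.  The number of strategies grows
quickly with N, yet only a handful are common in nature — the question
the growth-rate machinery in this package addresses.
"""

from lifecycles import (
    ReproductiveStrategy,
    enumerate_strategies,
    newborn_compositions,
)

for N in (3, 10, 20):
    print(f"N = {N:2d}: {len(enumerate_strategies(N)):4d} reproductive strategies")

print("\nAll strategies of a 5-celled organism (descending-lexicographic):")
print("  " + ", ".join(str(s) for s in enumerate_strategies(5)))

s = ReproductiveStrategy.from_string("2+1")
print(f"\nNewborn compositions (n_A, n_B) of the {s} population:")
print("  " + ", ".join(str(c) for c in newborn_compositions(s)))
print("Five newborn types: every way the two offspring sizes can be")
print("filled with the two cell phenotypes.")
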