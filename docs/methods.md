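# Methods

## The model

`lifecycles` implements a stage-structured population model for the
evolution of reproductive strategies in incipient multicellular
organisms.  An organism is a group of cells of two phenotypes, A and B;
its state is the composition (n_A, n_B).  It grows one cell at a time
until it reaches its maturity size N and then fragments instantaneously
into offspring units whose sizes are a fixed integer partition
n_1 + ... + n_M of N with M >= 2 — its *reproductive strategy*.  All
organisms of a population share one strategy; populations are density
independent and therefore grow exponentially.  Strategies compete
through the population growth rate λ, and the *optimal* strategy at a
parameter point maximizes λ.

### Growth times

The time for an organism of composition (n_A, n_B), n = n_A + n_B, to
add one cell factorises into

    t_n = t_sn · t_gn .

The size component is t_sn = χ_n · γ · ln((n+1)/n).  With χ_n ≡ 1 the
size-doubling time is size independent and every strategy grows at the
reference rate λ = 1; the multipliers χ_n (dimensionless, default 1,
γ = 1 time unit) express arbitrary size effects as perturbations of that
baseline.  Schedules are stored sparsely: only perturbed sizes are kept.

The threshold component is a volunteer's dilemma.  If n_B ≥ k every
cell receives a benefit b; each B cell always pays an individual cost c
(so P_A = b·1[n_B ≥ k], P_B = P_A − c, and the model requires b − c > 0
whenever selection is active).  Payoffs enter through exponential
weights: the dividing cell is of type A with probability
p_A = n_A e^{wP_A} / (n_A e^{wP_A} + n_B e^{wP_B}), and
t_gn = ((n_A e^{wP_A} + n_B e^{wP_B})/n)^{-1} is the inverse mean
fitness.  At w = 0 both reduce to neutral frequencies and t_gn = 1.

### Division and switching

A division consumes the parent cell and produces two daughter cells;
each daughter independently switches phenotype with probability m
(default 0.01).  Switching happens only at division.  The alternative
reading — parent persists, only the new daughter may switch — is not
implemented; with the consumed-parent semantics a homogeneous organism
can lose its founding type in a single division only via a double
switch (probability m²), which is the natural two-daughter model.

### Fragmentation

At maturity the N cells are assigned to the parts uniformly at random
without replacement: the composition of a part of size s is
hypergeometric, P[(a, s−a)] = C(n_A, a)·C(n_B, s−a)/C(N, s), and the
joint law over the brood is multivariate hypergeometric.  Probabilities
are exact rationals, making the conservation identities (expected A and
B cells over offspring equal the parent's counts; expected offspring
count equals M) exact rather than approximate.

## The growth rate

λ is defined by the generalized Euler–Lotka (renewal) condition of a
multitype branching process with deterministic, composition-dependent
stage durations.  Q(λ) is the newborn-to-newborn matrix: entry (i, j)
is the expected number of newborns of composition j produced per life
cycle of a newborn of composition i, with each growth trajectory
weighted by e^{−λ·(trajectory time)}.  Because discounting is
multiplicative along a path, the weight is applied per one-cell
increment and the matrix is assembled by exact products of per-layer
discounted transition matrices — no path enumeration.  Only *expected*
offspring counts enter Q: means of a branching process are linear, and
a test verifies that the joint fragmentation law marginalizes exactly to
those expectations.  ρ(Q(λ)) is continuous and strictly decreasing in
λ (every entry is), ρ(Q(0)) = M ≥ 2, so the root of ρ(Q(λ)) = 1 exists
and is unique.  The solver brackets it starting from [0, 2], doubling
the upper end until ρ < 1, then uses Brent's method (default tolerance
1e−10 on λ); results carry the residual |ρ(Q(λ*)) − 1|, the bracket and
the iteration count.

**Size-lumped fast path (w = 0).**  Without selection, step times depend
only on size and every mature composition yields, in expectation,
exactly the part multiplicities at each offspring size.  The
composition-resolved matrix is then exactly lumpable by newborn size and
the characteristic equation collapses to the scalar renewal equation

    Σ_i e^{−λ T(n_i)} = 1,   T(s) = Σ_{n=s}^{N−1} χ_n γ ln((n+1)/n).

`solve_growth_rate` takes this route automatically for w = 0
(`method="matrix"` forces the full route); a test checks both routes
agree to 1e−8, including at high switching probability.  Under the
neutral schedule T(s) = ln(N/s) and Σ n_i (n_i/N)^λ = 1 at λ = 1,
which is the neutral-universality property the test suite asserts for
all 58 strategies with N ≤ 8.

**Monte-Carlo oracle.**  An event-driven simulation provides an
independent estimate: organisms carry deterministic step times, sample
division outcomes (including switching) from the same per-composition
distribution, and fragment by actually sampling the multivariate
hypergeometric assignment.  λ is the least-squares slope of
log(total cell count) over the second half of the horizon; the standard
error comes from independent replicates (default 6, horizon 12 time
units, population cap 1500 organisms with random halving absorbed into
a running weight so the recorded trajectory stays unbiased).  The
population is founded with one newborn of *each* reachable composition:
with m = 0.01 a fast-growing B-rich lineage seeded only by rare
switching events would otherwise keep the log-slope in transient for
far longer than any practical horizon.  The founding set is
model-defined and independent of the matrix solver, so the two routes
remain separate checks on each other.  Simulation size defaults
(horizon, cap, replicates) were chosen so that the standard error is a
few 10⁻³ on rates of order 1–3 while a five-point comparison runs in
well under a minute.

## Experiments and classification

- *Single size perturbations*: one χ_n ≠ 1 at a time, w = 0.  Only
  strategies whose organisms spend growth time at size n (n_M ≤ n ≤
  N − 1) deviate from λ = 1; an advantageous perturbation uniquely
  promotes n + 1, an adverse one suppresses it hardest.
- *Random schedules*: χ_1..χ_7 i.i.d. uniform on [0.5, 1.5] (the
  library default is 10 000 samples; tests use 1 000), w = 0.  Every
  unique optimum observed is a binary split and 1+1 is the most
  frequent.
- *Threshold scans*: neutral schedule, defaults w = 0.1, b = 10, c = 1,
  m = 0.01.  Each maturity-bound column N admits all strategies with
  maturity ≤ N; this pooling convention is recorded in each record.
- *Combined scans*: one perturbation (χ_n ∈ {0.4, 1.5}) plus a
  threshold; records flag unique optima that neither single-effect scan
  produces.
- *Benefit/cost and switching scans* vary b/c (cost fixed) and m.

Co-optimality uses a relative tie tolerance of 1e−6 on λ; every record
retains all raw rates so ties can be audited at any tolerance.
`classify_category` labels records as multiple-optima, symmetric-binary
((N/2)+(N/2) or the near-even split), asymmetric-binary ((N−k)+k),
no-benefit (k ≥ N), or other.

### Near-ties at k = 1

At k = 1 and N ≤ 8 the model yields a *numerically* unique optimum
(1+1) whose lead over 55 further strategies is only ~0.06–0.2% in λ —
far below any biologically meaningful resolution but above the 1e−6 tie
tolerance.  We report this as "multiple optima at figure resolution":
56 of 58 strategies lie within 0.2% of the maximum, whereas for
k ≥ 3 the unique optimum stands clear even at that loose tolerance
(at k = 2 a handful of binary splits trail 4+4 by ~0.1%).  Records and
the k = 1 example script expose the raw gaps.

### Adverse perturbations and n+1

Under adverse single perturbations combined with thresholds, strategies
of the form n+1 are never uniquely optimal except 7+1 at high k: at
k = 7 (for every perturbed size) and, in this implementation, also at
(χ_6 = 1.5, k = 6), where 7+1 beats 6+2 by ~0.8% because the size-6
penalty hits 6+2's two growth paths but only 7+1's single-celled
newborn.  The second cell is a genuine, if marginal, model outcome.

## Numerical choices and degenerate inputs

- Partition enumeration is descending-lexicographic and stable, so
  result tables are reproducible; the no-fragmentation "strategy" (one
  part) is excluded everywhere.
- Matrices use the layered composition ordering (n_A descending within
  each size); stage structures and offspring matrices are memoized per
  (N, parameters, schedule).
- N < 2 (no strategy), parts exceeding the parent, composition/strategy
  size mismatches, χ ≤ 0, γ ≤ 0, k < 1, m outside [0, 1], w < 0 and
  b − c ≤ 0 under active selection all raise errors naming the
  violated constraint.
- Spectral radii come from dense eigenvalue decomposition (matrices are
  at most 9×9 for N ≤ 8).

## Scope and limitations

- No cell death, exactly two phenotypes, discrete size (cell count),
  density-independent growth: the growth rate is the sole fitness
  measure, and invasion in mixed populations is out of scope.
- One deterministic strategy per population; mixed or stochastic
  fragmentation modes are not modelled.
- The Monte-Carlo simulator emulates exactly the model's stochasticity
  (division choice, switching, fragmentation) with deterministic stage
  durations; it does not add demographic noise in timing, so agreement
  between its estimates and the matrix solver validates the projection
  construction, not robustness of the model to features of real
  biological data (measurement error, variable environments, density
  dependence).
- Analytical proofs of the binary-splitting optimality are not
  re-derived; the claims are verified empirically on the scanned grids
  (N ≤ 8, k ≤ 8, χ ∈ [0.4, 1.5]).
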