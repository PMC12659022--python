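# Methods

## Model and conventions

The package works with the exchange part of a spin Hamiltonian,

    H_ex = Σ_{i<j} (−2 g_ij) Ŝ_i · Ŝ_j ,

where `g_ij` (Ha) is the exchange parameter between magnetic sites or
localized orbitals. Model lattices use the antiferromagnetic convention
`g = −J` with `J > 0`, so `H_ex = Σ 2J Ŝ_i·Ŝ_j` reproduces the standard
antiferromagnetic Heisenberg form up to the overall factor 2 absorbed in
the coupling scale; ab initio exchange integrals `(ij|ji)` read from
FCIDUMP files are positive and invert the energetic order of the CSFs.
All quantities the package optimizes or correlates — min/max/spread of
diagonal elements, Pearson coefficients, L4 norms — are invariant under a
constant shift of the diagonal and (for the correlations) under positive
rescaling, so the convention affects no reported statistic. Under this
convention the CSF-independent constant of the diagonal-element formula
is identically zero and `diagonal_element` equals the exact CSF-basis
diagonal, which the test suite asserts directly.

Spins are carried as integers `2S` throughout; CSFs are strings over
`u`/`d` with optional closed-shell markers `2`/`0` that are transparent to
the cumulative-spin arithmetic. Positions and site labels are 1-based in
every user-facing structure and 0-based internally.

## The closed-form exchange weight T_ij

`t_factor` implements `T_ij = −2⟨m|Ŝ_i·Ŝ_j|m⟩` as a product over the
genealogical coupling levels between i and j (formula in the README and
module docstring). It is derived by applying the Landé projection theorem
level by level to the intermediate-spin chain: within the multiplet of
cumulative spin `J_k`, the vector operator `Ŝ_i` is proportional to
`Ĵ_k`, with proportionality `⟨Ŝ_i·Ĵ_k⟩ / (J_k(J_k+1))`, and each coupling
step updates `⟨Ŝ_i·Ĵ_k⟩` by a rational factor in `b_k = 2J_k`. The
published rendering of this product is typographically ambiguous in its
grouping, so the implemented form was certified instead: an independent
determinant-expansion oracle (sequential Clebsch–Gordan coupling)
reproduces every `T_ij` for all CSFs of all sectors up to 10 sites to
5·10⁻¹⁵. The sign structure `(−1)^{d_i+d_j+1}` is checked exhaustively;
`T_ij` vanishes exactly when `b_k = 0` anywhere in `[i, j)`, i.e. when the
two spins sit in decoupled singlet segments. A zero `T` with antiparallel
endpoints is therefore possible; "antiparallel couplings give positive
unmasked terms" holds in the weak sense `T ≥ 0`.

Closed-shell orbitals between i and j leave `b` unchanged and contribute a
unit factor, which is why enlarging an active space by doubly occupied
ligand orbitals changes no fitness score — orderings transfer unchanged.

## Exact reference layer

CSFs are expanded in the `M_S = S` determinant sector. For Heisenberg
Hamiltonians that sector contains every block `S' ≥ S` exactly once, so
`C^T H_det C` over the sector CSFs isolates the spin-S block without any
off-diagonal GUGA segment algebra. The 28 projected pair operators
`C^T(Ŝ_i·Ŝ_j)C` of an 8-site sector are precomputed once (LRU-cached),
after which the Hamiltonian of any reordered system is a 28-term linear
combination; the 40 320-ordering scans batch these into stacked `eigh`
calls and run in seconds.

Numerical choices: dense eigensolver below 2000 basis states, Lanczos with
a fixed all-ones start vector above; ground-state sign fixed by making the
largest-magnitude coefficient positive (ties to the lowest index);
degenerate lowest pairs resolve to the solver's first root. The L4 norm
defaults to `(Σc⁴)^{1/4}`; the rootless alternative `Σc⁴` is behind a
flag. Both conventions were computed for the 8-site validation scan; the
rooted one reproduces the published correlation table to all four printed
decimals, the rootless one does not (Min-E −0.8547 instead of −0.8490),
which settles the convention.

## Ordering symmetries

Two transformations provably leave every scan record (e_min, e_max, ΔE,
ground energy, L4) unchanged: relabelling sites by an automorphism of the
weighted coupling graph, and reversing the ordering sequence. Cyclic
rotation of the sequence — a candidate identification suggested by the
published 8!/8 count — was tested numerically and does **not** preserve
the records, so the package identifies orbits under the verified group
only. That action is not free (palindromic orderings have smaller orbits),
so representatives carry orbit multiplicities and symmetry-reduced
correlation studies use orbit-size-weighted Pearson coefficients, which
equal the full-set coefficients exactly. Default studies simply scan all
n! orderings.

## Fitness functions

* `delta_e_diag`: max − min of the diagonal elements over the collinear
  skeleton (one `u`/`d` per site, each carrying the full local moment).
  Site-level prefix validity is equivalent to orbital-level validity of
  the block expansion (property-tested for local spins 1/2…2). For local
  spin > 1/2 the energies are evaluated on the open-shell skeleton; paired
  orbitals shift all diagonals equally and are dropped.
* `sms_fitness`: minus the diagonal element of the Néel-consistent CSF.
  The sublattice containing site 1 receives `u`. Orderings with invalid
  CSFs get score −inf, a false validity flag and zero selection weight;
  they are kept in the population rather than repaired or resampled
  (resampling was tried and did not change the convergence statistics).

Both have vectorized population evaluators; the S–MS one uses prefix
products of the per-level factors with explicit zero tracking, so a whole
200-chromosome generation costs a few hundred microseconds.

## Genetic algorithm

Per generation: score → elites → roulette pool (size `N_T − N_E`, sampled
with replacement from the whole population) → random pairing → order
crossover, replaced entirely by cluster shuffling every `cs_period`-th
generation → swap mutation of all children (cluster-shuffle generations
included) → merge. Defaults: `N_E = 0.1·N_T` (both even), cluster reversal
probability 0.1, CS period 5. Selection weights are
`score − min(valid) + ε` with `ε = 10⁻⁸ · range` (uniform when all valid
scores tie). Termination is a fixed generation budget, optionally with an
early stop at a known target score.

Elites are deduplicated by genotype: the `N_E` best *distinct* orderings
are copied, not the `N_E` best rows. This choice was made after direct
comparison on the 20-site chain benchmark: with duplicate elites the
population collapses onto one genotype and runs stagnate for thousands of
generations on concatenations of two locally good motifs (≈70% of seeds
reach the optimum); with distinct elites competing motifs survive long
enough for crossover to assemble the global optimum (≈95% of seeds, median
≈450 generations). Raw-proportional selection and invalid-child rejection
were tested as alternatives and changed nothing.

In the order crossover, the copied segment is placed at a random position
in the child (not necessarily its original one), so identical parents can
produce children different from themselves; both children of an identical
pair coincide. Crossover-only evolution (m = 0, no CS) therefore still
carries some intrinsic randomness, but plateaus quickly in practice.

## Study conditions and problem sizes

The validation studies mirror the published conditions: open-boundary
NN chains with `J = 0.5 Ha` (8 and 20 sites), the J1–J2 chain with
`J2/J1 = 0.5` (the absolute scale is irrelevant to the correlations), the
2×11 ladder, and the 20-site GA benchmark at `N_T = 200`, `N_E = 20`,
CS period 2, mutation 0, 4000 generations, 100 seeds. The statistical GA
test stops a run as soon as it reaches the known optimal fitness, which
changes no outcome. The qualitative comparison against `m = 1.00` random
search uses 15 seeds × 600 generations per variant — enough for the best
GA variant to be near-converged while random search is far behind, so the
one-sided mean comparison is unambiguous at a fraction of the full-budget
cost.

## What the exact layer does and does not show

All validation is on Heisenberg-type exchange Hamiltonians and a synthetic
positive-exchange FCIDUMP fixture. Real ab initio CSF spaces add hopping
configurations outside the van Vleck–Sherman subspace, metal–ligand
charge transfer, and constant (Coulomb/one-body) terms that this package
deliberately keeps out of its fitness functions; passing tests show the
ordering machinery and the exchange-diagonal algebra are correct, not that
any particular ab initio system's absolute energies are reproduced.
Published absolute energies for the 2×11 ladder and the P-cluster depend
on integral sets and coupling conventions not derivable here and are out
of scope. Off-diagonal GUGA matrix elements are never evaluated in closed
form — the determinant oracle supplies them for small systems only, which
caps the exact layer at desk scale (≤ 10 sites for factorial scans,
≤ 14 for single diagonalizations).
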