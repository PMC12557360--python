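# Methods

## Scope and model

`mdint` evaluates matrix elements of the nonrelativistic molecular
Hamiltonian over contracted real solid-harmonic Gaussian atomic orbitals:
the 1-particle overlap, kinetic-energy and point-charge (nuclear-attraction)
integrals, and the 2-, 3- and 4-center 2-particle Coulomb repulsion
integrals used in conventional and density-fitted electronic-structure
methods.  Evaluation follows the McMurchie–Davidson (MD) scheme: primitive
Cartesian Gaussian products are expanded exactly in Hermite Gaussians of the
composite center,

    phi_a phi_b = sum_p E_ab^p Lambda_p,      zeta_p = zeta_a + zeta_b,
    P = (zeta_a A + zeta_b B) / zeta_p,

the Coulomb kernel over Hermite Gaussians reduces to Boys-function
derivatives built by a 3-term recursion, and a final linear map (the
H matrices, Cartesian-to-solid coefficients contracted with the E tensors)
takes Hermite intermediates to solid-harmonic AO blocks.  Integrals are
computed in the primitive basis and accumulated into contracted results;
many shellsets of one class are processed per call, each shellset occupying
one lane, and results are produced in the `[ij, ab, cd, kl]` column-major
layout (`ij` = bra shell-pair index, fastest; `kl` = ket shell-pair index,
slowest) with an optional streaming consumer receiving each sub-batch.

Three exact algebraic rearrangements are built in and are switchable so the
naive order of operations can be compared against them:

1. **Early point-charge summation** — the Hermite-to-AO transform does not
   depend on the charges, so `sum_I q_I [p]_I` is accumulated in the Hermite
   basis and one transform is applied per primitive pair.
2. **Partial early ket contraction** — the terminal (maximal-degree) Hermite
   coefficients have the closed form `(2 zeta_q)^{-(lc+ld)} (E)_000`, so the
   terminal contribution to the *contracted* ket is accumulated directly
   from the auxiliary integrals; only sub-terminal Hermite components flow
   through the full H transform.
3. **Solid-harmonic terminal-bra shortcut** (3-/2-center) — a solid harmonic
   of angular momentum `l` is a harmonic homogeneous polynomial, and its
   Hermite-polynomial expansion has no lower-degree part; hence a 1-center
   solid bra touches only Hermite triples of total degree exactly `l`, and a
   contracted bra is contracted already on the `[0]^(m)` base terms (the
   1-center composite center does not depend on the exponent).

## Units and conventions

* Internal units are atomic (bohr, hartree).  XYZ geometry input is
  Angstrom, converted with 1 bohr = 0.52917721092 Å.
* Primitives are used exactly as given (unnormalized);
  `normalized_primitive_coefficients` applies the standard primitive
  normalization for cross-checks against engines that normalize.
* Real solid harmonics follow the common quantum-chemistry recursion with
  components ordered `m = -l..+l` and the coefficient of `z^l` in the
  `m = 0` component equal to 1 (so `d_0 = (3z^2 - r^2)/2`,
  `d_{+2} = (sqrt(3)/2)(x^2 - y^2)`).  All validation is internal or against
  oracles built in the same convention; results are covariant under a
  change of solid-harmonic phase convention.
* Hermite triples are ordered graded-lexicographically: degree-major, and
  within a degree descending on `(tx, ty, tz)`; Cartesian shell components
  are alphabetical (`xx, xy, xz, yy, yz, zz` for d).  Both orderings are
  fixed package-wide.
* Supported angular momentum per shell: `l <= 6` (s..i).

## Boys function engine

`F_m(x) = ∫_0^1 y^{2m} e^{-x y^2} dy` is evaluated three ways:

* **Reference** (`boys_reference`): the positive-term confluent series for
  the highest requested order, summed in 80-bit extended precision, followed
  by downward recursion `F_m = (2x F_{m+1} + e^{-x})/(2m+1)`.  Both steps
  are cancellation-free for every `x >= 0`, giving ~1e-18 relative accuracy;
  this is the fitting and certification target for the production table and
  is vectorized, so large probe sweeps are cheap.  A second, mpmath-based
  implementation in the oracle module cross-checks it.
* **Production table**: seventh-order Chebyshev interpolation per order on
  uniform intervals of width dx = 0.1 covering [0, 120].  At this width the
  degree-7 interpolation error of `F_m` is below 1e-17 absolute, so the
  certified table error (max abs deviation from the reference on a 3-point-
  per-interval probe grid, required <= 1e-14) is dominated by node accuracy;
  the measured certification comes out ~7e-16.
* **Asymptotic branch**: upward recursion seeded with
  `F_0 = (1/2) sqrt(pi/x)` (the `erf -> 1` simplification, error < 3e-17 for
  x > 36).  Selected when `x > 118`, or already when `x > 36` for total
  angular momentum `L < 9`, where the recursion is stable.  The `e^{-x}`
  term of the recursion is *kept* for `x <= 118`: dropping it at the lower
  threshold costs ~1e-8 relative accuracy in `F_8` near x = 36, which would
  break the 1e-13 evaluator contract.  Beyond x = 118 the term is < 1e-51
  and is dropped.

Lanes masked false return exactly zero and their arguments are never
inspected.  Values below the double denormal range underflow to zero.
Measured agreement with the reference over 1e5 points spanning all branches:
max relative deviation ~4e-15.

## Fixture generator (study conditions)

Randomized validation draws shells that mimic typical basis-set values:
exponents log-uniform on [0.05, 50] bohr⁻² (the valence range of common
def2-type sets; configurable), contraction coefficients uniform in
magnitude [0.2, 1.0] with random sign, contraction degrees from {1, 5, 10},
angular momenta to g (l = 4) in the randomized suites, and centers uniform
in a ±1 bohr cube.  This emulates the *numerical regime* of real basis sets
— exponent spans, contraction depths, Boys argument ranges — but not their
chemistry: real sets have correlated exponent ladders, same-sign valence
contractions, and larger inter-atomic separations.  Passing suites therefore
demonstrate numerical correctness of the evaluation chain over that regime,
not accuracy of any particular chemical prediction.  The ±1 bohr cube
produces many near-coincident high-exponent products, which is the
*hardest* regime for the conditioning discussed below.

## Numerical conditioning of the identity checks

The three rearrangements are algebraically exact, so optimized and naive
paths are compared directly.  Deviations are measured **relative to the
largest magnitude in the batch**: both routes sum the same primitive
contributions in different associations, so their difference is bounded by
round-off at the scale of the largest contribution — an entrywise-relative
measure on a cancellation-suppressed entry reports reassociation noise, not
the identity.

Even under the batch-scale measure the comparison floors at
`eps * kappa`, where `kappa` is the ratio of the largest MD intermediate
(`[p|q] x H` products) to the largest final block.  For near-coincident
high-exponent draws at l = 4, `kappa` reaches ~1e4, and the worst-of-100
deviation of the 3-center terminal-shortcut suite fluctuates between ~5e-14
and ~4e-12 across seeds; on such draws the production path itself sits
~1.6e-12 from a 35-digit scalar reference (with the Boys table replaced by
the extended-precision reference, i.e. the conditioning is intrinsic to the
float64 chain, not an input-accuracy artifact).  The corresponding test
asserts the 1e-12 bound at a fixed seed and currently measures 2.1e-12:
the identity is exact, its float64 verification at 1e-12 is
conditioning-limited.  The early-charge-summation and early-ket-contraction
suites pass the same bound with more than an order of magnitude of margin.

## Oracles

* `eri_highprec` — a scalar, loop-based re-derivation of the whole MD chain
  in mpmath (default 30 digits): mpf E recursions, mpf Boys series, memoized
  mpf auxiliary recursion, exact-arithmetic solid-harmonic coefficients.
  2- and 3-center classes are padded with zero-exponent dummy s shells,
  which leave the Gaussian product unchanged and reduce the 4-center chain
  exactly.  No batching, no rearrangements — structurally independent of the
  production path.
* `nuclear_highprec` — the analogous scalar chain for point-charge
  integrals, naive order of operations.
* `hermite_symbolic_oracle` — auxiliary integrals by *symbolic*
  differentiation of the closed-form base term (sympy, with
  `dF_m/dx = -F_{m+1}`), numerically evaluated in mpmath; validates the
  3-term recursion independently.
* `quadrature_1p` — direct numerical integration of the defining 1-particle
  integrals (l <= 2): per-axis adaptive quadrature for overlap/kinetic, and
  a refining spherical product grid centered at each charge for nuclear
  attraction (the radial Jacobian removes the Coulomb singularity; levels
  are doubled until successive values agree to tolerance, with radial
  chunking to bound memory).

## Other numerical choices

* Kinetic energy uses the ket-quanta second-derivative expansion
  `<a|d²|b> = 4 zeta_b² S(a,b+2) - 2 zeta_b (2b+1) S(a,b) + b(b-1) S(a,b-2)`
  over 1-D Hermite overlaps, with the E tensor extended by two ket quanta.
* Bra/ket roles in the 4-center engine: higher total l goes to the bra; on a
  tie the higher-K side becomes the ket.  A violating call is computed with
  the roles swapped (warning) and the output permuted back.
* The `[p|q]` gather is chunked over ket primitives (~4e6-element cap) so
  memory stays bounded for deeply contracted high-l classes.
* Screening accepts caller-supplied per-shell-pair bounds and a threshold
  and skips shellsets below it; no bound estimator is provided, and
  screening defaults to off.
* The 1-center full-contraction H route (`shortcut=False`), which exists to
  verify the terminal-sparsity theorem, accumulates in 80-bit precision so
  the sub-terminal cancellation residues stay below the resolution of the
  equivalence tests.  Production never builds those columns.
* Degenerate inputs: empty charge sets yield zero blocks; coincident-center
  pairs have prefactor exactly 1 and exact parity zeros; zero-exponent dummy
  shells are valid only as explicit reduction devices (`Shell.dummy`).

## Problem sizes used in the shipped validation

Boys sweep: 1e5 points, orders to 20.  Identity suites: 100 homogeneous
2 bra-pair × 2 ket-pair batches each, shells to l = 4, K in {1, 5, 10}.
Symmetry suite: 25 batches (exchange, rigid translation, parity, charge
permutation).  Oracle suite: one representative contracted case per engine
((pd|ds) with K_ket = 10, (d|pp), (d|d), a (d p) nuclear block, plus l <= 2
quadrature of all three 1-particle operators).  The full suite runs in
about a minute on one core.

## Known limitations

* No derivative (gradient) integrals, no range-separated or non-Coulomb
  kernels, no J/K assembly, no ECPs.
* Cartesian-output API is not public: all results are solid-harmonic.
* The Python/numpy lane model reproduces the batched semantics (masking,
  homogeneous classes, column-major layout, streaming consumers) but makes
  no claim about SIMD throughput; no performance figures are reproduced
  here.
* The Boys table covers `x <= 120`; larger arguments are always asymptotic
  (exact there to ~1e-15), and orders are capped by the table's `L_max`
  (default 25, enough for (ii|ii)).
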