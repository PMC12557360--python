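# mdint

Batched McMurchie–Davidson evaluation of 1- and 2-particle Gaussian
atomic-orbital integrals.

Molecular electronic-structure methods spend much of their time computing
matrix elements over contracted Gaussian basis functions: the overlap S,
kinetic energy T, the Coulomb potential of point charges V, and the 2-, 3-
and 4-center electron-repulsion integrals

    [ab|cd] = ∫∫ φa(r1) φb(r1) φc(r2) φd(r2) / |r1 − r2|  dr1 dr2

used directly or through density fitting.  `mdint` implements the
McMurchie–Davidson scheme for all of these over real solid-harmonic shells
up to l = 6: Gaussian products are expanded exactly in Hermite Gaussians
(coefficients E by 3-term recursion), the Coulomb kernel reduces to Boys
functions F_m(x) whose derivatives are built by the auxiliary recursion
[r+1_i]^(m) = r_i [r−1_i]^(m+1) + (P−Q)_i [r]^(m+1), and H matrices carry
Hermite intermediates directly to solid-harmonic AO blocks.  Batches of
shellsets of one class are processed lane-wise and emitted in a
column-major `[ij, ab, cd, kl]` layout with an optional streaming consumer.

Three exact rearrangements of the chain are implemented and verified
against their naive counterparts:

* **early point-charge summation** — charges are summed in the Hermite
  basis, one AO transform per primitive pair;
* **partial early ket contraction** — terminal Hermite components, whose
  coefficient is the closed form (2ζ_q)^−(lc+ld)·(E)₀₀₀, are contracted
  directly from the auxiliary integrals;
* **solid-harmonic terminal-bra shortcut** — a 1-center solid bra touches
  only Hermite triples of total degree exactly l (harmonic polynomials have
  no lower-degree Hermite content), and a contracted bra contracts already
  on the [0]^(m) base terms.

A three-layer oracle stack (80-bit-precision Boys reference, 30+-digit
mpmath scalar re-derivation of the whole chain, symbolic differentiation,
and direct quadrature of the defining integrals) validates every engine;
see `docs/methods.md` for conventions, numerics and limitations.

## Worked example

Overlap and repulsion integrals for an s shell at the origin and a p shell
1 bohr up the z axis (unnormalized unit-coefficient primitives, ζ = 1.0 and
0.8):

```python
import numpy as np
from mdint import Shell, ShellPair, overlap_batch, eri4_batch

s = Shell(center=[0, 0, 0], l=0, exponents=[1.0], coefficients=[1.0])
p = Shell(center=[0, 0, 1.0], l=1, exponents=[0.8], coefficients=[1.0])

bra = ShellPair.from_shells(s, p)
print(overlap_batch([bra]).values[0])
# [[ 0.         -0.82134152  0.        ]]

ket = ShellPair.from_shells(s, s)
res = eri4_batch([bra], [ket])
print(res.cls, res.array[0, :, 0, 0])
# spss [ 0.        -1.8941189  0.       ]
```

Only the m = 0 (p_z) component is nonzero — the s·p product is
axially symmetric about z — and its sign is negative because the p lobe
pointing at the s function is the negative one; the repulsion integral
[s p_z|s s] = −1.894 hartree·bohr⁻¹-scaled accordingly.  The command-line
tool exposes the same engines, e.g.

```sh
$ mdint boys --x 0 --m 2      # F_0..F_2(0) = 1, 1/3, 1/5
1
0.333333333333333
0.2
$ mdint validate --classes ss,dpp --seed 7   # engines vs mpmath oracle
```

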