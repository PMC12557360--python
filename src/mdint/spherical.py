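"""Real solid harmonics and Hermite -> solid-harmonic transforms.

Real solid harmonics ``S_lm`` are the harmonic homogeneous polynomials that
turn a shell of ``(l+1)(l+2)/2`` Cartesian Gaussians into ``2l+1`` pure
functions.  We use the standard quantum-chemistry convention built from the
recursions

    S_00 = 1,   S_11 = x,  S_1,-1 = y,  S_10 = z
    S_{l+1,l+1}    = sqrt(2^{d_l0} (2l+1)/(2l+2)) (x S_ll - (1-d_l0) y S_l,-l)
    S_{l+1,-(l+1)} = sqrt(2^{d_l0} (2l+1)/(2l+2)) (y S_ll + (1-d_l0) x S_l,-l)
    S_{l+1,m} = ((2l+1) z S_lm - sqrt((l+m)(l-m)) r^2 S_{l-1,m})
                / sqrt((l+1+m)(l+1-m))

(``d_l0`` the Kronecker delta), which give e.g. ``S_20 = (3z^2 - r^2)/2`` and
``S_22 = (sqrt(3)/2)(x^2 - y^2)``.  Components are ordered ``m = -l..+l``.
Every row is a harmonic polynomial (annihilated by the Laplacian); this is
what makes the terminal-bra shortcut of the 3-/2-center engines exact.

The H matrices map primitive Hermite Gaussians directly to primitive real
solid Gaussians by contracting the Cartesian-to-solid coefficients with the
Hermite expansion coefficients E:

    1-center:  H_a^p  = sum_a  C_{l m}^a E_a^p
    2-center:  H_ab^p = sum_a C^a sum_b C^b E_ab^p

For a *solid-harmonic* 1-center function only the terminal Hermite triples
(total degree exactly ``l``) survive: a harmonic polynomial's Hermite-
polynomial expansion has no lower-degree part.  ``hmatrix`` therefore builds
the 1-center H from the closed-form terminal coefficient
``(2 zeta)^{-l}`` by default; the full-contraction route is kept for
verifying that equivalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .ecoeff import ETensor
from .shell_model import (
    InputError,
    L_MAX,
    Shell,
    ShellPair,
    cartesian_components,
    herm_exact_count,
    hermite_index,
    hermite_triples,
    shell_dims,
)

__all__ = ["CMatrix", "HMatrix", "solid_coeffs", "solid_polynomials", "hmatrix"]

Monomial = tuple[int, int, int]
Poly = dict[Monomial, float]


def _poly_mul_axis(p: Poly, axis: int) -> Poly:
    return {
        (m[0] + (axis == 0), m[1] + (axis == 1), m[2] + (axis == 2)): c
        for m, c in p.items()
    }


def _poly_mul_r2(p: Poly) -> Poly:
    out: Poly = {}
    for axis in range(3):
        for m, c in _poly_mul_axis(_poly_mul_axis(p, axis), axis).items():
            out[m] = out.get(m, 0.0) + c
    return out


def _poly_add(p: Poly, q: Poly, cq: float) -> Poly:
    out = dict(p)
    for m, c in q.items():
        out[m] = out.get(m, 0.0) + cq * c
    return out


@lru_cache(maxsize=None)
def solid_polynomials(l: int) -> tuple[Poly, ...]:
    """Monomial expansions of ``S_lm`` for ``m = -l..+l``."""
    if l < 0:
        raise InputError("l must be non-negative")
    if l == 0:
        return ({(0, 0, 0): 1.0},)
    if l == 1:
        return ({(0, 1, 0): 1.0}, {(0, 0, 1): 1.0}, {(1, 0, 0): 1.0})
    lower = solid_polynomials(l - 1)
    lower2 = solid_polynomials(l - 2)

    def S(ll: int, m: int) -> Poly:
        return (lower if ll == l - 1 else lower2)[m + ll]

    lm1 = l - 1
    out: list[Poly] = []
    for m in range(-l, l + 1):
        if abs(m) == l:
            f = math.sqrt((2.0 if lm1 == 0 else 1.0) * (2 * lm1 + 1) / (2 * lm1 + 2))
            top, bot = S(lm1, lm1), ({} if lm1 == 0 else S(lm1, -lm1))
            if m == l:
                p = _poly_add(_poly_mul_axis(top, 0), _poly_mul_axis(bot, 1), -1.0)
            else:
                p = _poly_add(_poly_mul_axis(top, 1), _poly_mul_axis(bot, 0), 1.0)
            out.append({k: f * c for k, c in p.items()})
        else:
            num = {k: (2 * lm1 + 1) * c for k, c in _poly_mul_axis(S(lm1, m), 2).items()}
            s = math.sqrt((lm1 + m) * (lm1 - m))
            if s:
                num = _poly_add(num, _poly_mul_r2(S(l - 2, m)), -s)
            den = math.sqrt((l + m) * (l - m))
            out.append({k: c / den for k, c in num.items()})
    return tuple(out)


@dataclass(frozen=True)
class CMatrix:
    """Cartesian -> real-solid-harmonic coefficients for one ``l``.

    ``matrix[m + l, cart]`` with Cartesian components in the alphabetical
    order of :func:`mdint.shell_model.cartesian_components`.
    """

    l: int
    matrix: np.ndarray


@lru_cache(maxsize=None)
def solid_coeffs(l: int) -> CMatrix:
    """Coefficient matrix ``(2l+1) x (l+1)(l+2)/2`` in the package convention."""
    if not 0 <= l <= L_MAX:
        raise InputError(f"l must be in [0, {L_MAX}]")
    comps = cartesian_components(l)
    col = {c: j for j, c in enumerate(comps)}
    mat = np.zeros((2 * l + 1, len(comps)))
    for row, poly in enumerate(solid_polynomials(l)):
        for mono, c in poly.items():
            mat[row, col[mono]] = c
    return CMatrix(l, mat)


@dataclass(frozen=True)
class HMatrix:
    """Hermite -> solid transform for a shell (``1c``) or shell pair (``2c``).

    ``values`` has shape ``(n_solid, n_herm)`` for the 1-center kind and
    ``(K, n_solid_pair, n_herm)`` per primitive pair for the 2-center kind;
    Hermite columns follow the graded triple ordering.  The solid pair row
    index is ``ma_index * (2 l_b + 1) + mb_index``.
    """

    kind: str
    values: np.ndarray


def hmatrix(target, E: ETensor | None = None, shortcut: bool = True) -> HMatrix:
    """Assemble the H matrix for a :class:`Shell` or :class:`ShellPair`.

    For a single (1-center) shell the solid-harmonic H is terminal: columns
    at Hermite triples of total degree ``< l`` vanish identically.  With
    ``shortcut=True`` (default) those zeros are exact by construction; with
    ``shortcut=False`` the full contraction of Eq-style ``C x E`` is carried
    out (the two agree to round-off, which the test suite asserts).

    For a shell pair, ``E`` defaults to the pair's own coefficients and the
    result carries one matrix per primitive pair.
    """
    if isinstance(target, Shell):
        return _hmatrix_1c(target, E, shortcut)
    if isinstance(target, ShellPair):
        return _hmatrix_2c(target, E)
    raise InputError(f"unsupported target {type(target).__name__}")


def _hmatrix_1c(shell: Shell, E: ETensor | None, shortcut: bool) -> HMatrix:
    from .ecoeff import ecoeff_1c

    l = shell.l
    C = solid_coeffs(l).matrix
    triples = hermite_triples(l)
    idx = hermite_index(l)
    nh = shell_dims(l)[2]
    if shortcut:
        # terminal closed form: column at triple a equals C[:, a] * (2 zeta)^-l
        H = np.zeros((shell.K, 2 * l + 1, nh))
        scale = (2.0 * shell.exponents) ** -l  # (K,)
        for j, comp in enumerate(cartesian_components(l)):
            H[:, :, idx[comp]] = scale[:, None] * C[None, :, j]
        return HMatrix("1c", H)
    # full contraction: the sub-terminal columns cancel exactly in real
    # arithmetic; accumulate in extended precision so the residues of that
    # cancellation stay far below the terminal values (this route exists to
    # verify the shortcut, not for production)
    H = np.zeros((shell.K, 2 * l + 1, nh), dtype=np.longdouble)
    Cl = C.astype(np.longdouble)
    for k, z in enumerate(shell.exponents):
        if E is not None and shell.K == 1:
            e = E.data.astype(np.longdouble)
        else:
            e = _ecoeff_1c_ld(l, float(z))
        for j, (ax, ay, az) in enumerate(cartesian_components(l)):
            for t_i, (px, py, pz) in enumerate(triples):
                if px <= ax and py <= ay and pz <= az:
                    H[k, :, t_i] += Cl[:, j] * e[ax, px] * e[ay, py] * e[az, pz]
    return HMatrix("1c", H.astype(np.float64))


def _ecoeff_1c_ld(l: int, zeta: float) -> np.ndarray:
    """1-center E recursion in extended precision (verification route only)."""
    E = np.zeros((l + 1, l + 2), dtype=np.longdouble)
    E[0, 0] = 1.0
    inv2z = np.longdouble(1.0) / (2.0 * np.longdouble(zeta))
    for a in range(l):
        for p in range(a + 2):
            E[a + 1, p] = (E[a, p - 1] * inv2z if p >= 1 else 0.0) + (p + 1) * E[
                a, p + 1
            ]
    return E[:, : l + 1]


@lru_cache(maxsize=None)
def _gather_indices(l_a: int, l_b: int):
    """Index arrays mapping (cart_a, cart_b, triple) -> per-axis E entries."""
    ca = np.array(cartesian_components(l_a))  # (na, 3)
    cb = np.array(cartesian_components(l_b))
    tr = np.array(hermite_triples(l_a + l_b))  # (nt, 3)
    return ca, cb, tr


def pair_etensor_product(E: ETensor, l_a: int, l_b: int) -> np.ndarray:
    """Dense 3-axis product ``E_ab^p`` of shape ``(K, n_cart_a, n_cart_b, n_herm)``."""
    ca, cb, tr = _gather_indices(l_a, l_b)
    d = E.data  # (3, K, la+1, lb+1, L+1)
    out = (
        d[0][:, ca[:, 0][:, None, None], cb[:, 0][None, :, None], tr[:, 0][None, None, :]]
        * d[1][:, ca[:, 1][:, None, None], cb[:, 1][None, :, None], tr[:, 1][None, None, :]]
        * d[2][:, ca[:, 2][:, None, None], cb[:, 2][None, :, None], tr[:, 2][None, None, :]]
    )
    return out


def _hmatrix_2c(pair: ShellPair, E: ETensor | None) -> HMatrix:
    from .ecoeff import ecoeff_2c_pairs

    a, b = pair.shells
    if E is None:
        E = ecoeff_2c_pairs(a.l, b.l, pair.zeta_a, pair.zeta_b, a.center, b.center)
    E3 = pair_etensor_product(E, a.l, b.l)  # (K, na, nb, nt)
    Ca = solid_coeffs(a.l).matrix
    Cb = solid_coeffs(b.l).matrix
    H = np.einsum("pa,qb,kabt->kpqt", Ca, Cb, E3, optimize=True)
    K, nt = E3.shape[0], E3.shape[3]
    return HMatrix("2c", H.reshape(K, a.nsolid * b.nsolid, nt))


def terminal_solid_map(l_a: int, l_b: int) -> np.ndarray:
    """Terminal Cartesian-pair -> solid-pair map ``T[solid_pair, exact-triple]``.

    ``T[(ma,mb), t] = sum_{c+d=t} C^c_{ma} C^d_{mb}``: the coefficients of
    the degree-``l_a+l_b`` Hermite triples in the solid pair, excluding the
    common factor ``(2 zeta_p)^{-(la+lb)} (E)_{000}``.  This is what the
    early-contraction ket path and the solid-bra shortcut consume.
    """
    L = l_a + l_b
    Ca = solid_coeffs(l_a).matrix
    Cb = solid_coeffs(l_b).matrix
    comps_a = cartesian_components(l_a)
    comps_b = cartesian_components(l_b)
    # index exact-degree triples within their own (contiguous, trailing) block
    exact = [t for t in hermite_triples(L) if sum(t) == L]
    pos = {t: j for j, t in enumerate(exact)}
    T = np.zeros((Ca.shape[0] * Cb.shape[0], len(exact)))
    for ia, c in enumerate(comps_a):
        for ib, d in enumerate(comps_b):
            t = (c[0] + d[0], c[1] + d[1], c[2] + d[2])
            T[:, pos[t]] += np.outer(Ca[:, ia], Cb[:, ib]).ravel()
    assert len(exact) == herm_exact_count(L)
    return T
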