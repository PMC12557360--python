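"""Independent reference implementations used to validate the engines.

Nothing here shares code with the production modules beyond the domain
types: the Boys function is summed in arbitrary-precision arithmetic, the
Hermite expansion/auxiliary recursions are re-derived scalar-by-scalar in
``mpmath``, the solid-harmonic coefficients are rebuilt from the recursion
in exact arithmetic, and the 1-particle integrals can be checked against
direct numerical quadrature of their defining 3-D integrals.

These oracles are orders of magnitude slower than the engines and are meant
for small shellsets only.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import mpmath as mp
import numpy as np
from scipy.integrate import quad

from .shell_model import ChargeSet, Shell, ShellPair, cartesian_components

__all__ = [
    "ComparisonReport",
    "boys_mp",
    "eri_highprec",
    "nuclear_highprec",
    "hermite_symbolic_oracle",
    "quadrature_1p",
    "compare",
]


# ---------------------------------------------------------------------------
# arbitrary-precision Boys


def boys_mp(x, m_max: int):
    """``F_0..F_{m_max}`` at the current mpmath precision.

    Positive-term series for the top order followed by downward recursion;
    both steps are cancellation-free for any ``x >= 0``.
    """
    x = mp.mpf(x)
    M = int(m_max)
    t = mp.mpf(1) / (2 * M + 1)
    total = t
    k = 0
    eps = mp.mpf(10) ** (-(mp.mp.dps + 12))
    while True:
        t = t * 2 * x / (2 * M + 2 * k + 3)
        total += t
        k += 1
        if t < total * eps:
            break
    emx = mp.e ** (-x)
    out = [mp.mpf(0)] * (M + 1)
    out[M] = emx * total
    for m in range(M - 1, -1, -1):
        out[m] = (2 * x * out[m + 1] + emx) / (2 * m + 1)
    return out


# ---------------------------------------------------------------------------
# exact solid-harmonic coefficients


@lru_cache(maxsize=None)
def _solid_poly_mp(l: int):
    """Real solid harmonics as monomial dicts with mpf coefficients."""
    if l == 0:
        return ({(0, 0, 0): mp.mpf(1)},)
    if l == 1:
        one = mp.mpf(1)
        return ({(0, 1, 0): one}, {(0, 0, 1): one}, {(1, 0, 0): one})
    lo, lo2 = _solid_poly_mp(l - 1), _solid_poly_mp(l - 2)

    def shift(p, axis):
        return {
            (m[0] + (axis == 0), m[1] + (axis == 1), m[2] + (axis == 2)): c
            for m, c in p.items()
        }

    def add(p, q, cq):
        out = dict(p)
        for m, c in q.items():
            out[m] = out.get(m, mp.mpf(0)) + cq * c
        return out

    lm1 = l - 1
    out = []
    for m in range(-l, l + 1):
        if abs(m) == l:
            f = mp.sqrt(
                mp.mpf((2 if lm1 == 0 else 1) * (2 * lm1 + 1)) / (2 * lm1 + 2)
            )
            top = lo[2 * lm1]
            bot = {} if lm1 == 0 else lo[0]
            if m == l:
                p = add(shift(top, 0), shift(bot, 1), mp.mpf(-1))
            else:
                p = add(shift(top, 1), shift(bot, 0), mp.mpf(1))
            out.append({k: f * c for k, c in p.items()})
        else:
            num = {
                k: (2 * lm1 + 1) * c for k, c in shift(lo[m + lm1], 2).items()
            }
            s = mp.sqrt(mp.mpf((lm1 + m) * (lm1 - m)))
            if s != 0:
                r2p = {}
                for axis in range(3):
                    for k, c in shift(shift(lo2[m + l - 2], axis), axis).items():
                        r2p[k] = r2p.get(k, mp.mpf(0)) + c
                num = add(num, r2p, -s)
            den = mp.sqrt(mp.mpf((l + m) * (l - m)))
            out.append({k: c / den for k, c in num.items()})
    return tuple(out)


def _cmatrix_mp(l: int):
    comps = cartesian_components(l)
    col = {c: j for j, c in enumerate(comps)}
    mat = [[mp.mpf(0)] * len(comps) for _ in range(2 * l + 1)]
    for row, poly in enumerate(_solid_poly_mp(l)):
        for mono, c in poly.items():
            mat[row][col[mono]] = c
    return mat


# ---------------------------------------------------------------------------
# scalar extended-precision MD chain


def _e1d_mp(la, lb, za, zb, Ai, Bi):
    """Per-axis 2-center E table ``E[a][b][p]`` in mpf."""
    zp = za + zb
    E = [
        [[mp.mpf(0)] * (la + lb + 2) for _ in range(lb + 1)] for _ in range(la + 1)
    ]
    E[0][0][0] = mp.e ** (-za * zb * (Ai - Bi) ** 2 / zp)
    P = (za * Ai + zb * Bi) / zp
    PA, PB = P - Ai, P - Bi
    inv2zp = 1 / (2 * zp)
    for a in range(la):
        for p in range(a + 2):
            E[a + 1][0][p] = (
                (E[a][0][p - 1] * inv2zp if p >= 1 else mp.mpf(0))
                + PA * E[a][0][p]
                + (p + 1) * E[a][0][p + 1]
            )
    for b in range(lb):
        for a in range(la + 1):
            for p in range(a + b + 2):
                E[a][b + 1][p] = (
                    (E[a][b][p - 1] * inv2zp if p >= 1 else mp.mpf(0))
                    + PB * E[a][b][p]
                    + (p + 1) * E[a][b][p + 1]
                )
    return E


def eri_highprec(shellset, precision_digits: int = 30) -> np.ndarray:
    """Scalar extended-precision Coulomb integral block over solid AOs.

    ``shellset`` is a tuple of 2, 3 or 4 :class:`Shell` objects; missing
    centers are padded with zero-exponent dummies, so the same loop-based
    chain covers every class.  Returns the ``(n_bra_solid, n_ket_solid)``
    float64 block; no batching, no early contraction, no shortcuts.
    """
    if precision_digits < 30:
        raise ValueError("precision_digits must be >= 30")
    shells = list(shellset)
    if len(shells) == 2:
        shells = [shells[0], Shell.dummy(shells[0].center), shells[1], Shell.dummy(shells[1].center)]
    elif len(shells) == 3:
        shells = [shells[0], Shell.dummy(shells[0].center), shells[1], shells[2]]
    elif len(shells) != 4:
        raise ValueError("shellset must have 2, 3 or 4 shells")
    a, b, c, d = shells
    with mp.workdps(precision_digits):
        A, B, C, D = (tuple(map(mp.mpf, s.center)) for s in (a, b, c, d))
        ca_comps, cb_comps = cartesian_components(a.l), cartesian_components(b.l)
        cc_comps, cd_comps = cartesian_components(c.l), cartesian_components(d.l)
        Lb, Lk = a.l + b.l, c.l + d.l
        L = Lb + Lk
        cart = [
            [
                [[mp.mpf(0) for _ in cd_comps] for _ in cc_comps]
                for _ in cb_comps
            ]
            for _ in ca_comps
        ]
        for ka in range(a.K):
            for kb in range(b.K):
                za, zb = mp.mpf(a.exponents[ka]), mp.mpf(b.exponents[kb])
                zp = za + zb
                P = tuple((za * A[i] + zb * B[i]) / zp for i in range(3))
                Eb = [_e1d_mp(a.l, b.l, za, zb, A[i], B[i]) for i in range(3)]
                cab = mp.mpf(a.coefficients[ka]) * mp.mpf(b.coefficients[kb])
                for kc in range(c.K):
                    for kd in range(d.K):
                        zc, zd = mp.mpf(c.exponents[kc]), mp.mpf(d.exponents[kd])
                        zq = zc + zd
                        Q = tuple((zc * C[i] + zd * D[i]) / zq for i in range(3))
                        Ek = [
                            _e1d_mp(c.l, d.l, zc, zd, C[i], D[i]) for i in range(3)
                        ]
                        ccd = mp.mpf(c.coefficients[kc]) * mp.mpf(
                            d.coefficients[kd]
                        )
                        rho = zp * zq / (zp + zq)
                        PQ = tuple(P[i] - Q[i] for i in range(3))
                        r2 = sum(v * v for v in PQ)
                        F = boys_mp(rho * r2, L)
                        pref = (
                            2
                            * mp.pi ** mp.mpf("2.5")
                            / (zp * zq * mp.sqrt(zp + zq))
                        )
                        base = [pref * (-2 * rho) ** m * F[m] for m in range(L + 1)]
                        memo: dict = {}

                        def R(t, m):
                            key = (t, m)
                            if key in memo:
                                return memo[key]
                            if t == (0, 0, 0):
                                v = base[m]
                            else:
                                i = next(ax for ax in range(3) if t[ax] > 0)
                                r = list(t)
                                r[i] -= 1
                                v = PQ[i] * R(tuple(r), m + 1)
                                if r[i] >= 1:
                                    r2_ = list(r)
                                    r2_[i] -= 1
                                    v += r[i] * R(tuple(r2_), m + 1)
                            memo[key] = v
                            return v

                        w = cab * ccd
                        for ia, av in enumerate(ca_comps):
                            for ib, bv in enumerate(cb_comps):
                                for ic, cv in enumerate(cc_comps):
                                    for id_, dv in enumerate(cd_comps):
                                        tot = mp.mpf(0)
                                        for px in range(av[0] + bv[0] + 1):
                                            ex = Eb[0][av[0]][bv[0]][px]
                                            if ex == 0:
                                                continue
                                            for py in range(av[1] + bv[1] + 1):
                                                ey = Eb[1][av[1]][bv[1]][py]
                                                if ey == 0:
                                                    continue
                                                for pz in range(av[2] + bv[2] + 1):
                                                    ez = Eb[2][av[2]][bv[2]][pz]
                                                    if ez == 0:
                                                        continue
                                                    eb3 = ex * ey * ez
                                                    for qx in range(cv[0] + dv[0] + 1):
                                                        fx = Ek[0][cv[0]][dv[0]][qx]
                                                        if fx == 0:
                                                            continue
                                                        for qy in range(cv[1] + dv[1] + 1):
                                                            fy = Ek[1][cv[1]][dv[1]][qy]
                                                            if fy == 0:
                                                                continue
                                                            for qz in range(cv[2] + dv[2] + 1):
                                                                fz = Ek[2][cv[2]][dv[2]][qz]
                                                                if fz == 0:
                                                                    continue
                                                                sign = (
                                                                    -1
                                                                    if (qx + qy + qz) % 2
                                                                    else 1
                                                                )
                                                                tot += (
                                                                    eb3
                                                                    * fx
                                                                    * fy
                                                                    * fz
                                                                    * sign
                                                                    * R(
                                                                        (
                                                                            px + qx,
                                                                            py + qy,
                                                                            pz + qz,
                                                                        ),
                                                                        0,
                                                                    )
                                                                )
                                        cart[ia][ib][ic][id_] += w * tot
        # Cartesian -> solid on all four centers, then collapse to pairs
        Ca, Cb = _cmatrix_mp(a.l), _cmatrix_mp(b.l)
        Cc, Cd = _cmatrix_mp(c.l), _cmatrix_mp(d.l)
        nsa, nsb, nsc, nsd = len(Ca), len(Cb), len(Cc), len(Cd)
        out = np.zeros((nsa * nsb, nsc * nsd))
        for ma in range(nsa):
            for mb in range(nsb):
                for mc in range(nsc):
                    for md in range(nsd):
                        tot = mp.mpf(0)
                        for ia in range(len(ca_comps)):
                            if Ca[ma][ia] == 0:
                                continue
                            for ib in range(len(cb_comps)):
                                if Cb[mb][ib] == 0:
                                    continue
                                for ic in range(len(cc_comps)):
                                    if Cc[mc][ic] == 0:
                                        continue
                                    for id_ in range(len(cd_comps)):
                                        if Cd[md][id_] == 0:
                                            continue
                                        tot += (
                                            Ca[ma][ia]
                                            * Cb[mb][ib]
                                            * Cc[mc][ic]
                                            * Cd[md][id_]
                                            * cart[ia][ib][ic][id_]
                                        )
                        out[ma * nsb + mb, mc * nsd + md] = float(tot)
    return out


def nuclear_highprec(
    pair: ShellPair, charges: ChargeSet, precision_digits: int = 30
) -> np.ndarray:
    """Scalar extended-precision nuclear-attraction block.

    Independent loop-based chain: per primitive pair and point charge, mpf
    E tables, Boys-based base terms and the 3-term recursion with ``P - I``,
    naive order of operations throughout.
    """
    a, b = pair.shells
    with mp.workdps(precision_digits):
        A = tuple(map(mp.mpf, a.center))
        B = tuple(map(mp.mpf, b.center))
        ca_comps, cb_comps = cartesian_components(a.l), cartesian_components(b.l)
        L = a.l + b.l
        cart = [[mp.mpf(0) for _ in cb_comps] for _ in ca_comps]
        for ka in range(a.K):
            for kb in range(b.K):
                za, zb = mp.mpf(a.exponents[ka]), mp.mpf(b.exponents[kb])
                zp = za + zb
                P = tuple((za * A[i] + zb * B[i]) / zp for i in range(3))
                E3 = [_e1d_mp(a.l, b.l, za, zb, A[i], B[i]) for i in range(3)]
                cab = mp.mpf(a.coefficients[ka]) * mp.mpf(b.coefficients[kb])
                for q, I in zip(charges.charges, charges.positions):
                    PI = tuple(P[i] - mp.mpf(I[i]) for i in range(3))
                    r2 = sum(v * v for v in PI)
                    F = boys_mp(zp * r2, L)
                    base = [
                        2 * mp.pi / zp * (-2 * zp) ** m * F[m] for m in range(L + 1)
                    ]
                    memo: dict = {}

                    def R(t, m):
                        key = (t, m)
                        if key in memo:
                            return memo[key]
                        if t == (0, 0, 0):
                            v = base[m]
                        else:
                            i = next(ax for ax in range(3) if t[ax] > 0)
                            r = list(t)
                            r[i] -= 1
                            v = PI[i] * R(tuple(r), m + 1)
                            if r[i] >= 1:
                                r2_ = list(r)
                                r2_[i] -= 1
                                v += r[i] * R(tuple(r2_), m + 1)
                        memo[key] = v
                        return v

                    for ia, av in enumerate(ca_comps):
                        for ib, bv in enumerate(cb_comps):
                            tot = mp.mpf(0)
                            for px in range(av[0] + bv[0] + 1):
                                ex = E3[0][av[0]][bv[0]][px]
                                if ex == 0:
                                    continue
                                for py in range(av[1] + bv[1] + 1):
                                    ey = E3[1][av[1]][bv[1]][py]
                                    if ey == 0:
                                        continue
                                    for pz in range(av[2] + bv[2] + 1):
                                        ez = E3[2][av[2]][bv[2]][pz]
                                        if ez == 0:
                                            continue
                                        tot += ex * ey * ez * R((px, py, pz), 0)
                            cart[ia][ib] -= mp.mpf(q) * cab * tot
        Ca, Cb = _cmatrix_mp(a.l), _cmatrix_mp(b.l)
        out = np.zeros((len(Ca), len(Cb)))
        for ma in range(len(Ca)):
            for mb in range(len(Cb)):
                tot = mp.mpf(0)
                for ia in range(len(ca_comps)):
                    if Ca[ma][ia] == 0:
                        continue
                    for ib in range(len(cb_comps)):
                        if Cb[mb][ib] == 0:
                            continue
                        tot += Ca[ma][ia] * Cb[mb][ib] * cart[ia][ib]
                out[ma, mb] = float(tot)
    return out


# ---------------------------------------------------------------------------
# symbolic-differentiation Hermite oracle


def hermite_symbolic_oracle(zeta_p, zeta_q, PQ, L: int, dps: int = 40) -> np.ndarray:
    """``[r]^(0)`` for all triples of degree <= L by symbolic differentiation.

    Differentiates the closed-form base term with respect to the components
    of ``P`` using ``d F_m(x)/dx = -F_{m+1}(x)`` symbolically (sympy), then
    substitutes high-precision Boys values.  Completely independent of the
    3-term recursion.
    """
    import sympy as sp

    from .shell_model import hermite_triples

    class FB(sp.Function):
        nargs = 2

        def fdiff(self, argindex=2):
            m, x = self.args
            return -FB(m + 1, x)

    Px, Py, Pz = sp.symbols("Px Py Pz")
    zp, zq = sp.Rational(str(zeta_p)), sp.Rational(str(zeta_q))
    rho = zp * zq / (zp + zq)
    xarg = rho * (Px**2 + Py**2 + Pz**2)
    pref = 2 * sp.pi ** sp.Rational(5, 2) / (zp * zq * sp.sqrt(zp + zq))
    base0 = pref * FB(0, xarg)
    syms = (Px, Py, Pz)
    vals = {}
    with mp.workdps(dps):
        rho_f = mp.mpf(zeta_p) * mp.mpf(zeta_q) / (mp.mpf(zeta_p) + mp.mpf(zeta_q))
        x_num = rho_f * sum(mp.mpf(v) ** 2 for v in PQ)
        maxm = 3 * L + 1
        F = boys_mp(x_num, maxm)
        out = []
        for t in hermite_triples(L):
            expr = base0
            for ax, n in enumerate(t):
                expr = sp.diff(expr, syms[ax], n)
            expr = sp.expand(expr)
            subs = {s: sp.Float(str(mp.nstr(mp.mpf(v), dps))) for s, v in zip(syms, PQ)}
            expr = expr.subs(subs)
            # replace FB(m, x) atoms by numeric Boys values
            total = mp.mpf(0)
            for term in sp.Add.make_args(expr):
                fbs = term.atoms(FB)
                coeff = term
                fac = mp.mpf(1)
                for fb in fbs:
                    m_idx = int(fb.args[0])
                    fac *= F[m_idx]
                    coeff = coeff.subs(fb, 1)
                total += mp.mpf(str(sp.N(coeff, dps))) * fac
            out.append(float(total))
    return np.array(out)


# ---------------------------------------------------------------------------
# quadrature oracle for 1-particle integrals


def _quad_1d(aa, bb, za, zb, Ai, Bi, tol=1e-12):
    f = lambda x: (x - Ai) ** aa * (x - Bi) ** bb * np.exp(
        -za * (x - Ai) ** 2 - zb * (x - Bi) ** 2
    )
    half = 10.0 / np.sqrt(min(za, zb) if min(za, zb) > 0 else max(za, zb))
    lo = min(Ai, Bi) - half
    hi = max(Ai, Bi) + half
    val, _ = quad(f, lo, hi, epsabs=tol, epsrel=tol, limit=400)
    return val


def quadrature_1p(
    pair: ShellPair,
    operator: str,
    charges: ChargeSet | None = None,
    tol: float = 1e-9,
) -> np.ndarray:
    """Numerical quadrature of the defining 1-particle integral (l <= 2).

    Overlap and kinetic integrals factor into adaptive 1-D quadratures per
    axis; nuclear attraction is integrated on a refining spherical product
    grid centered at each point charge (the radial Jacobian removes the
    Coulomb singularity).  Returns the solid-harmonic block.
    """
    a, b = pair.shells
    if max(a.l, b.l) > 2:
        raise ValueError("quadrature oracle restricted to l <= 2")
    from .spherical import solid_coeffs

    ca_comps, cb_comps = cartesian_components(a.l), cartesian_components(b.l)
    cart = np.zeros((len(ca_comps), len(cb_comps)))
    for k in range(pair.K):
        za, zb = pair.zeta_a[k], pair.zeta_b[k]
        cc = pair.coeff_product[k]
        for ia, av in enumerate(ca_comps):
            for ib, bv in enumerate(cb_comps):
                if operator == "overlap":
                    v = np.prod(
                        [
                            _quad_1d(av[i], bv[i], za, zb, a.center[i], b.center[i])
                            for i in range(3)
                        ]
                    )
                elif operator == "kinetic":
                    v = 0.0
                    for ax in range(3):
                        term = 1.0
                        for i in range(3):
                            if i == ax:
                                bq = bv[i]
                                d2 = 4 * zb**2 * _quad_1d(
                                    av[i], bq + 2, za, zb, a.center[i], b.center[i]
                                ) - 2 * zb * (2 * bq + 1) * _quad_1d(
                                    av[i], bq, za, zb, a.center[i], b.center[i]
                                )
                                if bq >= 2:
                                    d2 += (
                                        bq
                                        * (bq - 1)
                                        * _quad_1d(
                                            av[i],
                                            bq - 2,
                                            za,
                                            zb,
                                            a.center[i],
                                            b.center[i],
                                        )
                                    )
                                term *= d2
                            else:
                                term *= _quad_1d(
                                    av[i], bv[i], za, zb, a.center[i], b.center[i]
                                )
                        v += term
                    v *= -0.5
                elif operator == "nuclear":
                    v = _nuclear_quad(av, bv, za, zb, a.center, b.center, charges, tol)
                else:
                    raise ValueError(f"unknown operator {operator!r}")
                cart[ia, ib] += cc * v
    Ca = solid_coeffs(a.l).matrix
    Cb = solid_coeffs(b.l).matrix
    return Ca @ cart @ Cb.T


def _nuclear_quad(av, bv, za, zb, A, B, charges: ChargeSet, tol: float) -> float:
    """Spherical product-grid quadrature of ``-sum_I q_I rho_ab / |r - I|``.

    The grid is refined (doubled) until two successive levels agree to
    ``tol`` relative.
    """
    if charges is None or len(charges) == 0:
        return 0.0
    # crude scale of the charge-free density integral, for the convergence
    # criterion on near-zero matrix elements
    scale = (np.pi / (za + zb)) ** 1.5
    total = 0.0
    for q, I in zip(charges.charges, charges.positions):
        reach = (
            8.0 / np.sqrt(min(za, zb))
            + max(np.linalg.norm(A - I), np.linalg.norm(B - I))
        )
        prev = None
        n = 32
        while True:
            val = _nuclear_grid_value(av, bv, za, zb, A, B, I, reach, n)
            if prev is not None and abs(val - prev) <= tol * max(
                abs(val), 1e-4 * scale
            ):
                break
            if n >= 256:  # pragma: no cover - convergence guard
                break
            prev = val
            n *= 2
        total += q * val
    return -total


def _nuclear_grid_value(av, bv, za, zb, A, B, I, reach, n) -> float:
    """One spherical product-grid level, evaluated in radial chunks."""
    xr, wr = np.polynomial.legendre.leggauss(n)
    s_all = 0.5 * reach * (xr + 1.0)
    ws_all = 0.5 * reach * wr
    xc, wc = np.polynomial.legendre.leggauss(n)
    phi = np.linspace(0.0, 2 * np.pi, 2 * n, endpoint=False)
    wphi = 2 * np.pi / (2 * n)
    st = np.sqrt(1 - xc**2)
    ux = np.einsum("t,p->tp", st, np.cos(phi))
    uy = np.einsum("t,p->tp", st, np.sin(phi))
    uz = np.broadcast_to(xc[:, None], ux.shape)
    val = 0.0
    chunk = max(1, 4_000_000 // (ux.size))
    for lo in range(0, n, chunk):
        s = s_all[lo : lo + chunk]
        ws = ws_all[lo : lo + chunk]
        # r = I + s*u ; integrand s * rho(r)  (Jacobian s^2 over 1/|r-I| = s)
        rx = I[0] + s[:, None, None] * ux[None]
        ry = I[1] + s[:, None, None] * uy[None]
        rz = I[2] + s[:, None, None] * uz[None]
        rho = (
            (rx - A[0]) ** av[0]
            * (ry - A[1]) ** av[1]
            * (rz - A[2]) ** av[2]
            * (rx - B[0]) ** bv[0]
            * (ry - B[1]) ** bv[1]
            * (rz - B[2]) ** bv[2]
            * np.exp(
                -za * ((rx - A[0]) ** 2 + (ry - A[1]) ** 2 + (rz - A[2]) ** 2)
                - zb * ((rx - B[0]) ** 2 + (ry - B[1]) ** 2 + (rz - B[2]) ** 2)
            )
        )
        val += np.einsum("s,t,stp->", s * ws, wc, rho) * wphi
    return float(val)


# ---------------------------------------------------------------------------
# comparison reporting


@dataclass(frozen=True)
class ComparisonReport:
    """Summary of an engine-vs-oracle comparison."""

    cls: str
    n: int
    max_abs: float
    max_rel: float
    worst_abs_at: tuple
    worst_rel_at: tuple
    tol: float
    passed: bool

    def to_json(self) -> dict:
        return {
            "class": self.cls,
            "n": self.n,
            "max_abs": self.max_abs,
            "max_rel": self.max_rel,
            "worst_abs_at": list(self.worst_abs_at),
            "worst_rel_at": list(self.worst_rel_at),
            "tol": self.tol,
            "passed": self.passed,
        }


def compare(
    got: np.ndarray,
    want: np.ndarray,
    tol: float,
    cls: str = "",
    floor: float = 1e-12,
) -> ComparisonReport:
    """Max-deviation report; relative deviations only count above ``floor``.

    The absolute floor avoids 0/0 verdicts on parity-forced exact zeros.
    """
    got = np.asarray(got)
    want = np.asarray(want)
    if got.shape != want.shape:
        raise ValueError(f"shape mismatch {got.shape} vs {want.shape}")
    if got.size == 0:
        return ComparisonReport(cls, 0, 0.0, 0.0, (), (), tol, True)
    diff = np.abs(got - want)
    max_abs = float(diff.max())
    iabs = tuple(int(i) for i in np.unravel_index(int(diff.argmax()), diff.shape))
    denom = np.abs(want)
    rel = np.where(denom > floor, diff / np.maximum(denom, floor), 0.0)
    max_rel = float(rel.max())
    irel = tuple(int(i) for i in np.unravel_index(int(rel.argmax()), rel.shape))
    return ComparisonReport(
        cls, got.size, max_abs, max_rel, iabs, irel, tol, bool(max_rel <= tol)
    )
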