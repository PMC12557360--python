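"""Auxiliary Hermite integrals [r]^(m) and their 3-term recursion.

The Coulomb kernel integrated against (products of) Hermite Gaussians
reduces to derivatives of the Boys function.  The base terms are

    1-particle:  [0]_I^(m) = (2 pi / zeta_p) (-2 zeta_p)^m F_m(zeta_p |P-I|^2)
    2-particle:  [0]^(m)   = 2 pi^{5/2} / (zeta_p zeta_q sqrt(zeta_p+zeta_q))
                             * (-2 rho)^m F_m(rho |P-Q|^2),
                 rho = zeta_p zeta_q / (zeta_p + zeta_q)

and the full triangular tensor of ``[r]^(0)`` over Hermite triples of total
degree <= L follows from the downward-in-m recursion

    [r + 1_i]^(m) = r_i [r - 1_i]^(m+1) + D_i [r]^(m+1)

with ``D = P - Q`` (or ``P - I``).  Everything here is batched over lanes:
one lane is one primitive (pair-of-)pair(s)/charge combination.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .boys import boys_eval
from .shell_model import InputError, hermite_index, hermite_triples, shell_dims

__all__ = ["HermiteBlock", "base_terms_1p", "base_terms_2p", "build_r_block"]


@dataclass(frozen=True)
class HermiteBlock:
    """Per-lane triangular tensor ``[r]^(0)`` in graded triple ordering.

    ``values`` has shape ``(lanes, n_herm(L))``; ``meta`` carries whatever
    per-lane scalars the caller wants to keep (``zeta_p``, ``rho``, ...).
    """

    L: int
    values: np.ndarray
    meta: dict


def base_terms_2p(
    zeta_p: np.ndarray,
    zeta_q: np.ndarray,
    PQ: np.ndarray,
    L: int,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """2-particle base terms ``[0]^(m)``, shape ``(lanes, L+1)``.

    ``zeta_p``/``zeta_q`` are per-lane total exponents and ``PQ`` the
    per-lane ``P - Q`` displacement ``(lanes, 3)``.
    """
    zp = np.atleast_1d(np.asarray(zeta_p, dtype=float))
    zq = np.atleast_1d(np.asarray(zeta_q, dtype=float))
    PQ = np.asarray(PQ, dtype=float).reshape(-1, 3)
    if np.any(zp <= 0) or np.any(zq <= 0):
        raise InputError("pair exponents must be positive")
    rho = zp * zq / (zp + zq)
    r2 = np.einsum("ij,ij->i", PQ, PQ)
    F = boys_eval(rho * r2, L, mask=mask)
    pref = 2.0 * np.pi**2.5 / (zp * zq * np.sqrt(zp + zq))
    powers = (-2.0 * rho)[:, None] ** np.arange(L + 1)[None, :]
    return pref[:, None] * powers * F


def base_terms_1p(
    zeta_p: np.ndarray,
    PI: np.ndarray,
    m_max: int,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """1-particle base terms ``[0]_I^(m)``, shape ``(lanes, m_max+1)``."""
    zp = np.atleast_1d(np.asarray(zeta_p, dtype=float))
    PI = np.asarray(PI, dtype=float).reshape(-1, 3)
    if np.any(zp <= 0):
        raise InputError("pair exponent must be positive")
    r2 = np.einsum("ij,ij->i", PI, PI)
    F = boys_eval(zp * r2, m_max, mask=mask)
    pref = 2.0 * np.pi / zp
    powers = (-2.0 * zp)[:, None] ** np.arange(m_max + 1)[None, :]
    return pref[:, None] * powers * F


@lru_cache(maxsize=None)
def _recursion_tables(L: int):
    """Per-degree index tables driving the vectorized 3-term recursion.

    For every triple ``t`` of degree ``d >= 1``: pick the first nonzero axis
    ``i``; with ``r = t - e_i`` the recursion reads
    ``[t]^(m) = (t_i - 1) [r - e_i]^(m+1) + D_i [r]^(m+1)``.
    Returns, per degree d, arrays (target_idx, axis, coef, src1_idx,
    src2_idx) where src2_idx = -1 encodes an absent first term.
    """
    idx = hermite_index(L)
    tables = []
    for d in range(1, L + 1):
        tgt, axis, coef, s1, s2 = [], [], [], [], []
        for t in hermite_triples(L):
            if sum(t) != d:
                continue
            i = next(ax for ax in range(3) if t[ax] > 0)
            r = list(t)
            r[i] -= 1
            tgt.append(idx[t])
            axis.append(i)
            coef.append(t[i] - 1)
            s1.append(idx[tuple(r)])
            if t[i] >= 2:
                r2 = list(r)
                r2[i] -= 1
                s2.append(idx[tuple(r2)])
            else:
                s2.append(-1)
        tables.append(
            (
                np.array(tgt, dtype=np.intp),
                np.array(axis, dtype=np.intp),
                np.array(coef, dtype=float),
                np.array(s1, dtype=np.intp),
                np.array(s2, dtype=np.intp),
            )
        )
    return tables


def build_r_block(
    base: np.ndarray,
    D: np.ndarray,
    L: int,
    meta: dict | None = None,
) -> HermiteBlock:
    """Build ``[r]^(0)`` for all triples of degree <= L from ``[0]^(m)``.

    Parameters
    ----------
    base
        ``(lanes, >= L+1)`` base terms ``[0]^(m)`` for ``m = 0..L``.
    D
        ``(lanes, 3)`` displacement ``P - Q`` (or ``P - I``).
    """
    base = np.atleast_2d(np.asarray(base, dtype=float))
    D = np.asarray(D, dtype=float).reshape(-1, 3)
    lanes = base.shape[0]
    if base.shape[1] < L + 1:
        raise RuntimeError(f"need base terms for m=0..{L}, got {base.shape[1]}")
    nt = shell_dims(L)[2] if L <= 12 else (L + 1) * (L + 2) * (L + 3) // 6
    # R[m, triple, lane]; layer m holds valid data for degrees <= L - m
    R = np.zeros((L + 1, nt, lanes))
    R[:, 0, :] = base[:, : L + 1].T
    tables = _recursion_tables(L)
    Dt = D.T  # (3, lanes)
    for m in range(L - 1, -1, -1):
        for d in range(1, L - m + 1):
            tgt, axis, coef, s1, s2 = tables[d - 1]
            contrib = Dt[axis] * R[m + 1, s1]
            has2 = s2 >= 0
            if has2.any():
                contrib[has2] += coef[has2, None] * R[m + 1, s2[has2]]
            R[m, tgt] = contrib
    return HermiteBlock(L=L, values=R[0].T.copy(), meta=meta or {})
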