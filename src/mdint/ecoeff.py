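"""Hermite expansion coefficients E.

A primitive Cartesian Gaussian (or a product of two) expands exactly in
Hermite Gaussians of its (composite) center,

    phi_a            = sum_p  E_a^p    Lambda_p,      p_i <= a_i
    phi_a * phi_b    = sum_p  E_ab^p   Lambda_p,      p_i <= a_i + b_i

with coefficients that factor along Cartesian axes.  They obey three-term
upward recursions in the Cartesian quanta:

    1-center:  E_{a+1}^p = E_a^{p-1}/(2 zeta_a)                + (p+1) E_a^{p+1}
    2-center:  E_{a+1,b}^p = E_{ab}^{p-1}/(2 zeta_p) + (P-A)_i E_{ab}^p + (p+1) E_{ab}^{p+1}
               E_{a,b+1}^p = E_{ab}^{p-1}/(2 zeta_p) + (P-B)_i E_{ab}^p + (p+1) E_{ab}^{p+1}

seeded by ``E_0^0 = 1`` and ``(E_i)_{00}^0 = exp(-zeta_a zeta_b (A_i-B_i)^2
/ zeta_p)``.  Out-of-range entries are hard zeros and never read.  For the
1-center case entries with ``(p + a)`` odd vanish identically (the recursion
has no middle term); the 2-center coefficients inherit that parity pattern
only when the centers coincide, since the ``(P-A)_i`` terms then drop out.

The terminal (maximal-degree) coefficients have the closed forms

    E_a^a = (2 zeta_a)^{-a},     E_ab^{a+b} = (2 zeta_p)^{-(a+b)} (E_i)_{00}^0

which the early-contraction machinery of the 2-particle engine consumes;
:meth:`ETensor.terminal` exposes them directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .shell_model import InputError, L_MAX

__all__ = ["ETensor", "ecoeff_1c", "ecoeff_2c", "ecoeff_2c_pairs"]


@dataclass(frozen=True)
class ETensor:
    """Per-axis Hermite expansion coefficients for one (pair of) shell(s).

    ``kind`` is ``"1c"`` or ``"2c"``.  For the 1-center case ``data`` has
    shape ``(l+1, l+1)`` indexed ``[a, p]`` (the coefficients are identical
    for each axis and independent of the center).  For the 2-center case
    ``data`` has shape ``(3, K, la+1, lb+1, la+lb+1)`` indexed
    ``[axis, primitive-pair, a, b, p]``; the per-axis Gaussian-product
    prefactor is folded into the ``p = a = b = 0`` seed.
    """

    kind: str
    data: np.ndarray
    zeta: np.ndarray

    def terminal(self) -> np.ndarray:
        """Closed-form terminal coefficients.

        1-center: shape ``(l+1,)`` with ``E_a^a = (2 zeta)^-a``.
        2-center: shape ``(3, K)`` with the per-axis ``(E_i)_{00}^0`` seeds;
        the full terminal value is the seed times ``(2 zeta_p)^{-(a+b)}``.
        """
        if self.kind == "1c":
            l = self.data.shape[0] - 1
            return (2.0 * self.zeta) ** -np.arange(l + 1)
        return self.data[:, :, 0, 0, 0]


def ecoeff_1c(l_a: int, zeta_a: float) -> ETensor:
    """1-center E coefficients for all ``a <= l_a`` (any axis)."""
    if zeta_a <= 0:
        raise InputError("exponent must be positive")
    if not 0 <= l_a <= L_MAX:
        raise InputError(f"l must be in [0, {L_MAX}]")
    E = np.zeros((l_a + 1, l_a + 2))  # one spare p column as hard zero
    E[0, 0] = 1.0
    inv2z = 1.0 / (2.0 * zeta_a)
    for a in range(l_a):
        for p in range(a + 2):
            E[a + 1, p] = (E[a, p - 1] * inv2z if p >= 1 else 0.0) + (p + 1) * E[
                a, p + 1
            ]
    return ETensor("1c", E[:, : l_a + 1].copy(), np.asarray(zeta_a))


def ecoeff_2c(
    l_a: int,
    l_b: int,
    zeta_a: float,
    zeta_b: float,
    A: np.ndarray,
    B: np.ndarray,
) -> ETensor:
    """2-center E coefficients for a single primitive pair.

    Returns an :class:`ETensor` with a singleton primitive axis; see
    :func:`ecoeff_2c_pairs` for the batched form used by the engines.
    """
    t = ecoeff_2c_pairs(
        l_a, l_b, np.atleast_1d(float(zeta_a)), np.atleast_1d(float(zeta_b)), A, B
    )
    return t


def ecoeff_2c_pairs(
    l_a: int,
    l_b: int,
    zeta_a: np.ndarray,
    zeta_b: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
) -> ETensor:
    """2-center E coefficients batched over primitive pairs.

    ``zeta_a``/``zeta_b`` are matched flat arrays over the K = K_a*K_b
    primitive pairs.  Dummy pairs with ``zeta_a + zeta_b`` arising from a
    zero-exponent shell are allowed as long as the total is positive.
    """
    za = np.atleast_1d(np.asarray(zeta_a, dtype=float))
    zb = np.atleast_1d(np.asarray(zeta_b, dtype=float))
    if za.shape != zb.shape:
        raise InputError("exponent arrays must be matched")
    zp = za + zb
    if np.any(zp <= 0):
        raise InputError("pair exponent zeta_p must be positive")
    if not (0 <= l_a <= L_MAX and 0 <= l_b <= L_MAX):
        raise InputError(f"l must be in [0, {L_MAX}]")
    A = np.asarray(A, dtype=float).reshape(3)
    B = np.asarray(B, dtype=float).reshape(3)
    K = za.size
    L = l_a + l_b
    P = (za[:, None] * A + zb[:, None] * B) / zp[:, None]  # (K, 3)
    PA = P - A  # (K, 3)
    PB = P - B
    inv2zp = 1.0 / (2.0 * zp)

    E = np.zeros((3, K, l_a + 1, l_b + 1, L + 2))
    E[:, :, 0, 0, 0] = np.exp(-np.outer((A - B) ** 2, za * zb / zp))
    # grow a at b = 0, then grow b
    for a in range(l_a):
        for p in range(a + 2):
            low = E[:, :, a, 0, p - 1] * inv2zp if p >= 1 else 0.0
            E[:, :, a + 1, 0, p] = (
                low + PA.T * E[:, :, a, 0, p] + (p + 1) * E[:, :, a, 0, p + 1]
            )
    for b in range(l_b):
        for a in range(l_a + 1):
            for p in range(a + b + 2):
                low = E[:, :, a, b, p - 1] * inv2zp if p >= 1 else 0.0
                E[:, :, a, b + 1, p] = (
                    low + PB.T * E[:, :, a, b, p] + (p + 1) * E[:, :, a, b, p + 1]
                )
    return ETensor("2c", E[..., : L + 1].copy(), zp)
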