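"""Batched 1-particle integrals: overlap, kinetic energy, nuclear attraction.

Overlap and kinetic integrals reduce to products of one-dimensional Hermite
integrals: per axis, ``integral x_A^a x_B^b exp(..) dx = E_ab^0
sqrt(pi/zeta_p)``, since only the zeroth Hermite component survives
integration.  The kinetic operator ``-nabla^2/2`` is expanded over shifted
ket quanta,

    <a| d^2/dx^2 |b> = 4 zeta_b^2 S(a, b+2) - 2 zeta_b (2b+1) S(a, b)
                       + b (b-1) S(a, b-2),

so a single E tensor extended to ``l_b + 2`` supplies everything.

Nuclear attraction follows the Hermite chain with *early charge summation*:
the Hermite-to-AO transform does not depend on the charges, so the per-charge
auxiliary integrals are accumulated first,

    [bra]_phi = - sum_p H_bra^p ( sum_I q_I [p]_I )

and a single transform is applied outside the charge loop.  The naive
order of operations (transform per charge, then sum) is retained as an
option purely so the exact equivalence of the two paths can be asserted.

One lane corresponds to one contracted shell pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ecoeff import ecoeff_2c_pairs
from .hermite_aux import base_terms_1p, build_r_block
from .shell_model import (
    Batch,
    ChargeSet,
    Shell,
    ShellPair,
    cartesian_components,
    class_tag,
    shell_dims,
)
from .spherical import hmatrix, solid_coeffs

__all__ = [
    "OneBodyResult",
    "overlap_batch",
    "kinetic_batch",
    "nuclear_batch",
    "one_body_matrix",
]


@dataclass(frozen=True)
class OneBodyResult:
    """Solid-harmonic blocks ``(n_pairs, 2 l_a + 1, 2 l_b + 1)`` per batch."""

    operator: str
    values: np.ndarray
    pairs: tuple[ShellPair, ...]


def _as_pairs(pairs) -> list[ShellPair]:
    if isinstance(pairs, Batch):
        return list(pairs.lanes)
    return list(pairs)


def _solid_transform(pair: ShellPair, cart_block: np.ndarray) -> np.ndarray:
    Ca = solid_coeffs(pair.shells[0].l).matrix
    Cb = solid_coeffs(pair.shells[1].l).matrix
    return Ca @ cart_block @ Cb.T


def _overlap_1d(pair: ShellPair, extra_b: int = 0):
    """Per-axis 1-D overlap table ``s[axis, k, a, b]`` (b extended)."""
    a, b = pair.shells
    E = ecoeff_2c_pairs(
        a.l, b.l + extra_b, pair.zeta_a, pair.zeta_b, a.center, b.center
    )
    root = np.sqrt(np.pi / pair.zeta_p)  # (K,)
    return E.data[..., 0] * root[None, :, None, None]


def overlap_batch(pairs) -> OneBodyResult:
    """Contracted solid-harmonic overlap blocks for a batch of shell pairs."""
    pairs = _as_pairs(pairs)
    out = []
    for pair in pairs:
        a, b = pair.shells
        s = _overlap_1d(pair)  # (3, K, la+1, lb+1)
        ca = np.array(cartesian_components(a.l))
        cb = np.array(cartesian_components(b.l))
        cart = np.einsum(
            "k,kab->ab",
            pair.coeff_product,
            s[0][:, ca[:, 0]][:, :, cb[:, 0]]
            * s[1][:, ca[:, 1]][:, :, cb[:, 1]]
            * s[2][:, ca[:, 2]][:, :, cb[:, 2]],
        )
        out.append(_solid_transform(pair, cart))
    return OneBodyResult("overlap", np.array(out), tuple(pairs))


def kinetic_batch(pairs) -> OneBodyResult:
    """Contracted solid-harmonic kinetic-energy blocks ``<a| -nabla^2/2 |b>``."""
    pairs = _as_pairs(pairs)
    out = []
    for pair in pairs:
        a, b = pair.shells
        s = _overlap_1d(pair, extra_b=2)  # (3, K, la+1, lb+3)
        zb = pair.zeta_b  # (K,)
        lb = b.l
        # D[axis, k, a, b] = <a|d2/dx2|b> per axis
        D = np.zeros((3, pair.K, a.l + 1, lb + 1))
        for bq in range(lb + 1):
            D[..., bq] = (
                4.0 * zb[None, :, None] ** 2 * s[..., bq + 2]
                - 2.0 * zb[None, :, None] * (2 * bq + 1) * s[..., bq]
            )
            if bq >= 2:
                D[..., bq] += bq * (bq - 1) * s[..., bq - 2]
        ca = np.array(cartesian_components(a.l))
        cb = np.array(cartesian_components(b.l))

        def gather(tab, ax):
            return tab[ax][:, ca[:, ax]][:, :, cb[:, ax]]

        cart = np.zeros((len(ca), len(cb)))
        for ax in range(3):
            term = gather(D, ax).copy()
            for other in range(3):
                if other != ax:
                    term = term * gather(s[..., : lb + 1], other)
            cart += np.einsum("k,kab->ab", pair.coeff_product, term)
        out.append(_solid_transform(pair, -0.5 * cart))
    return OneBodyResult("kinetic", np.array(out), tuple(pairs))


def nuclear_batch(
    pairs, charges: ChargeSet, early_summation: bool = True
) -> OneBodyResult:
    """Nuclear-attraction blocks for the potential of ``charges``.

    ``early_summation`` selects the production path (charge sums inside the
    Hermite basis, one AO transform per primitive pair); disabling it
    reproduces the naive per-charge transform order, which is algebraically
    identical.
    """
    pairs = _as_pairs(pairs)
    out = []
    nI = len(charges)
    for pair in pairs:
        a, b = pair.shells
        nsa, nsb = a.nsolid, b.nsolid
        if nI == 0:
            out.append(np.zeros((nsa, nsb)))
            continue
        L = pair.L
        H = hmatrix(pair).values  # (K, nsa*nsb, nh)
        K = pair.K
        # lanes: primitive pair x charge
        zp = np.repeat(pair.zeta_p, nI)
        PI = (pair.P[:, None, :] - charges.positions[None, :, :]).reshape(-1, 3)
        base = base_terms_1p(zp, PI, L)
        R = build_r_block(base, PI, L).values.reshape(K, nI, -1)
        cc = pair.coeff_product
        if early_summation:
            w = np.einsum("i,kit->kt", charges.charges, R)
            block = -np.einsum("k,kst,kt->s", cc, H, w)
        else:
            per_charge = np.einsum("k,kst,kit->is", cc, H, R)
            block = -charges.charges @ per_charge
        out.append(block.reshape(nsa, nsb))
    return OneBodyResult("nuclear", np.array(out), tuple(pairs))


def one_body_matrix(
    shells: Sequence[Shell],
    operator: str,
    charges: ChargeSet | None = None,
) -> np.ndarray:
    """Dense operator matrix over the concatenated solid AOs of ``shells``."""
    ops = {"overlap": overlap_batch, "kinetic": kinetic_batch, "nuclear": None}
    if operator not in ops:
        raise ValueError(f"unknown operator {operator!r}")
    offsets = np.concatenate([[0], np.cumsum([s.nsolid for s in shells])])
    n = offsets[-1]
    mat = np.zeros((n, n))
    for i, si in enumerate(shells):
        for j, sj in enumerate(shells):
            if j < i:
                continue
            pair = ShellPair.from_shells(si, sj)
            if operator == "nuclear":
                blk = nuclear_batch([pair], charges or ChargeSet.empty()).values[0]
            else:
                blk = ops[operator]([pair]).values[0]
            mat[offsets[i] : offsets[i + 1], offsets[j] : offsets[j + 1]] = blk
            mat[offsets[j] : offsets[j + 1], offsets[i] : offsets[i + 1]] = blk.T
    return mat


def batch_tag(pairs) -> str:
    pairs = _as_pairs(pairs)
    a, b = pairs[0].shells
    return class_tag(a.l, b.l)
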