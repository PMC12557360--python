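"""Batched 2-, 3- and 4-center Coulomb repulsion integrals.

The evaluation chain per primitive bra x ket combination is

    [0]^(m)  --(3-term recursion)-->  [r]^(0)
             --(index addition, ket sign)-->  [p|q]
             --(ket transform, contraction-accumulated)-->  [p|ket]
             --(bra transform)-->  [bra|ket]

with the ket (conventionally the lower-l, higher-K side) transformed first.
Two exact algebraic rearrangements are built in:

* *Partial early contraction* (4-center, always available): the terminal
  Hermite components of the ket have the closed coefficient
  ``(2 zeta_q)^{-(lc+ld)} (E)_000``, so their contribution to the contracted
  ket is accumulated directly from ``[r]^(0)`` without forming the terminal
  columns of H.
* *Solid-bra terminal shortcut* (3-/2-center): a solid-harmonic 1-center
  function only touches Hermite triples of total degree exactly ``l``, so
  the bra transform collapses to the terminal map; when the bra is
  contracted, contraction happens already on the ``[0]^(m)`` base terms
  (the bra composite center does not depend on the primitive exponent).

Both optimized paths can be switched off, in which case the naive
full-transform order is used; the test suite asserts bit-level-tight
agreement between the routes.

Results are stored in the ``[ij, ab, cd, kl]`` column-major layout: ``ij``
(bra shell-pair index within the batch) fastest, then the bra and ket solid
AO pair indices ``ab`` and ``cd``, then ``kl``.  A streaming consumer can be
handed each freshly computed sub-batch before the full array materializes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .hermite_aux import base_terms_2p, build_r_block
from .shell_model import (
    Batch,
    InputError,
    Shell,
    ShellPair,
    class_tag,
    herm_exact_count,
    hermite_addition_table,
    hermite_triples,
    shell_dims,
)
from .spherical import hmatrix, terminal_solid_map

__all__ = ["EriResult", "eri4_batch", "eri3_batch", "eri2_batch", "assemble_layout"]

#: chunk size cap (elements) for the gathered [p|q] intermediate
_CHUNK_ELEMS = 4_000_000

Consumer = Callable[[str, tuple, np.ndarray], None]


@dataclass
class EriResult:
    """2-particle integral batch in ``[ij, ab, cd, kl]`` column-major order."""

    cls: str
    array: np.ndarray  # shape (nij, nab, ncd, nkl), F-ordered
    meta: dict = field(default_factory=dict)

    @property
    def flat(self) -> np.ndarray:
        return self.array.reshape(-1, order="F")

    def block(self, ij: int, kl: int) -> np.ndarray:
        """Solid AO block ``(nab, ncd)`` of one shellset."""
        return self.array[ij, :, :, kl]

    def index_of(self, ij: int, ab: int, cd: int, kl: int) -> int:
        nij, nab, ncd, _ = self.array.shape
        return ij + nij * (ab + nab * (cd + ncd * kl))

    def to_text(self, max_values: int = 10_000) -> str:
        """Whitespace dump ``ij ab cd kl value`` (small batches only)."""
        if self.array.size > max_values:
            raise InputError(
                f"{self.array.size} values exceed the text-dump cap {max_values}"
            )
        lines = [f"# class {self.cls} layout [ij,ab,cd,kl] column-major"]
        nij, nab, ncd, nkl = self.array.shape
        for kl in range(nkl):
            for cd in range(ncd):
                for ab in range(nab):
                    for ij in range(nij):
                        lines.append(
                            f"{ij} {ab} {cd} {kl} {self.array[ij, ab, cd, kl]:.16e}"
                        )
        return "\n".join(lines) + "\n"


def _as_list(batch, kind) -> list:
    members = list(batch.lanes) if isinstance(batch, Batch) else list(batch)
    if not members:
        raise InputError("empty batch")
    for m in members:
        if not isinstance(m, kind):
            raise InputError(f"expected {kind.__name__} members, got {type(m).__name__}")
    return members


def _ket_sign(L_ket: int) -> np.ndarray:
    """Per-column sign ``(-1)^{l_q}`` over ket Hermite triples."""
    return np.array([(-1.0) ** sum(t) for t in hermite_triples(L_ket)])


def _signed_ket_h(ket: ShellPair) -> np.ndarray:
    """Contraction-scaled ket H with the index-addition sign folded in."""
    H = hmatrix(ket).values  # (K, ncd, nh)
    return H * ket.coeff_product[:, None, None] * _ket_sign(ket.L)[None, None, :]


def _chunks(n: int, size: int):
    size = max(1, size)
    for lo in range(0, n, size):
        yield lo, min(n, lo + size)


# ---------------------------------------------------------------------------
# 4-center


def _eri4_block(
    bra: ShellPair, ket: ShellPair, early_contraction: bool
) -> np.ndarray:
    """One contracted shellset block ``(nab, ncd)``."""
    (a, b), (c, d) = bra.shells, ket.shells
    Lb, Lk = bra.L, ket.L
    L = Lb + Lk
    nhb = shell_dims(Lb)[2]
    nhk = shell_dims(Lk)[2]
    add = hermite_addition_table(Lb, Lk)  # (nhb, nhk)
    Hket = _signed_ket_h(ket)  # (Kk, ncd, nhk)
    ncd = Hket.shape[1]
    Kb, Kk = bra.K, ket.K

    if early_contraction:
        nex = herm_exact_count(Lk)
        Tk = terminal_solid_map(c.l, d.l)  # (ncd, nex)
        # terminal scalar per ket primitive, sign (-1)^Lk included
        s_term = (
            ket.coeff_product
            * ket.prefactor
            * (2.0 * ket.zeta_p) ** -Lk
            * (-1.0) ** Lk
        )
        Hket = Hket.copy()
        Hket[:, :, nhk - nex :] = 0.0
        add_term = add[:, nhk - nex :]

    pket = np.zeros((Kb, nhb, ncd))
    chunk = max(1, _CHUNK_ELEMS // max(1, Kb * nhb * nhk))
    for lo, hi in _chunks(Kk, chunk):
        nc = hi - lo
        zp = np.repeat(bra.zeta_p, nc)
        zq = np.tile(ket.zeta_p[lo:hi], Kb)
        PQ = (bra.P[:, None, :] - ket.P[None, lo:hi, :]).reshape(-1, 3)
        base = base_terms_2p(zp, zq, PQ, L)
        R = build_r_block(base, PQ, L).values.reshape(Kb, nc, -1)
        M = R[:, :, add]  # (Kb, nc, nhb, nhk)
        pket += np.einsum("bcpq,cdq->bpd", M, Hket[lo:hi], optimize=True)
        if early_contraction:
            Rt = R[:, :, add_term]  # (Kb, nc, nhb, nex)
            pket += np.einsum(
                "bcpe,de,c->bpd", Rt, Tk, s_term[lo:hi], optimize=True
            )
    Hbra = hmatrix(bra).values * bra.coeff_product[:, None, None]  # (Kb, nab, nhb)
    return np.einsum("kap,kpd->ad", Hbra, pket, optimize=True)


def eri4_batch(
    bra_pairs,
    ket_pairs,
    early_contraction: bool = True,
    consumer: Consumer | None = None,
    lane_width: int = 8,
    screen_bounds: tuple[np.ndarray, np.ndarray] | None = None,
    screen_threshold: float = 0.0,
) -> EriResult:
    """4-center Coulomb integrals for all bra-pair x ket-pair shellsets.

    The ket is expected to carry the lower angular momentum and higher
    contraction degree; if the roles are reversed the batch is computed with
    bra and ket swapped (with a warning) and the output is permuted back.
    Optional screening skips shellsets whose ``bra_bound * ket_bound`` falls
    below ``screen_threshold`` (bounds are caller-supplied; none are
    estimated here).
    """
    bras = _as_list(bra_pairs, ShellPair)
    kets = _as_list(ket_pairs, ShellPair)
    if _should_swap(bras[0], kets[0]):
        warnings.warn(
            "ket has higher l (or lower K) than bra; swapping roles internally",
            stacklevel=2,
        )
        swapped = eri4_batch(
            ket_pairs,
            bra_pairs,
            early_contraction=early_contraction,
            lane_width=lane_width,
        )
        arr = np.asfortranarray(swapped.array.transpose(3, 2, 1, 0))
        return EriResult(cls=_cls4(bras[0], kets[0]), array=arr, meta=swapped.meta)

    nab = bras[0].nsolid_pair
    ncd = kets[0].nsolid_pair
    arr = np.zeros((len(bras), nab, ncd, len(kets)), order="F")
    skipped = 0
    tag = _cls4(bras[0], kets[0])
    for kl, ket in enumerate(kets):
        for ij, bra in enumerate(bras):
            if screen_bounds is not None:
                if screen_bounds[0][ij] * screen_bounds[1][kl] < screen_threshold:
                    skipped += 1
                    continue
            arr[ij, :, :, kl] = _eri4_block(bra, ket, early_contraction)
        _consume(consumer, tag, arr, kl, lane_width)
    return EriResult(cls=tag, array=arr, meta={"skipped": skipped})


def _cls4(bra: ShellPair, ket: ShellPair) -> str:
    return class_tag(
        bra.shells[0].l, bra.shells[1].l, ket.shells[0].l, ket.shells[1].l
    )


def _should_swap(bra: ShellPair, ket: ShellPair) -> bool:
    # higher l -> bra; tie -> higher K -> ket
    if ket.L != bra.L:
        return ket.L > bra.L
    return bra.K > ket.K


def _consume(consumer, tag, arr, kl, lane_width):
    if consumer is None:
        return
    for lo, hi in _chunks(arr.shape[0], lane_width):
        consumer(tag, (slice(lo, hi), kl), arr[lo:hi, :, :, kl])


# ---------------------------------------------------------------------------
# 3-center


def _eri3_block(bra: Shell, ket: ShellPair, bra_shortcut: bool) -> np.ndarray:
    la = bra.l
    Lk = ket.L
    L = la + Lk
    nhk = shell_dims(Lk)[2]
    Hket = _signed_ket_h(ket)  # (Kk, ncd, nhk)
    ncd = Hket.shape[1]
    Kk = ket.K

    if bra_shortcut:
        # early bra contraction on the base terms; terminal bra map only
        nhb = shell_dims(la)[2]
        nexb = herm_exact_count(la)
        Tb = terminal_solid_map(la, 0)  # (2la+1, nexb)
        add = hermite_addition_table(la, Lk)[nhb - nexb :, :]  # (nexb, nhk)
        w = bra.coefficients * (2.0 * bra.exponents) ** -la  # (Ka,)
        zq = ket.zeta_p
        PQ = bra.center[None, :] - ket.P  # (Kk, 3)
        # contract [0]^(m) over bra primitives: P == A for every primitive
        base = np.zeros((Kk, L + 1))
        for k, (zk, wk) in enumerate(zip(bra.exponents, w)):
            base += wk * base_terms_2p(np.full(Kk, zk), zq, PQ, L)
        R = build_r_block(base, PQ, L).values  # (Kk, nherm(L))
        M = R[:, add]  # (Kk, nexb, nhk)
        return np.einsum("ae,keq,kdq->ad", Tb, M, Hket, optimize=True)

    # naive: full-range solid H over all bra triples <= la, per bra primitive
    nhb = shell_dims(la)[2]
    add = hermite_addition_table(la, Lk)
    Hbra = (
        hmatrix(bra, shortcut=False).values * bra.coefficients[:, None, None]
    )  # (Ka, 2la+1, nhb)
    Ka = bra.K
    zp = np.repeat(bra.exponents, Kk)
    zq = np.tile(ket.zeta_p, Ka)
    PQ = np.tile(bra.center[None, :] - ket.P, (Ka, 1))
    base = base_terms_2p(zp, zq, PQ, L)
    R = build_r_block(base, PQ, L).values.reshape(Ka, Kk, -1)
    M = R[:, :, add]  # (Ka, Kk, nhb, nhk)
    return np.einsum("bap,bkpq,kdq->ad", Hbra, M, Hket, optimize=True)


def eri3_batch(
    bras,
    ket_pairs,
    bra_shortcut: bool = True,
    consumer: Consumer | None = None,
    lane_width: int = 8,
) -> EriResult:
    """3-center Coulomb integrals ``[a|cd]`` for 1-center solid bras.

    ``bra_shortcut`` enables the solid-bra terminal path with early bra
    contraction of the base terms; disabling it runs the full-range Hermite
    transform (the two are algebraically identical).
    """
    shells = _as_list(bras, Shell)
    kets = _as_list(ket_pairs, ShellPair)
    nab = shells[0].nsolid
    ncd = kets[0].nsolid_pair
    arr = np.zeros((len(shells), nab, ncd, len(kets)), order="F")
    tag = class_tag(shells[0].l, kets[0].shells[0].l, kets[0].shells[1].l)
    for kl, ket in enumerate(kets):
        for ij, bra in enumerate(shells):
            arr[ij, :, :, kl] = _eri3_block(bra, ket, bra_shortcut)
        _consume(consumer, tag, arr, kl, lane_width)
    return EriResult(cls=tag, array=arr, meta={})


# ---------------------------------------------------------------------------
# 2-center


def _eri2_block(bra: Shell, ket: Shell) -> np.ndarray:
    la, lb = bra.l, ket.l
    L = la + lb
    nhb, nhk = shell_dims(la)[2], shell_dims(lb)[2]
    nexa, nexb = herm_exact_count(la), herm_exact_count(lb)
    Ta = terminal_solid_map(la, 0)
    Tb = terminal_solid_map(lb, 0)
    add = hermite_addition_table(la, lb)[nhb - nexa :, nhk - nexb :]
    wa = bra.coefficients * (2.0 * bra.exponents) ** -la
    wb = ket.coefficients * (2.0 * ket.exponents) ** -lb
    PQ = bra.center - ket.center
    # both sides contract on the base terms (P = A, Q = B for all primitives)
    zp = np.repeat(bra.exponents, ket.K)
    zq = np.tile(ket.exponents, bra.K)
    ww = np.outer(wa, wb).ravel()
    base = base_terms_2p(zp, zq, np.tile(PQ, (zp.size, 1)), L)
    base = ww @ base  # (L+1,)
    R = build_r_block(base[None, :], PQ[None, :], L).values[0]
    M = R[add] * (-1.0) ** lb
    return np.einsum("ae,bf,ef->ab", Ta, Tb, M, optimize=True)


def eri2_batch(
    bras,
    kets,
    consumer: Consumer | None = None,
    lane_width: int = 8,
) -> EriResult:
    """2-center Coulomb integrals ``[a|b]`` over 1-center solid shells.

    Both sides use the terminal solid shortcut with contraction applied
    directly to the base terms.
    """
    bshells = _as_list(bras, Shell)
    kshells = _as_list(kets, Shell)
    nab = bshells[0].nsolid
    ncd = kshells[0].nsolid
    arr = np.zeros((len(bshells), nab, ncd, len(kshells)), order="F")
    tag = class_tag(bshells[0].l, kshells[0].l)
    for kl, ket in enumerate(kshells):
        for ij, bra in enumerate(bshells):
            arr[ij, :, :, kl] = _eri2_block(bra, ket)
        _consume(consumer, tag, arr, kl, lane_width)
    return EriResult(cls=tag, array=arr, meta={})


# ---------------------------------------------------------------------------
# layout


def assemble_layout(
    blocks: Sequence[Sequence[np.ndarray]],
    cls: str,
    consumer: Consumer | None = None,
    lane_width: int = 8,
) -> EriResult:
    """Assemble per-shellset blocks into the ``[ij, ab, cd, kl]`` layout.

    ``blocks[kl][ij]`` is the ``(nab, ncd)`` solid block of one shellset;
    the flattened result orders ``ij`` fastest and ``kl`` slowest.
    """
    nkl = len(blocks)
    nij = len(blocks[0])
    nab, ncd = np.asarray(blocks[0][0]).shape
    arr = np.zeros((nij, nab, ncd, nkl), order="F")
    for kl in range(nkl):
        if len(blocks[kl]) != nij:
            raise InputError("ragged block table")
        for ij in range(nij):
            arr[ij, :, :, kl] = blocks[kl][ij]
        _consume(consumer, cls, arr, kl, lane_width)
    return EriResult(cls=cls, array=arr, meta={})
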