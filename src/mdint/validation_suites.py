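"""Randomized validation suites driving the engines against their oracles.

Each suite draws shellsets from the fixture generator under the benchmark
conditions (log-uniform exponents, contraction degrees from {1, 5, 10},
angular momenta up to g), runs a production path and its reference path, and
reports the worst deviation.  Deviations for the exact-rearrangement
identities are measured relative to the largest magnitude in each batch:
the two routes sum identical primitive contributions in different orders,
so their difference is reassociation noise at the scale of the largest
contribution, not of individual (possibly cancellation-suppressed) entries.

Used by both the test suite and the reproduction script.
"""

from __future__ import annotations

import warnings

import numpy as np

from .boys import boys_eval, boys_reference
from .one_particle import kinetic_batch, nuclear_batch, overlap_batch
from .oracle_validation import eri_highprec, nuclear_highprec, quadrature_1p
from .shell_model import ChargeSet, Shell, ShellPair, random_shell
from .two_particle import eri2_batch, eri3_batch, eri4_batch

__all__ = [
    "boys_sweep",
    "suite_early_charge_summation",
    "suite_early_contraction",
    "suite_bra_shortcut",
    "suite_oracle_agreement",
    "suite_symmetries",
]

K_POOL = (1, 5, 10)
L_SUITE_MAX = 4


def _scale_dev(got: np.ndarray, want: np.ndarray) -> float:
    scale = float(np.max(np.abs(want), initial=0.0)) or 1.0
    return float(np.max(np.abs(got - want))) / scale


def _spawn(seed: int, n: int):
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def _rand_shell(rng: np.random.Generator, l: int, K: int) -> Shell:
    return random_shell(l, K, seed=int(rng.integers(2**31)), center_scale=1.0)


def _assign_roles(p1: ShellPair, p2: ShellPair) -> tuple[ShellPair, ShellPair]:
    """Bra gets the higher total l; on a tie the higher-K side becomes ket."""
    if p2.L > p1.L or (p1.L == p2.L and p1.K > p2.K):
        return p2, p1
    return p1, p2


def _rand_pair(rng: np.random.Generator, lmax: int = L_SUITE_MAX) -> ShellPair:
    la, lb = rng.integers(0, lmax + 1, size=2)
    Ka, Kb = rng.choice(K_POOL, size=2)
    return ShellPair.from_shells(
        _rand_shell(rng, int(la), int(Ka)), _rand_shell(rng, int(lb), int(Kb))
    )


def _rand_pair_lanes(
    rng: np.random.Generator, n: int, lmax: int = L_SUITE_MAX
) -> list[ShellPair]:
    """``n`` independent shell pairs sharing one class signature (l's, K's)."""
    la, lb = (int(v) for v in rng.integers(0, lmax + 1, size=2))
    Ka, Kb = (int(v) for v in rng.choice(K_POOL, size=2))
    return [
        ShellPair.from_shells(_rand_shell(rng, la, Ka), _rand_shell(rng, lb, Kb))
        for _ in range(n)
    ]


def boys_sweep(n_points: int = 100_000, seed: int = 0) -> dict:
    """Production Boys evaluator vs the extended-precision reference.

    Points span the interpolation range, both asymptotic regimes and the
    branch thresholds, for orders covering every branch-selection rule.
    Returns the worst relative deviation (denominator floored at 1e-290,
    below which values underflow to zero by design).
    """
    rng = np.random.default_rng(seed)
    xs = np.concatenate(
        [
            rng.uniform(0.0, 130.0, n_points // 2),
            np.exp(rng.uniform(np.log(1e-6), np.log(130.0), n_points // 4)),
            36.0 + rng.uniform(-0.5, 0.5, n_points // 8),
            118.0 + rng.uniform(-0.5, 0.5, n_points - 2 * (n_points // 2) + n_points // 8),
        ]
    )
    xs = np.abs(xs)
    worst = 0.0
    n_used = 0
    for L in (2, 8, 12, 20):
        sel = rng.choice(xs.size, size=xs.size // 4, replace=False)
        x = xs[sel]
        got = boys_eval(x, L)
        want = boys_reference(x, L)
        rel = np.abs(got - want) / np.maximum(np.abs(want), 1e-290)
        worst = max(worst, float(rel.max()))
        n_used += x.size
    return {"max_rel_dev": worst, "n": n_used}


def suite_early_charge_summation(n_batches: int = 100, seed: int = 0) -> dict:
    """Early point-charge summation path vs naive per-charge transforms."""
    worst = 0.0
    for s in _spawn(seed, n_batches):
        rng = np.random.default_rng(s)
        pairs = _rand_pair_lanes(rng, 4)
        nI = int(rng.integers(5, 30))
        charges = ChargeSet(rng.normal(size=nI), 2.0 * rng.normal(size=(nI, 3)))
        early = nuclear_batch(pairs, charges, early_summation=True).values
        naive = nuclear_batch(pairs, charges, early_summation=False).values
        worst = max(worst, _scale_dev(early, naive))
    return {"max_rel_dev": worst, "n": n_batches}


def suite_early_contraction(n_batches: int = 100, seed: int = 0) -> dict:
    """Partial early ket contraction vs the naive full ket transform."""
    worst = 0.0
    for s in _spawn(seed, n_batches):
        rng = np.random.default_rng(s)
        b1, b2 = _rand_pair_lanes(rng, 2), _rand_pair_lanes(rng, 2)
        bras, kets = (b1, b2) if _assign_roles(b1[0], b2[0])[0] is b1[0] else (b2, b1)
        fast = eri4_batch(bras, kets, early_contraction=True).array
        naive = eri4_batch(bras, kets, early_contraction=False).array
        worst = max(worst, _scale_dev(fast, naive))
    return {"max_rel_dev": worst, "n": n_batches}


def suite_bra_shortcut(n_batches: int = 100, seed: int = 0) -> dict:
    """Solid-harmonic terminal-bra shortcut vs the full-range transform."""
    worst = 0.0
    for s in _spawn(seed, n_batches):
        rng = np.random.default_rng(s)
        la = int(rng.integers(0, L_SUITE_MAX + 1))
        Ka = int(rng.choice(K_POOL))
        bras = [_rand_shell(rng, la, Ka) for _ in range(2)]
        kets = _rand_pair_lanes(rng, 2)
        fast = eri3_batch(bras, kets, bra_shortcut=True).array
        full = eri3_batch(bras, kets, bra_shortcut=False).array
        worst = max(worst, _scale_dev(fast, full))
    return {"max_rel_dev": worst, "n": n_batches}


def suite_oracle_agreement(seed: int = 0) -> dict:
    """Engines vs the extended-precision scalar chain and direct quadrature."""
    rng = np.random.default_rng(seed)
    out: dict = {}

    def shell(l, K):
        return _rand_shell(rng, l, K)

    # 4-center (pd|ds), contracted ket
    a, b = shell(1, 5), shell(2, 1)
    c, d = shell(2, 2), shell(0, 5)
    got = eri4_batch([ShellPair.from_shells(a, b)], [ShellPair.from_shells(c, d)])
    want = eri_highprec((a, b, c, d))
    out["eri4_pdds"] = _scale_dev(got.array[0, :, :, 0], want)
    # 3-center (d|pp)
    x = shell(2, 2)
    k1, k2 = shell(1, 2), shell(1, 1)
    got = eri3_batch([x], [ShellPair.from_shells(k1, k2)])
    out["eri3_dpp"] = _scale_dev(
        got.array[0, :, :, 0], eri_highprec((x, k1, k2))
    )
    # 2-center (d|d)
    u, v = shell(2, 2), shell(2, 3)
    got = eri2_batch([u], [v])
    out["eri2_dd"] = _scale_dev(got.array[0, :, :, 0], eri_highprec((u, v)))
    # 1-particle nuclear vs scalar chain
    pair = ShellPair.from_shells(shell(2, 2), shell(1, 2))
    charges = ChargeSet(rng.normal(size=4), rng.normal(size=(4, 3)))
    out["nuclear_dp"] = _scale_dev(
        nuclear_batch([pair], charges).values[0],
        nuclear_highprec(pair, charges),
    )
    # l <= 2 quadrature of the defining integrals
    qpair = ShellPair.from_shells(shell(2, 1), shell(1, 1))
    out["overlap_quadrature"] = _scale_dev(
        overlap_batch([qpair]).values[0], quadrature_1p(qpair, "overlap")
    )
    out["kinetic_quadrature"] = _scale_dev(
        kinetic_batch([qpair]).values[0], quadrature_1p(qpair, "kinetic")
    )
    qch = ChargeSet(np.array([1.0, -0.5]), rng.normal(size=(2, 3)))
    spair = ShellPair.from_shells(shell(1, 1), shell(1, 1))
    out["nuclear_quadrature"] = _scale_dev(
        nuclear_batch([spair], qch).values[0],
        quadrature_1p(spair, "nuclear", qch),
    )
    return out


def suite_symmetries(n_batches: int = 25, seed: int = 0) -> dict:
    """Particle exchange, translation invariance, parity zeros, charge order."""
    out = {"exchange": 0.0, "translation": 0.0, "parity": 0.0, "charge_perm": 0.0}
    for s in _spawn(seed, n_batches):
        rng = np.random.default_rng(s)
        p1, p2 = _rand_pair(rng, lmax=3), _rand_pair(rng, lmax=3)
        bra, ket = _assign_roles(p1, p2)
        v = eri4_batch([bra], [ket]).array[0, :, :, 0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = eri4_batch([ket], [bra]).array[0, :, :, 0]
        out["exchange"] = max(out["exchange"], _scale_dev(w.T, v))

        shift = rng.normal(size=3)
        bra2 = ShellPair.from_shells(
            *(Shell(sh.center + shift, sh.l, sh.exponents, sh.coefficients)
              for sh in bra.shells)
        )
        ket2 = ShellPair.from_shells(
            *(Shell(sh.center + shift, sh.l, sh.exponents, sh.coefficients)
              for sh in ket.shells)
        )
        v2 = eri4_batch([bra2], [ket2]).array[0, :, :, 0]
        out["translation"] = max(out["translation"], _scale_dev(v2, v))

        # parity: same-center (p|p) blocks are diagonal
        p = _rand_shell(rng, 1, int(rng.choice(K_POOL)))
        blk = eri2_batch([p], [p]).array[0, :, :, 0]
        off = blk - np.diag(np.diag(blk))
        out["parity"] = max(
            out["parity"], float(np.max(np.abs(off)) / np.max(np.abs(blk)))
        )

        pair = _rand_pair(rng, lmax=2)
        nI = 10
        q = rng.normal(size=nI)
        pos = rng.normal(size=(nI, 3))
        perm = rng.permutation(nI)
        n1 = nuclear_batch([pair], ChargeSet(q, pos)).values
        n2 = nuclear_batch([pair], ChargeSet(q[perm], pos[perm])).values
        out["charge_perm"] = max(out["charge_perm"], _scale_dev(n2, n1))
    return out
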