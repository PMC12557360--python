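"""2-, 3- and 4-center Coulomb engines: closed forms, identities, layout."""

import math
import warnings

import numpy as np
import pytest

from conftest import rand_pair, rand_shell, rel_dev, scale_dev
from mdint.shell_model import Batch, InputError, Shell, ShellPair, shell_dims
from mdint.two_particle import (
    assemble_layout,
    eri2_batch,
    eri3_batch,
    eri4_batch,
)


def unit_s(center=(0, 0, 0), zeta=1.0):
    return Shell(np.array(center, float), 0, np.array([zeta]), np.array([1.0]))


class TestClosedForms:
    def test_ssss_coincident(self):
        p = ShellPair.from_shells(unit_s(), unit_s())
        v = eri4_batch([p], [p]).array[0, 0, 0, 0]
        np.testing.assert_allclose(v, math.pi**2.5 / 4, rtol=1e-14)

    def test_eri2_ss_coincident(self):
        v = eri2_batch([unit_s()], [unit_s()]).array[0, 0, 0, 0]
        np.testing.assert_allclose(v, 2 * math.pi**2.5 / math.sqrt(2), rtol=1e-14)

    def test_eri3_sss_matches_dummy_reduction(self):
        s = unit_s()
        ket = ShellPair.from_shells(unit_s(), unit_s())
        v3 = eri3_batch([s], [ket]).array[0, 0, 0, 0]
        pair = ShellPair.from_shells(s, Shell.dummy(s.center))
        v4 = eri4_batch([pair], [ket], early_contraction=False).array[0, 0, 0, 0]
        np.testing.assert_allclose(v3, v4, rtol=1e-13)

    def test_pp_same_center_diagonal(self):
        p = rand_shell(1, 1, seed=61)
        blk = eri2_batch([p], [p]).array[0, :, :, 0]
        off = blk - np.diag(np.diag(blk))
        assert np.max(np.abs(off)) < 1e-14 * np.max(np.abs(blk))


class TestEarlyContraction:
    @pytest.mark.parametrize(
        "ls, Ks",
        [
            ((2, 1, 1, 0), (1, 2, 5, 2)),  # (dp|ps)
            ((3, 2, 2, 0), (1, 1, 5, 2)),  # (fd|ds)
            ((1, 1, 1, 1), (2, 2, 2, 2)),  # (pp|pp)
        ],
    )
    def test_equivalence_with_naive_ket_transform(self, ls, Ks):
        bra = rand_pair(ls[0], ls[1], Ks[0], Ks[1], seed=sum(ls) * 13 + 1)
        ket = rand_pair(ls[2], ls[3], Ks[2], Ks[3], seed=sum(Ks) * 17 + 2)
        fast = eri4_batch([bra], [ket], early_contraction=True).array
        naive = eri4_batch([bra], [ket], early_contraction=False).array
        assert scale_dev(fast, naive) < 1e-12

    def test_ss_ket_is_pure_terminal(self):
        # for an (ss) ket the whole transform is the terminal term
        bra = rand_pair(2, 1, 2, 1, seed=71)
        ket = rand_pair(0, 0, 3, 1, seed=72)
        fast = eri4_batch([bra], [ket], early_contraction=True).array
        naive = eri4_batch([bra], [ket], early_contraction=False).array
        assert scale_dev(fast, naive) < 1e-13

    def test_d_hermite_terminal_share(self):
        # 6 of the 10 Hermite Gaussians of an l = 2 ket flow terminally
        from mdint.shell_model import herm_exact_count

        assert herm_exact_count(2) == 6
        assert shell_dims(2)[2] == 10


class TestSolidBraShortcut:
    @pytest.mark.parametrize(
        "la, kls, Ks",
        [(2, (1, 1), (3, 2, 2)), (4, (2, 1), (1, 1, 2)), (1, (0, 0), (5, 2, 1))],
    )
    def test_equivalence_with_full_range(self, la, kls, Ks):
        bra = rand_shell(la, Ks[0], seed=100 + la)
        ket = rand_pair(kls[0], kls[1], Ks[1], Ks[2], seed=200 + la)
        fast = eri3_batch([bra], [ket], bra_shortcut=True).array
        full = eri3_batch([bra], [ket], bra_shortcut=False).array
        assert scale_dev(fast, full) < 1e-12

    def test_eri3_vs_eri4_dummy(self):
        bra = rand_shell(2, 3, seed=301)
        ket = rand_pair(1, 1, 2, 2, seed=302)
        v3 = eri3_batch([bra], [ket]).array[0, :, :, 0]
        pair = ShellPair.from_shells(bra, Shell.dummy(bra.center))
        v4 = eri4_batch([pair], [ket], early_contraction=False).array[0, :, :, 0]
        assert rel_dev(v3, v4) < 1e-12

    def test_eri2_vs_eri4_double_dummy(self):
        a = rand_shell(2, 2, seed=311)
        b = rand_shell(2, 3, seed=312)
        v2 = eri2_batch([a], [b]).array[0, :, :, 0]
        pa = ShellPair.from_shells(a, Shell.dummy(a.center))
        pb = ShellPair.from_shells(b, Shell.dummy(b.center))
        v4 = eri4_batch([pa], [pb], early_contraction=False).array[0, :, :, 0]
        assert rel_dev(v2, v4) < 1e-10


class TestSymmetries:
    def test_particle_exchange(self):
        bra = rand_pair(2, 1, 2, 1, seed=401)
        ket = rand_pair(1, 0, 1, 2, seed=402)
        v = eri4_batch([bra], [ket]).array[0, :, :, 0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = eri4_batch([ket], [bra]).array[0, :, :, 0]
        assert rel_dev(w.T, v) < 1e-13

    def test_bra_within_pair_swap_is_row_permutation(self):
        a, b = rand_shell(1, 1, seed=411), rand_shell(2, 1, seed=412)
        ket = rand_pair(1, 0, 2, 1, seed=413)
        v1 = eri4_batch([ShellPair.from_shells(a, b)], [ket]).array[0]
        v2 = eri4_batch([ShellPair.from_shells(b, a)], [ket]).array[0]
        n1, n2 = a.nsolid, b.nsolid
        perm = v1.reshape(n1, n2, -1).transpose(1, 0, 2).reshape(n1 * n2, -1)
        assert rel_dev(v2, perm.reshape(v2.shape)) < 1e-13

    def test_translation_invariance(self):
        shift = np.array([0.9, -0.2, 1.4])

        def shifted(sh):
            return Shell(sh.center + shift, sh.l, sh.exponents, sh.coefficients)

        bra = rand_pair(2, 1, 2, 2, seed=421)
        ket = rand_pair(1, 1, 2, 1, seed=422)
        v = eri4_batch([bra], [ket]).array
        bra2 = ShellPair.from_shells(*(shifted(s) for s in bra.shells))
        ket2 = ShellPair.from_shells(*(shifted(s) for s in ket.shells))
        w = eri4_batch([bra2], [ket2]).array
        assert rel_dev(w, v) < 1e-12

    def test_automatic_role_swap_warns_and_matches(self):
        bra = rand_pair(0, 0, 2, 1, seed=431)  # low-l bra violates convention
        ket = rand_pair(2, 1, 1, 1, seed=432)
        with pytest.warns(UserWarning, match="swapping"):
            v = eri4_batch([bra], [ket]).array
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = eri4_batch([ket], [bra]).array
        assert rel_dev(v[0, :, :, 0], w[0, :, :, 0].T) < 1e-13


class TestBatchingAndLayout:
    def test_batched_equals_single_lane(self):
        bras = [rand_pair(1, 1, 2, 1, seed=500 + i) for i in range(2)]
        kets = [rand_pair(1, 0, 2, 2, seed=510 + i) for i in range(2)]
        full = eri4_batch(bras, kets).array
        for ij in range(2):
            for kl in range(2):
                single = eri4_batch([bras[ij]], [kets[kl]]).array[0, :, :, 0]
                np.testing.assert_array_equal(full[ij, :, :, kl], single)

    def test_text_dump_roundtrip(self):
        bras = [ShellPair.from_shells(unit_s(), unit_s(zeta=z)) for z in (1.0, 2.0)]
        res = eri4_batch(bras, bras)
        lines = [l for l in res.to_text().splitlines() if not l.startswith("#")]
        assert len(lines) == res.flat.size
        vals = np.array([float(l.split()[-1]) for l in lines])
        np.testing.assert_array_equal(vals, res.flat)
        with pytest.raises(InputError):
            res.to_text(max_values=2)

    def test_flat_layout_indexing(self):
        bras = [ShellPair.from_shells(unit_s(), unit_s(zeta=z)) for z in (1.0, 2.0)]
        kets = [ShellPair.from_shells(unit_s(zeta=z), unit_s()) for z in (1.0, 3.0)]
        res = eri4_batch(bras, kets)
        flat = res.flat
        assert flat.size == 4
        assert res.index_of(1, 0, 0, 0) == 1
        np.testing.assert_array_equal(
            flat, res.array.reshape(-1, order="F")
        )
        assert flat[res.index_of(1, 0, 0, 1)] == res.array[1, 0, 0, 1]

    def test_hh_pair_intermediate_counts(self):
        # an (hh| bra pair spans 286 Hermite components; (hh|hh) pairs 286^2
        n = shell_dims(5 + 5)[2]
        assert n == 286
        assert n * n == 81796

    def test_streaming_consumer_covers_array(self):
        bras = [rand_pair(1, 0, 1, 1, seed=520 + i) for i in range(3)]
        kets = [rand_pair(0, 0, 2, 1, seed=530 + i) for i in range(2)]
        seen = []

        def consumer(tag, where, view):
            seen.append((tag, where, view.copy()))

        res = eri4_batch(bras, kets, consumer=consumer, lane_width=2)
        assert all(tag == res.cls for tag, _, _ in seen)
        # union of views reconstructs the array
        rebuilt = np.zeros_like(res.array)
        for _, (ij_slice, kl), view in seen:
            rebuilt[ij_slice, :, :, kl] = view
        np.testing.assert_array_equal(rebuilt, res.array)
        # 3 ij lanes at width 2 -> 2 sub-batches per kl column
        assert len(seen) == 2 * 2

    def test_assemble_layout_matches_engine(self):
        bras = [rand_pair(1, 0, 1, 1, seed=540 + i) for i in range(2)]
        kets = [rand_pair(0, 0, 1, 1, seed=550 + i) for i in range(2)]
        res = eri4_batch(bras, kets)
        blocks = [
            [res.array[ij, :, :, kl] for ij in range(2)] for kl in range(2)
        ]
        asm = assemble_layout(blocks, res.cls)
        np.testing.assert_array_equal(asm.array, res.array)
        with pytest.raises(InputError):
            assemble_layout([[blocks[0][0]], blocks[1]], res.cls)

    def test_screening_skips_blocks(self):
        bras = [rand_pair(1, 0, 1, 1, seed=560 + i) for i in range(2)]
        kets = [rand_pair(0, 0, 1, 1, seed=570 + i) for i in range(2)]
        bounds = (np.array([1.0, 0.0]), np.array([1.0, 1.0]))
        res = eri4_batch(
            bras, kets, screen_bounds=bounds, screen_threshold=0.5
        )
        assert res.meta["skipped"] == 2
        assert np.all(res.array[1] == 0.0)
        assert np.any(res.array[0] != 0.0)

    def test_homogeneous_batch_enforced(self):
        with pytest.raises(InputError):
            Batch("x", [rand_pair(1, 0, 1, 1, seed=1), rand_pair(2, 0, 1, 1, seed=2)])

    def test_empty_batch_rejected(self):
        with pytest.raises(InputError):
            eri4_batch([], [])
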