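"""Shell arithmetic, pair data, fixture generator, file formats."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from mdint.shell_model import (
    ANGSTROM_TO_BOHR,
    ChargeSet,
    InputError,
    Shell,
    ShellPair,
    cartesian_components,
    herm_exact_count,
    hermite_addition_table,
    hermite_index,
    hermite_triples,
    make_shell_pairs,
    random_shell,
    read_charges,
    read_gbs,
    read_xyz,
    shell_dims,
    write_gbs,
    write_xyz,
)


class TestShellDims:
    @pytest.mark.parametrize(
        "l, expected",
        [
            (0, (1, 1, 1)),
            (2, (5, 6, 10)),  # 10 Hermite Gaussians in a d Hermite shell
            (10, (21, 66, 286)),  # 286 per (hh| side
        ],
    )
    def test_worked_values(self, l, expected):
        assert shell_dims(l) == expected

    @given(st.integers(min_value=0, max_value=12))
    def test_nherm_matches_enumeration(self, l):
        brute = sum(
            1
            for x in range(l + 1)
            for y in range(l + 1)
            for z in range(l + 1)
            if x + y + z <= l
        )
        assert shell_dims(l)[2] == brute

    @pytest.mark.parametrize("l, expected", [(0, 1), (2, 6), (5, 21)])
    def test_exact_count(self, l, expected):
        assert herm_exact_count(l) == expected

    @given(st.integers(min_value=0, max_value=12))
    def test_exact_counts_sum_to_cumulative(self, l):
        assert sum(herm_exact_count(d) for d in range(l + 1)) == shell_dims(l)[2]

    def test_negative_l_rejected(self):
        with pytest.raises(InputError):
            shell_dims(-1)


class TestHermiteOrdering:
    def test_graded_and_contiguous(self):
        tr = hermite_triples(4)
        degs = [sum(t) for t in tr]
        assert degs == sorted(degs)
        assert len(tr) == shell_dims(4)[2]
        assert len(set(tr)) == len(tr)

    def test_addition_table_consistent(self):
        add = hermite_addition_table(2, 3)
        tr_b, tr_k = hermite_triples(2), hermite_triples(3)
        idx = hermite_index(5)
        for i, p in enumerate(tr_b):
            for j, q in enumerate(tr_k):
                s = (p[0] + q[0], p[1] + q[1], p[2] + q[2])
                assert add[i, j] == idx[s]


class TestShellPair:
    def test_prefactor_one_for_coincident_centers(self):
        a = Shell(np.ones(3), 1, np.array([2.0, 0.3]), np.array([0.5, 0.5]))
        b = Shell(np.ones(3), 0, np.array([1.1]), np.array([1.0]))
        pair = ShellPair.from_shells(a, b)
        assert np.all(pair.prefactor == 1.0)

    def test_equal_exponent_midpoint(self):
        a = Shell(np.zeros(3), 0, np.array([1.3]), np.array([1.0]))
        b = Shell(np.array([1.0, 0, 0]), 0, np.array([1.3]), np.array([1.0]))
        pair = ShellPair.from_shells(a, b)
        np.testing.assert_allclose(pair.P[0], [0.5, 0, 0])

    def test_prefactor_value(self):
        a = Shell(np.zeros(3), 0, np.array([1.0]), np.array([1.0]))
        b = Shell(np.array([1.0, 0, 0]), 0, np.array([1.0]), np.array([1.0]))
        pair = ShellPair.from_shells(a, b)
        np.testing.assert_allclose(pair.prefactor[0], math.exp(-0.5), rtol=1e-15)

    def test_zeta_p_is_sum_and_translation_invariance(self):
        rng = np.random.default_rng(5)
        a = random_shell(2, 3, seed=1, center_scale=1.0)
        b = random_shell(1, 2, seed=2, center_scale=1.0)
        pair = ShellPair.from_shells(a, b)
        np.testing.assert_array_equal(pair.zeta_p, pair.zeta_a + pair.zeta_b)
        shift = rng.normal(size=3)
        a2 = Shell(a.center + shift, a.l, a.exponents, a.coefficients)
        b2 = Shell(b.center + shift, b.l, b.exponents, b.coefficients)
        pair2 = ShellPair.from_shells(a2, b2)
        np.testing.assert_allclose(pair2.prefactor, pair.prefactor, rtol=1e-14)

    def test_make_shell_pairs_product(self):
        a = [random_shell(1, 1, seed=i) for i in range(2)]
        b = [random_shell(0, 2, seed=10 + i) for i in range(3)]
        pairs = make_shell_pairs(a, b)
        assert len(pairs) == 6
        with pytest.raises(InputError):
            make_shell_pairs([], b)


class TestRandomShell:
    def test_deterministic(self):
        s1 = random_shell(2, 5, seed=42)
        s2 = random_shell(2, 5, seed=42)
        np.testing.assert_array_equal(s1.exponents, s2.exponents)
        np.testing.assert_array_equal(s1.coefficients, s2.coefficients)

    def test_single_primitive_coefficient_range(self):
        s = random_shell(0, 1, seed=3)
        assert s.K == 1
        assert 0.2 <= abs(s.coefficients[0]) <= 1.0

    def test_log_uniform_exponents(self):
        lo, hi = 0.05, 50.0
        draws = np.concatenate(
            [random_shell(0, 10, seed=s, exp_range=(lo, hi)).exponents
             for s in range(1000)]
        )
        assert draws.min() >= lo and draws.max() <= hi
        u = (np.log(draws) - math.log(lo)) / (math.log(hi) - math.log(lo))
        assert stats.kstest(u, "uniform").pvalue > 1e-3

    def test_invalid_range_rejected(self):
        with pytest.raises(InputError):
            random_shell(0, 1, seed=0, exp_range=(-1.0, 2.0))


class TestShellValidation:
    def test_bad_inputs(self):
        with pytest.raises(InputError):
            Shell(np.zeros(3), 7, np.array([1.0]), np.array([1.0]))
        with pytest.raises(InputError):
            Shell(np.zeros(3), 1, np.array([-1.0]), np.array([1.0]))
        with pytest.raises(InputError):
            Shell(np.zeros(3), 1, np.array([1.0, 2.0]), np.array([1.0]))

    def test_charge_set(self):
        cs = ChargeSet.empty()
        assert len(cs) == 0
        with pytest.raises(InputError):
            ChargeSet(np.array([1.0, 2.0]), np.zeros((1, 3)))


class TestFileFormats:
    XYZ = "2\ncomment\nH 0.0 0.0 0.0\nHe 0.0 0.0 1.0\n"

    def test_xyz_units(self):
        symbols, centers = read_xyz(self.XYZ)
        assert symbols == ["H", "He"]
        np.testing.assert_allclose(centers[1, 2], 1.0 / 0.52917721092, rtol=1e-15)

    def test_xyz_roundtrip(self):
        symbols, centers = read_xyz(self.XYZ)
        symbols2, centers2 = read_xyz(write_xyz(symbols, centers))
        assert symbols2 == symbols
        np.testing.assert_allclose(centers2, centers, atol=1e-12)

    def test_xyz_errors_carry_line_numbers(self):
        with pytest.raises(InputError, match="line 3"):
            read_xyz("1\nc\nH 0.0 0.0\n")

    def test_gbs_single_s(self):
        text = "H 0\nS 1 1.00\n 1.0 1.0\n****\n"
        shells = read_gbs(text, "H")
        assert len(shells) == 1 and shells[0].l == 0 and shells[0].K == 1

    def test_gbs_sp_split_and_roundtrip(self):
        text = (
            "C 0\nSP 2 1.00\n 1.0D+01 0.5 0.1\n 2.0 0.5 0.9\nD 1 1.00\n 0.8 1.0\n****\n"
        )
        shells = read_gbs(text, "C")
        assert [s.l for s in shells] == [0, 1, 2]
        np.testing.assert_allclose(shells[1].coefficients, [0.1, 0.9])
        rt = read_gbs(write_gbs("C", shells), "C")
        for s1, s2 in zip(shells, rt):
            assert s1.l == s2.l
            np.testing.assert_allclose(s1.exponents, s2.exponents, rtol=1e-12)
            np.testing.assert_allclose(s1.coefficients, s2.coefficients, rtol=1e-12)

    def test_gbs_unknown_element(self):
        with pytest.raises(InputError):
            read_gbs("H 0\nS 1 1.0\n 1.0 1.0\n****\n", "Xx")

    def test_charge_file(self):
        cs = read_charges("# comment\n1.0 0 0 0\n-0.5 1 2 3\n")
        assert len(cs) == 2
        np.testing.assert_allclose(cs.positions[1], [1, 2, 3])
        with pytest.raises(InputError, match="line 1"):
            read_charges("1.0 0 0\n")


def test_cartesian_components_alphabetical():
    assert cartesian_components(2) == (
        (2, 0, 0), (1, 1, 0), (1, 0, 1), (0, 2, 0), (0, 1, 1), (0, 0, 2),
    )
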