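"""Boys function: reference accuracy, table certification, branch behavior."""

import math

import mpmath as mp
import numpy as np
import pytest
from hypothesis import given, strategies as st

from mdint import boys
from mdint.shell_model import InputError


class TestReference:
    def test_x_zero_closed_form(self):
        np.testing.assert_allclose(
            boys.boys_reference(0.0, 4), [1 / (2 * m + 1) for m in range(5)], rtol=1e-15
        )

    def test_x_one_vs_erf_closed_form(self):
        # F_0(1) = (sqrt(pi)/2) erf(1)
        with mp.workdps(40):
            want = float(mp.sqrt(mp.pi) / 2 * mp.erf(1))
        np.testing.assert_allclose(boys.boys_reference(1.0, 0)[0], want, rtol=1e-15)

    def test_large_x_asymptotic(self):
        got = boys.boys_reference(144.0, 0)[0]
        np.testing.assert_allclose(got, 0.5 * math.sqrt(math.pi / 144), rtol=1e-15)

    def test_against_mpmath_incomplete_gamma(self):
        # F_m(x) = gammainc(m+1/2, 0, x) / (2 x^{m+1/2})
        xs = [0.3, 4.7, 22.0, 77.5, 119.0]
        for x in xs:
            got = boys.boys_reference(x, 8)
            with mp.workdps(40):
                want = [
                    float(mp.gammainc(m + mp.mpf(1) / 2, 0, x) / (2 * mp.mpf(x) ** (m + mp.mpf(1) / 2)))
                    for m in range(9)
                ]
            np.testing.assert_allclose(got, want, rtol=1e-15)

    def test_negative_x_rejected(self):
        with pytest.raises(InputError):
            boys.boys_reference(-1.0, 0)


class TestTable:
    def test_certified(self):
        tab = boys.get_table(25)
        assert tab.order == 7
        assert tab.certified_error <= 1e-14
        assert tab.x_max >= 117.0

    def test_value_at_zero(self):
        tab = boys.get_table(25)
        got = boys.boys_eval(np.array([0.0]), 0, table=tab)
        np.testing.assert_allclose(got[0, 0], 1.0, atol=1e-14)

    def test_interval_boundary_continuity(self):
        # value at an exact boundary from the left interval's coefficients
        # (t = +1) vs the right interval's (t = -1)
        tab = boys.get_table(25)
        c = tab.coeffs[:13]  # (m, interval, 8)
        signs = (-1.0) ** np.arange(8)
        left = np.einsum("mkj->mk", c[:, :-1, :])  # T_j(+1) = 1
        right = np.einsum("mkj,j->mk", c[:, 1:, :], signs)  # T_j(-1) = (-1)^j
        assert np.max(np.abs(left - right) / np.abs(left)) < 1e-13

    def test_probe_sweep(self):
        tab = boys.get_table(25)
        rng = np.random.default_rng(99)
        xs = rng.uniform(0, tab.x_max, 2000)
        got = boys._interpolate(tab, xs, 20)
        want = boys.boys_reference(xs, 20)
        assert np.max(np.abs(got - want)) <= 1e-14

    def test_roundtrip_serialization(self, tmp_path):
        import h5py

        tab = boys.get_table(25)
        with h5py.File(tmp_path / "tab.h5", "w") as f:
            tab.save(f)
        with h5py.File(tmp_path / "tab.h5") as f:
            tab2 = boys.BoysTable.load(f)
        assert tab2.dx == tab.dx and tab2.L_max == tab.L_max
        np.testing.assert_array_equal(tab2.coeffs, tab.coeffs)

    def test_bad_parameters_rejected(self):
        with pytest.raises(InputError):
            boys.build_table(order=5)
        with pytest.raises(InputError):
            boys.build_table(x_max=50.0)


class TestEvaluator:
    def test_all_masked_returns_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        out = boys.boys_eval(x, 4, mask=np.zeros(3, dtype=bool))
        assert np.all(out == 0.0)

    def test_mask_selects_lanes(self):
        x = np.array([np.nan, 2.0])  # masked lane never inspected
        out = boys.boys_eval(x, 2, mask=np.array([False, True]))
        assert np.all(out[0] == 0.0)
        np.testing.assert_allclose(out[1], boys.boys_reference(2.0, 2), rtol=1e-13)

    @pytest.mark.parametrize("L", [8, 12])
    def test_branch_selection_consistent_at_x40(self, L):
        # x=40 goes asymptotic for L=8 but through the table for L=12;
        # both must agree with the reference
        got = boys.boys_eval(np.array([40.0]), L)
        want = boys.boys_reference(40.0, L)
        np.testing.assert_allclose(got[0], want, rtol=1e-13)

    @pytest.mark.parametrize("edge", [36.0, 118.0])
    def test_no_discontinuity_at_branch_thresholds(self, edge):
        # both branches evaluated exactly at the threshold agree through the
        # reference, so the branch switch introduces no jump beyond 1e-13
        for L in (5, 12):
            want = boys.boys_reference(edge, L)
            table = boys._interpolate(boys.get_table(25), np.array([edge]), L)[0]
            asym = boys._upward_asymptotic(np.array([edge]), L)[0]
            assert np.max(np.abs(table - want) / want) < 1e-13
            assert np.max(np.abs(asym - want) / want) < 1e-13
            assert np.max(np.abs(table - asym) / want) < 1e-13

    def test_upward_recursion_residual_from_interpolation(self):
        # (2m+1) F_m - 2x F_{m+1} - e^{-x} = 0 on interpolated values
        x = 5.0
        F = boys.boys_eval(np.array([x]), 10)[0]
        for m in range(10):
            resid = (2 * m + 1) * F[m] - 2 * x * F[m + 1] - math.exp(-x)
            assert abs(resid) <= 1e-14 * F[m] + 1e-16

    def test_capability_error(self):
        tab = boys.get_table(25)
        with pytest.raises(boys.CapabilityError):
            boys.boys_eval(np.array([1.0]), tab.L_max + 1, table=tab)

    @given(
        st.floats(min_value=0.0, max_value=130.0),
        st.integers(min_value=0, max_value=20),
    )
    def test_bounds_and_monotonicity(self, x, L):
        F = boys.boys_eval(np.array([x]), L)[0]
        assert np.all(F > 0)
        assert np.all(F <= 1.0 / (2 * np.arange(L + 1) + 1) + 1e-15)
        if x > 0 and L > 0:
            assert np.all(np.diff(F) < 0)  # decreasing in m

    def test_decreasing_in_x(self):
        xs = np.linspace(0, 50, 2001)
        F = boys.boys_eval(xs, 6)
        assert np.all(np.diff(F, axis=0) < 0)
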