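import math

import numpy as np
import pytest

from polyel_eos import (
    V_STAR_OVER_D3,
    a_el_method1,
    a_el_method2,
    a_el_pol_method2,
    big_D,
    e_el_method2,
    mdoz_params,
    method2,
    p_el_method2,
    reduced_state,
    series_coeffs,
    shielding_gamma,
    validate_mixture,
)
from polyel_eos.validation_fixtures import taylor_coefficients

PI = math.pi


class TestParams:
    def test_monomeric_limit(self, monomeric):
        pr = mdoz_params(monomeric, reduced_state(monomeric, 0.2, 1.0))
        assert pr.m == pytest.approx(1.0, rel=1e-14)
        assert pr.f == pytest.approx(1.0, rel=1e-14)
        assert pr.H == 0.0

    def test_asymmetric_chain_average(self, pa_pc_s):
        pr = mdoz_params(pa_pc_s, reduced_state(pa_pc_s, 0.1, 1.0))
        # 1/m = (1/2)(1/50 + 1) = 0.51
        assert pr.m == pytest.approx(1.0 / 0.51, rel=1e-12)
        m = pr.m
        assert pr.f == pytest.approx(2 * m**2 / (5 * m**2 - 2 * m - 1), rel=1e-12)

    def test_asymmetry_parameter(self):
        # eta = 0.12, eta_S = 0.02 -> phi_S = 1/6
        mix = validate_mixture(N_A=50, N_C=1, phi_A=(1 - 1 / 6) / 2, phi_S=1 / 6)
        pr = mdoz_params(mix, reduced_state(mix, 0.12, 1.5))
        m = pr.m
        expected = 3 * (1 + m) * (1 - 50) * 0.10 / (2 * m * (1 - 0.12) * 50 * 1)
        assert pr.H == pytest.approx(expected, rel=1e-12)
        assert pr.H == pytest.approx(-0.25224, abs=2e-5)

    def test_symmetric_chains_have_zero_H(self):
        mix = validate_mixture(N_A=8, N_C=8, phi_A=0.2, phi_S=0.6)
        pr = mdoz_params(mix, reduced_state(mix, 0.3, 2.0))
        assert pr.H == 0.0

    def test_large_asymmetry_warns(self):
        mix = validate_mixture(N_A=50, N_C=1, phi_A=0.5, phi_S=0.0)
        with pytest.warns(RuntimeWarning, match=r"\|H\|"):
            mdoz_params(mix, reduced_state(mix, 0.6, 2.0))


class TestBigD:
    def test_zero_kappa(self):
        assert big_D(0.0, 1.0, 0.0) == 0.0
        assert big_D(0.0, 0.5, 0.3) == pytest.approx(0.0, abs=1e-14)

    def test_monomeric_value(self):
        # 24 + 48 - 2*27 + 2, with {1+8}^{3/2} = 27
        assert big_D(4.0, 1.0, 0.0) == pytest.approx(20.0, rel=1e-14)

    def test_free_energy_equals_blum_route(self):
        # at m = 1, kappa = 4: a_el = -20/12pi = -5/3pi
        assert -big_D(4.0, 1.0, 0.0) / (12 * PI) == pytest.approx(
            -5 / (3 * PI), rel=1e-14
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            big_D(-1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            big_D(1.0, 0.0, 0.0)


class TestMonomericIdentities:
    def test_energy_value(self, monomeric):
        # kappa = 4 at m = 1: (4/8pi)(-8 - 2 + 6) = -2/pi
        lb = 16.0 / (24.0 * (monomeric.phi_A + monomeric.phi_C))  # kappa^2=16 at eta=1
        st = reduced_state(monomeric, 0.5, lb / 0.5)
        assert st.kappa == pytest.approx(4.0, rel=1e-12)
        assert e_el_method2(monomeric, st) == pytest.approx(-2 / PI, rel=1e-12)

    def test_gibbs_helmholtz_gap_is_gamma_cubed(self, monomeric):
        # a_el - e_el = Gamma^3/(3 pi) for all kappa at m = 1
        for kappa in np.geomspace(1e-2, 20.0, 12):
            eta = 0.4
            lb = kappa**2 / (24 * eta * (monomeric.phi_A + monomeric.phi_C))
            st = reduced_state(monomeric, eta, lb)
            gap = a_el_method2(monomeric, st) - e_el_method2(monomeric, st)
            g = shielding_gamma(kappa)
            assert gap == pytest.approx(g**3 / (3 * PI), rel=1e-11, abs=1e-14)

    def test_method_equivalence_in_vstar_units(self, monomeric):
        for eta in (1e-3, 0.1, 0.4):
            for lb in (0.2, 2.0, 8.0):
                st = reduced_state(monomeric, eta, lb)
                a1 = a_el_method1(monomeric, st)
                a2 = V_STAR_OVER_D3 * a_el_method2(monomeric, st)
                assert abs(a1 - a2) < 1e-10

    def test_small_kappa_series_matches_dh_through_fourth_order(self):
        coeffs = taylor_coefficients(lambda k: -big_D(k, 1.0, 0.0) / (12 * PI))
        assert coeffs[3] == pytest.approx(-1 / (12 * PI), rel=1e-4)
        assert coeffs[4] == pytest.approx(1 / (16 * PI), rel=1e-4)
        # fifth order is -1/16pi, NOT the DH -1/20pi
        assert coeffs[5] == pytest.approx(-1 / (16 * PI), rel=1e-2)


class TestPressure:
    @pytest.mark.parametrize(
        "system",
        [(50, 1, 0.05, 0.9), (50, 10, 0.2, 0.6), (16, 1, 0.45, 0.1)],
        ids=["50-1", "50-10", "16-1"],
    )
    @pytest.mark.parametrize("eta", [0.05, 0.3])
    def test_matches_finite_difference_route(self, system, eta):
        """p_el equals eta d(a_el)/deta - a_el, exercising the H-derivative."""
        n_a, n_c, phi_a, phi_s = system
        mix = validate_mixture(N_A=n_a, N_C=n_c, phi_A=phi_a, phi_S=phi_s)
        lb = 4.0

        def a(e):
            return a_el_method2(mix, reduced_state(mix, e, lb))

        h = 1e-6 * eta
        d = (-a(eta + 2 * h) + 8 * a(eta + h) - 8 * a(eta - h) + a(eta - 2 * h)) / (
            12 * h
        )
        st = reduced_state(mix, eta, lb)
        assert p_el_method2(mix, st) == pytest.approx(eta * d - a(eta), rel=1e-6)

    def test_label_swap_invariance(self):
        # A <-> C flips the sign of H but |1 +/- H| combinations are even
        m1 = validate_mixture(N_A=50, N_C=10, phi_A=0.2, phi_S=0.6)
        m2 = validate_mixture(N_A=10, N_C=50, phi_A=0.2, phi_S=0.6)
        s1, s2 = reduced_state(m1, 0.3, 5.0), reduced_state(m2, 0.3, 5.0)
        p1, p2 = mdoz_params(m1, s1), mdoz_params(m2, s2)
        assert p1.H == pytest.approx(-p2.H, rel=1e-14)
        for fn in (a_el_method2, e_el_method2, p_el_method2):
            assert fn(m1, s1) == pytest.approx(fn(m2, s2), rel=1e-13)


class TestConnectivityPart:
    def test_monomeric_is_zero(self, monomeric):
        for eta in (0.05, 0.3):
            st = reduced_state(monomeric, eta, 5.0)
            assert a_el_pol_method2(monomeric, st) == pytest.approx(0.0, abs=1e-15)

    def test_zero_coupling_is_zero(self, pa_pc_s):
        st = reduced_state(pa_pc_s, 0.3, 0.0)
        assert a_el_pol_method2(pa_pc_s, st) == 0.0

    def test_negative_over_density_range(self):
        # PA(50)/PC(10) at phi_S = 0.6, lb = 5.516: finite, negative curve
        mix = validate_mixture(N_A=50, N_C=10, phi_A=0.2, phi_S=0.6)
        vals = [
            a_el_pol_method2(mix, reduced_state(mix, eta, 5.516))
            for eta in np.linspace(0.02, 0.5, 12)
        ]
        assert all(math.isfinite(v) and v < 0 for v in vals)


class TestSeriesCoeffs:
    def test_symmetric_monomeric_values(self):
        c = series_coeffs(1.0, 0.0)
        assert c.D1 == pytest.approx(0.0, abs=1e-15)
        assert c.D2 == pytest.approx(0.0, abs=1e-15)
        assert c.D3 == pytest.approx(-1 / (12 * PI), rel=1e-14)
        assert c.D4 == pytest.approx(1 / (16 * PI), rel=1e-14)
        # gap series: S3 = +1/24pi, S4 = -1/16pi
        assert c.S3 == pytest.approx(1 / (24 * PI), rel=1e-14)
        assert c.S4 == pytest.approx(-1 / (16 * PI), rel=1e-14)

    @pytest.mark.parametrize("H", [-0.9, -0.3, 0.0, 0.5, 0.99])
    def test_linear_coefficient_vanishes_inside_unit_band(self, H):
        assert series_coeffs(0.7, H).D1 == pytest.approx(0.0, abs=1e-15)

    def test_singular_at_unit_asymmetry(self):
        with pytest.raises(ValueError, match="singular"):
            series_coeffs(0.8, 1.0)

    def test_series_predicts_small_kappa_free_energy(self):
        f, H = 0.55, -0.25
        c = series_coeffs(f, H)
        for kappa in (1e-3, 3e-3):
            a = -big_D(kappa, f, H) / (12 * PI)
            series = (
                c.D1 * kappa + c.D2 * kappa**2 + c.D3 * kappa**3 + c.D4 * kappa**4
            )
            assert a == pytest.approx(series, rel=5e-3)

    def test_bundle(self, pa_pc_s):
        st = reduced_state(pa_pc_s, 0.3, 4.0)
        res = method2(pa_pc_s, st)
        assert res.a_el == pytest.approx(a_el_method2(pa_pc_s, st), rel=1e-14)
        assert res.series is not None
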