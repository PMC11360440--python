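import math

import numpy as np
import pytest
from scipy.integrate import quad

from polyel_eos import (
    chemical_potentials,
    gibbs_density,
    pressure_hsc,
    solve_eta_at_pressure,
    thermo_state,
    total_free_energy,
    total_pressure,
    validate_mixture,
)
from polyel_eos.hs_chain_eos import helmholtz_ex_hsc, helmholtz_id


@pytest.fixture
def hs_monomer():
    return validate_mixture(N_A=1, N_C=1, phi_A=0.0, phi_S=1.0)


class TestTotals:
    def test_method_none_is_reference_only(self, pa_pc_s):
        eta = 0.3
        navg = 1 / 0.951
        eta_k = [0.05 * eta, 0.05 * eta, 0.9 * eta]
        expected = helmholtz_id(eta_k, (50, 1, 1)) + helmholtz_ex_hsc(eta, navg)
        assert total_free_energy(pa_pc_s, eta, 5.0, "none") == pytest.approx(
            expected, rel=1e-12
        )

    def test_zero_coupling_has_no_electrostatics(self, pa_pc_s):
        for method in ("method1", "method2", "dh"):
            assert total_free_energy(pa_pc_s, 0.3, 0.0, method) == pytest.approx(
                total_free_energy(pa_pc_s, 0.3, 0.0, "none"), rel=1e-14
            )

    def test_methods_agree_for_monomeric_electrolyte(self, monomeric):
        for eta in (0.01, 0.2, 0.5):
            for lb in (0.5, 3.0):
                a1 = total_free_energy(monomeric, eta, lb, "method1")
                a2 = total_free_energy(monomeric, eta, lb, "method2")
                assert abs(a1 - a2) < 1e-10
                p1 = total_pressure(monomeric, eta, lb, "method1")
                p2 = total_pressure(monomeric, eta, lb, "method2")
                assert abs(p1 - p2) < 1e-10

    def test_uncharged_hard_sphere_pressure(self, hs_monomer):
        assert total_pressure(hs_monomer, 0.4, 0.0, "none") == pytest.approx(
            2.888888888889, rel=1e-10
        )

    def test_unknown_method_rejected(self, pa_pc_s):
        with pytest.raises(ValueError, match="unknown method"):
            total_free_energy(pa_pc_s, 0.3, 1.0, "method3")


class TestChemicalPotentials:
    def test_dilute_monomer_ideal_limit(self, hs_monomer):
        eta = 1e-7
        mu, _ = chemical_potentials(hs_monomer, eta, 0.0, "none")
        # excess part vanishes like 8 eta (PY contact value)
        assert mu["S"] == pytest.approx(math.log(eta) + 1.0, abs=2e-6)

    def test_absent_species_diverges(self, hs_monomer):
        mu, mu_eff = chemical_potentials(hs_monomer, 0.1, 0.0, "none")
        assert mu["A"] == -math.inf and mu_eff == -math.inf

    def test_hard_sphere_excess_against_quadrature(self, hs_monomer):
        """mu_ex of the PY hard-sphere fluid equals the independent
        quadrature route a_ex/eta + p_ex/eta obtained by integrating the
        pressure (solution of eta a' - a = p with a/eta -> 0)."""
        eta = 0.35

        def p_ex(s):
            return pressure_hsc(s, 1.0) - s

        integral, _ = quad(lambda s: p_ex(s) / s**2, 0.0, eta, epsabs=1e-13)
        mu_ex_oracle = integral + p_ex(eta) / eta
        mu, _ = chemical_potentials(hs_monomer, eta, 0.0, "none")
        assert mu["S"] - (math.log(eta) + 1.0) == pytest.approx(mu_ex_oracle, rel=1e-8)

    @pytest.mark.parametrize("method", ["method1", "method2", "dh", "none"])
    def test_euler_identity(self, method, pa_pc_s):
        """g = sum_k phi_k mu_k/(N_k kT) (Gibbs-Duhem/Euler relation)."""
        rng = np.random.default_rng(7)
        for _ in range(4):
            eta = float(rng.uniform(0.02, 0.55))
            lb = float(rng.uniform(0.1, 8.0))
            st = thermo_state(pa_pc_s, eta, lb, method)
            euler = (
                pa_pc_s.phi_A * st.mu_over_N["A"]
                + pa_pc_s.phi_C * st.mu_over_N["C"]
                + pa_pc_s.phi_S * st.mu_over_N["S"]
            )
            assert euler == pytest.approx(st.g, rel=1e-6)

    def test_mu_eff_is_sum_of_parts(self, pa_pc_s):
        mu, mu_eff = chemical_potentials(pa_pc_s, 0.3, 4.0, "method2")
        assert mu_eff == pytest.approx(mu["A"] + mu["C"], rel=1e-9)


class TestAnalyticGradients:
    @pytest.mark.parametrize("method", ["none", "dh", "method1", "method2"])
    def test_excess_gradient_matches_richardson_fd(self, method):
        """The closed-form gradient of the smooth (non-ideal) free-energy
        kernel agrees with Richardson-extrapolated central differences,
        including off the electroneutral manifold."""
        from polyel_eos.numdiff import richardson_d1
        from polyel_eos.thermo import _a_rest, _grad_rest

        rng = np.random.default_rng(3)
        for _ in range(6):
            eA, eC = rng.uniform(1e-3, 0.2, 2)
            eS = float(rng.uniform(0.0, 0.5))
            lb = float(rng.uniform(0.1, 8.0))
            grad = _grad_rest((eA, eC, eS), 50, 10, lb, method)
            for i, d in enumerate([(1, 0, 0), (0, 1, 0), (0, 0, 1)]):
                fd = richardson_d1(
                    lambda t: _a_rest(
                        eA + t * d[0], eC + t * d[1], eS + t * d[2], 50, 10, lb, method
                    ),
                    0.0,
                    h0=1e-5,
                )
                assert grad[i] == pytest.approx(fd, rel=1e-6, abs=1e-10)


class TestGibbsDensity:
    def test_single_component_equals_mu(self, hs_monomer):
        eta = 0.2
        g = gibbs_density(hs_monomer, eta, 0.0, "none")
        mu, _ = chemical_potentials(hs_monomer, eta, 0.0, "none")
        assert g == pytest.approx(mu["S"], rel=1e-9)

    def test_ideal_divergence_sign(self, hs_monomer):
        # g ~ ln eta -> -inf as eta -> 0
        assert gibbs_density(hs_monomer, 1e-8, 0.0, "none") < gibbs_density(
            hs_monomer, 1e-4, 0.0, "none"
        )

    def test_zero_density_rejected(self, hs_monomer):
        with pytest.raises(ValueError):
            gibbs_density(hs_monomer, 0.0, 0.0, "none")


class TestDensitySolve:
    def test_py_hard_sphere_root(self, hs_monomer):
        from scipy.optimize import brentq

        eta = solve_eta_at_pressure(hs_monomer, 0.0, "none", 1.0)
        oracle = brentq(
            lambda e: (e + e**2 + e**3) / (1 - e) ** 3 - 1.0, 1e-6, 0.7, xtol=1e-14
        )
        assert eta == pytest.approx(oracle, abs=1e-10)
        assert eta == pytest.approx(0.27788, abs=1e-4)

    def test_low_pressure_low_density(self, hs_monomer):
        eta = solve_eta_at_pressure(hs_monomer, 0.0, "none", 1e-6)
        assert eta < 1e-5

    def test_warm_start_agrees_with_scan(self, pa_pc_s):
        cold = solve_eta_at_pressure(pa_pc_s, 4.0, "method2", 1.0)
        warm = solve_eta_at_pressure(pa_pc_s, 4.0, "method2", 1.0, eta_guess=0.9 * cold)
        assert warm == pytest.approx(cold, abs=1e-11)
        assert total_pressure(pa_pc_s, warm, 4.0, "method2") == pytest.approx(
            1.0, abs=1e-10
        )

    def test_returned_root_is_mechanically_stable(self, pa_pc_s):
        eta = solve_eta_at_pressure(pa_pc_s, 6.0, "method1", 1.0)
        h = 1e-7
        dp = (
            total_pressure(pa_pc_s, eta + h, 6.0, "method1")
            - total_pressure(pa_pc_s, eta - h, 6.0, "method1")
        ) / (2 * h)
        assert dp > 0

    def test_nonpositive_target_rejected(self, hs_monomer):
        with pytest.raises(ValueError):
            solve_eta_at_pressure(hs_monomer, 0.0, "none", 0.0)
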