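import math

import pytest

from polyel_eos import (
    helmholtz_ex_hsc,
    helmholtz_id,
    hsc_eos,
    number_average_N,
    pressure_hsc,
    validate_mixture,
)


class TestNumberAverage:
    def test_monomeric_mixture(self):
        mix = validate_mixture(N_A=1, N_C=1, phi_A=0.2, phi_S=0.6)
        assert number_average_N(mix) == pytest.approx(1.0, rel=1e-14)

    def test_asymmetric_mixture(self, pa_pc_s):
        # 1/N = 0.05/50 + 0.05 + 0.9 = 0.951
        assert number_average_N(pa_pc_s) == pytest.approx(1 / 0.951, rel=1e-12)
        assert number_average_N(pa_pc_s) == pytest.approx(1.05152, rel=1e-5)

    def test_pure_solvent(self):
        mix = validate_mixture(N_A=5, N_C=5, phi_A=0.0, phi_S=1.0)
        assert number_average_N(mix) == 1.0


class TestPressure:
    def test_py_hard_sphere_value(self):
        # (0.4 + 0.16 + 0.064)/0.216
        assert pressure_hsc(0.4, 1.0) == pytest.approx(0.624 / 0.216, rel=1e-12)

    def test_zero_density(self):
        assert pressure_hsc(0.0, 5.0) == 0.0

    @pytest.mark.parametrize("navg", [1.0, 2.0, 16.0])
    def test_ideal_chain_gas_slope(self, navg):
        h = 1e-8
        slope = (pressure_hsc(h, navg) - pressure_hsc(0.0, navg)) / h
        assert slope == pytest.approx(1.0 / navg, rel=1e-6)

    def test_monotone_in_eta(self):
        etas = [0.05 * i for i in range(1, 16)]
        ps = [pressure_hsc(e, 4.0) for e in etas]
        assert all(b > a for a, b in zip(ps, ps[1:]))

    def test_decreasing_in_chain_length(self):
        # fewer translational units at fixed monomer density
        ps = [pressure_hsc(0.35, n) for n in (1.0, 2.0, 8.0, 64.0)]
        assert all(b < a for a, b in zip(ps, ps[1:]))

    def test_eta_at_one_rejected(self):
        with pytest.raises(ValueError):
            pressure_hsc(1.0, 2.0)


class TestFreeEnergy:
    def test_zero_density(self):
        assert helmholtz_ex_hsc(0.0, 7.0) == 0.0

    @pytest.mark.parametrize("eta", [0.05, 0.2, 0.45])
    @pytest.mark.parametrize("navg", [1.0, 2.0, 10.0])
    def test_pressure_route_consistency(self, eta, navg):
        """eta d(a_id + a_ex)/deta - (a_id + a_ex) equals the pressure.

        The ideal part along the fixed-composition ray contributes
        eta/navg analytically; the excess part is differentiated by a
        5-point stencil.
        """
        h = 1e-5 * eta
        d = (
            -helmholtz_ex_hsc(eta + 2 * h, navg)
            + 8 * helmholtz_ex_hsc(eta + h, navg)
            - 8 * helmholtz_ex_hsc(eta - h, navg)
            + helmholtz_ex_hsc(eta - 2 * h, navg)
        ) / (12 * h)
        route = eta / navg + eta * d - helmholtz_ex_hsc(eta, navg)
        assert route == pytest.approx(pressure_hsc(eta, navg), rel=1e-8)

    def test_bonding_part_vanishes_for_monomers(self):
        # navg = 1: the covalent prefactor (eta - eta/N) is zero, so the
        # excess free energy is pure hard-sphere and exceeds the bonded one
        eta = 0.3
        assert helmholtz_ex_hsc(eta, 1.0) > helmholtz_ex_hsc(eta, 4.0)
        bond = helmholtz_ex_hsc(eta, 1.0) - helmholtz_ex_hsc(eta, 2.0)
        expected = (eta - eta / 2) * (1.5 * eta / (1 - eta) - math.log(1 - eta))
        assert bond == pytest.approx(expected, rel=1e-12)


class TestIdealPart:
    def test_single_component_value(self):
        assert helmholtz_id([1 / math.e], [1]) == pytest.approx(-1 / math.e, rel=1e-14)

    def test_empty_system(self):
        assert helmholtz_id([0.0, 0.0, 0.0], [1, 2, 3]) == 0.0

    def test_chain_length_suppresses_translational_entropy(self):
        # doubling N halves the prefactor eta/N
        assert helmholtz_id([0.3], [2]) == pytest.approx(0.15 * math.log(0.15), rel=1e-14)

    def test_hsc_eos_bundles_parts(self, pa_pc_s):
        res = hsc_eos(pa_pc_s, 0.3)
        assert res.navg == pytest.approx(number_average_N(pa_pc_s), rel=1e-14)
        assert res.p == pytest.approx(pressure_hsc(0.3, res.navg), rel=1e-14)
        assert res.a_ex == pytest.approx(helmholtz_ex_hsc(0.3, res.navg), rel=1e-14)
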