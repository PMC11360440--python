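"""Deterministic fixture grids and cross-method/limit-law checks.

The two electrostatic routes (Blum--Stell and MDOZ) must coincide for a
monomeric electrolyte, both must reduce to the Debye--Hueckel limiting
law through order kappa^4, and every method must satisfy the
thermodynamic identities P = eta da/deta - a and
g = sum_k phi_k mu_k/(N_k kT).  This module evaluates those statements
on fixed deterministic grids and reports the worst deviations; the
``figure_fixtures`` entry point regenerates the package's reference
curves (connectivity free energy, pressure isochore, binodal) as plain
tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import blum_stell, dh_reference, mdoz, thermo
from .core import V_STAR_OVER_D3, Mixture, reduced_state, validate_mixture
from .phase_equilibria import find_critical_point, trace_binodal

__all__ = [
    "FixtureCheck",
    "LimitSuiteReport",
    "fixture_grid",
    "limit_suite",
    "figure_fixtures",
    "taylor_coefficients",
]


@dataclass(frozen=True)
class FixtureCheck:
    name: str
    max_err: float
    tol: float

    @property
    def passed(self) -> bool:
        return self.max_err < self.tol


@dataclass
class LimitSuiteReport:
    checks: list[FixtureCheck] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def __str__(self) -> str:
        lines = []
        for c in self.checks:
            status = "PASS" if c.passed else "FAIL"
            lines.append(f"[{status}] {c.name}: max_err={c.max_err:.3e} tol={c.tol:.1e}")
        lines.append("overall: " + ("PASS" if self.passed else "FAIL"))
        return "\n".join(lines)


def fixture_grid() -> list[tuple[Mixture, float, float]]:
    """Deterministic (mixture, eta, lb) grid spanning monomeric,
    symmetric and asymmetric chain systems from dilute to dense."""
    systems = [
        (1, 1, 0.05), (1, 1, 0.25),
        (8, 8, 0.1),
        (50, 1, 0.05), (16, 1, 0.2), (50, 10, 0.2),
    ]
    etas = [1e-4, 0.01, 0.1, 0.3, 0.5]
    lbs = [0.1, 1.0, 4.0, 10.0]
    grid = []
    for n_a, n_c, phi_a in systems:
        mix = validate_mixture(N_A=n_a, N_C=n_c, phi_A=phi_a, phi_S=1.0 - 2 * phi_a)
        for eta in etas:
            for lb in lbs:
                grid.append((mix, eta, lb))
    return grid


def taylor_coefficients(f, orders=(3, 4, 5), kappa_window=(3e-3, 3e-2), n=10):
    """Leading Taylor coefficients of ``f(kappa)`` assuming f = O(kappa^3).

    Fits f(kappa)/kappa^3 by a cubic polynomial on a geometric kappa grid
    and reads the coefficients of kappa^(orders).  Purely numerical; no
    symbolic machinery.
    """
    ks = np.geomspace(kappa_window[0], kappa_window[1], n)
    g = np.array([f(k) / k**3 for k in ks])
    coeffs = np.polyfit(ks, g, 3)[::-1]  # ascending in kappa
    return {o: float(coeffs[o - 3]) for o in orders if 0 <= o - 3 < len(coeffs)}


def limit_suite() -> LimitSuiteReport:
    """Run the cross-method and limiting-law checks; report only."""
    report = LimitSuiteReport()

    # (i) Method I == Method II for a monomeric electrolyte, v* units
    err = 0.0
    for mix, eta, lb in fixture_grid():
        if mix.N_A != 1 or mix.N_C != 1:
            continue
        st = reduced_state(mix, eta, lb)
        a1 = blum_stell.a_el_method1(mix, st)
        a2 = V_STAR_OVER_D3 * mdoz.a_el_method2(mix, st)
        err = max(err, abs(a1 - a2))
    report.checks.append(FixtureCheck("method equivalence at N=1 (v* units)", err, 1e-10))

    # (ii) DH and MDOZ share kappa^3 and kappa^4 coefficients ...
    def a2_of_kappa(kappa: float) -> float:
        return -mdoz.big_D(kappa, 1.0, 0.0) / (12.0 * math.pi)

    c_dh = taylor_coefficients(dh_reference.dh_free_energy)
    c_m2 = taylor_coefficients(a2_of_kappa)
    err34 = max(
        abs(c_m2[3] - (-1.0 / (12.0 * math.pi))) / (1.0 / (12.0 * math.pi)),
        abs(c_m2[4] - (1.0 / (16.0 * math.pi))) / (1.0 / (16.0 * math.pi)),
        abs(c_dh[3] - (-1.0 / (12.0 * math.pi))) / (1.0 / (12.0 * math.pi)),
        abs(c_dh[4] - (1.0 / (16.0 * math.pi))) / (1.0 / (16.0 * math.pi)),
    )
    report.checks.append(
        FixtureCheck("DH/MDOZ kappa^3, kappa^4 coefficients", err34, 1e-4)
    )
    # ... and FIRST DIFFER at kappa^5: -1/20pi (DH) vs -1/16pi (MDOZ)
    sep = abs(c_dh[5] - c_m2[5])
    expected_sep = abs(-1.0 / (20.0 * math.pi) + 1.0 / (16.0 * math.pi))
    err5 = abs(sep - expected_sep) / expected_sep
    report.checks.append(FixtureCheck("kappa^5 coefficients differ as expected", err5, 1e-2))

    # (iii) a_el - e_el = Gamma^3/(3 pi) at m = 1, all kappa
    err = 0.0
    for kappa in np.geomspace(1e-3, 30.0, 40):
        a = -mdoz.big_D(kappa, 1.0, 0.0) / (12.0 * math.pi)
        g = blum_stell.shielding_gamma(kappa)
        e = kappa / (8.0 * math.pi) * (-2.0 * kappa - 2.0 + 2.0 * math.sqrt(1.0 + 2.0 * kappa))
        err = max(err, abs((a - e) - g**3 / (3.0 * math.pi)))
    report.checks.append(FixtureCheck("a_el - e_el = Gamma^3/3pi at m=1", err, 1e-12))

    # (iv) thermodynamic consistency: P = eta da/deta - a, and Euler identity
    err_p, err_g = 0.0, 0.0
    for mix, eta, lb in fixture_grid():
        if not 0.01 <= eta <= 0.6:
            continue
        for method in ("method1", "method2", "dh", "none"):
            p = thermo.total_pressure(mix, eta, lb, method)
            h = 1e-5 * eta
            route = 0.0
            for sgn, w in ((2, -1.0), (1, 8.0), (-1, -8.0), (-2, 1.0)):
                route += w * thermo.total_free_energy(mix, eta + sgn * h, lb, method)
            dadeta = route / (12.0 * h)
            a = thermo.total_free_energy(mix, eta, lb, method)
            err_p = max(err_p, abs(eta * dadeta - a - p) / max(abs(p), 1e-8))
    for mix, eta, lb in fixture_grid()[::7]:
        if not 0.01 <= eta <= 0.6 or mix.phi_A == 0.0:
            continue
        for method in ("method1", "method2"):
            st = thermo.thermo_state(mix, eta, lb, method)
            euler = (
                mix.phi_A * st.mu_over_N["A"]
                + mix.phi_C * st.mu_over_N["C"]
                + mix.phi_S * st.mu_over_N["S"]
            )
            err_g = max(err_g, abs(euler - st.g) / max(abs(st.g), 1e-8))
    report.checks.append(FixtureCheck("pressure route consistency", err_p, 1e-6))
    report.checks.append(FixtureCheck("Euler identity g = sum phi_k mu_k/N_k", err_g, 1e-6))

    return report


def figure_fixtures(which: str, p_target: float = 1.0) -> pd.DataFrame:
    """Regenerate the package's reference curves as plain tables.

    * ``fig1`` -- connectivity free energy Delta A_el-pol vs eta for the
      N_A=50, N_C=10, phi_S=0.6 system at L_B/d = 5.516 (both unit
      conventions, both methods);
    * ``fig2`` -- pressure beta P d^3 vs 6 eta/pi for the salt-free
      N_A=16, N_C=1 system at L_B/d = 0.833 (phi_S -> 0 taken as 1e-10);
    * ``fig3`` -- coacervation binodals of the N_A=50, N_C=1 system at
      beta P v* = 1 for both methods.
    """
    if which == "fig1":
        mix = validate_mixture(N_A=50, N_C=10, phi_A=0.2, phi_S=0.6)
        rows = []
        for eta in np.linspace(0.02, 0.5, 25):
            st = reduced_state(mix, float(eta), 5.516)
            pol1_v = blum_stell.a_el_pol_method1(mix, st)
            pol2_d3 = mdoz.a_el_pol_method2(mix, st)
            rows.append(
                {
                    "eta": float(eta),
                    "a_pol_method1_vstar": pol1_v,
                    "a_pol_method2_vstar": V_STAR_OVER_D3 * pol2_d3,
                    "a_pol_method1_d3": pol1_v / V_STAR_OVER_D3,
                    "a_pol_method2_d3": pol2_d3,
                }
            )
        return pd.DataFrame(rows)
    if which == "fig2":
        phi_s = 1e-10  # phi_S -> 0 limit without the empty-solvent edge case
        mix = validate_mixture(N_A=16, N_C=1, phi_A=(1.0 - phi_s) / 2.0, phi_S=phi_s)
        rows = []
        for rho in np.linspace(0.02, 0.45, 24):
            eta = math.pi * float(rho) / 6.0
            p1 = thermo.total_pressure(mix, eta, 0.833, "method1") / V_STAR_OVER_D3
            p2 = thermo.total_pressure(mix, eta, 0.833, "method2") / V_STAR_OVER_D3
            rows.append({"rho": float(rho), "p_d3_method1": p1, "p_d3_method2": p2})
        return pd.DataFrame(rows)
    if which == "fig3":
        template = validate_mixture(N_A=50, N_C=1, phi_A=0.01, phi_S=0.98)
        rows = []
        for method in ("method1", "method2"):
            cp = find_critical_point(template, method, p_target)
            lbs = cp.lb_cp / (1.0 - np.geomspace(5e-3, 0.25, 10))
            for pt in trace_binodal(template, lbs, method, p_target, critical_point=cp):
                rows.append(
                    {
                        "method": method,
                        "lb": pt.lb,
                        "phi_a": pt.phi_a,
                        "phi_b": pt.phi_b,
                        "eta_a": pt.eta_a,
                        "eta_b": pt.eta_b,
                        "residual": pt.residual,
                    }
                )
        return pd.DataFrame(rows)
    raise ValueError(f"unknown figure fixture {which!r}; expected fig1|fig2|fig3")
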