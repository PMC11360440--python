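"""Method I electrostatics: Blum's MSA for charged hard spheres plus the
cavity-function treatment of charged-chain connectivity.

The mean-spherical-approximation solution for the restricted primitive
model is governed by the shielding parameter Gamma (the MSA analogue of
the inverse Debye length), fixed by the quadratic relation

    2 Gamma d (1 + Gamma d) = kappa d.

The electrostatic free energy density (in v* units, beta Delta A_el v*/V)
of the fully charged PA/PC/S mixture is the sum of three closed-form
terms:

    -(L_B/d) sum_k eta_k z_k^2 Gamma/(1+Gamma)        (unbonded energy)
    + Gamma^3/18                                      (MSA entropy)
    -(L_B/d) sum_k (eta_k/N_k)(N_k-1) [1 - 1/(1+Gamma)^2]
                                                      (chain connectivity)

The last term comes from the contact cavity functions of adjacent bonded
beads (adjacent like charges, z_i z_{i+1} = +1) and vanishes for a
monomeric electrolyte.  The pressure is obtained by the thermodynamic
route p = eta da/d eta - a at fixed composition, which is evaluated
analytically: the unbonded part collapses to -Gamma^3/18 because the MSA
free energy is stationary with respect to Gamma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import Mixture, ReducedState

__all__ = [
    "MethodIResult",
    "shielding_gamma",
    "a_el_method1",
    "a_el_pol_method1",
    "p_el_method1",
    "method1",
]


@dataclass(frozen=True)
class MethodIResult:
    """Method I electrostatic contributions at one state point (v* units)."""

    gamma: float      # reduced shielding parameter Gamma d
    a_el: float       # beta Delta A_el v*/V
    a_el_pol: float   # connectivity-only part, v* units
    p_el: float       # beta Delta P_el v*


def shielding_gamma(kappa: float) -> float:
    """Reduced MSA shielding parameter Gamma d from kappa d.

    Solves 2 Gamma (1 + Gamma) = kappa for the non-negative root:
    Gamma = (sqrt(1 + 2 kappa) - 1)/2.
    """
    if kappa < 0.0:
        raise ValueError(f"kappa must be >= 0, got {kappa!r}")
    return 0.5 * (math.sqrt(1.0 + 2.0 * kappa) - 1.0)


# -- density kernels -------------------------------------------------------
#
# The kernels take the partial packing fractions directly so that the
# thermodynamics layer can differentiate with respect to each eta_k
# (including the analytic continuation to slightly off-electroneutral
# states needed for individual chemical potentials).  kappa is always the
# physical sum-over-charges form kappa^2 = 24 lb (eta_A + eta_C).

def _kernel_a_v(eta_A: float, eta_C: float, N_A: int, N_C: int, lb: float) -> float:
    s = eta_A + eta_C
    if s <= 0.0 or lb == 0.0:
        return 0.0
    kappa = math.sqrt(24.0 * lb * s)
    g = shielding_gamma(kappa)
    term_energy = -lb * s * g / (1.0 + g)
    term_entropy = g**3 / 18.0
    conn = eta_A * (N_A - 1.0) / N_A + eta_C * (N_C - 1.0) / N_C
    term_conn = -lb * conn * (1.0 - 1.0 / (1.0 + g) ** 2)
    return term_energy + term_entropy + term_conn


def _kernel_a_pol_v(eta_A: float, eta_C: float, N_A: int, N_C: int, lb: float) -> float:
    s = eta_A + eta_C
    if s <= 0.0 or lb == 0.0:
        return 0.0
    g = shielding_gamma(math.sqrt(24.0 * lb * s))
    conn = eta_A * (N_A - 1.0) / N_A + eta_C * (N_C - 1.0) / N_C
    return -lb * conn * (1.0 - 1.0 / (1.0 + g) ** 2)


def _kernel_p_v(eta_A: float, eta_C: float, N_A: int, N_C: int, lb: float) -> float:
    # p = eta da/deta - a along the fixed-composition ray; the unbonded
    # contribution reduces to -Gamma^3/18 by stationarity of the MSA free
    # energy in Gamma, and the connectivity term uses
    # eta dGamma/deta = kappa/(4 (1 + 2 Gamma)) (kappa ~ sqrt(eta)).
    s = eta_A + eta_C
    if s <= 0.0 or lb == 0.0:
        return 0.0
    kappa = math.sqrt(24.0 * lb * s)
    g = shielding_gamma(kappa)
    conn = eta_A * (N_A - 1.0) / N_A + eta_C * (N_C - 1.0) / N_C
    # eta * d/deta[1 - (1+Gamma)^-2] = 2 eta Gamma'/(1+Gamma)^3
    #                                = kappa/(2 (1+Gamma)^3 (1+2Gamma))
    p_conn = -lb * conn * kappa / (2.0 * (1.0 + g) ** 3 * (1.0 + 2.0 * g))
    return -(g**3) / 18.0 + p_conn


def _grad_a_v(
    eta_A: float, eta_C: float, N_A: int, N_C: int, lb: float
) -> tuple[float, float, float]:
    """Analytic gradient of the v*-unit free energy with respect to the
    partial packing fractions.  Uses the stationarity of the unbonded MSA
    free energy in Gamma, so only the connectivity term contributes a
    Gamma-derivative piece."""
    s = eta_A + eta_C
    if s <= 0.0 or lb == 0.0:
        return (0.0, 0.0, 0.0)
    kappa = math.sqrt(24.0 * lb * s)
    g = shielding_gamma(kappa)
    one = 1.0 + g
    g1 = g / one                      # Gamma/(1+Gamma)
    g2 = 1.0 - 1.0 / one**2
    conn = eta_A * (N_A - 1.0) / N_A + eta_C * (N_C - 1.0) / N_C
    # dGamma/deta_A = dGamma/deta_C = kappa/(4 s (1 + 2 Gamma))
    dgamma = kappa / (4.0 * s * (1.0 + 2.0 * g))
    extra = -lb * conn * (2.0 / one**3) * dgamma
    grad_A = -lb * g1 - lb * (1.0 - 1.0 / N_A) * g2 + extra
    grad_C = -lb * g1 - lb * (1.0 - 1.0 / N_C) * g2 + extra
    return (grad_A, grad_C, 0.0)


# -- public API ------------------------------------------------------------

def a_el_method1(mixture: Mixture, state: ReducedState) -> float:
    """Electrostatic free energy density beta Delta A_el v*/V (Method I)."""
    return _kernel_a_v(state.eta_A, state.eta_C, mixture.N_A, mixture.N_C, state.lb)


def a_el_pol_method1(mixture: Mixture, state: ReducedState) -> float:
    """Connectivity-only part of the Method I free energy (v* units).

    Zero for a monomeric electrolyte (N_A = N_C = 1) and at kappa = 0.
    """
    return _kernel_a_pol_v(state.eta_A, state.eta_C, mixture.N_A, mixture.N_C, state.lb)


def p_el_method1(mixture: Mixture, state: ReducedState) -> float:
    """Electrostatic pressure beta Delta P_el v* (Method I), by the
    analytic thermodynamic route eta da/deta - a at fixed composition."""
    return _kernel_p_v(state.eta_A, state.eta_C, mixture.N_A, mixture.N_C, state.lb)


def method1(mixture: Mixture, state: ReducedState) -> MethodIResult:
    """All Method I electrostatic quantities at one state point."""
    return MethodIResult(
        gamma=shielding_gamma(state.kappa),
        a_el=a_el_method1(mixture, state),
        a_el_pol=a_el_pol_method1(mixture, state),
        p_el=p_el_method1(mixture, state),
    )
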