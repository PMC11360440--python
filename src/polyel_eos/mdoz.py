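"""Method II electrostatics: multi-density Ornstein--Zernike (MDOZ) closed
forms for the fully charged PA/PC/S mixture.

Wertheim's multi-density formalism tracks unbonded, singly bonded and
doubly bonded spheres separately; in the complete-bonding limit for
chains the electrostatics of the mixture collapses to closed forms
parameterized by three composition quantities:

* ``m``  -- number-average chain length of the *charged* species,
  1/m = (1/2)(1/m_plus + 1/m_minus) for an electroneutral mixture;
* ``f``  -- coupling factor f = 2 m^2/(5 m^2 - 2 m - 1), in (2/5, 1];
* ``H``  -- chain-length asymmetry parameter,
  H = 3 (1+m)(m_plus - m_minus)(eta - eta_S) / (2 m (1-eta) m_minus m_plus),
  zero for symmetric chains and odd under the A <-> C label swap.

All results are in d^3 units (beta X d^3/V); multiply by pi/6 for the v*
convention.  The free energy is

    beta Delta A_el/V = -D(kappa)/(12 pi)

with, writing phi = sqrt(f) and R(+/-) = (1 +/- H)^2 + 2 kappa/phi,

    D = 6 phi kappa + 3 kappa^2 - f [R-^(3/2) + R+^(3/2)]
        + f [|1-H|^3 + |1+H|^3].

Convention note: the half-power displays of this theory circulate with
the coupling factor written variously as f or sqrt(f) inside and outside
the radicals.  The form above is the unique member of that family that
simultaneously (i) reduces exactly to the one-component forms at m = 1,
(ii) is Gibbs--Helmholtz consistent with the internal energy derived from
the screened-pair sum (omega_0 = sqrt(f) kappa/(rho_T - rho_S), so the
radical shift is 2 kappa/sqrt(f)), and (iii) makes the pressure equal the
density derivative of the free energy.  The internal energy is then

    beta Delta E_el/V = (kappa/8 pi) (-2 kappa - 2 phi
                         + phi sqrt(R+) + phi sqrt(R-))

and the pressure follows analytically from
p = eta da/deta - a = E + H/(1-eta) * dA/dH - A  at fixed composition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .core import Mixture, ReducedState

__all__ = [
    "MdozParams",
    "SeriesCoeffs",
    "MethodIIResult",
    "mdoz_params",
    "big_D",
    "a_el_method2",
    "e_el_method2",
    "p_el_method2",
    "a_el_pol_method2",
    "series_coeffs",
    "method2",
]

_PI = math.pi


@dataclass(frozen=True)
class MdozParams:
    """Composition parameters of the MDOZ closed forms."""

    m_minus: float  # chain length of the anionic species (N_A)
    m_plus: float   # chain length of the cationic species (N_C)
    m: float        # number-average chain length of charged species
    f: float        # coupling factor, in (2/5, 1]
    H: float        # asymmetry parameter (0 for symmetric chains)
    omega0: float   # diagnostic only: sqrt(f alpha^2/(rho_T - rho_s))


@dataclass(frozen=True)
class SeriesCoeffs:
    """Small-kappa series: a_el = sum_j D_j kappa^j, a_el - e_el = sum_j S_j kappa^j."""

    D1: float
    D2: float
    D3: float
    D4: float
    S1: float
    S3: float
    S4: float


@dataclass(frozen=True)
class MethodIIResult:
    """Method II electrostatic contributions at one state point (d^3 units)."""

    a_el: float                    # beta Delta A_el d^3/V
    e_el: float                    # beta Delta E_el d^3/V
    p_el: float                    # beta Delta P_el d^3
    a_el_pol: float                # connectivity-only part, d^3 units
    params: MdozParams
    series: SeriesCoeffs | None    # None when |H| = 1 (singular)


def _f_of_m(m: float) -> float:
    return 2.0 * m * m / (5.0 * m * m - 2.0 * m - 1.0)


def _params(
    eta_A: float, eta_C: float, eta: float, N_A: float, N_C: float
) -> tuple[float, float, float]:
    """(m, f, H) from partial packing fractions; charged-monomer-weighted
    harmonic mean for m (weights are equal under electroneutrality)."""
    s = eta_A + eta_C
    m_minus, m_plus = float(N_A), float(N_C)
    if s > 0.0:
        inv_m = (eta_A / m_minus + eta_C / m_plus) / s
    else:
        inv_m = 0.5 * (1.0 / m_minus + 1.0 / m_plus)
    m = 1.0 / inv_m
    f = _f_of_m(m)
    if s > 0.0 and eta < 1.0:
        H = (
            3.0 * (1.0 + m) * (m_plus - m_minus) * s
            / (2.0 * m * (1.0 - eta) * m_minus * m_plus)
        )
    else:
        H = 0.0
    return m, f, H


def mdoz_params(mixture: Mixture, state: ReducedState) -> MdozParams:
    """Evaluate (m, f, H, omega_0) for a state point.

    At the kappa = 0 edge (no charged species, or eta = eta_S) m and f
    remain well defined from the chain lengths and H = 0.  A diagnostic
    warning is emitted when |H| >= 1 (the series coefficients D2..D4
    become singular at |H| = 1).
    """
    m, f, H = _params(state.eta_A, state.eta_C, state.eta, mixture.N_A, mixture.N_C)
    s = state.eta_A + state.eta_C
    if s > 0.0 and state.lb > 0.0:
        # omega0^2 = f alpha^2/(rho_T - rho_s), alpha^2 = 4 pi L_B
        omega0 = math.sqrt(4.0 * _PI * state.lb * f / (6.0 * s / _PI))
    else:
        omega0 = math.inf
    if abs(H) >= 1.0:
        warnings.warn(
            f"|H| = {abs(H):.6g} >= 1: series coefficients are singular "
            "at |H| = 1; closed forms remain valid",
            RuntimeWarning,
            stacklevel=2,
        )
    return MdozParams(
        m_minus=float(mixture.N_A),
        m_plus=float(mixture.N_C),
        m=m,
        f=f,
        H=H,
        omega0=omega0,
    )


def big_D(kappa: float, f: float, H: float) -> float:
    """The D(kappa) function whose -1/(12 pi) multiple is the free energy."""
    if kappa < 0.0:
        raise ValueError(f"kappa must be >= 0, got {kappa!r}")
    if not 0.0 < f <= 1.0:
        raise ValueError(f"f must lie in (0, 1], got {f!r}")
    phi = math.sqrt(f)
    am, ap = abs(1.0 - H), abs(1.0 + H)
    rm = (1.0 - H) ** 2 + 2.0 * kappa / phi
    rp = (1.0 + H) ** 2 + 2.0 * kappa / phi
    if rm < 0.0 or rp < 0.0:
        raise ValueError("negative radical argument in D(kappa)")
    return (
        6.0 * phi * kappa
        + 3.0 * kappa * kappa
        - f * (rm**1.5 + rp**1.5)
        + f * (am**3 + ap**3)
    )


def _kernel_a_d3(
    eta_A: float, eta_C: float, eta_S: float, N_A: float, N_C: float, lb: float
) -> float:
    s = eta_A + eta_C
    if s <= 0.0 or lb == 0.0:
        return 0.0
    eta = eta_A + eta_C + eta_S
    kappa = math.sqrt(24.0 * lb * s)
    m, f, H = _params(eta_A, eta_C, eta, N_A, N_C)
    return -big_D(kappa, f, H) / (12.0 * _PI)


def _kernel_e_d3(
    eta_A: float, eta_C: float, eta_S: float, N_A: float, N_C: float, lb: float
) -> float:
    s = eta_A + eta_C
    if s <= 0.0 or lb == 0.0:
        return 0.0
    eta = eta_A + eta_C + eta_S
    kappa = math.sqrt(24.0 * lb * s)
    m, f, H = _params(eta_A, eta_C, eta, N_A, N_C)
    phi = math.sqrt(f)
    rm = math.sqrt((1.0 - H) ** 2 + 2.0 * kappa / phi)
    rp = math.sqrt((1.0 + H) ** 2 + 2.0 * kappa / phi)
    return kappa / (8.0 * _PI) * (-2.0 * kappa - 2.0 * phi + phi * (rm + rp))


def _dA_dH(kappa: float, f: float, H: float) -> float:
    phi = math.sqrt(f)
    am, ap = abs(1.0 - H), abs(1.0 + H)
    rm = math.sqrt((1.0 - H) ** 2 + 2.0 * kappa / phi)
    rp = math.sqrt((1.0 + H) ** 2 + 2.0 * kappa / phi)
    return (f / (4.0 * _PI)) * (
        (1.0 + H) * (rp - ap) - (1.0 - H) * (rm - am)
    )


def _kernel_p_d3(
    eta_A: float, eta_C: float, eta_S: float, N_A: float, N_C: float, lb: float
) -> float:
    # p = eta da/deta - a at fixed composition.  Along the ray,
    # kappa ~ sqrt(eta) and H ~ eta/(1-eta), so
    # p = E + H/(1-eta) * dA/dH - A  (m and f are composition-only).
    s = eta_A + eta_C
    if s <= 0.0 or lb == 0.0:
        return 0.0
    eta = eta_A + eta_C + eta_S
    kappa = math.sqrt(24.0 * lb * s)
    m, f, H = _params(eta_A, eta_C, eta, N_A, N_C)
    a = -big_D(kappa, f, H) / (12.0 * _PI)
    e = _kernel_e_d3(eta_A, eta_C, eta_S, N_A, N_C, lb)
    return e + H / (1.0 - eta) * _dA_dH(kappa, f, H) - a


def _dA_dkappa(kappa: float, f: float, H: float) -> float:
    phi = math.sqrt(f)
    rm = math.sqrt((1.0 - H) ** 2 + 2.0 * kappa / phi)
    rp = math.sqrt((1.0 + H) ** 2 + 2.0 * kappa / phi)
    return -(2.0 * kappa + 2.0 * phi - phi * (rm + rp)) / (4.0 * _PI)


def _dA_df(kappa: float, f: float, H: float) -> float:
    phi = math.sqrt(f)
    am, ap = abs(1.0 - H), abs(1.0 + H)
    rm = (1.0 - H) ** 2 + 2.0 * kappa / phi
    rp = (1.0 + H) ** 2 + 2.0 * kappa / phi
    srm, srp = math.sqrt(rm), math.sqrt(rp)
    return -(
        3.0 * kappa / phi
        - rm * srm
        - rp * srp
        + 1.5 * kappa * (srm + srp) / phi
        + am**3
        + ap**3
    ) / (12.0 * _PI)


def _grad_a_d3(
    eta_A: float, eta_C: float, eta_S: float, N_A: float, N_C: float, lb: float
) -> tuple[float, float, float]:
    """Analytic gradient of the d^3 free energy with respect to the
    partial packing fractions (chain rule through kappa, m -> f, and H)."""
    s = eta_A + eta_C
    if s <= 0.0 or lb == 0.0:
        return (0.0, 0.0, 0.0)
    eta = eta_A + eta_C + eta_S
    kappa = math.sqrt(24.0 * lb * s)
    m, f, H = _params(eta_A, eta_C, eta, N_A, N_C)
    a_k = _dA_dkappa(kappa, f, H)
    a_f = _dA_df(kappa, f, H)
    a_h = _dA_dH(kappa, f, H)

    dk = kappa / (2.0 * s)  # dkappa/deta_A = dkappa/deta_C; 0 for S

    inv_m = 1.0 / m
    dinvm_A = (1.0 / N_A - inv_m) / s
    dinvm_C = (1.0 / N_C - inv_m) / s
    dm_A, dm_C = -m * m * dinvm_A, -m * m * dinvm_C
    denom = 5.0 * m * m - 2.0 * m - 1.0
    df_dm = -4.0 * m * (m + 1.0) / (denom * denom)

    one = 1.0 - eta
    K = 3.0 * (N_C - N_A) / (2.0 * N_A * N_C)  # m_plus - m_minus over sizes
    dH_A = K * (dinvm_A * s / one + (1.0 + inv_m) * (one + s) / one**2)
    dH_C = K * (dinvm_C * s / one + (1.0 + inv_m) * (one + s) / one**2)
    dH_S = K * (1.0 + inv_m) * s / one**2

    g_A = a_k * dk + a_f * df_dm * dm_A + a_h * dH_A
    g_C = a_k * dk + a_f * df_dm * dm_C + a_h * dH_C
    g_S = a_h * dH_S
    return (g_A, g_C, g_S)


def _monomer_a_d3(kappa: float) -> float:
    # m = 1 (f = 1, H = 0) limit of the free energy
    return -(
        6.0 * kappa + 3.0 * kappa * kappa - 2.0 * (1.0 + 2.0 * kappa) ** 1.5 + 2.0
    ) / (12.0 * _PI)


def a_el_method2(mixture: Mixture, state: ReducedState) -> float:
    """Electrostatic free energy density beta Delta A_el d^3/V (Method II)."""
    return _kernel_a_d3(
        state.eta_A, state.eta_C, state.eta_S, mixture.N_A, mixture.N_C, state.lb
    )


def e_el_method2(mixture: Mixture, state: ReducedState) -> float:
    """Electrostatic internal energy density beta Delta E_el d^3/V."""
    return _kernel_e_d3(
        state.eta_A, state.eta_C, state.eta_S, mixture.N_A, mixture.N_C, state.lb
    )


def p_el_method2(mixture: Mixture, state: ReducedState) -> float:
    """Electrostatic pressure beta Delta P_el d^3, by the analytic
    thermodynamic route (density derivative of the free energy)."""
    return _kernel_p_d3(
        state.eta_A, state.eta_C, state.eta_S, mixture.N_A, mixture.N_C, state.lb
    )


def a_el_pol_method2(mixture: Mixture, state: ReducedState) -> float:
    """Connectivity-only part of the Method II free energy (d^3 units):
    the full free energy minus its m -> 1 (monomeric) limit at the same
    kappa.  Zero when m = 1 and at kappa = 0."""
    a = a_el_method2(mixture, state)
    if a == 0.0:
        return 0.0
    return a - _monomer_a_d3(state.kappa)


def series_coeffs(f: float, H: float) -> SeriesCoeffs:
    """Small-kappa series coefficients of the free energy (D_j) and of the
    free-energy/internal-energy difference (S_j).

    The S_j follow exactly from the Gibbs--Helmholtz relation
    E = (kappa/2) dA/dkappa, which gives S_j = (1 - j/2) D_j term by term
    (so S2 = 0 identically).  Singular at |H| = 1.
    """
    if not 0.0 < f <= 1.0:
        raise ValueError(f"f must lie in (0, 1], got {f!r}")
    am, ap = abs(1.0 - H), abs(1.0 + H)
    if am == 0.0 or ap == 0.0:
        raise ValueError("series coefficients are singular at H = +/-1")
    phi = math.sqrt(f)
    d1 = phi / (4.0 * _PI) * (-2.0 + am + ap)
    d2 = 1.0 / (8.0 * _PI) * (-2.0 + 1.0 / am + 1.0 / ap)
    d3 = -1.0 / (24.0 * _PI * phi) * (1.0 / am**3 + 1.0 / ap**3)
    d4 = 1.0 / (32.0 * _PI * f) * (1.0 / am**5 + 1.0 / ap**5)
    return SeriesCoeffs(
        D1=d1, D2=d2, D3=d3, D4=d4, S1=0.5 * d1, S3=-0.5 * d3, S4=-d4
    )


def method2(mixture: Mixture, state: ReducedState) -> MethodIIResult:
    """All Method II electrostatic quantities at one state point."""
    params = mdoz_params(mixture, state)
    try:
        series: SeriesCoeffs | None = series_coeffs(params.f, params.H)
    except ValueError:
        series = None
    return MethodIIResult(
        a_el=a_el_method2(mixture, state),
        e_el=e_el_method2(mixture, state),
        p_el=p_el_method2(mixture, state),
        a_el_pol=a_el_pol_method2(mixture, state),
        params=params,
        series=series,
    )
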