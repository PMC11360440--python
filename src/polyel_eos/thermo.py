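"""Total thermodynamics of the PA/PC/S solution.

Assembles A = A_id + A_ex + Delta A_el and P = P_HSC + Delta P_el for a
selected electrostatic method (``"method1"`` Blum--Stell, ``"method2"``
MDOZ, ``"dh"`` Debye--Hueckel, or ``"none"`` for the uncharged chain
reference), and provides chemical potentials, the Gibbs free-energy
density and fixed-pressure density solving.  All free-energy and
pressure densities returned here are in v* units (beta X v*/V and
beta P v*); the d^3-unit results of the electrostatic modules are
converted with the exact factor pi/6.

Chemical potentials are per-monomer derivatives,

    mu_k/(N_k kT) = d(beta A v*/V)/d eta_k  at fixed other eta_l,

evaluated fully analytically: the ideal chain term carries the ln eta_k
singularity, and the excess + electrostatic remainder has closed-form
gradients (cross-validated against Richardson-extrapolated central
differences in the test suite).  Individual mu_A and mu_C use the
analytic continuation of the electrostatic kernels off the
electroneutral manifold; their sum mu_A,eff = mu_A/N_A + mu_C/N_C, the
quantity entering phase equilibria, is electroneutral by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import blum_stell, dh_reference, mdoz
from .core import V_STAR_OVER_D3, Mixture, validate_mixture
from .hs_chain_eos import helmholtz_id, number_average_N, pressure_hsc

__all__ = [
    "METHODS",
    "ThermoState",
    "total_free_energy",
    "total_pressure",
    "chemical_potentials",
    "gibbs_density",
    "solve_eta_at_pressure",
    "thermo_state",
]

METHODS = ("method1", "method2", "dh", "none")

#: upper bound of the physically trusted density range (random close
#: packing vicinity); density solves never cross it
ETA_MAX = 0.74


def _check_method(method: str) -> None:
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


# -- smooth (non-ideal) free-energy kernel, v* units -----------------------

def _a_rest(
    eta_A: float,
    eta_C: float,
    eta_S: float,
    N_A: int,
    N_C: int,
    lb: float,
    method: str,
) -> float:
    """Excess hard-sphere-chain + electrostatic free energy, beta A v*/V.

    Written directly in the partial packing fractions so it can be
    differentiated species by species (analytic continuation off the
    electroneutral manifold is used for individual chemical potentials).
    """
    eta = eta_A + eta_C + eta_S
    if eta <= 0.0:
        return 0.0
    one = 1.0 - eta
    log1m = math.log(one)
    hs = 1.5 * eta / one**2 - eta * (log1m + 1.5)
    s_bond = eta_A * (1.0 - 1.0 / N_A) + eta_C * (1.0 - 1.0 / N_C)
    a = hs - s_bond * (1.5 * eta / one - log1m)
    if method == "method1":
        a += blum_stell._kernel_a_v(eta_A, eta_C, N_A, N_C, lb)
    elif method == "method2":
        a += V_STAR_OVER_D3 * mdoz._kernel_a_d3(eta_A, eta_C, eta_S, N_A, N_C, lb)
    elif method == "dh":
        s = eta_A + eta_C
        if s > 0.0 and lb > 0.0:
            kappa = math.sqrt(24.0 * lb * s)
            a += V_STAR_OVER_D3 * dh_reference.dh_free_energy(kappa)
    return a


def _p_el_v(
    eta_A: float,
    eta_C: float,
    eta_S: float,
    N_A: int,
    N_C: int,
    lb: float,
    method: str,
) -> float:
    """Electrostatic pressure beta Delta P_el v* (analytic routes)."""
    if method == "method1":
        return blum_stell._kernel_p_v(eta_A, eta_C, N_A, N_C, lb)
    if method == "method2":
        return V_STAR_OVER_D3 * mdoz._kernel_p_d3(eta_A, eta_C, eta_S, N_A, N_C, lb)
    if method == "dh":
        s = eta_A + eta_C
        if s <= 0.0 or lb == 0.0:
            return 0.0
        kappa = math.sqrt(24.0 * lb * s)
        return V_STAR_OVER_D3 * dh_reference.dh_pressure(kappa)
    return 0.0


# -- public API ------------------------------------------------------------

def total_free_energy(mixture: Mixture, eta: float, lb: float, method: str) -> float:
    """Total free energy density beta A v*/V = a_id + a_ex + a_el."""
    _check_method(method)
    mixture = validate_mixture(mixture)
    eta_k = (mixture.phi_A * eta, mixture.phi_C * eta, mixture.phi_S * eta)
    a_id = helmholtz_id(eta_k, mixture.chain_lengths)
    return a_id + _a_rest(*eta_k, mixture.N_A, mixture.N_C, lb, method)


def total_pressure(mixture: Mixture, eta: float, lb: float, method: str) -> float:
    """Total reduced pressure beta P v* = beta P_HSC v* + beta Delta P_el v*."""
    _check_method(method)
    mixture = validate_mixture(mixture)
    if eta == 0.0:
        return 0.0
    navg = number_average_N(mixture)
    eta_k = (mixture.phi_A * eta, mixture.phi_C * eta, mixture.phi_S * eta)
    return pressure_hsc(eta, navg) + _p_el_v(*eta_k, mixture.N_A, mixture.N_C, lb, method)


def _grad_rest(
    eta_k: tuple[float, float, float],
    N_A: int,
    N_C: int,
    lb: float,
    method: str,
) -> tuple[float, float, float]:
    """Analytic gradient of the smooth kernel in the partial packing
    fractions (validated against Richardson finite differences)."""
    eA, eC, eS = eta_k
    eta = eA + eC + eS
    if eta <= 0.0:
        return (0.0, 0.0, 0.0)
    one = 1.0 - eta
    log1m = math.log(one)
    # hard-sphere part: d/deta of 1.5 eta/(1-eta)^2 - eta(ln(1-eta)+1.5)
    hs_prime = 1.5 * (1.0 + eta) / one**3 - log1m + eta / one - 1.5
    u = 1.5 * eta / one - log1m
    u_prime = 1.5 / one**2 + 1.0 / one
    s_bond = eA * (1.0 - 1.0 / N_A) + eC * (1.0 - 1.0 / N_C)
    grad = [
        hs_prime - (1.0 - 1.0 / N_A) * u - s_bond * u_prime,
        hs_prime - (1.0 - 1.0 / N_C) * u - s_bond * u_prime,
        hs_prime - s_bond * u_prime,
    ]
    if method == "method1":
        el = blum_stell._grad_a_v(eA, eC, N_A, N_C, lb)
    elif method == "method2":
        el = tuple(
            V_STAR_OVER_D3 * gi for gi in mdoz._grad_a_d3(eA, eC, eS, N_A, N_C, lb)
        )
    elif method == "dh":
        s = eA + eC
        if s > 0.0 and lb > 0.0:
            kappa = math.sqrt(24.0 * lb * s)
            # dA/dkappa = -kappa^2/(4 pi (1+kappa)); dkappa/deta = kappa/2s
            d = (
                V_STAR_OVER_D3
                * (-kappa * kappa / (4.0 * math.pi * (1.0 + kappa)))
                * kappa
                / (2.0 * s)
            )
            el = (d, d, 0.0)
        else:
            el = (0.0, 0.0, 0.0)
    else:
        el = (0.0, 0.0, 0.0)
    return (grad[0] + el[0], grad[1] + el[1], grad[2] + el[2])


def _mu_rest_directional(
    eta_k: tuple[float, float, float],
    direction: tuple[float, float, float],
    N_A: int,
    N_C: int,
    lb: float,
    method: str,
) -> float:
    """Directional derivative of the smooth kernel along ``direction``."""
    g = _grad_rest(eta_k, N_A, N_C, lb, method)
    return sum(gi * di for gi, di in zip(g, direction))


def _mu_hats(
    mixture: Mixture, eta: float, lb: float, method: str
) -> tuple[dict[str, float], float]:
    """Per-monomer chemical potentials mu_k/(N_k kT) and mu_A,eff."""
    eta_k = (mixture.phi_A * eta, mixture.phi_C * eta, mixture.phi_S * eta)
    N = {"A": mixture.N_A, "C": mixture.N_C, "S": 1}
    dirs = {"A": (1.0, 0.0, 0.0), "C": (0.0, 1.0, 0.0), "S": (0.0, 0.0, 1.0)}
    mu: dict[str, float] = {}
    for i, k in enumerate(("A", "C", "S")):
        e = eta_k[i]
        ideal = -math.inf if e == 0.0 else (math.log(e / N[k]) + 1.0) / N[k]
        mu[k] = ideal + _mu_rest_directional(
            eta_k, dirs[k], mixture.N_A, mixture.N_C, lb, method
        )
    # effective PA potential along the electroneutral direction
    eA, eC = eta_k[0], eta_k[1]
    if eA == 0.0 or eC == 0.0:
        mu_eff = -math.inf
    else:
        ideal_eff = (math.log(eA / mixture.N_A) + 1.0) / mixture.N_A + (
            math.log(eC / mixture.N_C) + 1.0
        ) / mixture.N_C
        mu_eff = ideal_eff + _mu_rest_directional(
            eta_k, (1.0, 1.0, 0.0), mixture.N_A, mixture.N_C, lb, method
        )
    return mu, mu_eff


def chemical_potentials(
    mixture: Mixture, eta: float, lb: float, method: str
) -> tuple[dict[str, float], float]:
    """Per-monomer chemical potentials.

    Returns
    -------
    mu_over_N : dict
        ``{"A": mu_A/(N_A kT), "C": ..., "S": ...}``; ``-inf`` for an
        absent species (ideal divergence).
    mu_A_eff : float
        mu_A/N_A + mu_C/N_C, the field conjugate to the polyelectrolyte
        composition in the electroneutral two-component reduction.
    """
    _check_method(method)
    mixture = validate_mixture(mixture)
    if not 0.0 < eta < 1.0:
        raise ValueError(f"eta must lie in (0, 1), got {eta!r}")
    return _mu_hats(mixture, eta, lb, method)


def gibbs_density(mixture: Mixture, eta: float, lb: float, method: str) -> float:
    """Gibbs free-energy density g = (beta A v*/V + beta P v*)/eta,
    i.e. the Gibbs free energy per monomer in kT units."""
    if eta == 0.0:
        raise ValueError("gibbs_density is undefined at eta = 0")
    a = total_free_energy(mixture, eta, lb, method)
    p = total_pressure(mixture, eta, lb, method)
    return (a + p) / eta


@dataclass(frozen=True)
class ThermoState:
    """Complete thermodynamic characterization of one state point."""

    method: str
    eta: float
    lb: float
    a_total: float               # beta A v*/V
    p_total: float               # beta P v*
    mu_over_N: dict[str, float]  # mu_k/(N_k kT)
    mu_A_eff: float              # mu_A/N_A + mu_C/N_C
    g: float                     # Gibbs density (a + p)/eta


def thermo_state(mixture: Mixture, eta: float, lb: float, method: str) -> ThermoState:
    """Evaluate the full :class:`ThermoState` at one state point."""
    _check_method(method)
    mixture = validate_mixture(mixture)
    a = total_free_energy(mixture, eta, lb, method)
    p = total_pressure(mixture, eta, lb, method)
    mu, mu_eff = _mu_hats(mixture, eta, lb, method)
    return ThermoState(
        method=method,
        eta=eta,
        lb=lb,
        a_total=a,
        p_total=p,
        mu_over_N=mu,
        mu_A_eff=mu_eff,
        g=(a + p) / eta,
    )


def _dp_deta(mixture: Mixture, eta: float, lb: float, method: str) -> float:
    h = 1e-7 * (1.0 + eta)
    h = min(h, 0.25 * (ETA_MAX - eta) if eta < ETA_MAX else h, 0.25 * eta)
    return (
        total_pressure(mixture, eta + h, lb, method)
        - total_pressure(mixture, eta - h, lb, method)
    ) / (2.0 * h)


def solve_eta_at_pressure(
    mixture: Mixture,
    lb: float,
    method: str,
    p_target: float,
    eta_guess: float | None = None,
) -> float:
    """Packing fraction eta in (0, ETA_MAX) at which beta P v* equals
    ``p_target``.

    A warm-started Newton iteration is used when ``eta_guess`` is given;
    otherwise the bracket is scanned for all mechanically stable roots
    (dP/deta > 0) and, when P(eta) is multivalued, the root of lowest
    Gibbs density g is returned (the equilibrium branch).
    """
    _check_method(method)
    mixture = validate_mixture(mixture)
    if p_target <= 0.0:
        raise ValueError(f"p_target must be > 0, got {p_target!r}")

    def pres(eta: float) -> float:
        return total_pressure(mixture, eta, lb, method)

    if eta_guess is not None and 0.0 < eta_guess < ETA_MAX:
        eta = eta_guess
        ok = False
        for _ in range(60):
            resid = pres(eta) - p_target
            if abs(resid) < 1e-13 * max(1.0, p_target):
                ok = True
                break
            d = _dp_deta(mixture, eta, lb, method)
            if d <= 0.0:
                break
            step = resid / d
            new = eta - step
            if not 1e-14 < new < ETA_MAX:
                break
            eta = new
        if ok and _dp_deta(mixture, eta, lb, method) > 0.0:
            return eta

    # full scan: log-spaced in the dilute regime, linear above
    import numpy as np
    from scipy.optimize import brentq

    grid = np.concatenate(
        [np.geomspace(1e-8, 0.01, 25), np.linspace(0.0125, ETA_MAX, 60)]
    )
    vals = [pres(x) - p_target for x in grid]
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0.0:
            roots.append(
                brentq(lambda x: pres(x) - p_target, grid[i], grid[i + 1], xtol=1e-15)
            )
    stable = [r for r in roots if _dp_deta(mixture, r, lb, method) > 0.0]
    if not stable:
        raise ValueError(
            f"no mechanically stable density with beta P v* = {p_target} "
            f"for lb={lb}, method={method!r}"
        )
    if len(stable) == 1:
        return float(stable[0])
    return float(min(stable, key=lambda r: gibbs_density(mixture, r, lb, method)))
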