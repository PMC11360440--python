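"""Baxter--Chiew hard-sphere-chain reference equation of state.

Covalently bonded chains of equal-diameter hard spheres are described by
Baxter's adhesive-sphere factorization taken to the complete-bonding
limit.  The resulting pressure is

    beta P_HSC v* = (eta + eta^2 + eta^3)/(1-eta)^3
                    - (1 - 1/N) (eta + eta^2/2)/(1-eta)^2

where N is the number-average chain length of the mixture, and the
matching excess Helmholtz free energy density (obtained by integrating
the pressure along an isotherm) is

    beta A_ex v*/V = [ (3/2) eta/(1-eta)^2 - eta (ln(1-eta) + 3/2) ]
                     - (eta - eta/N) [ (3/2) eta/(1-eta) - ln(1-eta) ]

The first bracket is the unbonded (Percus--Yevick compressibility route)
hard-sphere part, the second the covalent-bonding part.  The ideal chain
mixture contributes beta A_id v*/V = sum_j (eta_j/N_j) ln(eta_j T_j/N_j);
the molecular constants T_j only shift chemical potentials by
composition-independent amounts and are set to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .core import Mixture, validate_mixture

__all__ = [
    "HscResult",
    "number_average_N",
    "pressure_hsc",
    "helmholtz_ex_hsc",
    "helmholtz_id",
    "hsc_eos",
]


@dataclass(frozen=True)
class HscResult:
    """Hard-sphere-chain reference thermodynamics at one state point."""

    a_id: float  # beta A_id v*/V
    a_ex: float  # beta A_ex v*/V
    p: float     # beta P_HSC v*
    navg: float  # number-average chain length used


def number_average_N(mixture: Mixture) -> float:
    """Number-average chain length: 1/N = phi_A/N_A + phi_C/N_C + phi_S."""
    mixture = validate_mixture(mixture)
    return 1.0 / (
        mixture.phi_A / mixture.N_A + mixture.phi_C / mixture.N_C + mixture.phi_S
    )


def pressure_hsc(eta: float, navg: float) -> float:
    """Reduced pressure beta P_HSC v* of the hard-sphere-chain fluid.

    At ``navg == 1`` this is the Percus--Yevick compressibility-route
    hard-sphere pressure (eta + eta^2 + eta^3)/(1-eta)^3.
    """
    if not 0.0 <= eta < 1.0:
        raise ValueError(f"eta must lie in [0, 1), got {eta!r}")
    one = 1.0 - eta
    hs = eta * (1.0 + eta + eta * eta) / one**3
    bond = (1.0 - 1.0 / navg) * (eta + 0.5 * eta * eta) / one**2
    return hs - bond


def helmholtz_ex_hsc(eta: float, navg: float) -> float:
    """Excess free energy density beta A_ex v*/V of the chain fluid.

    Thermodynamically consistent with :func:`pressure_hsc` through
    P = eta d(a_id + a_ex)/d eta - (a_id + a_ex) at fixed composition.
    """
    if not 0.0 <= eta < 1.0:
        raise ValueError(f"eta must lie in [0, 1), got {eta!r}")
    if eta == 0.0:
        return 0.0
    one = 1.0 - eta
    log1m = math.log(one)
    hs = 1.5 * eta / one**2 - eta * (log1m + 1.5)
    bond = (eta - eta / navg) * (1.5 * eta / one - log1m)
    return hs - bond


def _xlogx(x: float) -> float:
    # x ln x with the continuous limit 0 at x = 0
    return 0.0 if x == 0.0 else x * math.log(x)


def helmholtz_id(eta_k: Sequence[float], N_k: Sequence[float]) -> float:
    """Ideal chain-mixture free energy density beta A_id v*/V.

    sum_j (eta_j/N_j) ln(eta_j/N_j) with molecular constants T_j = 1;
    species with eta_j = 0 contribute nothing.
    """
    if len(eta_k) != len(N_k):
        raise ValueError("eta_k and N_k must have equal length")
    return sum(_xlogx(e / n) for e, n in zip(eta_k, N_k))


def hsc_eos(mixture: Mixture, eta: float) -> HscResult:
    """Evaluate the full hard-sphere-chain reference at one state point."""
    mixture = validate_mixture(mixture)
    navg = number_average_N(mixture)
    eta_k = [mixture.phi_A * eta, mixture.phi_C * eta, mixture.phi_S * eta]
    return HscResult(
        a_id=helmholtz_id(eta_k, mixture.chain_lengths),
        a_ex=helmholtz_ex_hsc(eta, navg),
        p=pressure_hsc(eta, navg),
        navg=navg,
    )
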