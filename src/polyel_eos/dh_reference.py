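"""Classic Debye--Hueckel limiting law for electrolyte solutions.

Reference expressions used for series-matching checks against the MDOZ
closed forms (which agree with DH through order kappa^4 and first differ
at kappa^5: -1/(20 pi) here versus -1/(16 pi) there).  All densities are
in d^3 units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["DhResult", "dh_free_energy", "dh_energy", "dh_diff", "dh"]

_PI = math.pi


@dataclass(frozen=True)
class DhResult:
    a_el: float   # beta Delta A_el d^3/V
    e_el: float   # beta Delta E_el d^3/V
    diff: float   # a_el - e_el


def dh_free_energy(kappa: float) -> float:
    """beta Delta A_el d^3/V = -(1/4 pi)[ln(1+kappa) - kappa + kappa^2/2].

    Small-kappa series: -kappa^3/12pi + kappa^4/16pi - kappa^5/20pi + ...
    """
    if kappa < 0.0:
        raise ValueError(f"kappa must be >= 0, got {kappa!r}")
    return -(math.log1p(kappa) - kappa + 0.5 * kappa * kappa) / (4.0 * _PI)


def dh_energy(kappa: float) -> float:
    """beta Delta E_el d^3/V = -(kappa/8 pi)(-1 + kappa + 1/(1+kappa)),
    i.e. -kappa^3/(8 pi (1+kappa))."""
    if kappa < 0.0:
        raise ValueError(f"kappa must be >= 0, got {kappa!r}")
    return -(kappa / (8.0 * _PI)) * (-1.0 + kappa + 1.0 / (1.0 + kappa))


def dh_diff(kappa: float) -> float:
    """a_el - e_el in closed form:
    [kappa(2+kappa) - 2(1+kappa) ln(1+kappa)] / [8 pi (1+kappa)].

    Series: kappa^3/24pi - kappa^4/16pi + 3 kappa^5/40pi + ...
    """
    if kappa < 0.0:
        raise ValueError(f"kappa must be >= 0, got {kappa!r}")
    one = 1.0 + kappa
    return (kappa * (2.0 + kappa) - 2.0 * one * math.log1p(kappa)) / (8.0 * _PI * one)


def dh_pressure(kappa: float) -> float:
    """beta Delta P_el d^3 by the thermodynamic route.

    For any free energy depending on density only through kappa ~ sqrt(eta),
    eta da/deta = (kappa/2) da/dkappa = e_el (Gibbs--Helmholtz), so
    p_el = e_el - a_el = -dh_diff(kappa)."""
    return -dh_diff(kappa)


def dh(kappa: float) -> DhResult:
    a = dh_free_energy(kappa)
    e = dh_energy(kappa)
    return DhResult(a_el=a, e_el=e, diff=a - e)
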