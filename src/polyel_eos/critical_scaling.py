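"""Critical-exponent extraction by log--log regression near the
coacervation critical point.

The temperature-like variable is t = L_B,cp/L_B - 1: the Bjerrum length
is L_B = e^2/(eps kT), so at fixed dielectric constant T is proportional
to 1/L_B and t reduces to (T - T_C)/T_C near the critical point.  The
three exponents extracted are

* beta  : |phi_b - phi_a| ~ |t|^beta along the binodal (t < 0 side),
* gamma : chi^-1 = d^2 g/d phi_A^2 ~ t^gamma at phi_A = phi_cp on the
          one-phase side (t > 0, the critical-isochore analogue),
* delta : Delta mu_A,eff ~ (phi_A - phi_cp)^delta along the critical
          isotherm t = 0 in the mixed region.

An analytic equation of state yields the classical mean-field values
(1/2, 1, 3); the fits are plain least squares on ~20 log-spaced points
with the default windows |t| in [1e-4, 1e-2] and
phi_A - phi_cp in [1e-4, 1e-3].  The delta window is one decade chosen
well inside the asymptotic regime: corrections to scaling grow like
(phi_A - phi_cp)/phi_cp, so the window keeps that ratio below ~0.06
while staying far above the noise floor of the chemical-potential
derivatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import Mixture
from .phase_equilibria import (
    BinodalPoint,
    CriticalPoint,
    _Isobar,
    trace_binodal,
)

__all__ = [
    "ExponentEstimate",
    "fit_beta",
    "fit_gamma",
    "fit_delta",
    "beta_exponent",
    "gamma_exponent",
    "delta_exponent",
]

DEFAULT_T_WINDOW = (1e-4, 1e-2)
DEFAULT_PHI_WINDOW = (1e-4, 1e-3)


@dataclass(frozen=True)
class ExponentEstimate:
    name: str                       # "beta", "gamma" or "delta"
    value: float                    # fitted log-log slope
    fit_range: tuple[float, float]  # window in |t| or phi_A - phi_cp
    n_points: int
    r_squared: float


def _loglog_slope(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    lx, ly = np.log(np.asarray(x)), np.log(np.asarray(y))
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0.0 else 1.0
    return float(slope), r2


def _fit(name: str, x, y, fit_range) -> ExponentEstimate:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = (x >= fit_range[0] * (1 - 1e-9)) & (x <= fit_range[1] * (1 + 1e-9)) & (y > 0)
    if int(keep.sum()) < 5:
        raise ValueError(
            f"{name} fit needs >= 5 points inside the window {fit_range}, "
            f"got {int(keep.sum())}"
        )
    slope, r2 = _loglog_slope(x[keep], y[keep])
    return ExponentEstimate(
        name=name,
        value=slope,
        fit_range=(float(fit_range[0]), float(fit_range[1])),
        n_points=int(keep.sum()),
        r_squared=r2,
    )


# -- fits on precomputed traces -------------------------------------------

def fit_beta(
    binodal_trace: Iterable[BinodalPoint],
    critical_point: CriticalPoint,
    fit_range: tuple[float, float] = DEFAULT_T_WINDOW,
) -> ExponentEstimate:
    """Order-parameter exponent: slope of ln|phi_b - phi_a| vs ln|t|."""
    pts = list(binodal_trace)
    t = [abs(critical_point.lb_cp / p.lb - 1.0) for p in pts]
    dphi = [abs(p.phi_b - p.phi_a) for p in pts]
    return _fit("beta", t, dphi, fit_range)


def fit_gamma(
    chi_trace: Iterable[tuple[float, float]],
    critical_point: CriticalPoint,
    fit_range: tuple[float, float] = DEFAULT_T_WINDOW,
) -> ExponentEstimate:
    """Susceptibility exponent: slope of ln chi^-1 vs ln|t|.

    ``chi_trace`` holds (lb, chi_inv) pairs evaluated at phi_A = phi_cp
    on the one-phase side.
    """
    pairs = list(chi_trace)
    t = [abs(critical_point.lb_cp / lb - 1.0) for lb, _ in pairs]
    chi = [c for _, c in pairs]
    return _fit("gamma", t, chi, fit_range)


def fit_delta(
    isotherm_trace: Iterable[tuple[float, float]],
    critical_point: CriticalPoint,
    fit_range: tuple[float, float] = DEFAULT_PHI_WINDOW,
) -> ExponentEstimate:
    """Critical-isotherm exponent: slope of ln|Delta mu_A,eff| vs
    ln|phi_A - phi_cp|.

    ``isotherm_trace`` holds (phi_A, Delta mu_A,eff) pairs at lb = lb_cp.
    """
    pairs = list(isotherm_trace)
    x = [abs(phi - critical_point.phi_cp) for phi, _ in pairs]
    dmu = [abs(d) for _, d in pairs]
    return _fit("delta", x, dmu, fit_range)


# -- drivers that generate the traces --------------------------------------

def beta_exponent(
    mixture_template: Mixture,
    method: str,
    critical_point: CriticalPoint,
    p_target: float = 1.0,
    window: tuple[float, float] = DEFAULT_T_WINDOW,
    n_points: int = 20,
) -> tuple[ExponentEstimate, list[BinodalPoint]]:
    """Trace the binodal over |t| in ``window`` and fit beta."""
    ts = np.geomspace(window[0], window[1], n_points)
    lbs = critical_point.lb_cp / (1.0 - ts)  # two-phase side: lb > lb_cp
    trace = trace_binodal(
        mixture_template, lbs, method, p_target, critical_point=critical_point
    )
    return fit_beta(trace, critical_point, fit_range=window), trace


def gamma_exponent(
    mixture_template: Mixture,
    method: str,
    critical_point: CriticalPoint,
    p_target: float = 1.0,
    window: tuple[float, float] = DEFAULT_T_WINDOW,
    n_points: int = 20,
) -> tuple[ExponentEstimate, list[tuple[float, float]]]:
    """Evaluate chi^-1 on the critical isochore (t > 0) and fit gamma."""
    ws = _Isobar(mixture_template, method, p_target)
    ts = np.geomspace(window[0], window[1], n_points)
    trace = []
    for t in ts:
        lb = critical_point.lb_cp / (1.0 + t)  # one-phase side
        trace.append((float(lb), ws.chi_inv(critical_point.phi_cp, float(lb))))
    return fit_gamma(trace, critical_point, fit_range=window), trace


def delta_exponent(
    mixture_template: Mixture,
    method: str,
    critical_point: CriticalPoint,
    p_target: float = 1.0,
    window: tuple[float, float] = DEFAULT_PHI_WINDOW,
    n_points: int = 20,
) -> tuple[ExponentEstimate, list[tuple[float, float]]]:
    """Evaluate Delta mu_A,eff along the critical isotherm and fit delta."""
    ws = _Isobar(mixture_template, method, p_target)
    lb = critical_point.lb_cp
    mu_cp, _, _, _ = ws.potentials(critical_point.phi_cp, lb)
    xs = np.geomspace(window[0], window[1], n_points)
    trace = []
    for x in xs:
        phi = critical_point.phi_cp + float(x)
        mu, _, _, _ = ws.potentials(phi, lb)
        trace.append((phi, mu - mu_cp))
    return fit_delta(trace, critical_point, fit_range=window), trace
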