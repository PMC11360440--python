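"""Two-phase coexistence (complex coacervation), binodal tracing,
critical-point location and inverse susceptibility at fixed reduced
pressure.

Under electroneutrality (phi_C = phi_A) the mixture is a two-component
system of "polyelectrolyte" (composition variable phi_A) and solvent.
Coexistence between the dilute supernatant phase *a* and the dense
coacervate phase *b* at fixed beta P v* requires

    mu_A,eff^a = mu_A,eff^b     (mu_A,eff = mu_A/N_A + mu_C/N_C)
    mu_S^a     = mu_S^b

with each phase's packing fraction re-solved at the target pressure.
These are the common-tangent conditions on the Gibbs density g(phi_A):
by Gibbs--Duhem, dg/dphi_A|_P = mu_A,eff - 2 mu_S == W and
g - phi_A W = mu_S, so the inverse susceptibility chi^-1 = d^2g/dphi_A^2
and the third derivative needed for the critical point are computed as
first and second finite differences of W (never as high-order
differences of g itself).

The critical point is the state where the minimum of chi^-1 over phi_A
touches zero; it is located by a bracketed outer solve in L_B/d followed
by a two-dimensional Newton polish on (chi^-1, d chi^-1/d phi_A) = (0, 0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .core import Mixture, validate_mixture
from .numdiff import d1_5pt, d2_5pt
from .thermo import _mu_rest_directional, solve_eta_at_pressure, total_free_energy, total_pressure

__all__ = [
    "BinodalPoint",
    "CriticalPoint",
    "binodal_at_lb",
    "trace_binodal",
    "find_critical_point",
    "inverse_susceptibility",
]


@dataclass(frozen=True)
class BinodalPoint:
    """One converged coexistence point at fixed reduced pressure."""

    lb: float       # L_B/d
    phi_a: float    # supernatant PA volume fraction
    phi_b: float    # coacervate PA volume fraction
    eta_a: float    # supernatant packing fraction at the target pressure
    eta_b: float    # coacervate packing fraction
    residual: float # max |chemical-potential mismatch|


@dataclass(frozen=True)
class CriticalPoint:
    """Continuous-transition point of the coacervation binodal."""

    phi_cp: float   # critical PA volume fraction
    lb_cp: float    # critical L_B/d
    eta_cp: float   # packing fraction at the critical point


def _mix_at(template: Mixture, phi: float) -> Mixture:
    """Electroneutral mixture with phi_A = phi_C = phi from a template."""
    return validate_mixture(
        N_A=template.N_A, N_C=template.N_C, phi_A=phi, phi_S=1.0 - 2.0 * phi
    )


class _Isobar:
    """Workspace for repeated evaluations along a fixed-pressure path;
    warm-starts the inner density solve."""

    def __init__(self, template: Mixture, method: str, p_target: float):
        self.template = validate_mixture(template)
        self.method = method
        self.p_target = p_target
        self._eta_guess: float | None = None

    def solve_eta(self, phi: float, lb: float) -> float:
        mix = _mix_at(self.template, phi)
        eta = solve_eta_at_pressure(
            mix, lb, self.method, self.p_target, eta_guess=self._eta_guess
        )
        self._eta_guess = eta
        return eta

    def potentials(self, phi: float, lb: float) -> tuple[float, float, float, float]:
        """(mu_A_eff, mu_S, eta, g) at the solved density."""
        mix = _mix_at(self.template, phi)
        eta = self.solve_eta(phi, lb)
        eta_k = (mix.phi_A * eta, mix.phi_C * eta, mix.phi_S * eta)
        N_A, N_C = mix.N_A, mix.N_C
        ideal_eff = (math.log(eta_k[0] / N_A) + 1.0) / N_A + (
            math.log(eta_k[1] / N_C) + 1.0
        ) / N_C
        mu_eff = ideal_eff + _mu_rest_directional(
            eta_k, (1.0, 1.0, 0.0), N_A, N_C, lb, self.method
        )
        mu_s = (math.log(eta_k[2]) + 1.0) + _mu_rest_directional(
            eta_k, (0.0, 0.0, 1.0), N_A, N_C, lb, self.method
        )
        a = total_free_energy(mix, eta, lb, self.method)
        g = (a + self.p_target) / eta
        return mu_eff, mu_s, eta, g

    def W(self, phi: float, lb: float) -> float:
        """dg/dphi_A at fixed pressure (Gibbs--Duhem identity)."""
        mu_eff, mu_s, _, _ = self.potentials(phi, lb)
        return mu_eff - 2.0 * mu_s

    def chi_inv(self, phi: float, lb: float) -> float:
        """Inverse susceptibility chi^-1 = d^2 g/d phi_A^2 at fixed P."""
        h = max(1e-5, 1e-3 * phi)
        h = min(h, 0.2 * phi, 0.2 * (0.5 - phi))
        return d1_5pt(lambda x: self.W(x, lb), phi, h)

    def dchi_dphi(self, phi: float, lb: float) -> float:
        """d^3 g/d phi_A^3 at fixed P (second difference of W)."""
        h = max(2e-5, 2e-3 * phi)
        h = min(h, 0.2 * phi, 0.2 * (0.5 - phi))
        return d2_5pt(lambda x: self.W(x, lb), phi, h)


def inverse_susceptibility(
    mixture_template: Mixture,
    phi_A: float,
    lb: float,
    method: str,
    p_target: float = 1.0,
) -> float:
    """chi^-1 = d^2 g/d phi_A^2 at fixed pressure (eta re-solved per
    composition).  Negative inside the spinodal (a warning is emitted)."""
    ws = _Isobar(mixture_template, method, p_target)
    chi = ws.chi_inv(phi_A, lb)
    if chi < 0.0:
        warnings.warn(
            f"state (phi_A={phi_A}, lb={lb}) is inside the spinodal "
            f"(chi^-1 = {chi:.3e} < 0)",
            RuntimeWarning,
            stacklevel=2,
        )
    return chi


# -- coexistence -----------------------------------------------------------

def _spinodal_interval(
    ws: _Isobar, lb: float, phi_bounds: tuple[float, float]
) -> tuple[float, float] | None:
    """(phi_s1, phi_s2) roots of chi^-1 = 0, or None if single phase."""
    lo, hi = phi_bounds
    grid = np.geomspace(lo, hi, 40)
    vals = [ws.chi_inv(p, lb) for p in grid]
    neg = [i for i, v in enumerate(vals) if v < 0.0]
    if not neg:
        return None
    i0, i1 = neg[0], neg[-1]
    if i0 == 0 or i1 == len(grid) - 1:
        raise ValueError(
            f"spinodal extends beyond the composition bracket {phi_bounds}"
        )
    s1 = brentq(lambda p: ws.chi_inv(p, lb), grid[i0 - 1], grid[i0], xtol=1e-12)
    s2 = brentq(lambda p: ws.chi_inv(p, lb), grid[i1], grid[i1 + 1], xtol=1e-12)
    return float(s1), float(s2)


def _bracketed_coexistence(
    ws: _Isobar, lb: float, spin: tuple[float, float], phi_bounds: tuple[float, float]
) -> tuple[float, float]:
    """Robust coexistence estimate by the common-tangent construction.

    With chi^-1 > 0 on both sides of the spinodal (s1, s2), W = dg/dphi
    is monotone on (0, s1) and (s2, hi); for each supernatant candidate
    phi_a the slope-matching partner phi_b solves W(phi_b) = W(phi_a) in
    (s2, hi), and the coexistence root closes the intercept condition
    mu_S(phi_b) = mu_S(phi_a).  Everything stays strictly outside the
    spinodal, so the trivial coincident root cannot be reached.
    """
    s1, s2 = spin
    # the supernatant can be orders of magnitude more dilute than the
    # spinodal scan floor at strong coupling; W -> -inf as phi -> 0, so
    # a tiny lower end always brackets
    lo = 1e-12
    hi = phi_bounds[1]
    w_s2 = ws.W(s2 * 1.000001, lb)
    w_hi = ws.W(hi, lb)

    # admissible phi_a: W(phi_a) within the range W takes on (s2, hi)
    pa_min = brentq(lambda p: ws.W(p, lb) - w_s2, lo, s1, xtol=1e-14)
    w_s1 = ws.W(s1 * 0.999999, lb)
    if w_hi < w_s1:
        pa_max = brentq(lambda p: ws.W(p, lb) - w_hi, lo, s1, xtol=1e-14)
    else:
        pa_max = s1 * 0.999999

    def partner(pa: float) -> float:
        w = ws.W(pa, lb)
        return brentq(lambda p: ws.W(p, lb) - w, s2 * 1.000001, hi, xtol=1e-13)

    def intercept_gap(pa: float) -> float:
        pb = partner(pa)
        _, mu_s_a, _, _ = ws.potentials(pa, lb)
        _, mu_s_b, _, _ = ws.potentials(pb, lb)
        return mu_s_b - mu_s_a

    span = pa_max - pa_min
    a0, a1 = pa_min + 1e-6 * span, pa_max - 1e-6 * span
    g0, g1 = intercept_gap(a0), intercept_gap(a1)
    if g0 * g1 > 0.0:
        raise RuntimeError(
            f"common-tangent bracketing failed at lb={lb}: "
            f"gap({a0:.4g})={g0:.3e}, gap({a1:.4g})={g1:.3e}"
        )
    pa = brentq(intercept_gap, a0, a1, xtol=1e-14)
    return pa, partner(pa)


def binodal_at_lb(
    mixture_template: Mixture,
    lb: float,
    method: str,
    p_target: float = 1.0,
    guess: tuple[float, float] | None = None,
    phi_bounds: tuple[float, float] = (1e-5, 0.45),
) -> BinodalPoint | None:
    """Solve the two-phase coexistence at one coupling strength.

    Returns ``None`` when the state is single phase (no spinodal region,
    i.e. lb below the critical coupling).  Without a ``guess`` the
    bracketed common-tangent construction supplies the starting point; a
    Newton polish on (phi_A^a, phi_A^b) with residuals
    (Delta mu_A,eff, Delta mu_S) then drives the mismatch below 1e-9.
    A continuation ``guess`` that collapses toward the trivial
    phi_a = phi_b root is detected and recomputed from the bracket.
    """
    ws = _Isobar(mixture_template, method, p_target)
    spin_cache: list[tuple[float, float] | None] = []

    def spinodal() -> tuple[float, float] | None:
        if not spin_cache:
            spin_cache.append(_spinodal_interval(ws, lb, phi_bounds))
        return spin_cache[0]

    if guess is None:
        spin = spinodal()
        if spin is None:
            return None
        pa, pb = _bracketed_coexistence(ws, lb, spin, phi_bounds)
    else:
        pa, pb = guess
    init_gap = pb - pa

    def residuals(pa: float, pb: float) -> tuple[float, float]:
        mu_eff_a, mu_s_a, _, _ = ws.potentials(pa, lb)
        mu_eff_b, mu_s_b, _, _ = ws.potentials(pb, lb)
        return mu_eff_b - mu_eff_a, mu_s_b - mu_s_a

    def polish(pa: float, pb: float) -> tuple[float, float, float]:
        r1, r2 = residuals(pa, pb)
        norm = math.hypot(r1, r2)
        for _ in range(40):
            if norm < 1e-12:
                break
            h = max(1e-7, 0.05 * (pb - pa))
            r1a, r2a = residuals(pa + h, pb)
            r1b, r2b = residuals(pa, pb + h)
            j11, j21 = (r1a - r1) / h, (r2a - r2) / h
            j12, j22 = (r1b - r1) / h, (r2b - r2) / h
            det = j11 * j22 - j12 * j21
            if det == 0.0:
                break
            da = (-r1 * j22 + r2 * j12) / det
            db = (-r2 * j11 + r1 * j21) / det
            # clamp so a single step can never close the gap
            gap = pb - pa
            clamp = 0.4 * gap
            da = max(-clamp, min(clamp, da))
            db = max(-clamp, min(clamp, db))
            step, improved = 1.0, False
            for _ls in range(12):
                na, nb = pa + step * da, pb + step * db
                if 1e-13 < na < nb < phi_bounds[1]:
                    n1, n2 = residuals(na, nb)
                    nn = math.hypot(n1, n2)
                    if nn < norm:
                        pa, pb, r1, r2, norm = na, nb, n1, n2, nn
                        improved = True
                        break
                step *= 0.5
            if not improved:
                break
        return pa, pb, norm

    pa, pb, norm = polish(pa, pb)
    collapsed = (pb - pa) < 0.25 * init_gap
    if (collapsed or norm > 1e-9) and guess is not None:
        spin = spinodal()
        if spin is None:
            return None
        pa, pb = _bracketed_coexistence(ws, lb, spin, phi_bounds)
        pa, pb, norm = polish(pa, pb)
    if norm > 1e-9:
        raise RuntimeError(
            f"coexistence solve did not converge at lb={lb}: "
            f"residual={norm:.3e}, (phi_a, phi_b)=({pa:.6g}, {pb:.6g})"
        )
    if pb - pa < 1e-12:
        return None
    # both phases must sit outside the spinodal (compositional stability)
    if ws.chi_inv(pa, lb) <= 0.0 or ws.chi_inv(pb, lb) <= 0.0:
        raise RuntimeError(
            f"coexistence solve landed inside the spinodal at lb={lb}: "
            f"(phi_a, phi_b)=({pa:.6g}, {pb:.6g})"
        )
    eta_a = ws.solve_eta(pa, lb)
    eta_b = ws.solve_eta(pb, lb)
    return BinodalPoint(
        lb=lb, phi_a=pa, phi_b=pb, eta_a=eta_a, eta_b=eta_b, residual=norm
    )


def trace_binodal(
    mixture_template: Mixture,
    lb_grid,
    method: str,
    p_target: float = 1.0,
    critical_point: CriticalPoint | None = None,
) -> list[BinodalPoint]:
    """Trace the binodal over a grid of couplings by continuation.

    The grid is traversed from the strongest coupling (widest, most
    robust gap) toward the critical point, scaling the previous solution
    as the initial guess; single-phase grid points are skipped.  Points
    are returned sorted by ``lb`` ascending.
    """
    lbs = sorted(float(x) for x in lb_grid)
    points: list[BinodalPoint] = []
    prev: BinodalPoint | None = None
    for lb in reversed(lbs):
        guess = None
        if prev is not None:
            u = 0.5 * (prev.phi_a + prev.phi_b)
            v = 0.5 * (prev.phi_b - prev.phi_a)
            if critical_point is not None and prev.lb > critical_point.lb_cp:
                t_prev = prev.lb / critical_point.lb_cp - 1.0
                t_new = lb / critical_point.lb_cp - 1.0
                if t_new > 0.0:
                    scale = math.sqrt(t_new / t_prev)
                    du = (u - critical_point.phi_cp) * (t_new / t_prev)
                    guess = (
                        critical_point.phi_cp + du - v * scale,
                        critical_point.phi_cp + du + v * scale,
                    )
            if guess is None:
                guess = (prev.phi_a, prev.phi_b)
        pt = binodal_at_lb(mixture_template, lb, method, p_target, guess=guess)
        if pt is None:
            if prev is not None:
                break  # crossed below the critical coupling
            continue
        points.append(pt)
        prev = pt
    return sorted(points, key=lambda p: p.lb)


# -- critical point --------------------------------------------------------

def find_critical_point(
    mixture_template: Mixture,
    method: str,
    p_target: float = 1.0,
    phi_bounds: tuple[float, float] = (1e-4, 0.2),
    lb_bounds: tuple[float, float] = (0.5, 20.0),
) -> CriticalPoint:
    """Locate the critical point of the coacervation transition.

    Solves d^2 g/d phi_A^2 = 0 and d^3 g/d phi_A^3 = 0 simultaneously
    over (phi_A, L_B/d) at fixed reduced pressure: an outer bracketed
    root on min_phi chi^-1(phi; lb), then a 2x2 Newton polish.
    """
    ws = _Isobar(mixture_template, method, p_target)
    phi_grid = np.geomspace(phi_bounds[0], phi_bounds[1], 25)
    lb_grid = np.geomspace(lb_bounds[0], lb_bounds[1], 25)

    def coarse_min(lb: float) -> tuple[float, float]:
        vals = [ws.chi_inv(p, lb) for p in phi_grid]
        i = int(np.argmin(vals))
        return vals[i], float(phi_grid[i])

    bracket = None
    prev_lb = prev_val = None
    arg_hint = None
    for lb in lb_grid:
        val, arg = coarse_min(float(lb))
        if prev_val is not None and prev_val > 0.0 >= val:
            bracket = (prev_lb, float(lb))
            arg_hint = arg
            break
        prev_lb, prev_val = float(lb), val
    if bracket is None:
        raise ValueError(
            f"no critical point in the search box phi={phi_bounds}, lb={lb_bounds} "
            f"(method={method!r})"
        )

    lo_phi, hi_phi = arg_hint / 3.0, min(arg_hint * 3.0, phi_bounds[1])

    def smin(lb: float) -> float:
        res = minimize_scalar(
            lambda p: ws.chi_inv(p, lb),
            bounds=(lo_phi, hi_phi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        smin.last_phi = float(res.x)  # type: ignore[attr-defined]
        return float(res.fun)

    lb_cp = brentq(smin, bracket[0], bracket[1], xtol=1e-10, rtol=1e-14)
    phi_cp = smin.last_phi  # type: ignore[attr-defined]

    # Newton polish on F = (chi^-1, d chi^-1/d phi)
    phi, lb = float(phi_cp), float(lb_cp)
    for _ in range(8):
        f1 = ws.chi_inv(phi, lb)
        f2 = ws.dchi_dphi(phi, lb)
        hp, hl = 1e-3 * phi, 1e-5 * lb
        j11 = (ws.chi_inv(phi + hp, lb) - ws.chi_inv(phi - hp, lb)) / (2 * hp)
        j21 = (ws.dchi_dphi(phi + hp, lb) - ws.dchi_dphi(phi - hp, lb)) / (2 * hp)
        j12 = (ws.chi_inv(phi, lb + hl) - ws.chi_inv(phi, lb - hl)) / (2 * hl)
        j22 = (ws.dchi_dphi(phi, lb + hl) - ws.dchi_dphi(phi, lb - hl)) / (2 * hl)
        det = j11 * j22 - j12 * j21
        if det == 0.0:
            break
        dphi = (-f1 * j22 + f2 * j12) / det
        dlb = (-f2 * j11 + f1 * j21) / det
        phi, lb = phi + dphi, lb + dlb
        if abs(dphi) < 1e-10 * phi and abs(dlb) < 1e-10 * lb:
            break
    eta_cp = ws.solve_eta(phi, lb)
    return CriticalPoint(phi_cp=float(phi), lb_cp=float(lb), eta_cp=float(eta_cp))
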