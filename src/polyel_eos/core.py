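"""Mixture description and reduced-unit bookkeeping.

The system is a restricted primitive model of a polyelectrolyte solution:
a polyanion (PA, species A, charge -1 per monomer), a polycation (PC,
species C, charge +1 per monomer) and a monomeric neutral solvent S, all
represented as hard spheres of one common diameter d in a uniform
dielectric background.  Everything downstream works in dimensionless
reduced variables with d = 1:

* ``eta``      -- total packing fraction (sphere volume fraction),
* ``phi_k``    -- composition (volume fraction of species k, summing to 1),
* ``lb``       -- reduced Bjerrum length L_B/d = e^2/(eps kT d), the
                  inverse-temperature-like coupling,
* ``kappa``    -- reduced Debye screening strength kappa*d with
                  kappa^2 = 4 pi L_B (rho_T - rho_S), i.e.
                  (kappa d)^2 = 24 (L_B/d) (eta - eta_S).

Densities per unit volume are reported either per sphere volume
v* = pi d^3/6 (``beta X v*/V``) or per d^3 (``beta X d^3/V``); the two
conventions differ by the exact factor pi/6 (:data:`V_STAR_OVER_D3`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "V_STAR_OVER_D3",
    "Mixture",
    "ReducedState",
    "validate_mixture",
    "reduced_state",
]

#: v*/d^3 for spheres of diameter d: v* = pi d^3 / 6.
V_STAR_OVER_D3 = math.pi / 6.0

_PHI_TOL = 1e-12


@dataclass(frozen=True)
class Mixture:
    """Composition of the PA/PC/S mixture.

    Parameters
    ----------
    N_A, N_C : int
        Chain lengths (number of monomers) of the polyanion and polycation.
        The solvent is monomeric (N_S = 1).
    phi_A, phi_C, phi_S : float
        Volume fractions of the three species.  Electroneutrality of the
        fully charged restricted model forces ``phi_C == phi_A``.

    Per-monomer charge numbers are fixed: z_A = -1, z_C = +1, z_S = 0.
    """

    N_A: int
    N_C: int
    phi_A: float
    phi_C: float
    phi_S: float

    N_S: int = 1
    z_A: int = -1
    z_C: int = +1
    z_S: int = 0

    @property
    def phis(self) -> tuple[float, float, float]:
        return (self.phi_A, self.phi_C, self.phi_S)

    @property
    def chain_lengths(self) -> tuple[int, int, int]:
        return (self.N_A, self.N_C, self.N_S)


def validate_mixture(
    mixture: Mixture | None = None,
    *,
    N_A: int | None = None,
    N_C: int | None = None,
    phi_A: float | None = None,
    phi_C: float | None = None,
    phi_S: float | None = None,
) -> Mixture:
    """Validate a mixture and enforce the model invariants.

    Either pass an existing :class:`Mixture` or keyword components.  Missing
    ``phi_C`` is filled in by electroneutrality (``phi_C = phi_A``); missing
    ``phi_S`` is filled by closure (``phi_S = 1 - phi_A - phi_C``).

    Raises
    ------
    ValueError
        If the composition does not sum to one, electroneutrality is broken,
        any fraction is negative, or a chain length is not a positive integer.
    """
    if mixture is not None:
        N_A, N_C = mixture.N_A, mixture.N_C
        phi_A, phi_C, phi_S = mixture.phi_A, mixture.phi_C, mixture.phi_S
    if N_A is None or N_C is None or phi_A is None:
        raise ValueError("N_A, N_C and phi_A are required")
    for name, n in (("N_A", N_A), ("N_C", N_C)):
        if int(n) != n or n < 1:
            raise ValueError(f"{name} must be an integer >= 1, got {n!r}")
    if phi_C is None:
        phi_C = phi_A
    if phi_S is None:
        phi_S = 1.0 - phi_A - phi_C
    if phi_A < 0 or phi_C < 0 or phi_S < 0:
        raise ValueError("volume fractions must be non-negative")
    if abs(phi_A + phi_C + phi_S - 1.0) > _PHI_TOL:
        raise ValueError(
            f"volume fractions must sum to 1, got {phi_A + phi_C + phi_S!r}"
        )
    # electroneutrality: phi_A * z_A + phi_C * z_C = phi_C - phi_A = 0
    if abs(phi_C - phi_A) > _PHI_TOL:
        raise ValueError(
            "electroneutrality broken: fully charged chains require "
            f"phi_C == phi_A, got phi_A={phi_A!r}, phi_C={phi_C!r}"
        )
    return Mixture(int(N_A), int(N_C), float(phi_A), float(phi_A), float(phi_S))


@dataclass(frozen=True)
class ReducedState:
    """A thermodynamic state point in reduced units (d = 1).

    Carries the mixture, the packing fraction ``eta``, the coupling ``lb``
    (= L_B/d) and the derived quantities: partial packing fractions,
    reduced screening strength ``kappa`` (= kappa d), reduced number
    densities ``rho_total`` (= rho_T d^3 = 6 eta/pi) and ``rho_s``, and the
    number-average chain length ``navg``.
    """

    mixture: Mixture
    eta: float
    lb: float
    eta_A: float
    eta_C: float
    eta_S: float
    kappa: float
    rho_total: float
    rho_s: float
    navg: float

    vstar_over_d3: float = V_STAR_OVER_D3

    @property
    def eta_k(self) -> dict[str, float]:
        return {"A": self.eta_A, "C": self.eta_C, "S": self.eta_S}


def reduced_state(mixture: Mixture, eta: float, lb: float) -> ReducedState:
    """Build the :class:`ReducedState` at packing fraction ``eta`` and
    coupling ``lb`` = L_B/d.

    The screening strength follows from kappa^2 = 4 pi L_B (rho_T - rho_S),
    which in reduced units is (kappa d)^2 = 24 (L_B/d)(eta - eta_S).
    """
    if not 0.0 < eta < 1.0:
        raise ValueError(f"eta must lie in (0, 1), got {eta!r}")
    if lb < 0.0:
        raise ValueError(f"lb must be >= 0, got {lb!r}")
    mixture = validate_mixture(mixture)
    eta_A = mixture.phi_A * eta
    eta_C = mixture.phi_C * eta
    eta_S = mixture.phi_S * eta
    kappa = math.sqrt(24.0 * lb * (eta - eta_S))
    navg = 1.0 / (
        mixture.phi_A / mixture.N_A + mixture.phi_C / mixture.N_C + mixture.phi_S
    )
    return ReducedState(
        mixture=mixture,
        eta=float(eta),
        lb=float(lb),
        eta_A=eta_A,
        eta_C=eta_C,
        eta_S=eta_S,
        kappa=kappa,
        rho_total=6.0 * eta / math.pi,
        rho_s=6.0 * eta_S / math.pi,
        navg=navg,
    )
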