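"""Molecular and rheological property models.

Diffusion coefficients of small molecules (gases) in liquids via the
Stokes–Einstein–Gierer–Wirtz (SEGW) estimation, and evaluation of the
Ostwald–de Waele power law.

The plain Stokes–Einstein relation D = kB·T/(6·pi·eta·r) assumes a sphere
moving through a continuum; for solutes comparable in size to the solvent
molecules the Gierer–Wirtz microfriction factor f_GW corrects the friction
term. Hard-sphere radii are estimated from molecular weights with a fitted
effective density of 619 kg/m^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import K_BOLTZMANN, N_AVOGADRO

__all__ = [
    "RHO_EFF_DEFAULT",
    "SolutePair",
    "hard_sphere_radius",
    "gierer_wirtz_factor",
    "diffusion_coefficient",
    "power_law_eval",
]

#: effective hard-sphere packing density, kg/m^3 (fit over 109
#: solute/solvent combinations)
RHO_EFF_DEFAULT = 619.0


def hard_sphere_radius(MW: float, rho_eff: float = RHO_EFF_DEFAULT) -> float:
    """Hard-sphere molecule radius r = (3·MW/(4·pi·rho_eff·NA))^(1/3), m.

    MW in kg/mol.
    """
    if MW <= 0 or rho_eff <= 0:
        raise ValueError("molecular weight and effective density must be positive")
    return (3.0 * MW / (4.0 * math.pi * rho_eff * N_AVOGADRO)) ** (1.0 / 3.0)


def gierer_wirtz_factor(beta: float) -> float:
    """Microfriction correction f_GW = (3·beta/2 + 1/(1+beta))^(-1).

    beta is the solute/solvent radius ratio; f_GW -> 1 for beta -> 0
    (large continuum limit recovered) and 1/2 for equal radii.
    """
    if beta <= 0:
        raise ValueError("radius ratio beta must be positive")
    return 1.0 / (1.5 * beta + 1.0 / (1.0 + beta))


@dataclass(frozen=True)
class SolutePair:
    """Solute/solvent pair for the SEGW diffusion estimate.

    Molecular weights in kg/mol; eta is the solvent dynamic viscosity in
    Pa·s, T the temperature in K. Derived quantities (radii, radius ratio,
    Gierer–Wirtz factor) are exposed as properties.
    """

    MW_solute: float
    MW_solvent: float
    T: float
    eta: float
    rho_eff: float = RHO_EFF_DEFAULT

    def __post_init__(self) -> None:
        for name in ("MW_solute", "MW_solvent", "T", "eta", "rho_eff"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @classmethod
    def from_gmol(
        cls, MW_solute_gmol: float, MW_solvent_gmol: float, T: float, eta: float,
        rho_eff: float = RHO_EFF_DEFAULT,
    ) -> "SolutePair":
        return cls(MW_solute_gmol * 1e-3, MW_solvent_gmol * 1e-3, T, eta, rho_eff)

    @property
    def r_solute(self) -> float:
        return hard_sphere_radius(self.MW_solute, self.rho_eff)

    @property
    def r_solvent(self) -> float:
        return hard_sphere_radius(self.MW_solvent, self.rho_eff)

    @property
    def beta(self) -> float:
        """Radius ratio (MW_solute/MW_solvent)^(1/3)."""
        return (self.MW_solute / self.MW_solvent) ** (1.0 / 3.0)

    @property
    def f_GW(self) -> float:
        return gierer_wirtz_factor(self.beta)


def diffusion_coefficient(pair: SolutePair) -> float:
    """SEGW diffusion coefficient DL = kB·T·f_GW^(-1... ), m^2/s.

    DL = kB·T / (6·pi·eta·r_solute·f_GW) with the Gierer–Wirtz factor
    dividing the Stokes friction; DL is proportional to T and to 1/eta.
    """
    return K_BOLTZMANN * pair.T / (6.0 * math.pi * pair.eta * pair.r_solute * pair.f_GW)


def power_law_eval(K: float, m: float, gamma: float) -> tuple[float, float]:
    """Evaluate the power law at a shear rate.

    Returns ``(tau, eta_eff)`` with tau = K·gamma^m (Pa) and
    eta_eff = K·gamma^(m−1) (Pa·s); tau = eta_eff·gamma holds identically.
    gamma must be > 0: at zero shear rate the apparent viscosity of a
    shear-thinning fluid (m < 1) diverges.
    """
    if K <= 0:
        raise ValueError("consistency index K must be positive")
    if gamma <= 0:
        raise ValueError(
            "shear rate must be strictly positive (eta_eff undefined at "
            "gamma = 0 for m < 1)"
        )
    tau = K * gamma**m
    eta_eff = K * gamma ** (m - 1.0)
    return tau, eta_eff
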