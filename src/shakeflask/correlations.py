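"""Shake-flask operating-point characterization.

Dimensionless groups (Reynolds, film Reynolds, phase number), the modified
Newton number power-input correlation of Büchs et al., the Henzler–Schedel
kLa correlation, the Giese effective-shear-rate correlation, the exponential
out-of-phase correction of the power input, and the fixed-point coupling
that maps a power-law (shear-thinning) fluid onto an equivalent Newtonian
viscosity for a given shaking condition.

The phase number Ph = (d0/d)·(1 + 3·log10(Re_film)) indicates whether the
bulk liquid rotates in phase with the orbital shaking motion. Below a
critical value the liquid collapses to the flask bottom ("out of phase")
and the in-phase power correlation overpredicts; the exponential correction
quotient y(Ph) = 1 − a·exp(−b·Ph) captures the gradual transition.

All public functions take and return strict SI quantities; see
:class:`ShakingConditions.from_lab_units` for the rpm/mm/mL layer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .constants import (
    G_STANDARD,
    celsius_to_kelvin,
    ml_to_m3,
    mm_to_m,
    mpas_to_pas,
    rpm_to_hz,
)

__all__ = [
    "ShakingConditions",
    "Newtonian",
    "PowerLaw",
    "FluidSpec",
    "DimensionlessState",
    "CorrectionModel",
    "RegimeLabel",
    "PHASE_NUMBER_IN_PHASE",
    "PHASE_NUMBER_COLLAPSE",
    "FLASK_250ML_DIAMETER_M",
    "dimensionless_groups",
    "newton_number",
    "power_input_inphase",
    "oophase_quotient",
    "power_input_corrected",
    "classify_regime",
    "kla_correlation",
    "effective_shear_giese",
    "effective_viscosity_fixed_point",
    "fit_correction",
]

#: critical phase number below which first deviations from in-phase
#: behavior appear (power input falls below the in-phase correlation)
PHASE_NUMBER_IN_PHASE = 1.26
#: critical phase number below which the bulk liquid fully collapses
PHASE_NUMBER_COLLAPSE = 0.91

#: nominal largest inner diameter of a 250 mL narrow-neck Erlenmeyer flask.
#: Calibrated so the dimensionless groups reproduce published phase numbers
#: for this flask size; always user-overridable.
FLASK_250ML_DIAMETER_M = 0.0813

FLASK_PRESETS = {"250mL": FLASK_250ML_DIAMETER_M}


class DomainError(ValueError):
    """An input lies outside the physical/mathematical domain of a model."""


@dataclass(frozen=True)
class ShakingConditions:
    """Geometric and kinematic operating point of one shake-flask run.

    Parameters
    ----------
    n : float
        Shaking frequency, 1/s.
    d : float
        Largest inner flask diameter, m.
    d0 : float
        Shaking (orbit) diameter, m.
    VL : float
        Filling volume, m^3.
    T : float
        Temperature, K.
    g : float
        Gravitational acceleration, m/s^2.
    """

    n: float
    d: float
    d0: float
    VL: float
    T: float = 293.15
    g: float = G_STANDARD

    def __post_init__(self) -> None:
        for name in ("n", "d", "d0", "VL", "T", "g"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be strictly positive")
        if self.fill_ratio_sq > 1.0:
            raise DomainError(
                "filling volume too large for flask diameter: "
                "(4/pi)*(VL^(1/3)/d)^2 must be <= 1"
            )

    @property
    def fill_ratio_sq(self) -> float:
        """(4/pi)·(VL^(1/3)/d)^2, the argument of the film-Reynolds root."""
        return (4.0 / math.pi) * (self.VL ** (1.0 / 3.0) / self.d) ** 2

    @classmethod
    def from_lab_units(
        cls,
        n_rpm: float,
        d_mm: float,
        d0_mm: float,
        VL_mL: float,
        T_C: float = 20.0,
        g: float = G_STANDARD,
    ) -> "ShakingConditions":
        """Construct from the units shake-flask tables are printed in."""
        return cls(
            n=rpm_to_hz(n_rpm),
            d=mm_to_m(d_mm),
            d0=mm_to_m(d0_mm),
            VL=ml_to_m3(VL_mL),
            T=celsius_to_kelvin(T_C),
            g=g,
        )


@dataclass(frozen=True)
class Newtonian:
    """Constant-viscosity rheology. eta in Pa·s."""

    eta: float

    def __post_init__(self) -> None:
        if not self.eta > 0:
            raise DomainError("eta must be strictly positive")


@dataclass(frozen=True)
class PowerLaw:
    """Ostwald–de Waele rheology tau = K·gamma^m.

    K : flow consistency index, Pa·s^m; m : flow behavior index (m < 1 is
    shear-thinning, m = 1 Newtonian).
    """

    K: float
    m: float

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise DomainError("K must be strictly positive")
        if not 0 < self.m <= 1.5:
            raise DomainError("flow behavior index m must lie in (0, 1.5]")


@dataclass(frozen=True)
class FluidSpec:
    """Fluid density plus rheology; surface tension / contact angle are
    carried as provenance only and enter no computation here."""

    rho: float
    rheology: Newtonian | PowerLaw
    sigma: float | None = None  # N/m, provenance
    theta: float | None = None  # deg, provenance

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise DomainError("rho must be strictly positive")

    @property
    def eta(self) -> float:
        """Newtonian dynamic viscosity, Pa·s (raises for power-law)."""
        if isinstance(self.rheology, Newtonian):
            return self.rheology.eta
        raise DomainError(
            "power-law fluid has no single viscosity; resolve an effective "
            "viscosity first (effective_viscosity_fixed_point)"
        )

    @property
    def nu(self) -> float:
        """Kinematic viscosity eta/rho, m^2/s."""
        return self.eta / self.rho


@dataclass(frozen=True)
class DimensionlessState:
    """Dimensionless groups of one operating point."""

    Re: float
    Re_film: float
    Ph: float
    Ne_prime: float | None = None


@dataclass(frozen=True)
class CorrectionModel:
    """Exponential out-of-phase correction y(Ph) = 1 − a·exp(−b·Ph).

    y is the quotient of the true (CFD-derived) volumetric power input and
    the in-phase correlation; it approaches 1 at large phase numbers.
    Defaults are the published fit constants.
    """

    a: float = 3.43
    b: float = 2.02

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise DomainError("correction constants a, b must be positive")

    @property
    def valid_from(self) -> float:
        """Lowest phase number with a nonnegative quotient, ln(a)/b."""
        return math.log(self.a) / self.b


@dataclass(frozen=True)
class RegimeLabel:
    label: Literal["in_phase", "transition", "out_of_phase"]
    thresholds: tuple[float, float] = (PHASE_NUMBER_IN_PHASE, PHASE_NUMBER_COLLAPSE)


def dimensionless_groups(cond: ShakingConditions, fluid: FluidSpec) -> DimensionlessState:
    """Reynolds number, film Reynolds number and phase number.

    Re       = rho·n·d^2 / eta
    Re_film  = Re·(pi/2)·[1 − sqrt(1 − (4/pi)·(VL^(1/3)/d)^2)]^2
    Ph       = (d0/d)·(1 + 3·log10(Re_film))

    The film Reynolds number rescales Re with the geometry of the liquid
    film the rotating bulk leaves on the flask wall.
    """
    eta = fluid.eta
    Re = fluid.rho * cond.n * cond.d**2 / eta
    arg = 1.0 - cond.fill_ratio_sq
    if arg < 0:
        raise DomainError("film Reynolds number undefined: filling volume too large")
    Re_film = Re * (math.pi / 2.0) * (1.0 - math.sqrt(arg)) ** 2
    if Re_film <= 0:
        raise DomainError("Re_film must be positive for the phase number (log10)")
    Ph = (cond.d0 / cond.d) * (1.0 + 3.0 * math.log10(Re_film))
    return DimensionlessState(Re=Re, Re_film=Re_film, Ph=Ph)


def newton_number(Re: float) -> float:
    """Modified Newton number Ne' = 70/Re + 25·Re^−0.6 + 1.5·Re^−0.2.

    In-phase power correlation for 100–2000 mL shake flasks; strictly
    decreasing in Re.
    """
    Re = np.asarray(Re, dtype=float) if np.ndim(Re) else float(Re)
    if np.any(np.asarray(Re) <= 0):
        raise DomainError("Reynolds number must be strictly positive")
    return 70.0 * Re**-1.0 + 25.0 * Re**-0.6 + 1.5 * Re**-0.2


def power_input_inphase(cond: ShakingConditions, fluid: FluidSpec) -> float:
    """In-phase volumetric power input P/VL = Ne'(Re)·rho·n^3·d^4·VL^(−2/3), W/m^3.

    Follows from the modified Newton number definition
    Ne' = P / (rho·n^3·d^4·VL^(1/3)).
    """
    state = dimensionless_groups(cond, fluid)
    ne = newton_number(state.Re)
    return ne * fluid.rho * cond.n**3 * cond.d**4 * cond.VL ** (-2.0 / 3.0)


def oophase_quotient(
    Ph: float, model: CorrectionModel = CorrectionModel()
) -> tuple[float, float, bool]:
    """Out-of-phase power-input quotient y = 1 − a·exp(−b·Ph).

    Returns ``(raw, clamped, extrapolated)``: the raw quotient, the variant
    clamped at zero, and a flag set when the raw quotient is negative (i.e.
    Ph below ln(a)/b, outside the fitted data cloud).
    """
    if not Ph > 0:
        raise DomainError("phase number must be strictly positive")
    raw = 1.0 - model.a * math.exp(-model.b * Ph)
    clamped = max(raw, 0.0)
    return raw, clamped, raw < 0.0


@dataclass(frozen=True)
class CorrectedPowerReport:
    """Power input with the out-of-phase correction applied."""

    P_per_V_raw: float  # in-phase correlation, W/m^3
    P_per_V_corrected: float  # after multiplying by the clamped quotient
    quotient_raw: float
    quotient_clamped: float
    Ph: float
    regime: RegimeLabel
    extrapolated: bool  # quotient evaluated below its validity limit


def power_input_corrected(
    cond: ShakingConditions,
    fluid: FluidSpec,
    model: CorrectionModel = CorrectionModel(),
) -> CorrectedPowerReport:
    """In-phase power input multiplied by the clamped out-of-phase quotient."""
    state = dimensionless_groups(cond, fluid)
    p_raw = power_input_inphase(cond, fluid)
    q_raw, q_clamped, extrap = oophase_quotient(state.Ph, model)
    if extrap:
        warnings.warn(
            f"phase number {state.Ph:.3f} below correction validity limit "
            f"{model.valid_from:.3f}; corrected power input clamped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    return CorrectedPowerReport(
        P_per_V_raw=p_raw,
        P_per_V_corrected=p_raw * q_clamped,
        quotient_raw=q_raw,
        quotient_clamped=q_clamped,
        Ph=state.Ph,
        regime=classify_regime(state.Ph),
        extrapolated=extrap,
    )


def classify_regime(Ph: float) -> RegimeLabel:
    """Classify an operating point by its phase number.

    in_phase for Ph >= 1.26, transition for 0.91 <= Ph < 1.26,
    out_of_phase for Ph < 0.91 (lower threshold inclusive upward).
    """
    if not Ph > 0:
        raise DomainError("phase number must be strictly positive")
    if Ph >= PHASE_NUMBER_IN_PHASE:
        label = "in_phase"
    elif Ph >= PHASE_NUMBER_COLLAPSE:
        label = "transition"
    else:
        label = "out_of_phase"
    return RegimeLabel(label=label)


def kla_correlation(cond: ShakingConditions, fluid: FluidSpec, DL: float) -> float:
    """Henzler–Schedel shake-flask kLa correlation, 1/s.

    kLa = 0.5 · d^(73/36) · n · d0^(1/4) · VL^(−8/9) · nu^(−13/54)
              · g^(−7/54) · DL^(1/2)

    The exponent set is dimensionless overall, so any consistent unit
    system gives the same 1/s value.
    """
    if not DL > 0:
        raise DomainError("diffusion coefficient must be strictly positive")
    nu = fluid.nu
    return (
        0.5
        * cond.d ** (73.0 / 36.0)
        * cond.n
        * cond.d0 ** (1.0 / 4.0)
        * cond.VL ** (-8.0 / 9.0)
        * nu ** (-13.0 / 54.0)
        * cond.g ** (-7.0 / 54.0)
        * DL**0.5
    )


def effective_shear_giese(
    P_per_V: float, K: float, m: float, VL: float, d: float
) -> float:
    """Giese effective shear rate for shaken power-law fluids, 1/s.

    gamma = [2.06 · (P/VL)/K · (VL^(1/3)/d)^(−0.33)]^(1/(m+1))
    """
    if min(P_per_V, K, VL, d) <= 0:
        raise DomainError("all inputs must be strictly positive")
    if not 0 < m <= 1.5:
        raise DomainError("flow behavior index m must lie in (0, 1.5]")
    base = 2.06 * P_per_V / K * (VL ** (1.0 / 3.0) / d) ** (-0.33)
    return base ** (1.0 / (m + 1.0))


@dataclass(frozen=True)
class FixedPointResult:
    gamma_eff: float  # 1/s
    eta_eff: float  # Pa·s
    P_per_V: float  # W/m^3 (the value used in the last Giese evaluation)
    Ph: float
    iterations: int
    converged: bool


def effective_viscosity_fixed_point(
    cond: ShakingConditions,
    fluid: FluidSpec,
    use_correction: bool = False,
    model: CorrectionModel = CorrectionModel(),
    eta0: float | None = None,
    rtol: float = 1e-10,
    max_iter: int = 500,
) -> FixedPointResult:
    """Equivalent Newtonian viscosity of a power-law fluid at one condition.

    Iterates the loop eta -> Re -> Ne' -> P/VL (optionally corrected by the
    out-of-phase quotient) -> gamma (Giese) -> eta = K·gamma^(m−1) to a
    relative change below ``rtol``. For m = 1 the loop is exact after one
    step (eta = K). If the iterate oscillates, under-relaxation with factor
    0.5 is engaged; the contraction is mild as m -> 1 but monotone in
    practice.

    Raises on non-convergence with the last iterate in the message.
    """
    rheo = fluid.rheology
    if not isinstance(rheo, PowerLaw):
        raise DomainError("effective_viscosity_fixed_point requires power-law rheology")
    K, m = rheo.K, rheo.m

    eta = float(eta0) if eta0 is not None else K
    prev_delta = 0.0
    gamma = float("nan")
    p_used = float("nan")
    Ph = float("nan")
    for it in range(1, max_iter + 1):
        newton_fluid = FluidSpec(rho=fluid.rho, rheology=Newtonian(eta))
        state = dimensionless_groups(cond, newton_fluid)
        Ph = state.Ph
        p = power_input_inphase(cond, newton_fluid)
        if use_correction:
            _, q_clamped, _ = oophase_quotient(Ph, model)
            p = p * q_clamped
            if p <= 0:
                raise DomainError(
                    "corrected power input clamped to zero inside the fixed "
                    f"point (Ph={Ph:.3f} below validity limit); use the "
                    "uncorrected loop for this condition"
                )
        gamma = effective_shear_giese(p, K, m, cond.VL, cond.d)
        eta_new = K * gamma ** (m - 1.0)
        p_used = p
        delta = eta_new - eta
        if abs(delta) <= rtol * abs(eta_new):
            return FixedPointResult(
                gamma_eff=gamma, eta_eff=eta_new, P_per_V=p_used, Ph=Ph,
                iterations=it, converged=True,
            )
        # damp only when the update direction flips (oscillating iterate)
        if prev_delta * delta < 0:
            eta_new = eta + 0.5 * delta
        prev_delta = delta
        eta = eta_new
    raise RuntimeError(
        f"effective-viscosity fixed point did not converge in {max_iter} "
        f"iterations; last iterate eta={eta:.6g} Pa·s, gamma={gamma:.6g} 1/s"
    )


@dataclass(frozen=True)
class CorrectionFit:
    model: CorrectionModel
    residual_norm: float
    n_points: int
    identifiable: bool = True


def fit_correction(points: Sequence[tuple[float, float]]) -> CorrectionFit:
    """Least-squares fit of (a, b) in y = 1 − a·exp(−b·Ph).

    ``points`` are (Ph, quotient) pairs, the quotient being measured/CFD
    power input divided by the in-phase correlation. Needs at least three
    points with distinct Ph. Degenerate data with all quotients ~= 1 is
    reported with ``identifiable=False`` (b is unconstrained when a ~= 0).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (Ph, quotient) pairs")
    ph, y = pts[:, 0], pts[:, 1]
    if len(np.unique(ph)) < 3:
        raise ValueError("need at least 3 distinct phase numbers")

    if np.max(np.abs(y - 1.0)) < 1e-12:
        return CorrectionFit(
            model=CorrectionModel(a=1e-300, b=1.0),
            residual_norm=0.0, n_points=len(ph), identifiable=False,
        )

    def resid(p: np.ndarray) -> np.ndarray:
        a, b = p
        return 1.0 - a * np.exp(-b * ph) - y

    # log-linear seed from 1 - y = a·exp(-b·Ph) on points with 1 - y > 0
    mask = (1.0 - y) > 1e-12
    if mask.sum() >= 2:
        slope, intercept = np.polyfit(ph[mask], np.log(1.0 - y[mask]), 1)
        p0 = np.array([math.exp(intercept), -slope])
        p0 = np.clip(p0, 1e-6, None)
    else:
        p0 = np.array([1.0, 1.0])
    sol = least_squares(resid, p0, bounds=([1e-12, 1e-12], [np.inf, np.inf]))
    a_hat, b_hat = sol.x
    res_norm = float(np.linalg.norm(sol.fun))
    return CorrectionFit(
        model=CorrectionModel(a=float(a_hat), b=float(b_hat)),
        residual_norm=res_norm,
        n_points=len(ph),
    )
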