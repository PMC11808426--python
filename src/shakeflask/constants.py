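"""Physical constants (CODATA 2018, exact by SI definition) and unit helpers.

All internal computation is in strict SI. Lab-friendly units (rpm, mm, mL,
mPa·s, °C, g/mol) are converted once at the interface layer; the converters
live here so every module agrees on the factors.
"""

# Boltzmann and Avogadro constants, exact since the 2019 SI redefinition
K_BOLTZMANN = 1.380649e-23  # J/K
N_AVOGADRO = 6.02214076e23  # 1/mol

#: standard gravitational acceleration, m/s^2
G_STANDARD = 9.81

#: turbulence-model closure constant (k-omega SST), dimensionless
BETA_STAR = 0.09


def rpm_to_hz(n_rpm: float) -> float:
    """Shaking frequency: revolutions per minute -> 1/s."""
    return n_rpm / 60.0


def mm_to_m(x_mm: float) -> float:
    return x_mm * 1e-3


def ml_to_m3(v_ml: float) -> float:
    return v_ml * 1e-6


def mpas_to_pas(eta_mpas: float) -> float:
    return eta_mpas * 1e-3


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


def gmol_to_kgmol(mw_gmol: float) -> float:
    return mw_gmol * 1e-3
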