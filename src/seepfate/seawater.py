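"""Physical properties of seawater.

Standard one-atmosphere correlations used by the bubble and transport
stages: density (EOS-80 surface polynomial), dynamic viscosity and
surface tension (Sharqawy-type fits), and hydrostatic pressure.

All temperatures in degrees Celsius, salinities in ppt (g/kg), SI
outputs.
"""

from __future__ import annotations

import numpy as np

GRAVITY = 9.81  # m/s^2
P_ATM = 101_325.0  # Pa
R_GAS = 8.314462618  # J/(mol K)

T_MIN, T_MAX = -2.0, 40.0
S_MIN, S_MAX = 0.0, 42.0


def _check_ts(T, S):
    T = np.asarray(T, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(T < T_MIN) or np.any(T > T_MAX):
        raise ValueError(f"temperature out of range [{T_MIN}, {T_MAX}] degC")
    if np.any(S < S_MIN) or np.any(S > S_MAX):
        raise ValueError(f"salinity out of range [{S_MIN}, {S_MAX}] ppt")
    return T, S


def density(T, S):
    """Seawater density (kg/m^3) at one atmosphere, EOS-80 polynomial."""
    T, S = _check_ts(T, S)
    rho_w = (999.842594 + 6.793952e-2 * T - 9.095290e-3 * T**2
             + 1.001685e-4 * T**3 - 1.120083e-6 * T**4 + 6.536332e-9 * T**5)
    A = (0.824493 - 4.0899e-3 * T + 7.6438e-5 * T**2
         - 8.2467e-7 * T**3 + 5.3875e-9 * T**4)
    B = -5.72466e-3 + 1.0227e-4 * T - 1.6546e-6 * T**2
    C = 4.8314e-4
    return rho_w + A * S + B * S**1.5 + C * S**2


def viscosity(T, S):
    """Dynamic viscosity of seawater (Pa s)."""
    T, S = _check_ts(T, S)
    mu_w = 4.2844e-5 + 1.0 / (0.157 * (T + 64.993) ** 2 - 91.296)
    s = S / 1000.0  # kg/kg
    A = 1.541 + 1.998e-2 * T - 9.52e-5 * T**2
    B = 7.974 - 7.561e-2 * T + 4.724e-4 * T**2
    return mu_w * (1.0 + A * s + B * s**2)


def surface_tension(T, S):
    """Air-seawater surface tension (N/m).

    IAPWS pure-water value with a salinity enhancement factor.
    """
    T, S = _check_ts(T, S)
    tau = 1.0 - (T + 273.15) / 647.096
    sigma_w = 0.2358 * tau**1.256 * (1.0 - 0.625 * tau)
    return sigma_w * (1.0 + (2.26e-4 * T + 9.46e-3) * np.log1p(0.0331 * S))


def pressure(depth, T=7.0, S=34.0):
    """Absolute pressure (Pa) at depth (m), hydrostatic with constant density."""
    depth = np.asarray(depth, dtype=float)
    if np.any(depth < 0):
        raise ValueError("depth must be non-negative")
    return P_ATM + density(T, S) * GRAVITY * depth
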