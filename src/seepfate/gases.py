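"""Gas-phase thermodynamics and gas solubility in seawater.

Covers the three gases exchanged by a rising seep bubble: methane
leaving the bubble, and nitrogen/oxygen entering it from the ambient
water.  Real-gas molar volume and density come from the Peng-Robinson
cubic equation of state with a Peneloux volume-translation correction;
dissolved-phase equilibrium concentrations come from temperature-
dependent Henry constants with a Setschenow salting-out factor, with
the fugacity of each component approximated by its partial pressure
(fugacity coefficients are within a couple of percent of unity at
shelf depths).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seawater import R_GAS, density as sw_density, viscosity as sw_viscosity, _check_ts

T_REF_K = 298.15
_NACL_MOLAR_MASS = 58.44  # g/mol, sea salt treated as NaCl for ionic strength


@dataclass(frozen=True)
class GasComponent:
    """Pure-component constants for a bubble gas.

    henry_ref : Henry solubility Hcp at 298.15 K, mol/(m^3 Pa)
    vant_hoff : -d(ln Hcp)/d(1/T), K
    setschenow : salting-out coefficient, log10 basis, L/mol
    diff_ref : molecular diffusivity in water at 25 degC, m^2/s
    """

    name: str
    molar_mass: float       # kg/mol
    t_crit: float           # K
    p_crit: float           # Pa
    acentric: float
    henry_ref: float
    vant_hoff: float
    setschenow: float
    diff_ref: float

    def __post_init__(self):
        for field in ("molar_mass", "t_crit", "p_crit", "henry_ref",
                      "vant_hoff", "setschenow", "diff_ref"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{self.name}: {field} must be positive")


CH4 = GasComponent("CH4", 16.043e-3, 190.56, 4.599e6, 0.0115,
                   henry_ref=1.4e-5, vant_hoff=1750.0, setschenow=0.13,
                   diff_ref=1.85e-9)
N2 = GasComponent("N2", 28.014e-3, 126.20, 3.394e6, 0.0372,
                  henry_ref=6.4e-6, vant_hoff=1300.0, setschenow=0.10,
                  diff_ref=2.0e-9)
O2 = GasComponent("O2", 31.999e-3, 154.58, 5.043e6, 0.0222,
                  henry_ref=1.2e-5, vant_hoff=1700.0, setschenow=0.141,
                  diff_ref=2.1e-9)

COMPONENTS = (CH4, N2, O2)
_BY_NAME = {c.name: c for c in COMPONENTS}


def component(name: str) -> GasComponent:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise ValueError(f"unknown gas component {name!r}; "
                         f"known: {sorted(_BY_NAME)}") from None


# ---------------------------------------------------------------------------
# Peng-Robinson equation of state
# ---------------------------------------------------------------------------

def _pr_mixture_params(x, T, components):
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) != len(components):
        raise ValueError("composition and component list must align")
    if np.any(x < 0) or not np.isclose(x.sum(), 1.0, atol=1e-9):
        raise ValueError("mole fractions must be non-negative and sum to 1")
    a = np.empty(len(components))
    b = np.empty(len(components))
    for i, c in enumerate(components):
        kappa = 0.37464 + 1.54226 * c.acentric - 0.26992 * c.acentric**2
        tr = T / c.t_crit
        alpha = (1.0 + kappa * (1.0 - np.sqrt(tr))) ** 2
        a[i] = 0.45724 * (R_GAS * c.t_crit) ** 2 / c.p_crit * alpha
        b[i] = 0.07780 * R_GAS * c.t_crit / c.p_crit
    # van der Waals mixing, zero binary interaction parameters
    a_mix = float(np.dot(x, np.sqrt(a))) ** 2
    b_mix = float(np.dot(x, b))
    return a_mix, b_mix


def _volume_translation(x, components):
    """Peneloux shift c (m^3/mol) from the Rackett compressibility."""
    x = np.asarray(x, dtype=float)
    c = 0.0
    for xi, comp in zip(x, components):
        z_ra = 0.29056 - 0.08775 * comp.acentric
        c += xi * 0.40768 * R_GAS * comp.t_crit / comp.p_crit * (0.29441 - z_ra)
    return c


def compressibility(x, T_K, P, components=COMPONENTS):
    """Vapor-phase compressibility factor Z from the Peng-Robinson cubic."""
    if T_K <= 0 or P <= 0:
        raise ValueError("temperature and pressure must be positive")
    a_mix, b_mix = _pr_mixture_params(x, T_K, components)
    A = a_mix * P / (R_GAS * T_K) ** 2
    B = b_mix * P / (R_GAS * T_K)
    coeffs = [1.0, -(1.0 - B), A - 3.0 * B**2 - 2.0 * B, -(A * B - B**2 - B**3)]
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-10].real
    real = real[real > B]
    if len(real) == 0:
        raise ArithmeticError("no physical vapor root of the cubic EoS")
    return float(real.max())  # largest real root: vapor branch


def molar_volume(x, T_K, P, components=COMPONENTS, volume_translation=True):
    """Mixture molar volume (m^3/mol) of the gas phase."""
    Z = compressibility(x, T_K, P, components)
    v = Z * R_GAS * T_K / P
    if volume_translation:
        v -= _volume_translation(x, components)
    return v


def gas_density(x, T_K, P, components=COMPONENTS, volume_translation=True):
    """Gas-mixture mass density (kg/m^3)."""
    x = np.asarray(x, dtype=float)
    M = float(np.dot(x, [c.molar_mass for c in components]))
    return M / molar_volume(x, T_K, P, components, volume_translation)


# ---------------------------------------------------------------------------
# Solubility
# ---------------------------------------------------------------------------

def henry_constant(comp: GasComponent, T, S):
    """Effective Henry solubility Hcp (mol/(m^3 Pa)) in seawater."""
    T, S = _check_ts(T, S)
    T_K = T + 273.15
    h_fresh = comp.henry_ref * np.exp(comp.vant_hoff * (1.0 / T_K - 1.0 / T_REF_K))
    # molarity of sea salt, NaCl-equivalent
    c_salt = S * sw_density(T, S) / 1000.0 / _NACL_MOLAR_MASS  # mol/L
    return h_fresh * 10.0 ** (-comp.setschenow * c_salt)


def solubility(comp: GasComponent | str, T, S, partial_pressure):
    """Equilibrium dissolved concentration (kg/m^3) at a partial pressure (Pa).

    Modified Henry's law: linear in the component's partial pressure
    (fugacity ~ partial pressure), decreasing with salinity through the
    Setschenow factor.
    """
    if isinstance(comp, str):
        comp = component(comp)
    pp = np.asarray(partial_pressure, dtype=float)
    if np.any(pp < 0):
        raise ValueError("partial pressure must be non-negative")
    return henry_constant(comp, T, S) * pp * comp.molar_mass


def diffusivity(comp: GasComponent | str, T, S):
    """Molecular diffusivity in seawater (m^2/s).

    Stokes-Einstein scaling (D mu / T constant) of a 25 degC reference.
    """
    if isinstance(comp, str):
        comp = component(comp)
    T, S = _check_ts(T, S)
    scale = ((T + 273.15) / T_REF_K) * (sw_viscosity(25.0, S) / sw_viscosity(T, S))
    return comp.diff_ref * scale
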