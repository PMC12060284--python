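"""Single-bubble rise, gas exchange and the methane deposition profile.

A pure-methane bubble released at the seabed dissolves as it rises
while ambient nitrogen and oxygen diffuse in; the output is the
fraction of the released methane dissolved per metre of water column
(the initial condition for the dissolved-phase transport model) and
the fraction carried directly to the surface inside the bubble.

Correlations are for clean (surfactant-free) bubbles: shape from
Eotvos-number thresholds, rise velocity from the Fan-Tsuchiya unified
equation (Davies-Taylor for spherical caps), and a Johnson-type
mass-transfer coefficient in the ellipsoidal regime.  Hydrate shells
are ignored: releases are restricted to depths and temperatures
outside the hydrate stability zone.  The bubble is assumed thermally
equilibrated with the ambient water at all times (millimetre bubbles
equilibrate in seconds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import gases, seawater
from .environment import equilibrium_dissolved_gases
from .gases import COMPONENTS
from .seawater import GRAVITY, P_ATM

#: shape-regime Eotvos thresholds (Clift-style diagram, seawater bubbles)
EO_SPHERICAL = 0.25
EO_SPHERICAL_CAP = 40.0

#: Fan-Tsuchiya constants for clean bubbles in aqueous solutions
FT_C = 1.4
FT_KB0 = 14.7
FT_N = 1.6

#: maximum admissible relative velocity jump across a regime boundary
REGIME_CONTINUITY_TOL = 0.10

CLOSURE_TOL = 1e-9


@dataclass(frozen=True)
class FluidProperties:
    rho: float    # kg/m^3
    mu: float     # Pa s
    sigma: float  # N/m


def fluid_properties(T: float, S: float) -> FluidProperties:
    return FluidProperties(rho=float(seawater.density(T, S)),
                           mu=float(seawater.viscosity(T, S)),
                           sigma=float(seawater.surface_tension(T, S)))


# ---------------------------------------------------------------------------
# Shape, velocity, transfer correlations
# ---------------------------------------------------------------------------

def eotvos(diameter: float, fluid: FluidProperties, rho_gas: float = 1.0) -> float:
    return GRAVITY * (fluid.rho - rho_gas) * diameter**2 / fluid.sigma


def morton(fluid: FluidProperties, rho_gas: float = 1.0) -> float:
    return (GRAVITY * fluid.mu**4 * (fluid.rho - rho_gas)
            / (fluid.rho**2 * fluid.sigma**3))


def shape_regime(diameter: float, fluid: FluidProperties,
                 rho_gas: float = 1.0) -> str:
    """Classify a bubble as spherical, ellipsoidal or spherical-cap."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    eo = eotvos(diameter, fluid, rho_gas)
    if eo < EO_SPHERICAL:
        return "spherical"
    if eo > EO_SPHERICAL_CAP:
        return "spherical-cap"
    return "ellipsoidal"


def rise_velocity(diameter: float, fluid: FluidProperties,
                  rho_gas: float = 1.0, regime: str | None = None) -> float:
    """Terminal rise velocity (m/s) of a clean bubble.

    Spherical and ellipsoidal bubbles follow the Fan-Tsuchiya unified
    equation, whose small-diameter limit is the buoyancy-viscous
    closed form u = g (rho - rho_g) d^2 / (K_b mu); spherical caps
    follow Davies-Taylor.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    regime = regime or shape_regime(diameter, fluid, rho_gas)
    drho = fluid.rho - rho_gas
    if regime == "spherical-cap":
        return 0.711 * math.sqrt(GRAVITY * diameter * drho / fluid.rho)
    mo = morton(fluid, rho_gas)
    kb = max(12.0, FT_KB0 * mo ** (-0.038))
    u_visc = GRAVITY * drho * diameter**2 / (kb * fluid.mu)
    u_wave2 = (2.0 * FT_C * fluid.sigma / (fluid.rho * diameter)
               + GRAVITY * diameter * drho / (2.0 * fluid.rho))
    return (u_visc ** (-FT_N) + u_wave2 ** (-FT_N / 2.0)) ** (-1.0 / FT_N)


def viscous_limit_velocity(diameter: float, fluid: FluidProperties,
                           rho_gas: float = 1.0) -> float:
    """Analytic buoyancy-viscous closed form, the d -> 0 limit of the
    rise-velocity correlation."""
    mo = morton(fluid, rho_gas)
    kb = max(12.0, FT_KB0 * mo ** (-0.038))
    return GRAVITY * (fluid.rho - rho_gas) * diameter**2 / (kb * fluid.mu)


def mass_transfer_coeff(diameter: float, regime: str, velocity: float,
                        diffusivity: float) -> float:
    """Bubble-water mass transfer coefficient (m/s), clean surface.

    Ellipsoidal bubbles use a Johnson-type correlation; spherical and
    spherical-cap bubbles a potential-flow (Boussinesq) form with the
    Sh = 2 diffusive floor.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if velocity < 0 or diffusivity < 0:
        raise ValueError("velocity and diffusivity must be non-negative")
    if regime == "ellipsoidal":
        return 1.13 * math.sqrt(velocity * diffusivity
                                / (0.0045 + 0.2 * diameter))
    return (2.0 / math.sqrt(math.pi)) * math.sqrt(diffusivity * velocity / diameter) \
        + 2.0 * diffusivity / diameter


# ---------------------------------------------------------------------------
# Ambient profile
# ---------------------------------------------------------------------------

@dataclass
class AmbientProfile:
    """Column of ambient water the bubble rises through.

    dissolved holds background concentrations (kg/m^3) per gas;
    methane defaults to zero, nitrogen and oxygen to atmospheric
    equilibrium (evaluated at surface pressure, uniform over depth).
    """

    depth: np.ndarray
    T: np.ndarray
    S: np.ndarray
    dissolved: dict = field(default_factory=dict)

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if np.any(np.diff(self.depth) <= 0):
            raise ValueError("profile depths must be strictly increasing")
        if not self.dissolved:
            eq = equilibrium_dissolved_gases(self.T, self.S)
            self.dissolved = {"CH4": np.zeros_like(self.depth),
                              "N2": np.asarray(eq["N2"], dtype=float),
                              "O2": np.asarray(eq["O2"], dtype=float)}

    @classmethod
    def uniform(cls, station_depth: float, T: float = 7.0, S: float = 34.0,
                n: int = 8) -> "AmbientProfile":
        z = np.linspace(0.0, station_depth, n)
        return cls(depth=z, T=np.full(n, T), S=np.full(n, S))

    @classmethod
    def from_scenario(cls, scenario, day: float) -> "AmbientProfile":
        prof = scenario.profile_at(day)
        return cls(depth=prof["depth"].to_numpy(),
                   T=prof["T"].to_numpy(), S=prof["S"].to_numpy())

    def temperature(self, z: float) -> float:
        return float(np.interp(z, self.depth, self.T))

    def salinity(self, z: float) -> float:
        return float(np.interp(z, self.depth, self.S))

    def concentration(self, name: str, z: float) -> float:
        return float(np.interp(z, self.depth, self.dissolved[name]))

    def pressure(self, z: float) -> float:
        return P_ATM + float(seawater.density(self.temperature(z),
                                              self.salinity(z))) * GRAVITY * z


# ---------------------------------------------------------------------------
# Deposition profile
# ---------------------------------------------------------------------------

@dataclass
class DepositionProfile:
    """Fraction of released methane dissolved per depth cell, plus the
    fraction surfacing inside the bubble.  Fractions sum to one."""

    cell_edges: np.ndarray   # length n+1, starting at the surface (0 m)
    fractions: np.ndarray    # length n
    surfaced: float

    def __post_init__(self):
        self.cell_edges = np.asarray(self.cell_edges, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.surfaced = float(self.surfaced)
        if len(self.fractions) != len(self.cell_edges) - 1:
            raise ValueError("need one fraction per cell")
        if np.any(self.fractions < -CLOSURE_TOL) or self.surfaced < -CLOSURE_TOL:
            raise ValueError("fractions must be non-negative")
        total = float(self.fractions.sum()) + self.surfaced
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"fractions + surfaced = {total}, expected 1")

    @property
    def dissolved_total(self) -> float:
        return float(self.fractions.sum())

    def regrid(self, edges) -> "DepositionProfile":
        """Conservatively rebin onto new cell edges (must span the old)."""
        edges = np.asarray(edges, dtype=float)
        cum_old = np.concatenate([[0.0], np.cumsum(self.fractions)])
        cum_new = np.interp(edges, self.cell_edges, cum_old,
                            left=0.0, right=cum_old[-1])
        return DepositionProfile(edges, np.diff(cum_new), self.surfaced)

    def to_csv(self, path):
        with open(path, "w") as fh:
            fh.write(f"# surfaced_fraction = {self.surfaced!r}\n")
            pd.DataFrame({
                "cell_top_m": self.cell_edges[:-1],
                "cell_bottom_m": self.cell_edges[1:],
                "fraction": self.fractions,
            }).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "DepositionProfile":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# surfaced_fraction"):
                raise ValueError("missing surfaced_fraction header line")
            surfaced = float(header.split("=")[1])
            frame = pd.read_csv(fh)
        edges = np.concatenate([frame["cell_top_m"].to_numpy(),
                                [frame["cell_bottom_m"].iloc[-1]]])
        return cls(edges, frame["fraction"].to_numpy(), surfaced)


# ---------------------------------------------------------------------------
# Bubble integration
# ---------------------------------------------------------------------------

@dataclass
class BubbleResult:
    trajectory: pd.DataFrame
    deposition: DepositionProfile
    surfaced_composition: dict
    terminated_at: float          # depth (m) where integration stopped

    def trajectory_to_csv(self, path):
        self.trajectory.to_csv(path, index=False)


class BubbleIntegrationError(RuntimeError):
    pass


def _bubble_state(n, z, profile, comps):
    """Derived quantities (x, d, u, regime, fluid, T, P) from moles at depth."""
    n = np.clip(n, 0.0, None)
    n_tot = n.sum()
    x = n / n_tot
    T = profile.temperature(z)
    S = profile.salinity(z)
    P = profile.pressure(z)
    T_K = T + 273.15
    vm = gases.molar_volume(x, T_K, P, comps)
    d = (6.0 * n_tot * vm / math.pi) ** (1.0 / 3.0)
    rho_gas = float(np.dot(x, [c.molar_mass for c in comps])) / vm
    fluid = fluid_properties(T, S)
    regime = shape_regime(d, fluid, rho_gas)
    u = rise_velocity(d, fluid, rho_gas, regime)
    return x, d, u, regime, fluid, rho_gas, T, S, P


def integrate_bubble(profile: AmbientProfile, release_depth: float,
                     d0: float = 4.5e-3, cell_edges=None,
                     mass_transfer_scale: float = 1.0,
                     diameter_floor: float = 5e-5,
                     rtol: float = 1e-10, traj_step: float = 0.5
                     ) -> BubbleResult:
    """Integrate a pure-methane bubble from the seabed to the surface.

    Returns the trajectory, the per-cell deposition profile (binned on
    cell_edges, default 1 m cells) and the directly surfaced fraction.
    Mole balance is closed exactly by construction: released methane
    equals binned dissolved methane plus surfaced methane.
    """
    if release_depth <= 0 or d0 <= 0:
        raise ValueError("release depth and initial diameter must be positive")
    comps = COMPONENTS
    names = [c.name for c in comps]
    T0 = profile.temperature(release_depth)
    P0 = profile.pressure(release_depth)
    x0 = np.array([1.0, 0.0, 0.0])
    vm0 = gases.molar_volume(x0, T0 + 273.15, P0, comps)
    n_ch4_0 = (math.pi / 6.0) * d0**3 / vm0
    y0 = np.array([n_ch4_0, 0.0, 0.0])

    def rhs(z, y):
        x, d, u, regime, fluid, rho_gas, T, S, P = _bubble_state(y, z, profile, comps)
        dndz = np.empty(3)
        for i, comp in enumerate(comps):
            D = float(gases.diffusivity(comp, T, S))
            k = mass_transfer_coeff(d, regime, u, D) * mass_transfer_scale
            c_surf = float(gases.henry_constant(comp, T, S)) * x[i] * P \
                * comp.molar_mass                      # kg/m^3 at the interface
            c_amb = profile.concentration(comp.name, z)
            area = math.pi * d**2
            # rising: dz/dt = -u, dissolution flux leaves the bubble
            dndz[i] = k * area * (c_surf - c_amb) / comp.molar_mass / u
        return dndz

    def floor_event(z, y):
        _, d, *_ = _bubble_state(y, z, profile, comps)
        return d - diameter_floor
    floor_event.terminal = True
    floor_event.direction = -1.0

    sol = solve_ivp(rhs, (release_depth, 0.0), y0, method="LSODA",
                    events=[floor_event], dense_output=True,
                    rtol=rtol, atol=n_ch4_0 * 1e-12, max_step=2.0)
    if sol.status == -1:
        raise BubbleIntegrationError(
            f"bubble integration failed at depth {sol.t[-1]:.2f} m: {sol.message}")
    z_end = float(sol.t[-1])
    n_end = np.clip(sol.y[:, -1], 0.0, None)

    if cell_edges is None:
        cell_edges = np.concatenate([np.arange(0.0, release_depth, 1.0),
                                     [release_depth]])
    cell_edges = np.asarray(cell_edges, dtype=float)

    def n_ch4(z):
        if z >= release_depth:
            return n_ch4_0
        if z <= z_end:
            return float(n_end[0])
        return float(np.clip(sol.sol(z)[0], 0.0, n_ch4_0))

    # dissolved within a band [top, bottom] = n(bottom) - n(top); telescopes
    tops = np.minimum(cell_edges[:-1], release_depth)
    bottoms = np.minimum(cell_edges[1:], release_depth)
    dissolved = np.array([n_ch4(b) - n_ch4(t) for t, b in zip(tops, bottoms)])
    dissolved = np.clip(dissolved, 0.0, None)
    if z_end > 0.0:
        # terminated at the diameter floor: remaining methane deposits here
        idx = min(np.searchsorted(cell_edges, z_end, side="right") - 1,
                  len(dissolved) - 1)
        dissolved[idx] += n_end[0]
        surfaced = 0.0
    else:
        surfaced = float(n_end[0])
    # exact closure: absorb interpolation round-off into the release cell
    residual = n_ch4_0 - (dissolved.sum() + surfaced)
    dissolved[-1] += residual
    deposition = DepositionProfile(cell_edges, dissolved / n_ch4_0,
                                   surfaced / n_ch4_0)

    # trajectory sampled on a regular depth ladder
    z_traj = np.arange(release_depth, max(z_end, 0.0) - 1e-9, -traj_step)
    rows = []
    for z in z_traj:
        y = sol.sol(z) if z < release_depth else y0
        x, d, u, regime, *_ , tloc, sloc, ploc = _bubble_state(y, z, profile, comps)
        rows.append((z, d, u, regime, *x))
    trajectory = pd.DataFrame(rows, columns=["depth", "diameter", "velocity",
                                             "regime", *(f"x_{n}" for n in names)])

    n_tot_end = max(n_end.sum(), 1e-300)
    surfaced_composition = {name: float(v / n_tot_end)
                            for name, v in zip(names, n_end)}
    return BubbleResult(trajectory=trajectory, deposition=deposition,
                        surfaced_composition=surfaced_composition,
                        terminated_at=z_end)
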