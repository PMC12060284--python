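"""Synthetic environmental fields for Norwegian-shelf water columns.

The fate chain consumes depth-time fields of vertical eddy diffusivity,
temperature and salinity, a surface wind series, and a tracer-experiment
dataset.  This module generates all of them with the seasonal structure
the analysis assumes: a winter column homogenised by convection and
storms, and a summer surface mixed layer separated from the interior by
a low-diffusivity pycnocline from roughly May to October.  Deep
stations keep a weakly mixed interior year-round.

The constructions are parametric stand-ins for an ocean turbulence
model, not turbulence physics: the analysis consumes K(z, t), it does
not require the closure that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from . import seawater
from .kinetics import KineticsParams, TracerDataset, predict_activity

DAYS_PER_YEAR = 365.0

#: atmospheric mole fractions of the dissolved-gas pool
ATM_MOLE_FRACTION = {"N2": 0.7808, "O2": 0.2095}


# ---------------------------------------------------------------------------
# Scenario container
# ---------------------------------------------------------------------------

@dataclass
class EnvironmentScenario:
    """Depth-time environment for one station.

    depth_grid : cell centres, metres, positive downward
    time_grid  : days since the start of the year
    K, T, S    : (depth, time) fields; U10: (time,) wind series
    """

    depth_grid: np.ndarray
    time_grid: np.ndarray
    K: np.ndarray
    T: np.ndarray
    S: np.ndarray
    U10: np.ndarray
    station_depth: float

    def __post_init__(self):
        self.depth_grid = np.asarray(self.depth_grid, dtype=float)
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        for name in ("K", "T", "S", "U10"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self):
        nz, nt = len(self.depth_grid), len(self.time_grid)
        if np.any(np.diff(self.depth_grid) <= 0):
            raise ValueError("depth_grid must be strictly increasing")
        if np.any(np.diff(self.time_grid) <= 0):
            raise ValueError("time_grid must be strictly increasing")
        if self.time_grid[-1] - self.time_grid[0] < DAYS_PER_YEAR - 1.0:
            raise ValueError("time_grid must cover one full year")
        for name, arr, shape in (("K", self.K, (nz, nt)), ("T", self.T, (nz, nt)),
                                 ("S", self.S, (nz, nt)), ("U10", self.U10, (nt,))):
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if np.any(self.K < 0):
            raise ValueError("diffusivity must be non-negative")
        if np.any(self.T < -2) or np.any(self.T > 30):
            raise ValueError("temperature outside [-2, 30] degC")
        if np.any(self.S < 0) or np.any(self.S > 40):
            raise ValueError("salinity outside [0, 40] ppt")
        if np.any(self.U10 < 0):
            raise ValueError("wind speed must be non-negative")
        dz = np.diff(np.concatenate([[0.0], 0.5 * (self.depth_grid[1:] + self.depth_grid[:-1]),
                                     [self.station_depth]]))
        if np.any(dz <= 0) or self.depth_grid[-1] >= self.station_depth:
            raise ValueError("depth_grid must fit within station_depth")

    @property
    def cell_edges(self) -> np.ndarray:
        inner = 0.5 * (self.depth_grid[1:] + self.depth_grid[:-1])
        return np.concatenate([[0.0], inner, [self.station_depth]])

    def profile_at(self, day: float) -> pd.DataFrame:
        """Ambient (T, S) column profile at a given day, periodic in time."""
        t = float(day) % DAYS_PER_YEAR
        Tcol = _interp_time(self.T, self.time_grid, t)
        Scol = _interp_time(self.S, self.time_grid, t)
        return pd.DataFrame({"depth": self.depth_grid, "T": Tcol, "S": Scol})

    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {
                "K": (("depth", "time"), self.K, {"units": "m2 s-1"}),
                "T": (("depth", "time"), self.T, {"units": "degC"}),
                "S": (("depth", "time"), self.S, {"units": "ppt"}),
                "U10": (("time",), self.U10, {"units": "m s-1"}),
            },
            coords={
                "depth": ("depth", self.depth_grid, {"units": "m", "positive": "down"}),
                "time": ("time", self.time_grid, {"units": "day_of_year"}),
            },
            attrs={"station_depth": self.station_depth},
        )
        return ds

    def to_netcdf(self, path):
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "EnvironmentScenario":
        with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
            ds.load()
        return cls(
            depth_grid=ds["depth"].values,
            time_grid=ds["time"].values,
            K=ds["K"].values, T=ds["T"].values, S=ds["S"].values,
            U10=ds["U10"].values,
            station_depth=float(ds.attrs["station_depth"]),
        )


def _interp_time(field2d, time_grid, t):
    """Linear-in-time column interpolation with periodic wrap-around."""
    period = DAYS_PER_YEAR
    t = t % period
    idx = np.searchsorted(time_grid, t, side="right") - 1
    idx = np.clip(idx, 0, len(time_grid) - 1)
    j = (idx + 1) % len(time_grid)
    t0 = time_grid[idx]
    t1 = time_grid[j] if j != 0 else time_grid[0] + period
    w = 0.0 if t1 == t0 else (t - t0) / (t1 - t0)
    return (1.0 - w) * field2d[:, idx] + w * field2d[:, j]


# ---------------------------------------------------------------------------
# Seasonal diffusivity
# ---------------------------------------------------------------------------

@dataclass
class DiffusivityConfig:
    """Parametric two-layer seasonal diffusivity.

    Magnitudes in m^2/s, depths in m, times in day-of-year.  The winter
    column is mixed down to winter_mixed_depth (None: the full column);
    in summer a low-K pycnocline band at the mixed-layer base separates
    a moderately mixed surface layer from a quieter interior.
    winter_stratification in [0, 1] keeps part of the summer structure
    all year (deep stations are never completely homogenised).
    """

    winter_K: float = 0.1
    mixed_layer_K: float = 0.03
    pycnocline_K: float = 1e-5
    interior_K: float = 3e-3
    ceiling: float = 0.2
    onset_day: float = 120.0
    breakdown_day: float = 300.0
    ramp_days: float = 20.0
    ml_depth_summer: float = 15.0
    ml_depth_autumn: float = 40.0
    pycnocline_width: float = 6.0
    winter_mixed_depth: float | None = None
    winter_stratification: float = 0.0

    def validate(self):
        for name in ("winter_K", "mixed_layer_K", "pycnocline_K", "interior_K",
                     "ceiling", "ramp_days", "ml_depth_summer", "ml_depth_autumn",
                     "pycnocline_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.winter_stratification <= 1.0:
            raise ValueError("winter_stratification must lie in [0, 1]")


def stratification_index(time_grid, config: DiffusivityConfig) -> np.ndarray:
    """Seasonal stratification weight s(t) in [0, 1] (smooth ramps)."""
    t = np.asarray(time_grid, dtype=float)
    up = 0.5 * (1.0 + np.tanh((t - config.onset_day) / config.ramp_days))
    down = 0.5 * (1.0 - np.tanh((t - config.breakdown_day) / config.ramp_days))
    s = up * down
    return config.winter_stratification + (1.0 - config.winter_stratification) * s


def mixed_layer_depth(time_grid, config: DiffusivityConfig) -> np.ndarray:
    """Summer mixed-layer depth trajectory: shallow after onset, deepening
    toward the autumn breakdown."""
    t = np.asarray(time_grid, dtype=float)
    frac = np.clip((t - config.onset_day)
                   / max(config.breakdown_day - config.onset_day, 1.0), 0.0, 1.0)
    return config.ml_depth_summer + (config.ml_depth_autumn - config.ml_depth_summer) * frac


def make_seasonal_diffusivity(depth_grid, time_grid,
                              config: DiffusivityConfig | None = None) -> np.ndarray:
    """Build the K(z, t) field on (depth, time)."""
    config = config or DiffusivityConfig()
    config.validate()
    z = np.asarray(depth_grid, dtype=float)[:, None]
    t = np.asarray(time_grid, dtype=float)
    if np.any(np.diff(z[:, 0]) <= 0) or np.any(np.diff(t) <= 0):
        raise ValueError("grids must be strictly increasing")

    s = stratification_index(t, config)[None, :]
    zml = mixed_layer_depth(t, config)[None, :]
    w = config.pycnocline_width

    # stratified-season profile: mixed layer over interior, with a
    # low-K band at the mixed-layer base; the band is flat-bottomed
    # (super-Gaussian) so its minimum spans several grid cells --
    # a sub-cell dip would be short-circuited by face averaging
    base = (config.interior_K
            + (config.mixed_layer_K - config.interior_K)
            * 0.5 * (1.0 - np.tanh((z - zml) / w)))
    notch = np.exp(-((z - zml) / w) ** 4)
    k_strat = base * (1.0 - notch) + config.pycnocline_K * notch

    # winter profile: homogenised to winter_mixed_depth
    if config.winter_mixed_depth is None:
        k_winter = np.full_like(z * np.ones_like(t), config.winter_K)
    else:
        k_winter = (config.interior_K
                    + (config.winter_K - config.interior_K)
                    * 0.5 * (1.0 - np.tanh((z - config.winter_mixed_depth) / 10.0)))
        k_winter = np.broadcast_to(k_winter, (len(z), len(t))).copy()

    # geometric (log-space) seasonal blend: K spans orders of magnitude,
    # and an arithmetic blend would let the winter value leak into and
    # wash out the summer pycnocline minimum
    floor = 1e-12
    K = np.exp((1.0 - s) * np.log(np.maximum(k_winter, floor))
               + s * np.log(np.maximum(k_strat, floor)))
    return np.clip(K, 0.0, config.ceiling)


# ---------------------------------------------------------------------------
# Wind
# ---------------------------------------------------------------------------

@dataclass
class WindConfig:
    """Clipped first-order autoregressive wind-speed series."""

    mean: float = 8.0       # m/s
    std: float = 3.0        # m/s, stationary standard deviation
    corr: float = 0.7       # day-to-day autocorrelation

    def validate(self):
        if self.mean < 0 or self.std < 0:
            raise ValueError("wind mean and std must be non-negative")
        if not 0.0 <= self.corr < 1.0:
            raise ValueError("wind autocorrelation must lie in [0, 1)")


def make_wind_series(time_grid, seed: int, config: WindConfig | None = None) -> np.ndarray:
    """U10 time series (m/s), non-negative, reproducible for fixed seed."""
    config = config or WindConfig()
    config.validate()
    n = len(np.asarray(time_grid))
    rng = np.random.default_rng(seed)
    if config.std == 0.0:
        return np.full(n, config.mean)
    eps_std = config.std * np.sqrt(1.0 - config.corr**2)
    u = np.empty(n)
    u[0] = config.mean + config.std * rng.standard_normal()
    for i in range(1, n):
        u[i] = (config.mean + config.corr * (u[i - 1] - config.mean)
                + eps_std * rng.standard_normal())
    return np.clip(u, 0.0, None)


# ---------------------------------------------------------------------------
# Dissolved gases at atmospheric equilibrium
# ---------------------------------------------------------------------------

def equilibrium_dissolved_gases(T, S) -> dict:
    """Dissolved N2 and O2 (kg/m^3) in equilibrium with a moist atmosphere.

    Henry's law at surface pressure with the water-vapour partial
    pressure removed; applied uniformly over depth, mirroring the
    assumption that the deep gas pool was set at the surface.
    """
    from . import gases

    T_arr, _ = seawater._check_ts(T, S)
    # Magnus vapour pressure over seawater (2% activity reduction)
    p_w = 610.94 * np.exp(17.625 * T_arr / (T_arr + 243.04)) * 0.98
    p_dry = seawater.P_ATM - p_w
    return {
        name: gases.solubility(name, T, S, frac * p_dry)
        for name, frac in ATM_MOLE_FRACTION.items()
    }


# ---------------------------------------------------------------------------
# Scenario assembly
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Everything needed to synthesise one station-year."""

    station_depth: float = 65.0
    dz: float = 1.0
    n_days: int = 365
    diffusivity: DiffusivityConfig = field(default_factory=DiffusivityConfig)
    wind: WindConfig = field(default_factory=WindConfig)
    T_deep: float = 7.0
    T_surface_winter: float = 6.0
    T_surface_summer: float = 14.0
    warmest_day: float = 220.0
    S_deep: float = 34.0
    surface_freshening: float = 1.0


#: station presets spanning the shelf-depth range of the study
STATION_PRESETS = {
    65: ScenarioConfig(station_depth=65.0),
    106: ScenarioConfig(
        station_depth=106.0,
        diffusivity=DiffusivityConfig(interior_K=2e-3, ml_depth_autumn=55.0),
    ),
    303: ScenarioConfig(
        station_depth=303.0,
        diffusivity=DiffusivityConfig(
            winter_K=0.08, interior_K=3e-4, ml_depth_summer=20.0,
            ml_depth_autumn=80.0, winter_mixed_depth=130.0,
            winter_stratification=0.3,
        ),
    ),
}


def station_preset(depth: int) -> ScenarioConfig:
    try:
        return STATION_PRESETS[int(depth)]
    except KeyError:
        raise ValueError(f"no preset for {depth} m; known: {sorted(STATION_PRESETS)}"
                         ) from None


def make_scenario(config: ScenarioConfig | None = None, seed: int = 0
                  ) -> EnvironmentScenario:
    """Synthesise a full station-year on 1 m cells with daily snapshots."""
    config = config or ScenarioConfig()
    if config.station_depth <= 0 or config.dz <= 0:
        raise ValueError("station depth and cell size must be positive")
    n_cells = int(round(config.station_depth / config.dz))
    depth = (np.arange(n_cells) + 0.5) * config.dz
    time = np.arange(config.n_days, dtype=float)

    K = make_seasonal_diffusivity(depth, time, config.diffusivity)
    U10 = make_wind_series(time, seed=seed, config=config.wind)

    s = stratification_index(time, config.diffusivity)[None, :]
    zml = mixed_layer_depth(time, config.diffusivity)[None, :]
    w = config.diffusivity.pycnocline_width
    layer = 0.5 * (1.0 - np.tanh((depth[:, None] - zml) / w))

    t_mid = 0.5 * (config.T_surface_winter + config.T_surface_summer)
    t_amp = 0.5 * (config.T_surface_summer - config.T_surface_winter)
    T_surf = t_mid - t_amp * np.cos(2.0 * np.pi * (time - config.warmest_day
                                                   + DAYS_PER_YEAR / 2.0)
                                    / DAYS_PER_YEAR)[None, :]
    mix = (1.0 - s) + s * layer
    T = config.T_deep + (T_surf - config.T_deep) * mix
    S = config.S_deep - config.surface_freshening * s * layer

    return EnvironmentScenario(depth_grid=depth, time_grid=time, K=K, T=T, S=S,
                               U10=U10, station_depth=config.station_depth)


# ---------------------------------------------------------------------------
# Tracer-experiment simulator
# ---------------------------------------------------------------------------

@dataclass
class TracerExperimentDesign:
    """Layout of the incubation experiment: which flasks, when, how warm.

    Defaults reproduce the study conditions: sampling after 2, 4, 13,
    17 and 27 days at 5 and 8.5 degC, with the true parameter vector at
    the posterior medians of the laboratory analysis.
    """

    sampling_days: tuple = (2.0, 4.0, 13.0, 17.0, 27.0)
    temperatures: tuple = (5.0, 5.0, 8.5)   # one entry per experiment series
    replicates: int = 1
    true_params: KineticsParams = field(default_factory=lambda: KineticsParams(
        t12_ref=11.622, Cb=0.461, Ctot=3.883, ln_sigma=-0.133))
    noise_scale: float | None = None        # None: exp(true_params.ln_sigma)
    n_control: int = 4
    n_pre: int = 4

    def validate(self):
        if any(d < 0 for d in self.sampling_days):
            raise ValueError("sampling days must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_scale is not None and self.noise_scale < 0:
            raise ValueError("noise scale must be non-negative")
        if self.n_control < 1 or self.n_pre < 1:
            raise ValueError("need at least one control and one pre sample")

    @property
    def sigma(self) -> float:
        return (self.noise_scale if self.noise_scale is not None
                else self.true_params.sigma)


def simulate_tracer_experiment(design: TracerExperimentDesign | None = None,
                               seed: int = 0) -> TracerDataset:
    """Draw one synthetic tracer dataset from the decay-curve data model.

    Each incubated flask observes the model mean at its (day,
    temperature) plus Gaussian noise; sterile controls observe Cb and
    pre-incubation samples observe Ctot with the same noise scale.
    """
    design = design or TracerExperimentDesign()
    design.validate()
    rng = np.random.default_rng(seed)
    p = design.true_params
    rows = []
    for temp in design.temperatures:
        for day in design.sampling_days:
            mean = float(predict_activity(p, day, temp))
            for rep in range(design.replicates):
                rows.append((day, temp, rep, "test", mean))
    for i in range(design.n_control):
        rows.append((0.0, 5.0, i, "control", p.Cb))
    for i in range(design.n_pre):
        rows.append((0.0, 5.0, i, "pre", p.Ctot))
    frame = pd.DataFrame(rows, columns=list(TracerDataset.COLUMNS))
    if design.sigma > 0:
        frame["activity_normalized"] += design.sigma * rng.standard_normal(len(frame))
    return TracerDataset(frame)
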