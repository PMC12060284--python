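"""Shared fixtures: small synthetic inputs, generated at session start."""

import numpy as np
import pytest

from seepfate import bubble as bub
from seepfate.environment import (DiffusivityConfig, ScenarioConfig, WindConfig,
                                  TracerExperimentDesign, make_scenario,
                                  simulate_tracer_experiment, station_preset)
from seepfate.kinetics import KineticsParams

TRUE_PARAMS = KineticsParams(t12_ref=11.622, Cb=0.461, Ctot=3.883,
                             ln_sigma=-0.133)


@pytest.fixture(scope="session")
def seawater_fluid():
    return bub.fluid_properties(7.0, 34.0)


@pytest.fixture(scope="session")
def winter_profile():
    """Homogeneous winter shelf column: 7 degC, 34 ppt down to 65 m."""
    return bub.AmbientProfile.uniform(65.0, T=7.0, S=34.0)


@pytest.fixture(scope="session")
def bubble_65(winter_profile):
    """Reference single-bubble run: 4.5 mm pure methane from 65 m."""
    return bub.integrate_bubble(winter_profile, 65.0, d0=4.5e-3)


@pytest.fixture(scope="session")
def shelf_scenario():
    """Seasonal 65 m station-year."""
    return make_scenario(station_preset(65), seed=1)


@pytest.fixture(scope="session")
def mixed_box_scenario():
    """Permanently well-mixed shallow column with constant wind: the
    configuration whose fate branching has a closed-form box-model
    answer."""
    cfg = ScenarioConfig(
        station_depth=25.0,
        diffusivity=DiffusivityConfig(winter_K=0.2, ceiling=0.2, onset_day=1e9),
        wind=WindConfig(mean=8.0, std=0.0),
    )
    return make_scenario(cfg, seed=0)


@pytest.fixture(scope="session")
def uniform_box_deposition(mixed_box_scenario):
    edges = mixed_box_scenario.cell_edges
    n = len(edges) - 1
    return bub.DepositionProfile(edges, np.full(n, 1.0 / n), 0.0)


@pytest.fixture(scope="session")
def tracer_noise_free():
    return simulate_tracer_experiment(
        TracerExperimentDesign(noise_scale=0.0, replicates=3,
                               true_params=TRUE_PARAMS), seed=0)


@pytest.fixture(scope="session")
def tracer_noisy():
    return simulate_tracer_experiment(
        TracerExperimentDesign(replicates=3, true_params=TRUE_PARAMS), seed=42)
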