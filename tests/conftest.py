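"""Shared fixtures: one default forward model per session.

The heavy objects (transient temperature solution, Conc(t) library over the
default S_T dictionary) are session-scoped; individual tests derive traces
and fits from them.
"""

from __future__ import annotations

import numpy as np
import pytest

import thermotrace as tt


@pytest.fixture(scope="session")
def temperature() -> tt.TemperatureSeries:
    """Default laser/geometry/medium transient heat solution (20 s on-phase)."""
    return tt.simulate_temperature()


@pytest.fixture(scope="session")
def library(temperature) -> tt.ConcLibrary:
    """Default Conc(t) dictionary: S_T in [-2.5, 2.5] 1/K, 51 points."""
    return tt.build_conc_library(np.linspace(-2.5, 2.5, 51), temperature)


@pytest.fixture(scope="session")
def steady_field(temperature) -> np.ndarray:
    return temperature.steady_state


def make_particle_trace(temperature, truth_soret, noise_sigma=0.0, seed=0,
                        decay_rate_k=-0.22):
    """Noise-controlled particle trace from a direct solver run at the truth."""
    curve = tt.simulate_conc_curve(truth_soret, temperature)
    minilib = tt.ConcLibrary.from_curves([truth_soret], [curve])
    recipe = tt.TraceRecipe(role="particle", soret_ST=truth_soret,
                            noise_sigma=noise_sigma, seed=seed,
                            decay_rate_k=decay_rate_k)
    return tt.generate_particle_trace(recipe, minilib)
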