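"""Laser-heating solver: source bookkeeping, steady/transient solutions."""

import numpy as np
import pytest

import thermotrace as tt
from thermotrace.heat import (EstablishmentNotReachedError,
                              boundary_heat_outflow)
from thermotrace.grids import Grid


GEOM = tt.CapillaryGeometry()
MEDIUM = tt.Medium()


def test_zero_power_gives_zero_source():
    grid = tt.default_grid(GEOM)
    q = tt.heat_source_field(tt.LaserSource(power_Q0=0.0), GEOM, grid)
    assert np.all(q == 0.0)


def test_source_integrates_to_absorbed_power():
    """Volume integral equals Q0 (1-Rc) (1-exp(-Ac*2L)) ~ 9.4e-4 W."""
    laser = tt.LaserSource()
    grid = tt.default_grid(GEOM)
    q = tt.heat_source_field(laser, GEOM, grid)
    absorbed = float(np.sum(q * grid.volumes))
    expected = 0.05 * 0.95 * (1.0 - np.exp(-50.0 * 4.0e-4))
    assert absorbed == pytest.approx(expected, rel=1e-12)
    assert absorbed == pytest.approx(9.4e-4, rel=0.01)


def test_source_gaussian_transverse_falloff():
    laser = tt.LaserSource()
    sigma = laser.sigma
    grid = Grid(r_nodes=np.concatenate([np.linspace(0, 4 * sigma, 17),
                                        np.linspace(5 * sigma, 2e-4, 20)]),
                z_nodes=np.linspace(-2e-4, 2e-4, 21))
    q = tt.heat_source_field(laser, GEOM, grid)
    i5 = int(np.argmin(np.abs(grid.r_nodes - 5 * sigma)))
    assert np.all(q[i5, :] < np.exp(-12.5) * q[0, :] * (1 + 1e-9))


def test_source_refuses_grid_missing_beam_waist():
    coarse = Grid(r_nodes=np.linspace(0, 2e-4, 10),
                  z_nodes=np.linspace(-2e-4, 2e-4, 11))
    with pytest.raises(ValueError, match="beam waist"):
        tt.heat_source_field(tt.LaserSource(), GEOM, coarse)


def test_zero_source_steady_is_ambient():
    grid = tt.default_grid(GEOM)
    T = tt.solve_steady_temperature(MEDIUM, np.zeros(grid.shape), GEOM, grid)
    assert np.allclose(T, MEDIUM.ambient_temperature)


def test_steady_peak_rise_in_expected_band(temperature):
    """A ~1 mW absorbed load warms the focal region by a few kelvin."""
    rise = temperature.steady_state.max() - temperature.ambient
    assert 2.0 <= rise <= 8.0
    # maximum sits on the axis near the focal plane
    i, k = np.unravel_index(int(np.argmax(temperature.steady_state)),
                            temperature.grid.shape)
    assert i == 0
    assert abs(temperature.grid.z_nodes[k]) < 3e-5


def test_no_temperature_below_ambient_or_above_focus(temperature):
    assert temperature.fields.min() >= temperature.ambient - 1e-9
    assert temperature.fields.max() <= temperature.steady_state.max() + 1e-6


def test_steady_energy_balance():
    """Boundary heat outflow matches the volume-integrated source to 1%."""
    grid = tt.default_grid(GEOM)
    laser = tt.LaserSource()
    q = tt.heat_source_field(laser, GEOM, grid)
    T = tt.solve_steady_temperature(MEDIUM, q, GEOM, grid)
    out = boundary_heat_outflow(T, MEDIUM, grid, source=q)
    source = float(np.sum(q * grid.volumes))
    assert out == pytest.approx(source, rel=0.01)


def test_mesh_convergence_of_peak_rise(temperature):
    """2x refinement moves the steady peak rise by < 2%."""
    fine = tt.default_grid(GEOM, refine=2.0)
    q = tt.heat_source_field(tt.LaserSource(), GEOM, fine)
    T = tt.solve_steady_temperature(MEDIUM, q, GEOM, fine)
    rise_fine = T.max() - MEDIUM.ambient_temperature
    rise = temperature.steady_state.max() - temperature.ambient
    assert abs(rise_fine - rise) / rise_fine < 0.02


def test_transient_initial_condition_and_convergence(temperature):
    """Ambient at switch-on; within 0.5% of the steady focal rise by t=2 s."""
    assert np.allclose(temperature.fields[0], temperature.ambient)
    i, k = temperature.focus
    steady_rise = temperature.steady_state[i, k] - temperature.ambient
    rise_2s = temperature.field_at(2.0)[i, k] - temperature.ambient
    assert rise_2s == pytest.approx(steady_rise, rel=0.005)


def test_focal_rise_monotone_during_laser_on(temperature):
    rise = temperature.focal_rise()
    assert np.all(np.diff(rise) >= -1e-10)


def test_laser_never_on_stays_ambient():
    grid = tt.default_grid(GEOM)
    q = tt.heat_source_field(tt.LaserSource(), GEOM, grid)
    series = tt.solve_transient_temperature(
        MEDIUM, q, GEOM, grid, np.linspace(0.0, 1.0, 11),
        laser_on=100.0, laser_off=101.0)
    assert np.allclose(series.fields, MEDIUM.ambient_temperature)


def test_establishment_time_contract(temperature):
    """99% establishment within 1 s; monotone in the fraction; 0 at 0."""
    t99 = tt.gradient_establishment_time(temperature, 0.99)
    assert 0.0 < t99 <= 1.0
    assert tt.gradient_establishment_time(temperature, 0.0) == 0.0
    fracs = [0.5, 0.9, 0.99]
    times = [tt.gradient_establishment_time(temperature, f) for f in fracs]
    assert times == sorted(times)


def test_establishment_unreached_reports_attained_fraction():
    grid = tt.default_grid(GEOM)
    q = tt.heat_source_field(tt.LaserSource(), GEOM, grid)
    steady = tt.solve_steady_temperature(MEDIUM, q, GEOM, grid)
    short = tt.solve_transient_temperature(
        MEDIUM, q, GEOM, grid, np.arange(0.0, 0.031, 0.01),
        laser_on=0.0, laser_off=20.0, steady=steady)
    with pytest.raises(EstablishmentNotReachedError) as err:
        tt.gradient_establishment_time(short, 0.999)
    assert 0.0 < err.value.attained < 0.999


def test_transient_mesh_convergence_of_establishment():
    """2x refinement moves the 99% establishment time by < 2%."""
    est = []
    for refine in (1.0, 2.0):
        grid = tt.default_grid(GEOM, refine=refine)
        q = tt.heat_source_field(tt.LaserSource(), GEOM, grid)
        steady = tt.solve_steady_temperature(MEDIUM, q, GEOM, grid)
        series = tt.solve_transient_temperature(
            MEDIUM, q, GEOM, grid, np.arange(0.0, 0.5, 0.002),
            laser_on=0.0, laser_off=20.0, steady=steady)
        est.append(tt.gradient_establishment_time(series, 0.99))
    assert abs(est[1] - est[0]) / est[1] < 0.02
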