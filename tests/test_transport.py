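"""Drift-diffusion solver, Conc(t) reduction and the S_T curve library."""

import warnings

import numpy as np
import pytest

import thermotrace as tt
from thermotrace.transport import steady_drift_diffusion


def test_zero_soret_stays_uniform(temperature):
    params = tt.TransportParams(soret_ST=0.0)
    series = tt.solve_drift_diffusion(params, temperature)
    assert np.allclose(series.fields, 1.0, atol=1e-12)


def test_mass_conserved_over_cycle(temperature):
    series = tt.solve_drift_diffusion(
        tt.TransportParams(soret_ST=0.66), temperature)
    assert series.mass_drift() < 1e-6


@pytest.mark.parametrize("soret", [-2.0, -0.5, 1.0, 2.0])
def test_long_time_field_matches_boltzmann(temperature, soret):
    """Stationary solution is c0 exp(-S_T (T - T_ref)) pointwise within 1%.

    The long-time limit depends on S_T only; mass conservation fixes the
    reference temperature normalisation.
    """
    grid = temperature.grid
    ceq = steady_drift_diffusion(tt.TransportParams(soret_ST=soret),
                                 temperature.steady_state, grid)
    ana = np.exp(-soret * (temperature.steady_state - temperature.ambient))
    ana *= np.sum(ceq * grid.volumes) / np.sum(ana * grid.volumes)
    assert np.max(np.abs(ceq - ana) / ana) < 0.01


def test_focal_depletion_monotone_for_positive_soret(temperature):
    """Warm-seeking sign convention: S_T > 0 depletes the focus steadily."""
    series = tt.solve_drift_diffusion(
        tt.TransportParams(soret_ST=0.66), temperature)
    i, k = temperature.focus
    focal = series.fields[:, i, k]
    assert np.all(np.diff(focal) < 0)


def test_conc_curve_normalisation_and_shape(temperature):
    curve = tt.simulate_conc_curve(0.66, temperature)
    assert curve.values[0] == 1.0
    assert np.all(curve.values > 0)
    assert np.all(np.diff(curve.values) < 0)
    # the focal line integral decays non-linearly: the decay rate in the
    # first second far exceeds the rate in the last
    line = tt.simulate_conc_curve(
        0.66, temperature,
        region=tt.ProbeRegion(kind="line", planar_diameter=6.5e-5))
    early_rate = 1.0 - line.at(1.0)
    late_rate = line.at(19.0) - line.at(20.0)
    assert early_rate > 3.0 * late_rate > 0.0


def test_disk_and_circle_probes_agree(temperature):
    """3-D disk vs 2-D focal-plane circle: Conc(t) within 5% at all times."""
    series = tt.solve_drift_diffusion(
        tt.TransportParams(soret_ST=0.66), temperature)
    disk = tt.reduce_to_conc_curve(series, tt.ProbeRegion(kind="disk"))
    circ = tt.reduce_to_conc_curve(series, tt.ProbeRegion(kind="circle"))
    assert np.max(np.abs(disk.values - circ.values)) < 0.05
    # and on the depletion scale they track within a few percent
    depth = np.max(1 - circ.values)
    assert np.max(np.abs(disk.values - circ.values)) < 0.5 * depth


def test_probe_larger_than_domain_refused(temperature):
    series = tt.solve_drift_diffusion(
        tt.TransportParams(soret_ST=0.1), temperature,
        times=np.linspace(0, 1, 5))
    with pytest.raises(ValueError, match="exceeds the domain"):
        tt.reduce_to_conc_curve(series, tt.ProbeRegion(planar_diameter=1e-3))


def test_library_zero_grid_is_identity(temperature):
    lib = tt.build_conc_library([0.0], temperature)
    assert np.allclose(lib.values, 1.0, atol=1e-12)


def test_library_monotone_in_soret(library):
    """Larger S_T means deeper depletion at every t > 0."""
    assert np.all(np.diff(library.values[:, 1:], axis=0) <= 1e-12)


def test_linear_response_and_sign_symmetry(temperature):
    """Depletion depth proportional to S_T (2%) and antisymmetric in sign."""
    c05 = tt.simulate_conc_curve(0.05, temperature)
    c10 = tt.simulate_conc_curve(0.10, temperature)
    cm5 = tt.simulate_conc_curve(-0.05, temperature)
    d05, d10 = 1 - c05.values[-1], 1 - c10.values[-1]
    assert d10 / d05 == pytest.approx(2.0, rel=0.02)
    enrich = cm5.values[-1] - 1
    assert enrich == pytest.approx(d05, rel=0.02)


def test_interpolation_contract(temperature, library):
    """Exact at grid points, between brackets at midpoints, and within
    0.5% of depletion depth of a direct solver run off-grid."""
    s_grid = library.soret_values[30]
    assert np.array_equal(tt.interpolate_conc_curve(library, s_grid).values,
                          library.values[30])
    mid = 0.5 * (library.soret_values[30] + library.soret_values[31])
    vm = tt.interpolate_conc_curve(library, mid).values
    lo = np.minimum(library.values[30], library.values[31])
    hi = np.maximum(library.values[30], library.values[31])
    assert np.all(vm >= lo - 1e-12) and np.all(vm <= hi + 1e-12)
    direct = tt.simulate_conc_curve(mid, temperature)
    err = np.max(np.abs(vm - direct.values))
    assert err < 0.005 * direct.depletion_depth()


def test_interpolation_refuses_extrapolation(library):
    with pytest.raises(ValueError, match="outside library range"):
        tt.interpolate_conc_curve(library, 3.0)


def test_library_cache_roundtrip(tmp_path, temperature):
    cache = tmp_path / "lib.csv"
    notes = []
    grid_s = [0.0, 0.5]
    lib1 = tt.build_conc_library(grid_s, temperature, cache_path=cache,
                                 log=notes.append)
    assert cache.exists() and any("written" in n for n in notes)
    notes.clear()
    lib2 = tt.build_conc_library(grid_s, temperature, cache_path=cache,
                                 log=notes.append)
    assert any("cache hit" in n for n in notes)
    assert np.array_equal(lib1.values, lib2.values)
    # changed settings: provenance mismatch triggers a rebuild warning
    with pytest.warns(UserWarning, match="provenance mismatch"):
        lib3 = tt.build_conc_library(
            grid_s, temperature, cache_path=cache,
            region=tt.ProbeRegion(kind="line", planar_diameter=1.3e-4),
            log=notes.append)
    assert not np.allclose(lib3.values, lib1.values)


def test_library_csv_roundtrip(tmp_path, library):
    path = tmp_path / "lib.csv"
    library.to_csv(path)
    back = tt.ConcLibrary.from_csv(path)
    assert np.array_equal(back.soret_values, library.soret_values)
    assert np.array_equal(back.values, library.values)
    assert back.provenance == library.provenance


def test_conc_curve_rejects_unnormalised():
    with pytest.raises(ValueError, match="normalised"):
        tt.ConcCurve(times=np.array([0.0, 1.0]), values=np.array([0.9, 0.8]))
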