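"""Two-stage fit: fluorophore decay, particle S_T profile, aggregation, QC."""

import numpy as np
import pytest

import thermotrace as tt
from thermotrace.fitting import _linear_subfit

from conftest import make_particle_trace


# ---------------------------------------------------------------------------
# stage 1
# ---------------------------------------------------------------------------

def test_fluorophore_noiseless_recovery_exact():
    """Noiseless B + C exp(-0.22 t) recovers the decay rate to 1e-6."""
    trace = tt.generate_fluorophore_trace(
        tt.TraceRecipe(role="fluorophore", decay_rate_k=-0.22))
    res = tt.fit_fluorophore(trace)
    assert res.converged
    assert res.decay_rate_k == pytest.approx(-0.22, abs=1e-6)
    assert res.background_B == pytest.approx(200.0, abs=1e-6)
    assert res.amplitude_C == pytest.approx(800.0, abs=1e-6)


def test_fluorophore_constant_trace_degenerate():
    trace = tt.generate_fluorophore_trace(
        tt.TraceRecipe(role="fluorophore", amplitude=0.0, background=500.0))
    res = tt.fit_fluorophore(trace)
    assert res.amplitude_C == pytest.approx(0.0, abs=1e-9)
    assert res.background_B == pytest.approx(500.0)
    assert "decay-unidentifiable" in res.flags


def test_fluorophore_monte_carlo_calibration():
    """With 1% amplitude noise, median |k_hat - k| < 0.01 1/s over 100 seeds."""
    errs = []
    for seed in range(100):
        trace = tt.generate_fluorophore_trace(
            tt.TraceRecipe(role="fluorophore", decay_rate_k=-0.22,
                           noise_sigma=0.01, seed=seed))
        errs.append(abs(tt.fit_fluorophore(trace).decay_rate_k + 0.22))
    assert np.median(errs) < 0.01


def test_fluorophore_wrong_role_rejected():
    trace = tt.generate_fluorophore_trace(tt.TraceRecipe(role="fluorophore"))
    trace = trace.copy_with(role="particle")
    with pytest.raises(ValueError, match="fluorophore"):
        tt.FluorophoreDecayModel(trace)


# ---------------------------------------------------------------------------
# stage 2
# ---------------------------------------------------------------------------

def test_linear_subproblem_matches_lstsq_oracle():
    """Closed-form (d0, e0) equals the generic least-squares solution."""
    rng = np.random.default_rng(7)
    t = np.linspace(0, 20, 200)
    basis = np.exp(-0.22 * t) * (1 - 0.01 * t / 20)
    y = 123.4 + 567.8 * basis + rng.standard_normal(t.size)
    d0, e0, sse = _linear_subfit(y, basis)
    X = np.column_stack([np.ones_like(t), basis])
    ref, res_sq, *_ = np.linalg.lstsq(X, y, rcond=None)
    assert d0 == pytest.approx(ref[0], rel=1e-10)
    assert e0 == pytest.approx(ref[1], rel=1e-10)
    assert sse == pytest.approx(float(res_sq[0]), rel=1e-10)


@pytest.mark.parametrize("truth", [0.07, 0.66, -1.86, 1.23])
def test_particle_roundtrip_recovery(temperature, library, truth):
    """Noiseless forward trace at an off-grid truth recovers S_T within
    max(0.02 1/K, 5%)."""
    trace = make_particle_trace(temperature, truth)
    res = tt.fit_particle_trace(trace, -0.22, library)
    tol = max(0.02, 0.05 * abs(truth))
    assert abs(res.soret_ST - truth) < tol
    assert "range-limited" not in res.flags
    # amplitudes come back too (noiseless identity)
    assert res.background_d0 == pytest.approx(200.0, abs=0.5)
    assert res.amplitude_e0 == pytest.approx(800.0, abs=0.5)


def test_particle_on_grid_roundtrip_exact(temperature, library):
    """Truth on the dictionary grid: recovery to refinement tolerance."""
    truth = float(library.soret_values[38])  # 1.3 1/K
    recipe = tt.TraceRecipe(role="particle", soret_ST=truth)
    trace = tt.generate_particle_trace(recipe, library)
    res = tt.fit_particle_trace(trace, -0.22, library)
    assert abs(res.soret_ST - truth) < 1e-4


def test_parabolic_refinement_vs_brute_force(temperature, library):
    """Parabolic minimum agrees with a 10x finer SSE scan to < 0.005 1/K."""
    trace = make_particle_trace(temperature, 0.66)
    model = tt.ParticleTraceModel(trace, -0.22, library)
    res = model.fit()
    fine = np.arange(res.soret_grid[0], res.soret_grid[-1] + 1e-9, 0.01)
    sse_fine = np.array([model._sse_at(s)[2] for s in fine])
    brute = fine[int(np.argmin(sse_fine))]
    assert abs(res.soret_parabolic - brute) < 0.005


def test_flat_conc_trace_flags_weak_identification(library):
    """A particle trace with Conc == 1 gives S_T ~ 0 and a weak-ID flag."""
    flat = tt.ConcLibrary.from_curves(
        [0.0], [tt.ConcCurve(library.times, np.ones_like(library.times))])
    trace = tt.generate_particle_trace(
        tt.TraceRecipe(role="particle", soret_ST=0.0), flat)
    res = tt.fit_particle_trace(trace, -0.22, library)
    assert abs(res.soret_ST) < 0.02
    assert "weakly-identified" in res.flags


def test_boundary_minimum_flags_range_limited(temperature, library):
    """Truth outside the dictionary: flagged, never silently extrapolated."""
    trace = make_particle_trace(temperature, 3.5)
    res = tt.fit_particle_trace(trace, -0.22, library)
    assert "range-limited" in res.flags
    assert res.soret_ST == library.soret_values[-1]


# ---------------------------------------------------------------------------
# replicate aggregation
# ---------------------------------------------------------------------------

def test_extract_soret_noiseless_replicates(temperature, library):
    """8 noiseless replicates at 0.05 1/K: mean 0.05, SD ~ 0, n = 8."""
    truth = 0.05
    curve = tt.simulate_conc_curve(truth, temperature)
    minilib = tt.ConcLibrary.from_curves([truth], [curve])
    recipe = tt.TraceRecipe(role="particle", soret_ST=truth)
    particles = tt.generate_replicate_set(recipe, 8, 100, minilib)
    ff = [tt.generate_fluorophore_trace(
        tt.TraceRecipe(role="fluorophore", decay_rate_k=-0.22))]
    res = tt.extract_soret(ff, particles, library)
    assert res.n == 8
    assert res.soret_mean == pytest.approx(truth, abs=0.001)
    assert res.soret_sd < 1e-6
    assert res.decay_rate_k == pytest.approx(-0.22, abs=1e-6)


def test_replicate_sd_scales_with_noise(temperature, library):
    """Sample SD of S_T grows with the injected noise amplitude."""
    truth = 0.66
    curve = tt.simulate_conc_curve(truth, temperature)
    minilib = tt.ConcLibrary.from_curves([truth], [curve])
    ff = [tt.generate_fluorophore_trace(
        tt.TraceRecipe(role="fluorophore", decay_rate_k=-0.22))]
    sds = []
    for noise in (0.002, 0.01):
        recipe = tt.TraceRecipe(role="particle", soret_ST=truth,
                                noise_sigma=noise)
        reps = tt.generate_replicate_set(recipe, 8, 42, minilib)
        sds.append(tt.extract_soret(ff, reps, library).soret_sd)
    assert 0 < sds[0] < sds[1]


def test_soret_results_report_table(temperature, library):
    trace = make_particle_trace(temperature, 0.18)
    ff = [tt.generate_fluorophore_trace(
        tt.TraceRecipe(role="fluorophore", decay_rate_k=-0.22))]
    res = tt.extract_soret(ff, [trace], library, condition="100 nm PS")
    df = res.to_frame()
    assert list(df.columns[:4]) == ["condition", "n", "mean_ST_per_K",
                                    "sd_ST_per_K"]
    assert df.loc[0, "condition"] == "100 nm PS"
    assert df.loc[0, "n"] == 1
    assert "S_T" in res.summary()


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def test_qc_smooth_trace_passes():
    trace = tt.generate_fluorophore_trace(tt.TraceRecipe(role="fluorophore"))
    rep = tt.qc_bumpiness(trace)
    assert rep.spike_count == 0 and rep.verdict == "pass"


def test_qc_counts_injected_spikes():
    """Three 10-sigma jumps on a noisy trace are each detected, no extras."""
    recipe = tt.TraceRecipe(role="fluorophore", noise_sigma=0.01, seed=3)
    trace = tt.generate_fluorophore_trace(recipe)
    sigma = 0.01 * recipe.amplitude
    spiked = tt.inject_aggregation_spikes(trace, [8.0, 12.0, 18.0],
                                          10.0 * sigma)
    rep = tt.qc_bumpiness(spiked)
    assert rep.spike_count == 3
    assert rep.verdict == "flag"
    assert np.allclose(sorted(rep.spike_times), [8.0, 12.0, 18.0], atol=0.1)


def test_qc_infinite_threshold_always_passes():
    recipe = tt.TraceRecipe(role="fluorophore", noise_sigma=0.02, seed=1)
    trace = tt.inject_aggregation_spikes(
        tt.generate_fluorophore_trace(recipe), [10.0], 1e4)
    rep = tt.qc_bumpiness(trace, threshold=np.inf)
    assert rep.spike_count == 0 and rep.verdict == "pass"


def test_qc_refuses_too_short_trace():
    t = np.linspace(0, 30, 25)
    trace = tt.MSTTrace(times=t, intensities=np.ones(25) * 100,
                        laser_on=1.0, laser_off=29.0)
    with pytest.raises(ValueError, match="too short"):
        tt.qc_bumpiness(trace, window=31)
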