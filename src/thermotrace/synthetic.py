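"""Synthetic MST trace generation with known ground truth.

Emulates the canonical trace morphology: a flat pre-laser baseline, an
exponential-times-depletion decay while the IR laser is on, and a plateau
after switch-off.  Fluorophore traces follow B + C exp(k t); particle
traces multiply the exponential by a Conc(t) curve drawn from a forward-
model library at the recipe's Soret coefficient.  Noise is additive
Gaussian with a standard deviation specified as a fraction of the decay
amplitude, and every trace is bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .traces import MSTTrace
from .transport import ConcLibrary, interpolate_conc_curve

__all__ = ["TraceRecipe", "RecipeError", "generate_fluorophore_trace",
           "generate_particle_trace", "generate_replicate_set",
           "inject_aggregation_spikes"]


class RecipeError(ValueError):
    """Invalid trace recipe; message lists the violated fields."""


@dataclass(frozen=True)
class TraceRecipe:
    """Ground-truth parameters for one synthetic trace.

    ``noise_sigma`` is the Gaussian noise SD as a fraction of ``amplitude``.
    ``soret_ST`` is required for particle traces and ignored for
    fluorophore traces.
    """

    role: str = "fluorophore"
    background: float = 200.0       # counts
    amplitude: float = 800.0        # counts
    decay_rate_k: float = -0.22     # 1/s
    soret_ST: float | None = None   # 1/K (particle only)
    noise_sigma: float = 0.0        # fraction of amplitude
    n_points: int = 301
    duration: float = 30.0          # s
    laser_on: float = 5.0           # s
    laser_off: float = 25.0         # s
    seed: int = 0
    trace_id: str = ""

    def violations(self) -> list[str]:
        bad = []
        if self.role not in ("fluorophore", "particle"):
            bad.append(f"role={self.role!r} (must be fluorophore|particle)")
        if self.n_points < 20:
            bad.append(f"n_points={self.n_points} (must be >= 20)")
        if self.noise_sigma < 0:
            bad.append(f"noise_sigma={self.noise_sigma} (must be >= 0)")
        if self.duration <= 0:
            bad.append(f"duration={self.duration} (must be > 0)")
        if not 0 <= self.laser_on < self.laser_off <= self.duration:
            bad.append("laser window must satisfy 0 <= laser_on < laser_off "
                       f"<= duration (got {self.laser_on}, {self.laser_off}, "
                       f"{self.duration})")
        if self.role == "particle" and self.soret_ST is None:
            bad.append("soret_ST required for particle recipes")
        return bad

    def validate(self) -> None:
        bad = self.violations()
        if bad:
            raise RecipeError("invalid trace recipe: " + "; ".join(bad))

    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.duration, self.n_points)


def _assemble(recipe: TraceRecipe, on_factor) -> MSTTrace:
    """Shared morphology: baseline, on-phase model, post-laser plateau."""
    t = recipe.times()
    y = np.empty_like(t)
    pre = t < recipe.laser_on
    on = (t >= recipe.laser_on) & (t <= recipe.laser_off)
    post = t > recipe.laser_off
    y[pre] = recipe.background + recipe.amplitude
    tau = t[on] - recipe.laser_on
    y[on] = (recipe.background
             + recipe.amplitude * np.exp(recipe.decay_rate_k * tau)
             * on_factor(tau))
    y[post] = y[on][-1] if on.any() else recipe.background + recipe.amplitude
    if recipe.noise_sigma > 0:
        rng = np.random.default_rng(recipe.seed)
        y = y + recipe.noise_sigma * recipe.amplitude * \
            rng.standard_normal(y.size)
    return MSTTrace(times=t, intensities=y, laser_on=recipe.laser_on,
                    laser_off=recipe.laser_off,
                    trace_id=recipe.trace_id or f"{recipe.role}-{recipe.seed}",
                    role=recipe.role,
                    metadata={"recipe_seed": recipe.seed,
                              "truth_decay_rate_k": recipe.decay_rate_k,
                              "truth_soret_ST": recipe.soret_ST})


def generate_fluorophore_trace(recipe: TraceRecipe) -> MSTTrace:
    """Free-fluorophore trace: pure exponential decay during laser-on."""
    recipe.validate()
    if recipe.role != "fluorophore":
        raise RecipeError("recipe role must be 'fluorophore'")
    return _assemble(recipe, lambda tau: 1.0)


def generate_particle_trace(recipe: TraceRecipe,
                            library: ConcLibrary) -> MSTTrace:
    """Particle trace: decay times the library Conc(t) at the recipe's S_T."""
    recipe.validate()
    if recipe.role != "particle":
        raise RecipeError("recipe role must be 'particle'")
    curve = interpolate_conc_curve(library, recipe.soret_ST)
    return _assemble(recipe, lambda tau: curve.at(tau))


def generate_replicate_set(recipe: TraceRecipe, n: int, base_seed: int,
                           library: ConcLibrary | None = None
                           ) -> list[MSTTrace]:
    """n traces with identical truth, seeds base_seed..base_seed+n-1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = []
    for j in range(n):
        r = replace(recipe, seed=base_seed + j,
                    trace_id=f"{recipe.role}-rep{j}")
        if r.role == "particle":
            if library is None:
                raise ValueError("particle replicate set requires a library")
            out.append(generate_particle_trace(r, library))
        else:
            out.append(generate_fluorophore_trace(r))
    return out


def inject_aggregation_spikes(trace: MSTTrace, spike_times,
                              magnitude: float) -> MSTTrace:
    """Return a copy of the trace with additive jumps at the given times.

    Each spike lands on the sample nearest its requested time; the input
    trace is left unmodified.
    """
    spike_times = np.atleast_1d(np.asarray(spike_times, dtype=float))
    out = trace.copy_with()
    for st in spike_times:
        if st < trace.times[0] or st > trace.times[-1]:
            raise ValueError(
                f"spike time {st:g} s outside the trace span "
                f"[{trace.times[0]:g}, {trace.times[-1]:g}] s")
        out.intensities[int(np.argmin(np.abs(trace.times - st)))] += magnitude
    return out
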