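"""Two-stage Soret-coefficient extraction from MST traces.

Stage 1 fits the free-fluorophore trace with a lumped exponential,

    I_FF(t) = B + C exp(k t),

where k (1/s, negative for decay) absorbs temperature-related intensity
change (TRIC) and photobleaching.  Stage 2 carries that decay rate, fixed,
into the particle-trace model

    I_PS(t) = d0 + e0 exp(k t) Conc(t; S_T),

where Conc(t; S_T) is the simulated probe-region concentration from the
drift-diffusion forward model.  For each candidate S_T the model is linear
in (d0, e0), so the profile of least-squares error over the S_T dictionary
is evaluated in closed form; the minimising S_T, refined by a parabolic
step and a bounded polish on interpolated curves, is the estimate.

The API follows the Model/Results convention: construct a model from data,
call ``fit()``, inspect the Results object (estimates, uncertainties,
diagnostics, ``summary()``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import median_filter
from scipy.optimize import least_squares, minimize_scalar

from .traces import MSTTrace
from .transport import ConcLibrary, interpolate_conc_curve

__all__ = [
    "FluorophoreDecayModel", "FluorophoreDecayResults",
    "ParticleTraceModel", "ParticleTraceResults",
    "SoretModel", "SoretResults", "QCReport", "FitConvergenceError",
    "fit_fluorophore", "fit_particle_trace", "extract_soret", "qc_bumpiness",
]


class FitConvergenceError(RuntimeError):
    """Nonlinear fit failed; carries the best iterate and gradient norm."""

    def __init__(self, message: str, best_params=None, grad_norm=None):
        self.best_params = best_params
        self.grad_norm = grad_norm
        super().__init__(message)


# ---------------------------------------------------------------------------
# Stage 1: fluorophore decay
# ---------------------------------------------------------------------------

@dataclass
class FluorophoreDecayResults:
    """Fitted B + C exp(k t) over the laser-on window.

    ``decay_rate_k`` is the signed exponent coefficient: negative values
    decay.  ``bse`` are asymptotic standard errors from the Jacobian at the
    solution (NaN when degenerate).
    """

    background_B: float
    amplitude_C: float
    decay_rate_k: float
    sse: float
    nobs: int
    bse: np.ndarray
    converged: bool
    flags: tuple[str, ...] = ()
    trace_id: str = ""

    @property
    def params(self) -> np.ndarray:
        return np.array([self.background_B, self.amplitude_C,
                         self.decay_rate_k])

    def predict(self, t: np.ndarray) -> np.ndarray:
        """Model intensities at times t (t measured from laser-on)."""
        return self.background_B + self.amplitude_C * np.exp(
            self.decay_rate_k * np.asarray(t, dtype=float))

    def summary(self) -> str:
        lines = [
            "Fluorophore decay fit (I = B + C exp(k t))",
            "-" * 46,
            f"trace:         {self.trace_id}",
            f"nobs:          {self.nobs}",
            f"B (counts):    {self.background_B:.6g} (se {self.bse[0]:.3g})",
            f"C (counts):    {self.amplitude_C:.6g} (se {self.bse[1]:.3g})",
            f"k (1/s):       {self.decay_rate_k:.6g} (se {self.bse[2]:.3g})",
            f"SSE:           {self.sse:.6g}",
            f"converged:     {self.converged}",
        ]
        if self.flags:
            lines.append("flags:         " + ", ".join(self.flags))
        return "\n".join(lines)


class FluorophoreDecayModel:
    """Stage-1 model for a free-fluorophore MST trace."""

    def __init__(self, trace: MSTTrace):
        if trace.role != "fluorophore":
            raise ValueError("FluorophoreDecayModel requires a fluorophore trace")
        self.trace = trace
        self.t, self.y = trace.on_window()
        if np.any(self.y <= 0):
            warnings.warn("non-positive intensities in the fit window; "
                          "fit proceeds", stacklevel=2)

    def _initial_guess(self) -> np.ndarray:
        t, y = self.t, self.y
        n = t.size
        tail = float(np.mean(y[-max(n // 10, 3):]))
        head = float(np.mean(y[:max(n // 20, 2)]))
        c0 = head - tail
        # log-ratio decay estimate from two interior quantiles
        i1, i2 = n // 3, (2 * n) // 3
        with np.errstate(divide="ignore", invalid="ignore"):
            r1, r2 = y[i1] - tail, y[i2] - tail
            if r1 * r2 > 0 and t[i2] > t[i1]:
                k0 = float(np.log(r2 / r1) / (t[i2] - t[i1]))
            else:
                k0 = -1.0 / max(t[-1], 1.0)
        if not np.isfinite(k0) or k0 == 0.0:
            k0 = -0.1
        return np.array([tail, c0, k0])

    def fit(self) -> FluorophoreDecayResults:
        t, y = self.t, self.y
        scale = float(np.max(np.abs(y))) or 1.0
        if np.std(y) < 1e-12 * scale:
            # constant trace: decay amplitude and rate unidentifiable
            return FluorophoreDecayResults(
                background_B=float(np.mean(y)), amplitude_C=0.0,
                decay_rate_k=0.0, sse=float(np.sum((y - np.mean(y)) ** 2)),
                nobs=t.size, bse=np.array([0.0, np.nan, np.nan]),
                converged=True, flags=("decay-unidentifiable",),
                trace_id=self.trace.trace_id)

        def resid(p):
            return p[0] + p[1] * np.exp(np.clip(p[2] * t, -700, 700)) - y

        def jac(p):
            e = np.exp(np.clip(p[2] * t, -700, 700))
            return np.column_stack([np.ones_like(t), e, p[1] * t * e])

        sol = least_squares(resid, self._initial_guess(), jac=jac,
                            method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
                            max_nfev=2000)
        grad_norm = float(np.linalg.norm(sol.grad))
        if not sol.success:
            raise FitConvergenceError(
                f"fluorophore fit did not converge: {sol.message} "
                f"(gradient norm {grad_norm:.3g})",
                best_params=sol.x, grad_norm=grad_norm)
        r = resid(sol.x)
        sse = float(r @ r)
        dof = max(t.size - 3, 1)
        J = jac(sol.x)
        flags: list[str] = []
        try:
            cov = sse / dof * np.linalg.inv(J.T @ J)
            bse = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            bse = np.full(3, np.nan)
            flags.append("covariance-singular")
        if abs(sol.x[1]) < 1e-9 * scale:
            flags.append("decay-unidentifiable")
        return FluorophoreDecayResults(
            background_B=float(sol.x[0]), amplitude_C=float(sol.x[1]),
            decay_rate_k=float(sol.x[2]), sse=sse, nobs=t.size, bse=bse,
            converged=True, flags=tuple(flags), trace_id=self.trace.trace_id)


def fit_fluorophore(trace: MSTTrace) -> FluorophoreDecayResults:
    """Fit the lumped exponential decay to a free-fluorophore trace."""
    return FluorophoreDecayModel(trace).fit()


# ---------------------------------------------------------------------------
# Stage 2: particle trace
# ---------------------------------------------------------------------------

def _linear_subfit(y: np.ndarray, basis: np.ndarray
                   ) -> tuple[float, float, float]:
    """Closed-form LSQ of y ~ d0 + e0*basis; returns (d0, e0, sse)."""
    n = y.size
    sb = float(basis.sum())
    sbb = float(basis @ basis)
    sy = float(y.sum())
    sby = float(basis @ y)
    det = n * sbb - sb * sb
    if det <= 1e-14 * max(n * sbb, 1.0):
        d0, e0 = sy / n, 0.0
    else:
        e0 = (n * sby - sb * sy) / det
        d0 = (sy - sb * e0) / n
    r = y - d0 - e0 * basis
    return d0, e0, float(r @ r)


@dataclass
class ParticleTraceResults:
    """Stage-2 fit: S_T from the SSE profile over the Conc(t) dictionary.

    ``soret_grid``/``sse_profile`` hold the full profile; ``soret_parabolic``
    is the 3-point parabolic refinement and ``soret_ST`` the final estimate
    after the bounded polish on interpolated curves.  Flags:
    ``range-limited`` (minimum at the dictionary boundary) and
    ``weakly-identified`` (thermophoretic signal below the noise floor).
    """

    soret_ST: float
    background_d0: float
    amplitude_e0: float
    sse: float
    nobs: int
    soret_grid: np.ndarray
    sse_profile: np.ndarray
    soret_parabolic: float
    decay_rate_k: float
    flags: tuple[str, ...] = ()
    trace_id: str = ""
    _library: ConcLibrary | None = dc_field(default=None, repr=False)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.background_d0, self.amplitude_e0,
                         self.soret_ST])

    def predict(self, t: np.ndarray) -> np.ndarray:
        """Model intensities at times t (from laser-on), at the fitted S_T."""
        if self._library is None:
            raise ValueError("library not retained; cannot predict")
        conc = interpolate_conc_curve(self._library, self.soret_ST).at(t)
        return self.background_d0 + self.amplitude_e0 * np.exp(
            self.decay_rate_k * np.asarray(t, float)) * conc

    def summary(self) -> str:
        lines = [
            "Particle trace fit (I = d0 + e0 exp(k t) Conc(t; S_T))",
            "-" * 54,
            f"trace:          {self.trace_id}",
            f"nobs:           {self.nobs}",
            f"k fixed (1/s):  {self.decay_rate_k:.6g}",
            f"S_T (1/K):      {self.soret_ST:.6g}",
            f"d0 (counts):    {self.background_d0:.6g}",
            f"e0 (counts):    {self.amplitude_e0:.6g}",
            f"SSE:            {self.sse:.6g}",
            f"profile range:  [{self.soret_grid[0]:g}, {self.soret_grid[-1]:g}] 1/K",
        ]
        if self.flags:
            lines.append("flags:          " + ", ".join(self.flags))
        return "\n".join(lines)

    def plot(self, ax=None):
        """SSE profile over the S_T dictionary with the refined minimum."""
        import matplotlib.pyplot as plt
        ax = ax or plt.gca()
        ax.plot(self.soret_grid, self.sse_profile, ".-")
        ax.axvline(self.soret_ST, color="r", lw=0.8)
        ax.set_xlabel("$S_T$ (1/K)")
        ax.set_ylabel("SSE")
        return ax


class ParticleTraceModel:
    """Stage-2 model: particle trace + fixed decay rate + Conc(t) dictionary."""

    def __init__(self, trace: MSTTrace, decay_rate_k: float,
                 library: ConcLibrary):
        if trace.role != "particle":
            raise ValueError("ParticleTraceModel requires a particle trace")
        self.trace = trace
        self.decay_rate_k = float(decay_rate_k)
        self.library = library
        self.t, self.y = trace.on_window()
        # dictionary curves resampled once to the trace's on-window times
        self._conc = np.vstack([
            np.interp(self.t, library.times, library.values[i])
            for i in range(library.soret_values.size)])
        self._decay = np.exp(np.clip(self.decay_rate_k * self.t, -700, 700))

    def _sse_at(self, soret: float) -> tuple[float, float, float]:
        conc = interpolate_conc_curve(self.library, soret).at(self.t)
        return _linear_subfit(self.y, self._decay * conc)

    def fit(self) -> ParticleTraceResults:
        grid = self.library.soret_values
        prof = np.empty(grid.size)
        lin = []
        for i in range(grid.size):
            d0, e0, sse = _linear_subfit(self.y, self._decay * self._conc[i])
            prof[i] = sse
            lin.append((d0, e0))
        imin = int(np.argmin(prof))
        flags: list[str] = []
        if imin in (0, grid.size - 1):
            flags.append("range-limited")
            s_par = s_hat = float(grid[imin])
            d0, e0 = lin[imin]
            sse_hat = float(prof[imin])
        else:
            # parabolic refinement through the minimum and its neighbours
            s0, s1, s2 = grid[imin - 1:imin + 2]
            f0, f1, f2 = prof[imin - 1:imin + 2]
            denom = (s0 - s1) * (s0 - s2) * (s1 - s2)
            a = (s2 * (f1 - f0) + s1 * (f0 - f2) + s0 * (f2 - f1)) / denom
            if a > 0:
                b = (s2 ** 2 * (f0 - f1) + s1 ** 2 * (f2 - f0)
                     + s0 ** 2 * (f1 - f2)) / denom
                s_par = float(np.clip(-b / (2 * a), s0, s2))
            else:
                s_par = float(grid[imin])
            # bounded polish on interpolated dictionary curves
            res = minimize_scalar(lambda s: self._sse_at(s)[2],
                                  bounds=(float(s0), float(s2)),
                                  method="bounded",
                                  options={"xatol": 1e-7})
            s_hat = float(res.x)
            d0, e0, sse_hat = self._sse_at(s_hat)
            if sse_hat > prof[imin]:
                s_hat, (d0, e0), sse_hat = float(grid[imin]), lin[imin], float(prof[imin])
        # identifiability: thermophoretic signal vs residual noise
        conc_hat = interpolate_conc_curve(self.library, s_hat).at(self.t)
        signal = abs(e0) * float(np.max(np.abs(self._decay * (conc_hat - 1.0))))
        noise_rms = np.sqrt(sse_hat / max(self.t.size - 2, 1))
        scale = float(np.max(np.abs(self.y))) or 1.0
        if signal <= 3.0 * noise_rms + 1e-9 * scale:
            flags.append("weakly-identified")
        return ParticleTraceResults(
            soret_ST=s_hat, background_d0=d0, amplitude_e0=e0, sse=sse_hat,
            nobs=self.t.size, soret_grid=grid.copy(), sse_profile=prof,
            soret_parabolic=s_par, decay_rate_k=self.decay_rate_k,
            flags=tuple(flags), trace_id=self.trace.trace_id,
            _library=self.library)


def fit_particle_trace(trace: MSTTrace, decay_rate_k: float,
                       library: ConcLibrary) -> ParticleTraceResults:
    """Extract S_T from one particle trace with the stage-1 decay rate fixed."""
    return ParticleTraceModel(trace, decay_rate_k, library).fit()


# ---------------------------------------------------------------------------
# Replicate aggregation
# ---------------------------------------------------------------------------

@dataclass
class SoretResults:
    """Replicate-aggregated Soret coefficient: mean +/- sample SD over fits."""

    soret_mean: float
    soret_sd: float
    n: int
    decay_rate_k: float
    fluorophore_fits: list[FluorophoreDecayResults]
    particle_fits: list[ParticleTraceResults]
    flags: tuple[str, ...] = ()
    condition: str = ""

    @property
    def soret_values(self) -> np.ndarray:
        return np.array([f.soret_ST for f in self.particle_fits])

    def to_frame(self):
        """One-row report table: condition, n, mean, SD, flags."""
        import pandas as pd
        return pd.DataFrame([{
            "condition": self.condition, "n": self.n,
            "mean_ST_per_K": self.soret_mean, "sd_ST_per_K": self.soret_sd,
            "decay_rate_per_s": self.decay_rate_k,
            "flags": ";".join(self.flags),
        }])

    def summary(self, literature_ST: float | None = None) -> str:
        sd = "n/a" if np.isnan(self.soret_sd) else f"{self.soret_sd:.3g}"
        lines = [
            "Soret coefficient extraction",
            "=" * 44,
            f"condition:        {self.condition or '-'}",
            f"replicates (n):   {self.n}",
            f"decay rate k:     {self.decay_rate_k:.6g} 1/s "
            f"(from {len(self.fluorophore_fits)} fluorophore trace(s))",
            f"mean S_T:         {self.soret_mean:.4g} 1/K",
            f"SD S_T:           {sd} 1/K",
        ]
        if literature_ST is not None:
            lines.append(f"literature S_T:   {literature_ST:.4g} 1/K")
        if self.flags:
            lines.append("flags:            " + ", ".join(self.flags))
        return "\n".join(lines)


class SoretModel:
    """Full two-stage extraction over replicate fluorophore/particle traces."""

    def __init__(self, fluorophore_traces: list[MSTTrace],
                 particle_traces: list[MSTTrace], library: ConcLibrary,
                 condition: str = ""):
        if not fluorophore_traces:
            raise ValueError("at least one fluorophore trace required")
        if not particle_traces:
            raise ValueError("at least one particle trace required")
        self.fluorophore_traces = list(fluorophore_traces)
        self.particle_traces = list(particle_traces)
        self.library = library
        self.condition = condition

    def fit(self) -> SoretResults:
        ff = [fit_fluorophore(tr) for tr in self.fluorophore_traces]
        k = float(np.mean([f.decay_rate_k for f in ff]))
        pf = [fit_particle_trace(tr, k, self.library)
              for tr in self.particle_traces]
        vals = np.array([f.soret_ST for f in pf])
        n = vals.size
        sd = float(np.std(vals, ddof=1)) if n > 1 else float("nan")
        flags: list[str] = []
        if all(f.flags for f in pf):
            flags.append("all-replicates-flagged")
        return SoretResults(soret_mean=float(np.mean(vals)), soret_sd=sd,
                            n=n, decay_rate_k=k, fluorophore_fits=ff,
                            particle_fits=pf, flags=tuple(flags),
                            condition=self.condition)


def extract_soret(fluorophore_traces: list[MSTTrace],
                  particle_traces: list[MSTTrace], library: ConcLibrary,
                  condition: str = "") -> SoretResults:
    """Two-stage extraction: mean decay rate, per-replicate S_T, mean +/- SD."""
    return SoretModel(fluorophore_traces, particle_traces, library,
                      condition).fit()


# ---------------------------------------------------------------------------
# Trace quality control
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Aggregation-spike screen: counts of sudden jumps in the trace."""

    spike_count: int
    spike_times: np.ndarray
    max_jump_z: float
    verdict: str            # "pass" | "flag"
    threshold: float
    window: int
    trace_id: str = ""


def qc_bumpiness(trace: MSTTrace, window: int = 11,
                 threshold: float = 5.0) -> QCReport:
    """Screen a trace for aggregation artefacts ("bumpiness").

    Residuals from a rolling-median detrend are z-scored against a robust
    noise scale (the larger of the residual MAD and the first-difference
    MAD, so a smooth decay does not read as noise); samples with |z| above
    ``threshold`` count as spikes.  The verdict is "flag" iff any spike is
    found.
    """
    y = trace.intensities
    if y.size < window + 2:
        raise ValueError(
            f"trace too short for QC: {y.size} samples < window {window} + 2")
    med = median_filter(y, size=window, mode="nearest")
    resid = y - med
    d = np.diff(y)
    sig_d = 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)
    sig_r = 1.4826 * float(np.median(np.abs(resid)))
    sigma = max(sig_d, sig_r)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, np.abs(resid) / sigma,
                     np.where(np.abs(resid) > 0, np.inf, 0.0))
    spikes = z > threshold
    max_z = float(np.max(z)) if z.size else 0.0
    count = int(np.count_nonzero(spikes))
    return QCReport(spike_count=count, spike_times=trace.times[spikes],
                    max_jump_z=max_z,
                    verdict="flag" if count > 0 else "pass",
                    threshold=threshold, window=window,
                    trace_id=trace.trace_id)
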