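"""Thermophoretic drift-diffusion of colloid particles and the Conc(t) observable.

The particle flux in a temperature gradient is

    J = -D grad(c) - c D_T grad(T),        D_T = D * S_T,

so the Soret coefficient S_T sets both the direction (positive = thermophobic,
depletion at the warm focus) and the magnitude of the migration.  This module
integrates the conservation law dc/dt = -div(J) on the axisymmetric grid with
no-flux walls, one-way coupled to a TemperatureSeries (heat establishes within
a second; mass transport takes the whole 20 s laser-on phase).

Face fluxes use Scharfetter-Gummel exponential fitting.  Because the drift
velocity derives from the potential S_T*T, this discretisation reproduces the
Boltzmann steady state c ~ exp(-S_T (T - T_ref)) exactly at the grid nodes,
is monotone at any cell Peclet number, and conserves mass to solver precision.

The measurement reduces the field to Conc(t): the probe-region mean
concentration normalised to 1 at laser-on.  Families of Conc(t) curves indexed
by S_T (the fitting dictionary) are built and cached by ConcLibrary.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grids import Grid
from .heat import TemperatureSeries

__all__ = [
    "TransportParams", "ConcentrationSeries", "ProbeRegion", "ConcCurve",
    "ConcLibrary", "TransportError", "solve_drift_diffusion",
    "reduce_to_conc_curve", "build_conc_library", "interpolate_conc_curve",
    "transport_times", "simulate_conc_curve",
]


class TransportError(RuntimeError):
    """Raised when the drift-diffusion solve violates its contracts."""


@dataclass(frozen=True)
class TransportParams:
    """Particle transport coefficients.

    ``thermal_diffusion_DT`` is always D * S_T; only D and S_T are free.
    The default D is the 200 nm polystyrene value used throughout.
    """

    diffusion_D: float = 2.25e-12       # m^2/s
    soret_ST: float = 0.0               # 1/K, signed
    initial_concentration: float = 1.0  # mol/m^3

    def __post_init__(self) -> None:
        if self.diffusion_D <= 0:
            raise ValueError("diffusion_D must be > 0")
        if self.initial_concentration <= 0:
            raise ValueError("initial_concentration must be > 0")

    @property
    def thermal_diffusion_DT(self) -> float:
        return self.diffusion_D * self.soret_ST

    def with_soret(self, soret_ST: float) -> "TransportParams":
        return TransportParams(self.diffusion_D, soret_ST,
                               self.initial_concentration)


@dataclass
class ConcentrationSeries:
    """Particle concentration fields over time (mol/m^3, shape (nt, nr, nz))."""

    times: np.ndarray
    fields: np.ndarray
    grid: Grid
    max_cell_peclet: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.fields.shape != (self.times.size, *self.grid.shape):
            raise ValueError("fields shape does not match times/grid")

    def total_mass(self) -> np.ndarray:
        """Volume-integrated amount per stored time (mol)."""
        return np.einsum("tij,ij->t", self.fields, self.grid.volumes)

    def mass_drift(self) -> float:
        m = self.total_mass()
        return float(np.max(np.abs(m - m[0])) / m[0])


@dataclass(frozen=True)
class ProbeRegion:
    """Optical detection volume centred on the laser focus.

    kind 'disk' is the 3-D probe (planar diameter x thickness), 'circle' the
    2-D area average in the focal plane, 'line' the 1-D radial line integral
    through the focus.
    """

    kind: str = "circle"
    planar_diameter: float = 1.30e-4  # m
    thickness: float = 2.0e-5         # m, used for kind='disk'

    def __post_init__(self) -> None:
        if self.kind not in ("disk", "circle", "line"):
            raise ValueError("kind must be 'disk', 'circle' or 'line'")
        if self.planar_diameter <= 0:
            raise ValueError("planar_diameter must be > 0")
        if self.kind == "disk" and self.thickness <= 0:
            raise ValueError("disk probe requires thickness > 0")

    @property
    def radius(self) -> float:
        return self.planar_diameter / 2.0


@dataclass
class ConcCurve:
    """Normalised probe-mean concentration vs time; values[0] = 1."""

    times: np.ndarray
    values: np.ndarray
    soret_ST: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if abs(self.values[0] - 1.0) > 1e-9:
            raise ValueError("Conc curve must be normalised to 1 at t = 0")
        if np.any(self.values <= 0):
            raise ValueError("Conc values must be positive")

    def at(self, t: np.ndarray) -> np.ndarray:
        """Values resampled to times t (linear; clamped at the ends)."""
        return np.interp(t, self.times, self.values)

    def depletion_depth(self) -> float:
        """max |1 - Conc(t)| over the curve."""
        return float(np.max(np.abs(1.0 - self.values)))


def _bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x / (e^x - 1), the Scharfetter-Gummel weighting, B(0) = 1."""
    out = np.empty_like(x)
    small = np.abs(x) < 1e-10
    out[small] = 1.0 - 0.5 * x[small]
    out[~small] = x[~small] / np.expm1(x[~small])
    return out


def _sg_matrix(grid: Grid, D: float, soret: float,
               T_field: np.ndarray) -> tuple[sp.csr_matrix, float]:
    """Assemble the negative divergence of the SG flux; returns (A, max |Pe|).

    The face Peclet number is Pe = -S_T * (T_b - T_a): dimensionless, and
    independent of D because the drift velocity is itself proportional to D.
    """
    nr, nz = grid.shape
    n = grid.n_cells
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    max_pe = 0.0

    def add(a_idx, b_idx, g, pe):
        nonlocal max_pe
        max_pe = max(max_pe, float(np.max(np.abs(pe))) if pe.size else 0.0)
        bm, bp = _bernoulli(-pe), _bernoulli(pe)
        a, b = a_idx.ravel(), b_idx.ravel()
        gm, gp = (g * bm).ravel(), (g * bp).ravel()
        # F_ab = g (B(-Pe) c_a - B(Pe) c_b); +F out of a, -F out of b
        np.add.at(diag, a, gm)
        np.add.at(diag, b, gp)
        rows.extend([a, b])
        cols.extend([b, a])
        vals.extend([-gp, -gm])

    i = np.arange(nr - 1)[:, None]
    kz = np.arange(nz)[None, :]
    add(i * nz + kz, (i + 1) * nz + kz, grid.radial_conductances(D),
        -soret * (T_field[1:, :] - T_field[:-1, :]))
    i = np.arange(nr)[:, None]
    kz = np.arange(nz - 1)[None, :]
    add(i * nz + kz, i * nz + kz + 1, grid.axial_conductances(D),
        -soret * (T_field[:, 1:] - T_field[:, :-1]))

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sp.csr_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n, n))
    return A, max_pe


def transport_times(laser_on: float = 0.0, laser_off: float = 20.0,
                    dt_fine: float = 0.05, fine_window: float = 1.0,
                    dt_coarse: float = 0.25, t_end: float | None = None
                    ) -> np.ndarray:
    """Default mass-transport time base for the 20 s laser-on phase."""
    t_end = laser_off if t_end is None else t_end
    t1 = min(laser_on + fine_window, t_end)
    n_fine = int(round((t1 - laser_on) / dt_fine))
    fine = laser_on + dt_fine * np.arange(n_fine + 1)
    if t_end <= t1 + dt_coarse / 2:
        return fine
    n_coarse = int(round((t_end - t1) / dt_coarse))
    coarse = t1 + dt_coarse * np.arange(1, n_coarse + 1)
    coarse[-1] = t_end
    return np.concatenate([fine, coarse])


def solve_drift_diffusion(params: TransportParams,
                          temperature: TemperatureSeries,
                          grid: Grid | None = None,
                          times: np.ndarray | None = None
                          ) -> ConcentrationSeries:
    """Integrate dc/dt = div(D grad c + c D S_T grad T), no-flux walls.

    The temperature field is frozen per implicit-Euler step (one-way
    coupling): the flux matrix is rebuilt whenever the interpolated
    temperature field changes, then reused (the field is steady after the
    ~0.2 s establishment transient).  Starts from a uniform concentration.
    """
    grid = grid if grid is not None else temperature.grid
    if grid.shape != temperature.grid.shape:
        raise ValueError("temperature series and grid shapes disagree")
    times = transport_times(temperature.laser_on) if times is None \
        else np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    vol = grid.volumes.ravel()
    c = np.full(grid.n_cells, params.initial_concentration)
    fields = np.empty((times.size, *grid.shape))
    fields[0] = c.reshape(grid.shape)
    max_pe = 0.0
    cached_T: np.ndarray | None = None
    lu = None
    lu_dt = None
    A = None
    for j in range(1, times.size):
        dt = times[j] - times[j - 1]
        T_now = temperature.field_at(times[j])
        if cached_T is None or np.max(np.abs(T_now - cached_T)) > 1e-9:
            A, pe = _sg_matrix(grid, params.diffusion_D, params.soret_ST, T_now)
            max_pe = max(max_pe, pe)
            cached_T = T_now
            lu = None
        if lu is None or abs(dt - lu_dt) > 1e-12:
            lu = spla.splu((sp.diags(vol / dt) + A).tocsc())
            lu_dt = dt
        c = lu.solve(vol / dt * c)
        if c.min() < -1e-10 * params.initial_concentration:
            raise TransportError(
                f"negative concentration ({c.min():.3e}) at t = {times[j]:g} s; "
                f"max face Peclet {max_pe:.3g} — refine the grid near the focus")
        fields[j] = c.reshape(grid.shape)
    return ConcentrationSeries(times=times, fields=fields, grid=grid,
                               max_cell_peclet=max_pe)


def steady_drift_diffusion(params: TransportParams, T_field: np.ndarray,
                           grid: Grid, n_pseudo_steps: int = 80,
                           dt_pseudo: float = 1.0e4) -> np.ndarray:
    """Long-time limit of the drift-diffusion field on a frozen temperature.

    Large implicit pseudo-time steps drive the field to the stationary
    solution (which depends on S_T only, not on D); mass is conserved
    throughout, fixing the normalisation.
    """
    A, _ = _sg_matrix(grid, params.diffusion_D, params.soret_ST, T_field)
    vol = grid.volumes.ravel()
    lu = spla.splu((sp.diags(vol / dt_pseudo) + A).tocsc())
    c = np.full(grid.n_cells, params.initial_concentration)
    for _ in range(n_pseudo_steps):
        c = lu.solve(vol / dt_pseudo * c)
    return c.reshape(grid.shape)


def _probe_weights(region: ProbeRegion, grid: Grid) -> np.ndarray:
    """(nr, nz) quadrature weights for the probe-region mean."""
    R = region.radius
    if R > grid.r_nodes[-1] + 1e-12:
        raise ValueError(
            f"probe radius {R:g} m exceeds the domain radius "
            f"{grid.r_nodes[-1]:g} m")
    rf = grid.r_faces
    if region.kind == "line":
        w_r = np.clip(np.minimum(rf[1:], R) - np.minimum(rf[:-1], R), 0.0, None)
    else:
        w_r = np.pi * np.clip(np.minimum(rf[1:], R) ** 2
                              - np.minimum(rf[:-1], R) ** 2, 0.0, None)
    w = np.zeros(grid.shape)
    if region.kind == "disk":
        h = region.thickness / 2.0
        if h > grid.z_nodes[-1] + 1e-12:
            raise ValueError("probe thickness exceeds the domain half-length")
        zf = grid.z_faces
        w_z = np.clip(np.minimum(zf[1:], h) - np.maximum(zf[:-1], -h), 0.0, None)
        w = w_r[:, None] * w_z[None, :]
    else:
        k0 = int(np.argmin(np.abs(grid.z_nodes)))
        w[:, k0] = w_r
    return w / w.sum()


def reduce_to_conc_curve(series: ConcentrationSeries,
                         region: ProbeRegion | None = None) -> ConcCurve:
    """Probe-region mean concentration per time, normalised at t = 0."""
    region = region or ProbeRegion()
    w = _probe_weights(region, series.grid)
    vals = np.einsum("tij,ij->t", series.fields, w)
    return ConcCurve(times=series.times, values=vals / vals[0])


def simulate_conc_curve(soret_ST: float, temperature: TemperatureSeries,
                        params: TransportParams | None = None,
                        region: ProbeRegion | None = None,
                        times: np.ndarray | None = None) -> ConcCurve:
    """Single forward run: drift-diffusion at one S_T reduced to Conc(t)."""
    params = (params or TransportParams()).with_soret(soret_ST)
    series = solve_drift_diffusion(params, temperature, times=times)
    curve = reduce_to_conc_curve(series, region)
    curve.soret_ST = soret_ST
    return curve


@dataclass
class ConcLibrary:
    """Family of Conc(t) curves on a sorted S_T grid, with provenance.

    ``values`` is (n_soret, nt); all curves share ``times``.  ``provenance``
    hashes the solver settings that produced the family, so a cached library
    is only ever reused against identical settings.
    """

    soret_values: np.ndarray
    times: np.ndarray
    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.soret_values = np.asarray(self.soret_values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.soret_values) <= 0):
            raise ValueError("soret grid must be strictly increasing")
        if self.values.shape != (self.soret_values.size, self.times.size):
            raise ValueError("values shape must be (n_soret, n_times)")

    @property
    def soret_min(self) -> float:
        return float(self.soret_values[0])

    @property
    def soret_max(self) -> float:
        return float(self.soret_values[-1])

    def curve(self, index: int) -> ConcCurve:
        return ConcCurve(self.times, self.values[index],
                         soret_ST=float(self.soret_values[index]))

    @classmethod
    def from_curves(cls, soret_values, curves: list[ConcCurve],
                    provenance: str = "") -> "ConcLibrary":
        times = curves[0].times
        for c in curves[1:]:
            if not np.array_equal(c.times, times):
                raise ValueError("all curves must share one time base")
        return cls(np.asarray(soret_values, float), times,
                   np.vstack([c.values for c in curves]), provenance)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values.T, columns=[f"{s:.17g}" for s in
                                                  self.soret_values])
        df.insert(0, "time_s", self.times)
        return df

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.17g")
        meta = {"provenance": self.provenance,
                "soret_per_K": [float(s) for s in self.soret_values]}
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConcLibrary":
        path = Path(path)
        df = pd.read_csv(path, float_precision="round_trip")
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        provenance = ""
        if meta_path.exists():
            provenance = json.loads(meta_path.read_text()).get("provenance", "")
        soret = np.array([float(c) for c in df.columns[1:]])
        return cls(soret, df["time_s"].to_numpy(),
                   df.iloc[:, 1:].to_numpy().T, provenance)

    def plot(self, ax=None):
        """Depletion curves vs time, one line per S_T."""
        import matplotlib.pyplot as plt
        ax = ax or plt.gca()
        for s, v in zip(self.soret_values, self.values):
            ax.plot(self.times, v, label=f"$S_T$ = {s:g} K$^{{-1}}$")
        ax.set_xlabel("time since laser-on (s)")
        ax.set_ylabel("Conc(t)")
        return ax


def _provenance_hash(soret_values, params: TransportParams,
                     temperature: TemperatureSeries, region: ProbeRegion,
                     times: np.ndarray) -> str:
    h = hashlib.sha256()
    for arr in (np.asarray(soret_values, float), temperature.grid.r_nodes,
                temperature.grid.z_nodes, temperature.times,
                temperature.steady_state, times):
        h.update(np.ascontiguousarray(arr).tobytes())
    h.update(temperature.fields[-1].tobytes())
    h.update(json.dumps([params.diffusion_D, params.initial_concentration,
                         region.kind, region.planar_diameter,
                         region.thickness, temperature.ambient]).encode())
    return h.hexdigest()[:16]


def build_conc_library(soret_values, temperature: TemperatureSeries,
                       params: TransportParams | None = None,
                       region: ProbeRegion | None = None,
                       times: np.ndarray | None = None,
                       cache_path: str | Path | None = None,
                       log=None) -> ConcLibrary:
    """One drift-diffusion run per S_T grid point, optionally disk-cached.

    The cache (a CSV + provenance sidecar) is reused only when its recorded
    provenance hash matches the requested solver settings; any mismatch
    triggers a rebuild with a warning, never a silent reuse.
    """
    soret_values = np.sort(np.asarray(soret_values, dtype=float))
    if np.any(np.diff(soret_values) <= 0):
        raise ValueError("soret grid contains duplicates")
    params = params or TransportParams()
    region = region or ProbeRegion()
    times = transport_times(temperature.laser_on) if times is None \
        else np.asarray(times, dtype=float)
    prov = _provenance_hash(soret_values, params, temperature, region, times)
    if cache_path is not None and Path(cache_path).exists():
        cached = ConcLibrary.from_csv(cache_path)
        if cached.provenance == prov and \
                np.allclose(cached.soret_values, soret_values):
            if log is not None:
                log("library cache hit: %s" % cache_path)
            return cached
        warnings.warn("conc-library cache provenance mismatch; rebuilding",
                      stacklevel=2)
    curves = [simulate_conc_curve(s, temperature, params, region, times)
              for s in soret_values]
    lib = ConcLibrary.from_curves(soret_values, curves, provenance=prov)
    if cache_path is not None:
        lib.to_csv(cache_path)
        if log is not None:
            log("library cache written: %s" % cache_path)
    return lib


def interpolate_conc_curve(library: ConcLibrary, soret: float) -> ConcCurve:
    """Conc(t) at an off-grid S_T by pointwise interpolation.

    Linear between the bracketing curves (the probe-averaged depletion is
    very nearly linear in S_T over the default grid spacing); exact at grid
    points; refuses extrapolation.
    """
    s = library.soret_values
    if not s[0] - 1e-12 <= soret <= s[-1] + 1e-12:
        raise ValueError(
            f"S_T = {soret:g} outside library range [{s[0]:g}, {s[-1]:g}] K^-1")
    nearest = int(np.argmin(np.abs(s - soret)))
    if abs(s[nearest] - soret) <= 1e-12 * max(1.0, abs(soret)):
        vals = library.values[nearest].copy()
    else:
        j = int(np.clip(np.searchsorted(s, soret), 1, s.size - 1))
        w = (soret - s[j - 1]) / (s[j] - s[j - 1])
        vals = (1.0 - w) * library.values[j - 1] + w * library.values[j]
    return ConcCurve(library.times, vals, soret_ST=float(soret))
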