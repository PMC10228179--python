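"""Laser-induced heating of the capillary sample.

An IR laser focused at the capillary centre deposits power with a Gaussian
transverse profile and Beer-Lambert attenuation along the beam, locally
heating the aqueous sample by a few kelvin.  This module computes that
temperature field: the volumetric heat source, the steady-state conduction
solution, and the transient establishment of the gradient after the laser
switches on (and its relaxation after switch-off).

Only conduction is modelled; convection is negligible in the thin-capillary
geometry the instrument was designed around.  The glass wall is not meshed:
reflection and absorption enter through the lumped coefficients R_c and A_c,
and the outer boundary holds the ambient temperature (Dirichlet).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grids import CapillaryGeometry, Grid

__all__ = [
    "LaserSource", "Medium", "TemperatureSeries", "HeatSolverError",
    "EstablishmentNotReachedError", "heat_source_field",
    "solve_steady_temperature", "solve_transient_temperature",
    "gradient_establishment_time", "simulate_temperature", "heating_times",
]


class HeatSolverError(RuntimeError):
    """Raised when the conduction solve fails or produces non-finite values."""


class EstablishmentNotReachedError(RuntimeError):
    """Raised when a requested establishment fraction is never attained."""

    def __init__(self, fraction: float, attained: float):
        self.fraction = fraction
        self.attained = attained
        super().__init__(
            f"focal temperature rise never reached fraction {fraction:g} of "
            f"steady state within the series (final fraction attained: "
            f"{attained:.4f})")


@dataclass(frozen=True)
class LaserSource:
    """IR heating laser: power, capillary losses and beam geometry.

    ``beam_diameter`` is the 1/e^2 intensity diameter, so the Gaussian
    widths default to sigma = diameter/4.  ``reflection_Rc`` and
    ``absorption_Ac`` are the lumped reflection coefficient and absorption
    coefficient (1/m) of the glass capillary.
    """

    power_Q0: float = 0.05          # W
    reflection_Rc: float = 0.05     # dimensionless
    absorption_Ac: float = 50.0     # 1/m  (0.50 cm^-1)
    beam_diameter: float = 1.0e-5   # m, 1/e^2 intensity diameter
    focus_r0: float = 0.0           # m
    focus_z0: float = 0.0           # m
    sigma_x: float | None = None    # m; derived from beam_diameter if None
    sigma_y: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.reflection_Rc < 1.0:
            raise ValueError("reflection_Rc must be in [0, 1)")
        if self.absorption_Ac < 0:
            raise ValueError("absorption_Ac must be >= 0")
        if self.power_Q0 < 0:
            raise ValueError("power_Q0 must be >= 0")
        if self.beam_diameter <= 0:
            raise ValueError("beam_diameter must be > 0")
        sig = self.beam_diameter / 4.0
        if self.sigma_x is None:
            object.__setattr__(self, "sigma_x", sig)
        if self.sigma_y is None:
            object.__setattr__(self, "sigma_y", sig)

    @property
    def sigma(self) -> float:
        """Axisymmetric transverse width (requires sigma_x == sigma_y)."""
        if not np.isclose(self.sigma_x, self.sigma_y):
            raise ValueError("axisymmetric solver requires sigma_x == sigma_y")
        return float(self.sigma_x)


@dataclass(frozen=True)
class Medium:
    """Thermal properties of the sample; defaults are room-temperature water."""

    thermal_conductivity: float = 0.60   # W/(m K)
    density: float = 998.0               # kg/m^3
    heat_capacity: float = 4182.0        # J/(kg K)
    ambient_temperature: float = 293.15  # K

    def __post_init__(self) -> None:
        for name in ("thermal_conductivity", "density", "heat_capacity",
                     "ambient_temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def diffusivity(self) -> float:
        return self.thermal_conductivity / (self.density * self.heat_capacity)


@dataclass
class TemperatureSeries:
    """Transient temperature solution plus its steady-state limit.

    ``fields`` holds the absolute temperature (K) per grid node per stored
    time; ``steady_state`` is the laser-on steady solution on the same grid.
    All temperatures are bounded below by the ambient (non-negative source,
    ambient Dirichlet wall).
    """

    times: np.ndarray                 # s
    fields: np.ndarray                # (nt, nr, nz), K
    steady_state: np.ndarray          # (nr, nz), K
    ambient: float                    # K
    grid: Grid
    laser_on: float
    laser_off: float
    focus: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.fields.shape != (self.times.size, *self.grid.shape):
            raise ValueError("fields shape does not match times/grid")
        if self.fields.min() < self.ambient - 1e-9:
            raise ValueError("temperature below ambient: solver defect")
        if self.focus is None:
            self.focus = tuple(np.unravel_index(
                int(np.argmax(self.steady_state)), self.grid.shape))

    def rise(self) -> np.ndarray:
        return self.fields - self.ambient

    def steady_rise(self) -> np.ndarray:
        return self.steady_state - self.ambient

    def field_at(self, t: float) -> np.ndarray:
        """Absolute temperature field at time t (linear in time, clamped)."""
        if t <= self.times[0]:
            return self.fields[0]
        if t >= self.times[-1]:
            return self.fields[-1]
        j = int(np.searchsorted(self.times, t))
        w = (t - self.times[j - 1]) / (self.times[j] - self.times[j - 1])
        return (1.0 - w) * self.fields[j - 1] + w * self.fields[j]

    def focal_rise(self) -> np.ndarray:
        i, k = self.focus
        return self.fields[:, i, k] - self.ambient


def heat_source_field(laser: LaserSource, geom: CapillaryGeometry,
                      grid: Grid) -> np.ndarray:
    """Volumetric heating power density q(r, z) in W/m^3.

    Gaussian transverse profile of width sigma centred on the axis, with
    Beer-Lambert attenuation exp(-A_c (z + L)) along the beam.  The field is
    normalised so the discrete volume integral equals the absorbed power
    Q0 (1 - R_c) (1 - exp(-A_c * 2L)) exactly.
    """
    sigma = laser.sigma
    n_waist = int(np.sum(grid.r_nodes < 2.0 * sigma))
    if n_waist < 4:
        raise ValueError(
            f"grid does not resolve the beam waist: {n_waist} radial nodes "
            f"inside 2*sigma = {2 * sigma:.3g} m (need >= 4); refine the "
            "radial grid near the axis")
    if grid.r_nodes[-1] < geom.capillary_radius - 1e-12 or \
            grid.z_nodes[0] > -geom.domain_axial_half_length + 1e-12:
        raise ValueError("grid does not cover the capillary domain")
    L = geom.domain_axial_half_length
    r = grid.r_nodes[:, None] - laser.focus_r0
    z = grid.z_nodes[None, :]
    q = np.exp(-r ** 2 / (2.0 * sigma ** 2)) * np.exp(-laser.absorption_Ac * (z + L))
    absorbed = laser.power_Q0 * (1.0 - laser.reflection_Rc) * \
        (1.0 - np.exp(-laser.absorption_Ac * 2.0 * L))
    total = float(np.sum(q * grid.volumes))
    if absorbed == 0.0:
        return np.zeros_like(q)
    return q * (absorbed / total)


def _conduction_matrix(medium: Medium, grid: Grid) -> sp.csr_matrix:
    """Discrete negative divergence of k*grad(T): FV Laplacian, no BCs."""
    k = medium.thermal_conductivity
    nr, nz = grid.shape
    n = grid.n_cells
    rows, cols, vals = [], [], []
    diag = np.zeros(n)

    def add_faces(a_idx, b_idx, g):
        a, b, gf = a_idx.ravel(), b_idx.ravel(), g.ravel()
        rows.extend([a, b])
        cols.extend([b, a])
        vals.extend([-gf, -gf])
        np.add.at(diag, a, gf)
        np.add.at(diag, b, gf)

    i = np.arange(nr - 1)[:, None]
    kz = np.arange(nz)[None, :]
    add_faces(i * nz + kz, (i + 1) * nz + kz, grid.radial_conductances(k))
    i = np.arange(nr)[:, None]
    kz = np.arange(nz - 1)[None, :]
    add_faces(i * nz + kz, i * nz + kz + 1, grid.axial_conductances(k))

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    return sp.csr_matrix((np.concatenate(vals),
                          (np.concatenate(rows), np.concatenate(cols))),
                         shape=(n, n))


def _apply_dirichlet(A: sp.csr_matrix, mask: np.ndarray) -> sp.csr_matrix:
    """Replace rows of Dirichlet nodes with identity (solve in rise form)."""
    n = A.shape[0]
    flat = mask.ravel()
    keep = sp.diags((~flat).astype(float))
    fix = sp.diags(flat.astype(float))
    return (keep @ A + fix).tocsc()


def solve_steady_temperature(medium: Medium, source: np.ndarray,
                             geom: CapillaryGeometry, grid: Grid) -> np.ndarray:
    """Steady conduction solution: k * lap(T) + q = 0, ambient walls.

    Returns the absolute temperature field (K), shape (nr, nz).
    """
    A = _apply_dirichlet(_conduction_matrix(medium, grid), grid.boundary_mask())
    b = (source * grid.volumes).ravel()
    b[grid.boundary_mask().ravel()] = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("error", spla.MatrixRankWarning)
        try:
            rise = spla.spsolve(A, b)
        except Exception as exc:  # singular / rank warnings
            raise HeatSolverError(
                "steady conduction system is singular or ill-conditioned; "
                "check for degenerate grid spacing or a grid that does not "
                "touch the Dirichlet wall") from exc
    if not np.all(np.isfinite(rise)):
        bad = np.unravel_index(int(np.argmax(~np.isfinite(rise))), grid.shape)
        raise HeatSolverError(f"non-finite steady temperature at node {bad}")
    rise = rise.reshape(grid.shape)
    return medium.ambient_temperature + np.maximum(rise, 0.0)


def solve_transient_temperature(medium: Medium, source: np.ndarray,
                                geom: CapillaryGeometry, grid: Grid,
                                times: np.ndarray, laser_on: float,
                                laser_off: float,
                                steady: np.ndarray | None = None
                                ) -> TemperatureSeries:
    """Implicit-Euler transient conduction through a laser on/off cycle.

    rho c_p dT/dt = k lap(T) + q(t), with q switched on over
    (laser_on, laser_off].  The initial field at ``times[0]`` is ambient.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if not laser_on < laser_off:
        raise ValueError("laser_on must precede laser_off")
    mask = grid.boundary_mask().ravel()
    K = _conduction_matrix(medium, grid)
    cap = (medium.density * medium.heat_capacity * grid.volumes).ravel()
    b_on = (source * grid.volumes).ravel()
    b_on[mask] = 0.0

    n = grid.n_cells
    fields = np.empty((times.size, *grid.shape))
    rise = np.zeros(n)
    fields[0] = medium.ambient_temperature
    lu_cache: dict[float, spla.SuperLU] = {}
    for j in range(1, times.size):
        dt = times[j] - times[j - 1]
        key = round(dt, 12)
        if key not in lu_cache:
            A = _apply_dirichlet(K + sp.diags(cap / dt), grid.boundary_mask())
            lu_cache[key] = spla.splu(A)
        rhs = cap / dt * rise
        if laser_on + 1e-12 < times[j] <= laser_off + 1e-9:
            rhs = rhs + b_on
        rhs[mask] = 0.0
        rise = lu_cache[key].solve(rhs)
        if not np.all(np.isfinite(rise)):
            bad = np.unravel_index(int(np.argmax(~np.isfinite(rise))), grid.shape)
            raise HeatSolverError(
                f"non-finite temperature at step {j} (t = {times[j]:g} s), "
                f"node {bad}")
        fields[j] = medium.ambient_temperature + np.maximum(rise.reshape(grid.shape), 0.0)
    if steady is None:
        steady = solve_steady_temperature(medium, source, geom, grid)
    return TemperatureSeries(times=times, fields=fields, steady_state=steady,
                             ambient=medium.ambient_temperature, grid=grid,
                             laser_on=laser_on, laser_off=laser_off)


def gradient_establishment_time(series: TemperatureSeries,
                                fraction: float) -> float:
    """Time after laser-on to reach ``fraction`` of the steady focal rise.

    Linear interpolation between stored time points; ``fraction`` in (0, 1)
    (0 returns 0 immediately).
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0.0:
        return 0.0
    if series.times[-1] <= series.laser_on:
        raise ValueError("series does not include a laser-on segment")
    i, k = series.focus
    target = fraction * (series.steady_state[i, k] - series.ambient)
    rise = series.focal_rise()
    t = series.times
    on = t >= series.laser_on
    rise, t = rise[on], t[on]
    above = rise >= target
    if not above.any():
        raise EstablishmentNotReachedError(fraction, float(rise[-1] / (target / fraction)))
    j = int(np.argmax(above))
    if j == 0:
        return float(t[0] - series.laser_on)
    w = (target - rise[j - 1]) / (rise[j] - rise[j - 1])
    return float(t[j - 1] + w * (t[j] - t[j - 1]) - series.laser_on)


def heating_times(laser_on: float = 0.0, laser_off: float = 20.0,
                  dt_fine: float = 0.01, fine_window: float = 1.0,
                  dt_coarse: float = 0.05, t_end: float | None = None
                  ) -> np.ndarray:
    """Default transient time base: fine steps through the establishment
    transient, coarser steps for the remainder of the cycle."""
    t_end = laser_off if t_end is None else t_end
    t1 = min(laser_on + fine_window, t_end)
    n_fine = int(round((t1 - laser_on) / dt_fine))
    fine = laser_on + dt_fine * np.arange(n_fine + 1)
    if t_end <= t1 + dt_coarse / 2:
        return fine
    n_coarse = int(round((t_end - t1) / dt_coarse))
    coarse = t1 + dt_coarse * np.arange(1, n_coarse + 1)
    coarse[-1] = t_end  # land exactly on the end of the window
    return np.concatenate([fine, coarse])


def simulate_temperature(laser: LaserSource | None = None,
                         geom: CapillaryGeometry | None = None,
                         medium: Medium | None = None,
                         grid: Grid | None = None,
                         times: np.ndarray | None = None,
                         laser_on: float = 0.0,
                         laser_off: float = 20.0) -> TemperatureSeries:
    """Convenience driver: source + steady + transient at the defaults."""
    from .grids import default_grid
    laser = laser or LaserSource()
    geom = geom or CapillaryGeometry()
    medium = medium or Medium()
    grid = grid if grid is not None else default_grid(geom, laser.sigma)
    times = times if times is not None else heating_times(laser_on, laser_off)
    q = heat_source_field(laser, geom, grid)
    steady = solve_steady_temperature(medium, q, geom, grid)
    return solve_transient_temperature(medium, q, geom, grid, times,
                                       laser_on, laser_off, steady=steady)


def boundary_heat_outflow(field_K: np.ndarray, medium: Medium, grid: Grid,
                          source: np.ndarray | None = None) -> float:
    """Power (W) leaving through the Dirichlet wall.

    Conductive flux into the clamped wall nodes, plus any source deposited
    directly in the wall cells themselves (the clamp removes it instantly).
    At steady state this balances the volume-integrated source — the
    discrete-conservation diagnostic.
    """
    k = medium.thermal_conductivity
    g_r = grid.radial_conductances(k)
    g_z = grid.axial_conductances(k)
    out = float(np.sum(g_r[-1, :] * (field_K[-2, :] - field_K[-1, :])))
    out += float(np.sum(g_z[:, 0] * (field_K[:, 1] - field_K[:, 0])))
    out += float(np.sum(g_z[:, -1] * (field_K[:, -2] - field_K[:, -1])))
    if source is not None:
        wall = grid.boundary_mask()
        out += float(np.sum((source * grid.volumes)[wall]))
    return out
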