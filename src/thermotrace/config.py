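"""Run configuration: schema-validated, unit-suffixed keys, YAML round-trip.

Every default traces to either an instrument/sample parameter of the
modelled experiment or a documented numerical choice; unknown keys are
rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

from .grids import CapillaryGeometry, Grid, default_grid
from .heat import LaserSource, Medium
from .transport import ProbeRegion, TransportParams

__all__ = ["RunConfig"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LaserConfig(_Section):
    power_W: float = 0.05
    reflection: float = 0.05
    absorption_per_m: float = 50.0
    beam_diameter_m: float = 1.0e-5


class GeometryConfig(_Section):
    capillary_radius_m: float = 2.0e-4
    axial_half_length_m: float = 2.0e-4


class MediumConfig(_Section):
    ambient_K: float = 293.15
    conductivity_W_per_m_K: float = 0.60
    density_kg_per_m3: float = 998.0
    heat_capacity_J_per_kg_K: float = 4182.0


class TransportConfig(_Section):
    diffusion_m2_per_s: float = 2.25e-12
    initial_concentration_mol_per_m3: float = 1.0


class GridConfig(_Section):
    refine: float = 1.0


class TimesConfig(_Section):
    on_s: float = 0.0
    off_s: float = 20.0


class ProbeConfig(_Section):
    kind: str = "circle"
    planar_diameter_m: float = 1.30e-4
    thickness_m: float = 2.0e-5


class FitConfig(_Section):
    soret_min_per_K: float = -2.5
    soret_max_per_K: float = 2.5
    n_soret: int = 51


class SyntheticConfig(_Section):
    background_counts: float = 200.0
    amplitude_counts: float = 800.0
    decay_rate_per_s: float = -0.22
    noise_sigma: float = 0.0
    n_points: int = 301
    duration_s: float = 30.0
    laser_on_s: float = 5.0
    laser_off_s: float = 25.0


class RunConfig(_Section):
    """Top-level configuration binding all module parameters."""

    laser: LaserConfig = LaserConfig()
    geometry: GeometryConfig = GeometryConfig()
    medium: MediumConfig = MediumConfig()
    transport: TransportConfig = TransportConfig()
    grid: GridConfig = GridConfig()
    times: TimesConfig = TimesConfig()
    probe: ProbeConfig = ProbeConfig()
    fit: FitConfig = FitConfig()
    synthetic: SyntheticConfig = SyntheticConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(),
                                             sort_keys=False))

    def digest(self) -> str:
        """Short hash of the full configuration, for run logs."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    # ---- object builders -------------------------------------------------

    def build_laser(self) -> LaserSource:
        c = self.laser
        return LaserSource(power_Q0=c.power_W, reflection_Rc=c.reflection,
                           absorption_Ac=c.absorption_per_m,
                           beam_diameter=c.beam_diameter_m)

    def build_geometry(self) -> CapillaryGeometry:
        c = self.geometry
        return CapillaryGeometry(capillary_radius=c.capillary_radius_m,
                                 domain_axial_half_length=c.axial_half_length_m)

    def build_medium(self) -> Medium:
        c = self.medium
        return Medium(thermal_conductivity=c.conductivity_W_per_m_K,
                      density=c.density_kg_per_m3,
                      heat_capacity=c.heat_capacity_J_per_kg_K,
                      ambient_temperature=c.ambient_K)

    def build_grid(self) -> Grid:
        return default_grid(self.build_geometry(),
                            self.build_laser().sigma,
                            refine=self.grid.refine)

    def build_probe(self) -> ProbeRegion:
        c = self.probe
        return ProbeRegion(kind=c.kind, planar_diameter=c.planar_diameter_m,
                           thickness=c.thickness_m)

    def build_transport(self, soret_ST: float = 0.0) -> TransportParams:
        c = self.transport
        return TransportParams(
            diffusion_D=c.diffusion_m2_per_s, soret_ST=soret_ST,
            initial_concentration=c.initial_concentration_mol_per_m3)

    def soret_grid(self) -> np.ndarray:
        c = self.fit
        return np.linspace(c.soret_min_per_K, c.soret_max_per_K, c.n_soret)
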