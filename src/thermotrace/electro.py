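"""Electrokinetic side-calculations: Debye screening, zeta-to-charge, S_T scaling.

The zeta potential measured by electrophoresis relates to the total surface
charge Q of a sphere through the Debye-Hueckel relation

    zeta = Q / (4 pi eps0 eps_r R (1 + kappa R)),

valid at moderate potentials (|zeta| below ~50 mV).  The screening length
lambda = 1/kappa follows the standard electrolyte form

    lambda = sqrt(eps0 eps_r k_B T / (2 N_A e^2 I)),

with I the ionic strength in mol/m^3.  Double-layer theories predict the
Soret coefficient of a charged colloid to scale as S_T ~ sigma^2 lambda,
with sigma the surface charge density; only the *ratio* between two
conditions is computed here (the proportionality carries no prefactor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.constants import Avogadro, Boltzmann, elementary_charge, epsilon_0

__all__ = [
    "ElectrolyteState", "ParticleSurface", "debye_length", "charge_from_zeta",
    "zeta_from_charge", "surface_charge_density", "soret_scaling_ratio",
]

MODERATE_ZETA_V = 0.050  # Debye-Hueckel validity warning threshold


@dataclass(frozen=True)
class ElectrolyteState:
    """Dispersing-medium electrostatics: ionic strength, T, permittivity.

    ``ionic_strength`` is in mol/m^3 (1 mol/m^3 = 1 mM for a 1:1 salt).
    """

    ionic_strength: float           # mol/m^3
    temperature: float = 298.15     # K
    relative_permittivity: float = 78.5

    def __post_init__(self) -> None:
        if self.ionic_strength < 0:
            raise ValueError("ionic_strength must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.relative_permittivity <= 0:
            raise ValueError("relative_permittivity must be > 0")


@dataclass(frozen=True)
class ParticleSurface:
    """Charged sphere: radius, zeta potential and derived charge quantities.

    ``total_charge_Q`` is in elementary charges and
    ``charge_density_sigma`` in e/um^2 = Q / (4 pi R[um]^2).
    """

    radius_R: float                 # m
    zeta: float                     # V
    total_charge_Q: float           # e
    charge_density_sigma: float     # e/um^2

    @classmethod
    def from_zeta(cls, zeta: float, radius_R: float,
                  state: ElectrolyteState) -> "ParticleSurface":
        q = charge_from_zeta(zeta, radius_R, state)
        return cls(radius_R=radius_R, zeta=zeta, total_charge_Q=q,
                   charge_density_sigma=surface_charge_density(q, radius_R))


def debye_length(state: ElectrolyteState) -> float:
    """Electrolyte screening length lambda (m); kappa = 1/lambda."""
    if state.ionic_strength == 0:
        raise ValueError("ionic strength is zero: screening length is "
                         "infinite (pure solvent has no double layer)")
    num = epsilon_0 * state.relative_permittivity * Boltzmann * state.temperature
    den = 2.0 * Avogadro * elementary_charge ** 2 * state.ionic_strength
    return float(np.sqrt(num / den))


def charge_from_zeta(zeta: float, radius_R: float,
                     state: ElectrolyteState) -> float:
    """Total surface charge (elementary charges) from the zeta potential.

    Debye-Hueckel sphere: Q = 4 pi eps0 eps_r R (1 + kappa R) zeta.  In the
    kappa -> 0 limit this is the isolated-sphere Coulomb relation.
    """
    if radius_R <= 0:
        raise ValueError("radius_R must be > 0")
    if abs(zeta) > MODERATE_ZETA_V:
        warnings.warn(
            f"|zeta| = {abs(zeta) * 1e3:.0f} mV exceeds the moderate-"
            "potential regime of the Debye-Hueckel approximation (~50 mV)",
            stacklevel=2)
    kappa = 0.0 if state.ionic_strength == 0 else 1.0 / debye_length(state)
    q_coulomb = (4.0 * np.pi * epsilon_0 * state.relative_permittivity
                 * radius_R * (1.0 + kappa * radius_R) * zeta)
    return float(q_coulomb / elementary_charge)


def zeta_from_charge(total_charge_Q: float, radius_R: float,
                     state: ElectrolyteState) -> float:
    """Inverse of :func:`charge_from_zeta` (volts)."""
    if radius_R <= 0:
        raise ValueError("radius_R must be > 0")
    kappa = 0.0 if state.ionic_strength == 0 else 1.0 / debye_length(state)
    return float(total_charge_Q * elementary_charge
                 / (4.0 * np.pi * epsilon_0 * state.relative_permittivity
                    * radius_R * (1.0 + kappa * radius_R)))


def surface_charge_density(total_charge_Q: float, radius_R: float) -> float:
    """Surface charge density sigma in e/um^2 for a sphere of radius R (m)."""
    if radius_R <= 0:
        raise ValueError("radius_R must be > 0")
    r_um = radius_R * 1e6
    return float(total_charge_Q / (4.0 * np.pi * r_um ** 2))


def soret_scaling_ratio(sigma1: float, lambda1: float,
                        sigma2: float, lambda2: float) -> float:
    """Predicted S_T ratio between two conditions from S_T ~ sigma^2 lambda.

    Returns (sigma1^2 lambda1) / (sigma2^2 lambda2); proportionality only,
    no absolute prefactor.
    """
    for name, v in (("sigma1", sigma1), ("lambda1", lambda1),
                    ("sigma2", sigma2), ("lambda2", lambda2)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0 (got {v!r})")
    return float((sigma1 ** 2 * lambda1) / (sigma2 ** 2 * lambda2))
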