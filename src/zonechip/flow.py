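"""Laminar chamber hydrodynamics: plane-Poiseuille profile and wall shear.

At the working flow rates (0.2–5 µL/min in a ~14 mm wide, 1 mm high
chamber) the Reynolds number is far below one, so the steady incompressible
Navier–Stokes problem reduces exactly to fully developed plane Poiseuille
flow between the culture surface and the chamber ceiling:

    u(z) = (6 Q / (w h³)) · z (h − z),      τ_wall = 6 µ Q / (w h²),

with Q the volumetric flow rate, w the chamber width, h the chamber height
and z measured from the culture surface. A numerical Stokes solver is
deliberately omitted; the closed form is the solution for this reduced
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .device import DeviceGeometry, Material, MultiDomainGrid
from .errors import ConfigurationError
from .units import ul_min_to_m3s


class FlowSpec(BaseModel):
    """Medium perfusion settings. ``flow_rate`` is SI (m³/s)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    flow_rate: float = ul_min_to_m3s(0.5)
    body_force: float = 0.0          # N/m³, unused by the closed form
    outlet_pressure: float = 101325.0  # Pa

    @model_validator(mode="after")
    def _check(self) -> "FlowSpec":
        if self.flow_rate < 0:
            raise ConfigurationError("flow_rate must be >= 0")
        return self

    @classmethod
    def from_ul_min(cls, q_ul_min: float, **kw) -> "FlowSpec":
        return cls(flow_rate=ul_min_to_m3s(q_ul_min), **kw)


@dataclass(frozen=True)
class VelocityField:
    """Axial velocity sampled on the medium cells of a grid.

    ``u`` is (nz, nx), zero outside MEDIUM cells. ``row_flux`` holds the
    exact analytic flux per unit width through each medium row (m²/s), so
    that sum(row_flux) · width == Q to machine precision regardless of the
    vertical resolution.
    """

    u: np.ndarray
    row_flux: np.ndarray   # (n_medium_rows,)
    medium_rows: np.ndarray
    Q: float
    geometry: DeviceGeometry


def poiseuille_profile(flow: FlowSpec, geometry: DeviceGeometry,
                       grid: MultiDomainGrid) -> VelocityField:
    """Sample the plane-Poiseuille profile on the grid's medium cells."""
    w = geometry.chamber_width
    h = geometry.chamber_height
    if w <= 0 or h <= 0:
        raise ConfigurationError("chamber width and height must be positive")
    Q = flow.flow_rate
    a = 6.0 * Q / (w * h ** 3)

    u = np.zeros(grid.shape)
    rows = np.arange(grid.i_medium0, grid.i_medium1)
    z_local = grid.z[rows] - grid.i_medium0 * grid.dz  # z from culture surface
    u[rows, :] = (a * z_local * (h - z_local))[:, None]

    # Exact row fluxes: ∫ u dz over each cell via the antiderivative.
    def F(z):  # ∫ a z (h − z) dz
        return a * (h * z ** 2 / 2.0 - z ** 3 / 3.0)

    z0 = z_local - grid.dz / 2.0
    z1 = z_local + grid.dz / 2.0
    row_flux = F(np.clip(z1, 0.0, h)) - F(np.clip(z0, 0.0, h))
    return VelocityField(u=u, row_flux=row_flux, medium_rows=rows, Q=Q,
                         geometry=geometry)


def wall_shear(flow: FlowSpec, geometry: DeviceGeometry,
               mu: float = 0.93e-3) -> float:
    """Wall shear stress τ = 6µQ/(w h²) on the culture surface (Pa)."""
    w = geometry.chamber_width
    h = geometry.chamber_height
    if w <= 0 or h <= 0:
        raise ConfigurationError("chamber width and height must be positive")
    return 6.0 * mu * flow.flow_rate / (w * h ** 2)


def shear_table(flow_rates_ul_min, geometry: DeviceGeometry,
                mu: float = 0.93e-3) -> list[dict]:
    """Shear stress for a list of flow rates (µL/min) as table rows."""
    return [{"flow_rate_uL_min": q,
             "shear_Pa": wall_shear(FlowSpec.from_ul_min(q), geometry, mu=mu)}
            for q in flow_rates_ul_min]
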