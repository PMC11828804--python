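"""Device data model: geometry, physical parameters, grid and zone layout.

The chip is a two-layer PDMS device bonded to a glass slide. The lower layer
(nominally 2 mm thick) carries a serpentine gas-channel network (channels
0.2 mm wide, 0.1 mm high) fed with incubator air (19% O2) on one side and
nitrogen (0% O2) on the other, which imprints three oxygen zones onto the
cell-culture chamber carved into the upper layer (nominally 3 mm thick,
chamber 1 mm deep). Medium flows along the chamber length (x), parallel to
the oxygen gradient, so zone 1 (periportal, high O2) sits at the medium
inlet and zone 3 (pericentral, low O2) at the outlet.

All solvers in this package work on a 2-D vertical cross-section (x = flow
direction, z = vertical, z = 0 at the glass slide), treating the chamber
width as homogeneous. The chamber footprint is not a published dimension;
the defaults here are reconstructions (see docs/methods.md) constrained by
the published wall shear stress and glucose drop, and every field is
config-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigurationError, DomainError, ResolutionError

#: Seeding density used in the study (cells per mL of chamber volume).
DEFAULT_SEEDING_DENSITY_PER_ML = 4.0e5


def default_roi_centers() -> list[tuple[float, float]]:
    """Default layout of the ten 1.5-mm sensor sections.

    Two staggered rows of five disks, placed well inside each zone so the
    ROI means report zone levels rather than boundary blends: four disks in
    zone 1, two in zone 2, four in zone 3 (zone boundaries at L/3 and 2L/3).
    Positions are fractions of the default chamber footprint, returned in
    metres.
    """
    L, W = 49.4e-3, 13.7e-3
    fracs = [(0.08, 0.30), (0.08, 0.70), (0.20, 0.30), (0.20, 0.70),
             (0.50, 0.30), (0.50, 0.70),
             (0.80, 0.30), (0.80, 0.70), (0.92, 0.30), (0.92, 0.70)]
    return [(fx * L, fy * W) for fx, fy in fracs]


class DeviceGeometry(BaseModel):
    """Geometric description of the two-layer device (SI metres)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    chamber_length: float = 49.4e-3
    chamber_width: float = 13.7e-3
    chamber_height: float = 1.0e-3
    gas_layer_thickness: float = 2.0e-3
    cell_layer_thickness: float = 3.0e-3
    gas_channel_width: float = 0.2e-3
    gas_channel_height: float = 0.1e-3
    zone_boundaries: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    roi_centers: tuple[tuple[float, float], ...] = Field(
        default_factory=lambda: tuple(default_roi_centers()))
    roi_diameter: float = 1.5e-3

    @model_validator(mode="after")
    def _check(self) -> "DeviceGeometry":
        dims = dict(chamber_length=self.chamber_length,
                    chamber_width=self.chamber_width,
                    chamber_height=self.chamber_height,
                    gas_layer_thickness=self.gas_layer_thickness,
                    cell_layer_thickness=self.cell_layer_thickness,
                    gas_channel_width=self.gas_channel_width,
                    gas_channel_height=self.gas_channel_height,
                    roi_diameter=self.roi_diameter)
        for name, v in dims.items():
            if not v > 0:
                raise ConfigurationError(f"{name} must be > 0, got {v!r}")
        b1, b2 = self.zone_boundaries
        if not (0.0 < b1 < b2 < 1.0):
            raise ConfigurationError(
                f"zone_boundaries must be strictly increasing in (0, 1), got {self.zone_boundaries!r}")
        if self.gas_channel_height >= self.gas_layer_thickness:
            raise ConfigurationError(
                "gas_channel_height must be smaller than gas_layer_thickness "
                "(no PDMS membrane would remain above the channels)")
        if self.chamber_height > self.cell_layer_thickness:
            raise ConfigurationError(
                "chamber_height cannot exceed the upper-layer thickness")
        for (x, y) in self.roi_centers:
            if not (0.0 <= x <= self.chamber_length and 0.0 <= y <= self.chamber_width):
                raise ConfigurationError(
                    f"ROI center ({x}, {y}) lies outside the chamber footprint")
        return self

    @property
    def total_thickness(self) -> float:
        """Total device thickness: gas layer + upper (cell) layer."""
        return self.gas_layer_thickness + self.cell_layer_thickness

    @property
    def membrane_thickness(self) -> float:
        """PDMS between the gas-channel tops and the culture surface."""
        return self.gas_layer_thickness - self.gas_channel_height

    @property
    def culture_area(self) -> float:
        """Chamber footprint area (m²)."""
        return self.chamber_length * self.chamber_width

    @property
    def chamber_volume(self) -> float:
        """Chamber volume (m³)."""
        return self.culture_area * self.chamber_height


class TransportParams(BaseModel):
    """Physical constants for flow and species transport (SI unless noted).

    ``glucose_uptake`` keeps the literature unit, mol/min per 10⁶ cells;
    :meth:`glucose_uptake_per_cell` converts to mol/s per cell.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    D_glucose_medium: float = 6.16e-10   # m²/s
    D_O2_medium: float = 2.69e-9         # m²/s
    D_O2_pdms: float = 3.25e-9           # m²/s
    partition_K: float = 10.0            # C_pdms / C_medium, dimensionless
    C_sat_pdms: float = 1.8              # mol/m³ at the reference gas level
    Km: float = 6.3e-3                   # mol/m³, Michaelis–Menten constant
    q_cell: float = 3.5e-16              # mol/s per cell, max per-cell OCR
    N_total: float = 270_712.0           # cells (400k/mL × default chamber volume)
    A_culture: float = 6.7678e-4         # m², default chamber footprint
    C_necrosis: float = 1.0e-4           # mol/m³, consumption cutoff
    glucose_uptake: float = 2.4e-9       # mol/min per 10⁶ cells
    mu: float = 0.93e-3                  # Pa·s
    rho: float = 1009.0                  # kg/m³
    C_glucose_in: float = 5.5            # mol/m³ (= mM)
    reference_O2_percent: float = 19.0   # % O2 of the high-oxygen gas

    @model_validator(mode="after")
    def _check(self) -> "TransportParams":
        for name, v in self.model_dump().items():
            if not v > 0:
                raise ConfigurationError(f"{name} must be strictly positive, got {v!r}")
        if not self.Km > self.C_necrosis:
            raise ConfigurationError("Km must exceed C_necrosis")
        if self.partition_K < 1.0:
            raise ConfigurationError("partition_K must be >= 1 (PDMS:medium)")
        return self

    @classmethod
    def for_geometry(cls, geometry: DeviceGeometry,
                     seeding_density_per_ml: float = DEFAULT_SEEDING_DENSITY_PER_ML,
                     **overrides) -> "TransportParams":
        """Derive N_total and A_culture from a geometry and seeding density."""
        volume_ml = geometry.chamber_volume * 1e6
        overrides.setdefault("N_total", seeding_density_per_ml * volume_ml)
        overrides.setdefault("A_culture", geometry.culture_area)
        return cls(**overrides)

    def glucose_uptake_per_cell(self) -> float:
        """Glucose uptake in mol/s per cell."""
        return self.glucose_uptake / 60.0 / 1e6

    @property
    def psi_ref(self) -> float:
        """Medium-side oxygen concentration (mol/m³) at the reference gas level.

        The partition-scaled potential ψ used by the oxygen solver equals the
        medium concentration; ψ_ref = C_sat_pdms / partition_K corresponds to
        ``reference_O2_percent``.
        """
        return self.C_sat_pdms / self.partition_K

    def percent_to_psi(self, percent) -> np.ndarray | float:
        """%O2 → partition potential ψ (mol/m³, medium scale)."""
        return np.asarray(percent) / self.reference_O2_percent * self.psi_ref

    def psi_to_percent(self, psi) -> np.ndarray | float:
        """Partition potential ψ (mol/m³) → %O2."""
        return np.asarray(psi) / self.psi_ref * self.reference_O2_percent


class Material(IntEnum):
    """Cell material labels on the structured grid."""

    PDMS = 0
    MEDIUM = 1
    GAS_CHANNEL = 2


@dataclass(frozen=True)
class MultiDomainGrid:
    """Uniform rectilinear 2-D (x–z) multi-material grid.

    x runs from the medium inlet (high-oxygen end) to the outlet; z from the
    glass slide (z=0) to the device top. ``material`` has shape (nz, nx) with
    row 0 at the glass. Gas-channel cells act as Dirichlet patches whose
    value is set per zone by a gas boundary condition; the Dirichlet plane
    sits on the face between the channel rows and the PDMS membrane.
    """

    x: np.ndarray          # cell-centre x, shape (nx,)
    z: np.ndarray          # cell-centre z, shape (nz,)
    dx: float
    dz: float
    material: np.ndarray   # (nz, nx) int, Material values
    geometry: DeviceGeometry
    i_gas_top: int         # first row index above the gas-channel rows
    i_medium0: int         # first MEDIUM row
    i_medium1: int         # one past the last MEDIUM row

    @property
    def nx(self) -> int:
        return self.x.size

    @property
    def nz(self) -> int:
        return self.z.size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nz, self.nx)

    @property
    def culture_row(self) -> int:
        """Row index of the culture surface (bottom row of MEDIUM cells)."""
        return self.i_medium0

    @property
    def membrane_cells(self) -> int:
        """Number of PDMS rows between the gas patches and the medium."""
        return self.i_medium0 - self.i_gas_top

    def interface_faces(self) -> list[tuple[int, int]]:
        """Horizontal PDMS/medium interface faces as (row_below, row_above).

        Each face spans the full chamber length and carries the partition
        condition C_pdms = K · C_medium.
        """
        faces = [(self.i_medium0 - 1, self.i_medium0)]
        if self.i_medium1 < self.nz:
            faces.append((self.i_medium1 - 1, self.i_medium1))
        return faces

    def zone_of_column(self) -> np.ndarray:
        """Zone id (1..3) of every x column."""
        return np.array([zone_of((xc, self.geometry.chamber_width / 2), self.geometry)
                         for xc in self.x])

    def metadata(self) -> dict:
        """JSON-serializable grid summary."""
        counts = {m.name: int(np.sum(self.material == m)) for m in Material}
        return {
            "nx": self.nx, "nz": self.nz,
            "dx_m": self.dx, "dz_m": self.dz,
            "domain_height_m": float(self.nz * self.dz),
            "membrane_cells": self.membrane_cells,
            "culture_row": self.culture_row,
            "material_cell_counts": counts,
        }


def build_grid(geometry: DeviceGeometry, nx: int = 100, nz: int = 50) -> MultiDomainGrid:
    """Discretize the device cross-section on a uniform (nx × nz) grid.

    The domain spans the full device height (gas layer + upper layer) and
    the chamber length. Material boundaries are snapped to the nearest cell
    face; the vertical resolution must keep at least one gas-channel row,
    at least three PDMS membrane rows, and at least two medium rows.

    Raises
    ------
    ConfigurationError
        If nx/nz are below the minimum supported resolution.
    ResolutionError
        If nz cannot resolve the channel, membrane or chamber.
    """
    if nx < 20 or nz < 10:
        raise ConfigurationError(f"need nx >= 20 and nz >= 10, got nx={nx}, nz={nz}")
    H = geometry.total_thickness
    L = geometry.chamber_length
    dz = H / nz
    dx = L / nx

    i_gas_top = max(1, round(geometry.gas_channel_height / dz))
    i_medium0 = round(geometry.gas_layer_thickness / dz)
    i_medium1 = round((geometry.gas_layer_thickness + geometry.chamber_height) / dz)
    if i_medium0 - i_gas_top < 3:
        raise ResolutionError(
            f"nz={nz} leaves only {i_medium0 - i_gas_top} cells across the PDMS "
            "membrane; at least 3 are required")
    if i_medium1 - i_medium0 < 2:
        raise ResolutionError(f"nz={nz} cannot resolve the medium chamber height")
    if i_medium1 > nz:
        raise ResolutionError("chamber extends beyond the grid top")

    material = np.full((nz, nx), int(Material.PDMS), dtype=np.int8)
    material[:i_gas_top, :] = int(Material.GAS_CHANNEL)
    material[i_medium0:i_medium1, :] = int(Material.MEDIUM)

    x = (np.arange(nx) + 0.5) * dx
    z = (np.arange(nz) + 0.5) * dz
    return MultiDomainGrid(x=x, z=z, dx=dx, dz=dz, material=material,
                           geometry=geometry, i_gas_top=i_gas_top,
                           i_medium0=i_medium0, i_medium1=i_medium1)


def zone_of(position: Sequence[float], geometry: DeviceGeometry) -> int:
    """Zone id (1, 2 or 3) of a chamber-footprint position (x, y) in metres.

    Points exactly on a zone boundary belong to the lower-numbered zone.
    """
    x, y = position
    if not (0.0 <= x <= geometry.chamber_length and 0.0 <= y <= geometry.chamber_width):
        raise DomainError(f"position ({x}, {y}) outside the chamber footprint")
    frac = x / geometry.chamber_length
    b1, b2 = geometry.zone_boundaries
    if frac <= b1:
        return 1
    if frac <= b2:
        return 2
    return 3


@dataclass(frozen=True)
class ZoneMap:
    """Zone id per ROI, derived from ROI centres and zone boundaries."""

    roi_zones: tuple[int, ...]

    @classmethod
    def from_geometry(cls, geometry: DeviceGeometry) -> "ZoneMap":
        return cls(tuple(zone_of(c, geometry) for c in geometry.roi_centers))
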