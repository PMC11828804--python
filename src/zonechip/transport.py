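"""Advection–diffusion–reaction transport of oxygen and glucose.

Oxygen is solved over the whole device cross-section (gas channels, PDMS
bulk, medium). The PDMS/medium interface carries an equilibrium partition
condition C_pdms = K · C_medium (K = 10 for oxygen); the solver works in a
partition-scaled potential ψ that is continuous across the interface
(ψ = C_medium in medium, ψ = C_pdms / K in PDMS), with an effective
diffusivity D_eff = K·D_pdms in PDMS and D_medium in medium, so the jump
condition and flux continuity hold exactly by construction. The gas
channels are Dirichlet patches at the channel-top face, patterned by zone
(high-O2 line / nitrogen line / interleaved stripes under zone 2); faces
exposed to the incubator atmosphere are held at the reference saturation.

Cellular oxygen consumption is a Michaelis–Menten surface sink on the
culture surface,

    OCR = (q·N_t/A_t) · C/(K_m + C) · H(C − C_nec),

with a Heaviside necrosis cutoff at C_nec (an optional smooth step is
available to aid convergence). The nonlinearity is resolved by damped
Picard iteration with the saturation factor taken implicitly.

Glucose is confined to the medium: upwind finite-volume advection by the
plane-Poiseuille profile, inlet Dirichlet at the feed concentration,
outflow (zero diffusive flux) outlet, and a zero-order uptake flux on the
culture surface, clipped where glucose is locally exhausted.

Discretization is a uniform finite-volume scheme with harmonic-mean face
diffusivities; time integration is backward Euler (unconditionally stable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from pydantic import BaseModel, ConfigDict

from .device import DeviceGeometry, Material, MultiDomainGrid, TransportParams, zone_of
from .errors import ConfigurationError, DomainError, ResolutionError, SolverError
from .flow import VelocityField

__all__ = [
    "GasBC", "CellField", "ScalarFieldSeries", "ROISeries",
    "ocr_flux", "steady_oxygen", "transient_oxygen", "steady_glucose",
    "glucose_mass_balance", "outlet_concentration", "extract_roi_series",
    "stabilization_time", "slab_step_response",
]


class GasBC(BaseModel):
    """Per-zone gas-channel oxygen levels (Dirichlet patches).

    ``high_percent`` feeds the zone-1 patch, ``low_percent`` the zone-3
    patch. Zone 2 is covered by the serpentine interleave of both lines:
    ``zone2_mode='stripes'`` alternates the two levels at the channel pitch
    (snapped to whole grid cells), ``'mid'`` applies their average.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    high_percent: float = 19.0
    low_percent: float = 19.0
    zone2_mode: str = "stripes"
    stripe_pitch: float = 0.5e-3  # m

    def percent_columns(self, grid: MultiDomainGrid) -> np.ndarray:
        """%O2 imposed under each x column of the grid."""
        if self.zone2_mode not in ("stripes", "mid"):
            raise ConfigurationError(f"unknown zone2_mode {self.zone2_mode!r}")
        geo = grid.geometry
        b1, b2 = geo.zone_boundaries
        frac = grid.x / geo.chamber_length
        out = np.empty(grid.nx)
        out[frac <= b1] = self.high_percent
        out[frac > b2] = self.low_percent
        z2 = (frac > b1) & (frac <= b2)
        if self.zone2_mode == "mid":
            out[z2] = 0.5 * (self.high_percent + self.low_percent)
        else:
            pitch_cells = max(1, round(self.stripe_pitch / grid.dx))
            idx = np.nonzero(z2)[0]
            block = ((idx - idx[0]) // pitch_cells) % 2
            out[z2] = np.where(block == 0, self.high_percent, self.low_percent)
        return out

    def psi_columns(self, grid: MultiDomainGrid, params: TransportParams) -> np.ndarray:
        return np.asarray(params.percent_to_psi(self.percent_columns(grid)), dtype=float)


@dataclass(frozen=True)
class CellField:
    """Surface cell density on the culture surface (cells/m² per column)."""

    density: np.ndarray          # (nx,)
    alive: np.ndarray            # (nx,) bool

    @classmethod
    def uniform(cls, grid: MultiDomainGrid, params: TransportParams) -> "CellField":
        """Uniform seeding: total N_total spread over the culture area."""
        d = np.full(grid.nx, params.N_total / params.A_culture)
        return cls(density=d, alive=np.ones(grid.nx, dtype=bool))

    def total_cells(self, grid: MultiDomainGrid) -> float:
        width = grid.geometry.chamber_width
        return float(np.sum(self.density) * grid.dx * width)


@dataclass
class ScalarFieldSeries:
    """Concentration field(s) on the grid, optionally time resolved.

    ``psi`` has shape (nt, nz, nx). For oxygen it is the partition
    potential (equal to the medium concentration, mol/m³); for glucose it
    is the concentration itself (NaN outside the medium).
    """

    species: str
    times: np.ndarray
    psi: np.ndarray
    grid: MultiDomainGrid
    params: TransportParams

    def concentration(self) -> np.ndarray:
        """Actual concentration per material (mol/m³)."""
        if self.species != "oxygen":
            return self.psi
        scale = np.where(self.grid.material == int(Material.MEDIUM),
                         1.0, self.params.partition_K)
        return self.psi * scale[None, :, :]

    def percent(self) -> np.ndarray:
        """%O2 on the reference scale (only meaningful for oxygen)."""
        return np.asarray(self.params.psi_to_percent(self.psi))

    def surface_percent(self) -> np.ndarray:
        """%O2 along the culture surface, shape (nt, nx)."""
        return self.percent()[:, self.grid.culture_row, :]


@dataclass
class ROISeries:
    """Per-ROI mean oxygen (%O2) versus time."""

    times: np.ndarray            # (nt,) s
    o2_percent: np.ndarray       # (nt, n_roi)
    roi_ids: np.ndarray
    zones: np.ndarray
    roi_centers: tuple


def ocr_flux(C_local, params: TransportParams, surface_density: float | np.ndarray | None = None,
             smooth_halfwidth: float = 0.0):
    """Michaelis–Menten oxygen consumption flux (mol/(m²·s)).

    ``surface_density`` defaults to N_total/A_culture. The necrosis cutoff
    is a hard Heaviside step at C_necrosis by default; ``smooth_halfwidth``
    (mol/m³) switches to a cubic smooth step across ±halfwidth.
    """
    C = np.asarray(C_local, dtype=float)
    if np.any(C < 0):
        raise DomainError("oxygen concentration must be non-negative")
    dens = params.N_total / params.A_culture if surface_density is None else surface_density
    sat = C / (params.Km + C)
    if smooth_halfwidth > 0:
        s = np.clip((C - (params.C_necrosis - smooth_halfwidth))
                    / (2.0 * smooth_halfwidth), 0.0, 1.0)
        step = s * s * (3.0 - 2.0 * s)
    else:
        step = (C >= params.C_necrosis).astype(float)
    out = params.q_cell * dens * sat * step
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# finite-volume assembly
# ---------------------------------------------------------------------------

def _necrosis_step(psi, params, smooth_halfwidth):
    if smooth_halfwidth > 0:
        s = np.clip((psi - (params.C_necrosis - smooth_halfwidth))
                    / (2.0 * smooth_halfwidth), 0.0, 1.0)
        return s * s * (3.0 - 2.0 * s)
    return (psi >= params.C_necrosis).astype(float)


class _OxygenSystem:
    """Assembled linear operator for the oxygen potential ψ.

    Gas-channel cells are identity rows whose RHS carries the imposed ψ, so
    a boundary-level switch changes only the RHS and a transient solve can
    reuse one factorization.
    """

    def __init__(self, grid: MultiDomainGrid, params: TransportParams, *,
                 gas_dirichlet: bool = True,
                 top_bc: str = "ambient", side_bc: str = "ambient",
                 ambient_percent: float | None = None,
                 advection: VelocityField | None = None,
                 inlet_percent: float | None = None):
        self.grid, self.params = grid, params
        nz, nx = grid.shape
        mat = grid.material
        K = params.partition_K
        self.active = (mat != int(Material.GAS_CHANNEL)) if gas_dirichlet \
            else np.ones(grid.shape, dtype=bool)
        # effective diffusivity of the potential ψ
        D = np.where(mat == int(Material.MEDIUM), params.D_O2_medium,
                     params.D_O2_pdms * K)
        self.D = D
        self.capacity = np.where(mat == int(Material.MEDIUM), 1.0, K) * grid.dx * grid.dz
        ids = np.arange(nz * nx).reshape(nz, nx)
        dx, dz = grid.dx, grid.dz
        amb = params.reference_O2_percent if ambient_percent is None else ambient_percent
        psi_amb = float(params.percent_to_psi(amb))
        self.psi_amb = psi_amb

        rows, cols, vals = [], [], []
        b = np.zeros(nz * nx)

        def add(r, c, v):
            rows.append(np.atleast_1d(r)); cols.append(np.atleast_1d(c))
            vals.append(np.atleast_1d(v))

        def pair(idA, idB, Da, Db, actA, actB, area, dist):
            both = actA & actB
            if np.any(both):
                g = area * 2.0 * Da[both] * Db[both] / (Da[both] + Db[both]) / dist
                a, bb = idA[both], idB[both]
                add(a, a, g); add(bb, bb, g); add(a, bb, -g); add(bb, a, -g)
            onlyA = actA & ~actB
            if np.any(onlyA):   # B is a fixed (identity) cell: Dirichlet at the face
                g = area * Da[onlyA] / (dist / 2.0)
                a, bb = idA[onlyA], idB[onlyA]
                add(a, a, g); add(a, bb, -g)
            onlyB = actB & ~actA
            if np.any(onlyB):
                g = area * Db[onlyB] / (dist / 2.0)
                a, bb = idA[onlyB], idB[onlyB]
                add(bb, bb, g); add(bb, a, -g)

        # interior faces
        pair(ids[:-1, :].ravel(), ids[1:, :].ravel(),
             D[:-1, :].ravel(), D[1:, :].ravel(),
             self.active[:-1, :].ravel(), self.active[1:, :].ravel(), dx, dz)
        pair(ids[:, :-1].ravel(), ids[:, 1:].ravel(),
             D[:, :-1].ravel(), D[:, 1:].ravel(),
             self.active[:, :-1].ravel(), self.active[:, 1:].ravel(), dz, dx)

        # identity rows for fixed gas cells
        fixed = ~self.active
        if np.any(fixed):
            f = ids[fixed]
            add(f, f, np.ones(f.size))
        self.fixed_ids = ids[fixed]

        # top boundary (always PDMS)
        if top_bc == "ambient":
            t = ids[-1, :][self.active[-1, :]]
            g = D[-1, :][self.active[-1, :]] * dx / (dz / 2.0)
            add(t, t, g)
            b[t] += g * psi_amb
        elif top_bc != "noflux":
            raise ConfigurationError(f"unknown top_bc {top_bc!r}")

        # side boundaries: ambient on PDMS faces, sealed on medium/gas rows
        if side_bc == "ambient":
            for j in (0, nx - 1):
                col_act = self.active[:, j] & (mat[:, j] == int(Material.PDMS))
                s = ids[:, j][col_act]
                g = D[:, j][col_act] * dz / (dx / 2.0)
                add(s, s, g)
                b[s] += g * psi_amb
        elif side_bc != "noflux":
            raise ConfigurationError(f"unknown side_bc {side_bc!r}")

        # optional medium advection (upwind, +x flow)
        if advection is not None:
            inlet = params.reference_O2_percent if inlet_percent is None else inlet_percent
            psi_in = float(params.percent_to_psi(inlet))
            for k, r in enumerate(advection.medium_rows):
                phi = advection.row_flux[k]
                if phi == 0.0:
                    continue
                c = ids[r, :]
                add(c, c, np.full(nx, phi))
                add(c[1:], c[:-1], np.full(nx - 1, -phi))
                b[c[0]] += phi * psi_in
                gd = params.D_O2_medium * dz / (dx / 2.0)   # diffusive inlet Dirichlet
                add(c[0], c[0], gd)
                b[c[0]] += gd * psi_in

        n = nz * nx
        self.A0 = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n))
        self.b0 = b
        self.ids = ids
        self.culture_ids = ids[grid.culture_row, :]

    def rhs(self, gas_psi_cols: np.ndarray | None) -> np.ndarray:
        b = self.b0.copy()
        if gas_psi_cols is not None and self.fixed_ids.size:
            nx = self.grid.nx
            b[self.fixed_ids] = np.tile(gas_psi_cols, self.fixed_ids.size // nx)
        return b

    def sink_vector(self, psi_flat: np.ndarray, cells: CellField,
                    smooth_halfwidth: float) -> np.ndarray:
        """Nonlinear sink S(ψ) on the culture row (per unit width, mol/(m·s))."""
        p = self.params
        c = self.culture_ids
        psi = psi_flat[c]
        dens = self.grid.dx * cells.density * cells.alive
        step = _necrosis_step(psi, p, smooth_halfwidth)
        s = np.zeros_like(psi_flat)
        s[c] = p.q_cell * dens * psi / (p.Km + psi) * step
        return s

    def sink_diag(self, psi_old_flat: np.ndarray, cells: CellField,
                  smooth_halfwidth: float) -> sp.csr_matrix:
        """Picard linearization: S(ψ) ≈ [j·dx·H/(Km+ψ_old)] · ψ."""
        p = self.params
        c = self.culture_ids
        psi = psi_old_flat[c]
        dens = self.grid.dx * cells.density * cells.alive
        step = _necrosis_step(psi, p, smooth_halfwidth)
        coeff = np.zeros_like(psi_old_flat)
        coeff[c] = p.q_cell * dens * step / (p.Km + psi)
        return sp.diags(coeff).tocsr()


def _solve_steady(system: _OxygenSystem, gas_psi_cols, cells: CellField | None,
                  tol: float, max_iter: int, smooth_halfwidth: float,
                  damping: float = 1.0) -> np.ndarray:
    b = system.rhs(gas_psi_cols)
    psi = spla.spsolve(system.A0.tocsc(), b)
    if cells is None:
        return psi
    bscale = max(float(np.linalg.norm(b)), 1e-300)
    for _ in range(max_iter):
        A = system.A0 + system.sink_diag(psi, cells, smooth_halfwidth)
        psi_new = spla.spsolve(A.tocsc(), b)
        psi = psi + damping * (psi_new - psi)
        res = system.A0 @ psi - b + system.sink_vector(psi, cells, smooth_halfwidth)
        if np.linalg.norm(res) / bscale < tol:
            break
    else:
        raise SolverError(
            f"Michaelis–Menten iteration did not reach relative residual {tol:g} "
            f"in {max_iter} iterations (residual "
            f"{np.linalg.norm(res) / bscale:.3e})")
    crow = psi[system.culture_ids]
    if np.all(crow < system.params.C_necrosis):
        warnings.warn("necrotic oxygen levels over the entire culture surface",
                      stacklevel=2)
    return psi


def steady_oxygen(grid: MultiDomainGrid, params: TransportParams, gas_bc: GasBC,
                  cells: CellField | None = None, *,
                  ambient_percent: float | None = None,
                  advection: VelocityField | None = None,
                  inlet_percent: float | None = None,
                  top_bc: str = "ambient", side_bc: str = "ambient",
                  gas_dirichlet: bool = True,
                  tol: float = 1e-10, max_iter: int = 200,
                  smooth_halfwidth: float = 0.0) -> ScalarFieldSeries:
    """Steady oxygen distribution over the whole device.

    Returns a single-time :class:`ScalarFieldSeries` of the partition
    potential ψ (medium-scale concentration, mol/m³).
    """
    system = _OxygenSystem(grid, params, gas_dirichlet=gas_dirichlet,
                           top_bc=top_bc, side_bc=side_bc,
                           ambient_percent=ambient_percent,
                           advection=advection, inlet_percent=inlet_percent)
    gas_cols = gas_bc.psi_columns(grid, params) if gas_dirichlet else None
    psi = _solve_steady(system, gas_cols, cells, tol, max_iter, smooth_halfwidth)
    return ScalarFieldSeries(species="oxygen", times=np.array([0.0]),
                             psi=psi.reshape(1, *grid.shape), grid=grid,
                             params=params)


def transient_oxygen(grid: MultiDomainGrid, params: TransportParams,
                     gas_bc_schedule: list[tuple[float, GasBC]],
                     t_end: float, dt: float = 10.0, *,
                     out_every: float = 600.0,
                     cells: CellField | None = None,
                     ambient_percent: float | None = None,
                     top_bc: str = "ambient", side_bc: str = "ambient",
                     gas_dirichlet: bool = True,
                     initial_psi: np.ndarray | None = None,
                     tol: float = 1e-10, max_iter: int = 200,
                     smooth_halfwidth: float = 0.0) -> ScalarFieldSeries:
    """Backward-Euler transient oxygen solve.

    ``gas_bc_schedule`` is a list of ``(switch_time_s, GasBC)``; the first
    entry defines t ≤ 0 and the initial condition is the corresponding
    steady state (by default the device equilibrated at the reference
    level). Fields are recorded at t = 0 and every ``out_every`` seconds.
    """
    if dt <= 0 or t_end <= 0:
        raise ConfigurationError("dt and t_end must be positive")
    n_per_out = round(out_every / dt)
    if n_per_out < 1 or abs(n_per_out * dt - out_every) > 1e-9 * out_every:
        raise ConfigurationError("out_every must be an integer multiple of dt")
    if not gas_bc_schedule:
        raise ConfigurationError("gas_bc_schedule must contain at least one entry")
    schedule = sorted(gas_bc_schedule, key=lambda kv: kv[0])

    system = _OxygenSystem(grid, params, gas_dirichlet=gas_dirichlet,
                           top_bc=top_bc, side_bc=side_bc,
                           ambient_percent=ambient_percent)

    def gas_cols_at(t):
        if not gas_dirichlet:
            return None
        bc = schedule[0][1]
        for ts, cand in schedule:
            if ts <= t + 1e-12:
                bc = cand
        return bc.psi_columns(grid, params)

    if initial_psi is None:
        psi = _solve_steady(system, gas_cols_at(schedule[0][0]), cells,
                            tol, max_iter, smooth_halfwidth)
    else:
        psi = np.asarray(initial_psi, dtype=float).ravel().copy()

    Minv_dt = system.capacity.ravel() / dt
    Minv_dt[~system.active.ravel()] = 0.0    # identity rows carry no capacity
    Mdiag = sp.diags(Minv_dt).tocsr()
    n_steps = int(round(t_end / dt))
    times = [0.0]
    snaps = [psi.copy()]
    lu = None
    if cells is None:
        lu = spla.splu((system.A0 + Mdiag).tocsc())
    for step in range(1, n_steps + 1):
        t_new = step * dt
        b = system.rhs(gas_cols_at(t_new)) + Mdiag @ psi
        if cells is None:
            psi = lu.solve(b)
        else:
            bscale = max(float(np.linalg.norm(b)), 1e-300)
            for _ in range(max_iter):
                A = system.A0 + Mdiag + system.sink_diag(psi, cells, smooth_halfwidth)
                psi_new = spla.spsolve(A.tocsc(), b)
                res = ((system.A0 + Mdiag) @ psi_new - b
                       + system.sink_vector(psi_new, cells, smooth_halfwidth))
                psi = psi_new
                if np.linalg.norm(res) / bscale < max(tol, 1e-12):
                    break
            else:
                raise SolverError(f"transient step at t={t_new:g}s did not converge")
        if step % n_per_out == 0:
            times.append(t_new)
            snaps.append(psi.copy())
    return ScalarFieldSeries(species="oxygen", times=np.asarray(times),
                             psi=np.stack(snaps).reshape(len(times), *grid.shape),
                             grid=grid, params=params)


def total_oxygen_mass(series: ScalarFieldSeries, width: float | None = None) -> np.ndarray:
    """Total dissolved oxygen per snapshot (mol), for conservation checks."""
    grid, params = series.grid, series.params
    w = grid.geometry.chamber_width if width is None else width
    scale = np.where(grid.material == int(Material.MEDIUM), 1.0, params.partition_K)
    return np.sum(series.psi * scale[None], axis=(1, 2)) * grid.dx * grid.dz * w


# ---------------------------------------------------------------------------
# glucose
# ---------------------------------------------------------------------------

def glucose_mass_balance(Q: float, params: TransportParams) -> float:
    """Closed-form steady outlet glucose: C_out = C_in − r·N_total/Q (mol/m³).

    Floored at zero where cellular demand exceeds the supplied flux.
    """
    if Q <= 0:
        raise DomainError("flow rate must be positive for the mass balance")
    r = params.glucose_uptake_per_cell()
    return max(0.0, params.C_glucose_in - r * params.N_total / Q)


def steady_glucose(grid: MultiDomainGrid, params: TransportParams,
                   velocity: VelocityField,
                   cells: CellField | None = None) -> ScalarFieldSeries:
    """Steady glucose in the medium with zero-order surface uptake.

    The uptake flux r·N_total/A_culture is applied uniformly on the culture
    surface (or per-column for a non-uniform :class:`CellField`). Where the
    local surface concentration falls below a small cutoff (0.1% of the
    inlet level) the flux is reduced proportionally to the remaining
    concentration, so uptake ceases smoothly where glucose is exhausted and
    the solution stays non-negative (supply-limited regime).
    """
    if velocity is None:
        raise ConfigurationError("steady_glucose requires a velocity field")
    if velocity.Q <= 0:
        raise ConfigurationError("steady glucose transport requires Q > 0")
    nz, nx = grid.shape
    rows = velocity.medium_rows
    nzm = rows.size
    D = params.D_glucose_medium
    dx, dz = grid.dx, grid.dz
    ids = np.arange(nzm * nx).reshape(nzm, nx)
    r_cell = params.glucose_uptake_per_cell()
    if cells is None:
        dens = np.full(nx, params.N_total / params.A_culture)
    else:
        dens = cells.density * cells.alive
    flux_col = r_cell * dens  # mol/(m²·s) per column
    c_eps = 1e-3 * params.C_glucose_in   # exhaustion cutoff for the uptake

    # limited[j] is True where the surface uptake runs concentration-limited
    # (flux scaled by C/c_eps, taken implicitly) instead of at full rate
    limited = np.zeros(nx, dtype=bool)
    C_bottom_prev = None
    for _ in range(200):
        rows_l, cols_l, vals_l = [], [], []
        b = np.zeros(nzm * nx)

        def add(r, c, v):
            rows_l.append(np.atleast_1d(r)); cols_l.append(np.atleast_1d(c))
            vals_l.append(np.atleast_1d(v))

        # diffusion, interior faces
        a, bb = ids[:-1, :].ravel(), ids[1:, :].ravel()
        g = np.full(a.size, D * dx / dz)
        add(a, a, g); add(bb, bb, g); add(a, bb, -g); add(bb, a, -g)
        a, bb = ids[:, :-1].ravel(), ids[:, 1:].ravel()
        g = np.full(a.size, D * dz / dx)
        add(a, a, g); add(bb, bb, g); add(a, bb, -g); add(bb, a, -g)

        # advection, upwind; inflow carries the inlet Dirichlet value so the
        # total supplied flux is exactly Q·C_in (discrete conservation)
        for k in range(nzm):
            phi = velocity.row_flux[k]
            if phi == 0.0:
                continue
            c = ids[k, :]
            add(c, c, np.full(nx, phi))
            add(c[1:], c[:-1], np.full(nx - 1, -phi))
            b[c[0]] += phi * params.C_glucose_in

        # surface uptake on the bottom medium row: constant flux where the
        # surface is supplied, implicit linear ramp where near-exhausted
        full = ~limited
        b[ids[0, full]] -= flux_col[full] * dx
        lim_ids = ids[0, limited]
        add(lim_ids, lim_ids, flux_col[limited] * dx / c_eps)

        A = sp.csr_matrix(
            (np.concatenate(vals_l), (np.concatenate(rows_l), np.concatenate(cols_l))),
            shape=(nzm * nx, nzm * nx))
        C = spla.spsolve(A.tocsc(), b).reshape(nzm, nx)
        limited_new = C[0, :] < c_eps
        converged = (C_bottom_prev is not None
                     and np.array_equal(limited_new, limited)
                     and np.allclose(C[0, :], C_bottom_prev,
                                     atol=1e-12 * params.C_glucose_in))
        C_bottom_prev = C[0, :].copy()
        limited = limited_new
        if converged:
            break
    C = np.clip(C, 0.0, None)

    full = np.full((1, nz, nx), np.nan)
    full[0, rows[0]:rows[-1] + 1, :] = C
    return ScalarFieldSeries(species="glucose", times=np.array([0.0]),
                             psi=full, grid=grid, params=params)


def outlet_concentration(fields: ScalarFieldSeries, velocity: VelocityField) -> float:
    """Flow-averaged concentration at the outlet column (mol/m³)."""
    rows = velocity.medium_rows
    c_out = fields.psi[-1, rows[0]:rows[-1] + 1, -1]
    w = velocity.row_flux
    return float(np.sum(w * c_out) / np.sum(w))


# ---------------------------------------------------------------------------
# ROI extraction and time metrics
# ---------------------------------------------------------------------------

def roi_column_weights(grid: MultiDomainGrid, center_x: float,
                       radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Columns covered by an ROI disk and their chord-length area weights."""
    dx = grid.dx
    sel = np.nonzero(np.abs(grid.x - center_x) < radius)[0]
    if sel.size == 0:
        raise ResolutionError(
            f"ROI at x={center_x:g} m is empty at dx={dx:g} m")
    chord = 2.0 * np.sqrt(radius ** 2 - (grid.x[sel] - center_x) ** 2)
    return sel, chord


def extract_roi_series(fields: ScalarFieldSeries,
                       geometry: DeviceGeometry | None = None) -> ROISeries:
    """Area-weighted ROI means of the culture-surface oxygen, as %O2.

    Each sensor disk is reduced to its x-footprint with chord-length
    weights (the cross-section model is homogeneous in y).
    """
    geo = fields.grid.geometry if geometry is None else geometry
    grid = fields.grid
    surf = fields.surface_percent()           # (nt, nx)
    radius = geo.roi_diameter / 2.0
    means, zones = [], []
    for (cx, cy) in geo.roi_centers:
        sel, wgt = roi_column_weights(grid, cx, radius)
        means.append(surf[:, sel] @ wgt / np.sum(wgt))
        zones.append(zone_of((cx, cy), geo))
    o2 = np.stack(means, axis=1)
    n = len(geo.roi_centers)
    return ROISeries(times=fields.times.copy(), o2_percent=o2,
                     roi_ids=np.arange(1, n + 1), zones=np.asarray(zones),
                     roi_centers=tuple(geo.roi_centers))


def stabilization_time(series: ROISeries, window: float = 600.0,
                       tol_fraction: float = 0.01,
                       full_scale: float | None = None) -> float | None:
    """Earliest time after which every ROI drifts < tol per window.

    Returns the first time t (on the window grid) such that for every
    subsequent window of length ``window`` the change of every ROI signal
    stays below ``tol_fraction`` of full scale. ``full_scale`` defaults to
    the global data range. Returns ``None`` if the series never stabilizes.
    """
    t = series.times
    if t[-1] - t[0] < 2.0 * window:
        raise DomainError("series must cover at least two windows")
    fs = (np.max(series.o2_percent) - np.min(series.o2_percent)
          if full_scale is None else full_scale)
    grid_t = np.arange(t[0], t[-1] + 1e-9, window)
    sampled = np.stack([np.interp(grid_t, t, series.o2_percent[:, k])
                        for k in range(series.o2_percent.shape[1])], axis=1)
    if fs == 0:
        return float(t[0])
    diffs = np.max(np.abs(np.diff(sampled, axis=0)), axis=1)   # per window
    quiet = diffs < tol_fraction * fs
    # last window that is NOT quiet determines the stabilization point
    noisy = np.nonzero(~quiet)[0]
    if noisy.size == 0:
        return float(grid_t[0])
    k = noisy[-1] + 1
    if k >= diffs.size + 1:
        return None
    if k == diffs.size:      # only the very last window is quiet-less
        return None
    return float(grid_t[k])


def slab_step_response(thickness: float, D: float, start_value: float,
                       end_value: float, t_end: float, dt: float = 5.0,
                       nz: int = 80, far_side: str = "noflux",
                       ambient_value: float | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """1-D transient diffusion through a slab after a boundary step.

    The near face (z=0, gas-channel side) is Dirichlet: ``start_value``
    for t ≤ 0, ``end_value`` for t > 0. The far face is sealed
    (``'noflux'``, e.g. a low-permeability sensor film) or held at
    ``ambient_value`` (``'dirichlet'``). Returns (times, far-face value
    series), in whatever units the levels are given (the equation is
    linear). Backward-Euler finite volumes.
    """
    if thickness <= 0 or D <= 0 or dt <= 0 or t_end <= 0:
        raise ConfigurationError("thickness, D, dt and t_end must be positive")
    dz = thickness / nz
    g = D / dz
    main = np.full(nz, 2.0 * g)
    main[0] = g + D / (dz / 2.0)
    if far_side == "noflux":
        main[-1] = g
    elif far_side == "dirichlet":
        main[-1] = g + D / (dz / 2.0)
    else:
        raise ConfigurationError(f"unknown far_side {far_side!r}")
    off = np.full(nz - 1, -g)
    A = sp.diags([off, main, off], [-1, 0, 1]).tocsc()
    M = dz / dt
    lu = spla.splu(A + sp.eye(nz, format="csc") * M)

    u = np.full(nz, float(start_value))
    n_steps = int(round(t_end / dt))
    times = np.zeros(n_steps + 1)
    sensor = np.zeros(n_steps + 1)
    sensor[0] = u[-1]
    amb = start_value if ambient_value is None else ambient_value
    for s in range(1, n_steps + 1):
        b = M * u
        b[0] += (D / (dz / 2.0)) * end_value
        if far_side == "dirichlet":
            b[-1] += (D / (dz / 2.0)) * amb
        u = lu.solve(b)
        times[s] = s * dt
        sensor[s] = u[-1]
    return times, sensor
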