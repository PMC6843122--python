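"""Barber-Cushman radial solute transport and root P uptake.

Solves the convection-diffusion equation for the solution concentration
Cl(r, t) in a hollow soil cylinder around a mean root,

    dCl/dt = (1/r) d/dr ( r De dCl/dr + r0 v0 Cl / b ) - Ih / b,

with a Michaelis-Menten uptake boundary at the root surface r = r0,

    De b dCl/dr + v0 Cl = Imax (Cl - Cmin) / (Km + Cl - Cmin),

zero transfer at the outer radius r1 (half the mean inter-root distance),
and root hairs as a distributed Michaelis-Menten sink in the annulus
r0 <= r <= r0 + hair_zone_radius.

Discretisation: cell-centred finite volumes on a log-spaced radial grid,
backward-Euler time stepping with Newton iteration on the nonlinear
boundary flux.  The scheme is conservative: solute lost from the annulus
equals root-surface plus root-hair uptake to solver tolerance.  A
method-of-lines reference integrator on a refined grid
(:func:`solve_radial_reference`) serves as an independent accuracy check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp
from scipy.linalg import solve_banded
from scipy.optimize import brentq

from . import units
from .pools import LayerEnvironment, PoolState


class ParameterError(ValueError):
    """Physically invalid uptake parameter."""


class NumericalStateError(ArithmeticError):
    """Solver produced a non-finite or strongly negative concentration."""


@dataclass
class UptakeParams:
    """Root and solute parameters of the radial uptake model.

    Units follow the rhizosphere-modelling convention: lengths cm, time s,
    concentrations umol cm-3, fluxes umol cm-2 s-1.
    """

    De: float = 1e-7  # effective diffusion coefficient, cm2 s-1
    b: float = 20.0  # buffer power, dimensionless
    r0: float = 0.015  # mean root radius, cm
    v0: float = 1e-7  # mean water influx at the root surface, cm s-1
    Imax: float = 3e-6  # maximal influx, umol cm-2 s-1
    Km: float = 6e-3  # half-saturation offset concentration, umol cm-3
    Cmin: float = 2e-4  # concentration of zero net influx, umol cm-3
    Imaxh: float = 0.0  # root-hair maximal influx, umol cm-2 s-1
    Kmh: float = 6e-3  # root-hair half-saturation, umol cm-3
    hair_zone_radius: float = 0.05  # hair cylinder thickness beyond r0, cm
    hair_surface_density: float = 0.0  # cm2 hair surface per cm3 soil

    def __post_init__(self) -> None:
        if self.De <= 0 or self.b <= 0 or self.r0 <= 0:
            raise ParameterError("De, b and r0 must be positive")
        if self.Km <= 0 or self.Kmh <= 0:
            raise ParameterError("Km and Kmh must be positive")
        if self.Imax < 0 or self.Imaxh < 0 or self.Cmin < 0:
            raise ParameterError("Imax, Imaxh and Cmin must be non-negative")


def mm_influx(cl, Imax: float, Km: float, Cmin: float):
    """Michaelis-Menten net influx, zero at and below Cmin.

    influx = Imax (Cl - Cmin) / (Km + Cl - Cmin); influx(Cmin) = 0 and
    influx = Imax/2 where Cl - Cmin = Km.  Accepts scalars or arrays.
    """
    if Km <= 0:
        raise ParameterError(f"Km must be positive, got {Km}")
    cl = np.asarray(cl, dtype=float)
    excess = np.maximum(cl - Cmin, 0.0)
    out = Imax * excess / (Km + excess)
    return out if out.ndim else float(out)


def _mm_deriv(cl: float, Imax: float, Km: float, Cmin: float) -> float:
    excess = cl - Cmin
    if excess <= 0:
        return 0.0
    return Imax * Km / (Km + excess) ** 2


def hair_uptake(clh, params: UptakeParams):
    """Root-hair uptake: per hair surface (Ih0) and per soil volume (Ih).

    Ih0 follows the same Michaelis-Menten law with the hair parameters;
    Ih = Ih0 * hair_surface_density inside the hair zone (the caller masks
    cells outside the zone).
    """
    ih0 = mm_influx(clh, params.Imaxh, params.Kmh, params.Cmin)
    return ih0, np.asarray(ih0) * params.hair_surface_density


@dataclass
class RadialGrid:
    """Finite-volume grid: cell-centre radii, face radii and concentrations."""

    r: np.ndarray  # cell centres, cm, strictly increasing
    cl: np.ndarray  # umol cm-3
    r1: float  # outer no-transfer radius, cm
    faces: np.ndarray  # cell faces, len(r) + 1

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.cl = np.asarray(self.cl, dtype=float)
        self.faces = np.asarray(self.faces, dtype=float)
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("node radii must be strictly increasing")
        if np.any(self.cl < 0):
            raise ValueError("concentrations must be non-negative")

    @property
    def cell_volumes(self) -> np.ndarray:
        """Annular soil volume per unit root length, cm3 cm-1."""
        return math.pi * np.diff(self.faces**2)

    def solute_mass(self, b: float) -> float:
        """Total diffusable solute per unit root length, umol cm-1."""
        return float(np.sum(b * self.cell_volumes * self.cl))


def make_grid(r0: float, r1: float, cl0: float, n_cells: int = 48) -> RadialGrid:
    """Log-spaced grid from r0 to r1 (refined at the root) at uniform cl0."""
    if r1 <= r0:
        raise ValueError(f"r1 ({r1}) must exceed r0 ({r0})")
    faces = np.geomspace(r0, r1, n_cells + 1)
    centres = np.sqrt(faces[:-1] * faces[1:])
    return RadialGrid(r=centres, cl=np.full(n_cells, float(cl0)), r1=r1, faces=faces)


def _surface_concentration(c0: float, d0: float, params: UptakeParams) -> float:
    """Solve the root-surface balance De*b*(C0-Cs)/d0 + v0*Cs = MM(Cs) for Cs."""
    g = lambda cs: (
        params.De * params.b * (c0 - cs) / d0
        + params.v0 * cs
        - mm_influx(cs, params.Imax, params.Km, params.Cmin)
    )
    hi = max(c0, params.Cmin) + params.Km
    lo = 0.0
    if g(lo) <= 0.0:
        return 0.0
    while g(hi) > 0.0:
        hi *= 2.0
        if hi > 1e12:
            raise NumericalStateError("surface-balance bracket failed")
    return brentq(g, lo, hi, xtol=1e-16, rtol=8.9e-16)


def _surface_uptake(c0: float, d0: float, params: UptakeParams) -> Tuple[float, float]:
    """Root-surface uptake per unit root length (umol cm-1 s-1) and dU/dC0."""
    cs = _surface_concentration(c0, d0, params)
    u = 2.0 * math.pi * params.r0 * mm_influx(cs, params.Imax, params.Km, params.Cmin)
    a = params.De * params.b / d0
    mmp = _mm_deriv(cs, params.Imax, params.Km, params.Cmin)
    denom = a - params.v0 + mmp
    dcs_dc0 = a / denom if denom > 0 else 0.0
    du_dc0 = 2.0 * math.pi * params.r0 * mmp * dcs_dc0
    return u, du_dc0


def _assemble(grid: RadialGrid, params: UptakeParams):
    """Precompute geometry and linear transport operator pieces."""
    r = grid.r
    faces = grid.faces
    n = r.size
    vol = grid.cell_volumes
    d0 = r[0] - faces[0]
    # interior faces j = 1..n-1 between cells j-1 and j
    rf = faces[1:-1]
    dr = np.diff(r)
    diff_coef = 2.0 * math.pi * rf * params.De * params.b / dr  # umol cm-1 s-1 per unit dC
    conv_coef = 2.0 * math.pi * params.r0 * params.v0  # inward convection, upwind = outer cell
    hair_mask = r <= params.r0 + params.hair_zone_radius
    return n, vol, d0, diff_coef, conv_coef, hair_mask


def _interior_fluxes(c: np.ndarray, diff_coef: np.ndarray, conv_coef: float) -> np.ndarray:
    """Outward-positive transport across interior faces, umol cm-1 s-1."""
    return -diff_coef * np.diff(c) - conv_coef * c[1:]


def solve_radial(
    grid: RadialGrid,
    params: UptakeParams,
    duration: float,
    dt: Optional[float] = None,
    *,
    newton_tol: float = 1e-12,
    max_newton: int = 50,
) -> Tuple[RadialGrid, float]:
    """Advance the radial problem by ``duration`` seconds.

    Returns the final grid and the cumulative uptake per unit root length
    (umol cm-1), root surface plus root hairs.  Backward Euler; if Newton
    fails to converge the step is automatically halved (never silently
    unstable).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt is None:
        dt = duration / 96.0
    n, vol, d0, diff_coef, conv_coef, hair_mask = _assemble(grid, params)
    bvol = params.b * vol
    hair_area = vol * params.hair_surface_density * hair_mask

    c = grid.cl.copy()
    cumulative = 0.0
    t = 0.0
    step = min(dt, duration)
    while t < duration - 1e-9:
        h = min(step, duration - t)
        result = _backward_euler_step(
            c, h, params, bvol, d0, diff_coef, conv_coef, hair_area,
            newton_tol, max_newton,
        )
        if result is None:
            step = h / 2.0
            if step < 1e-6:
                raise NumericalStateError("Newton failed to converge at minimal step")
            continue
        c_new, uptake_rate = result
        if not np.all(np.isfinite(c_new)):
            raise NumericalStateError(f"non-finite concentration at t={t + h:.1f}s")
        if c_new.min() < -1e-9 * max(c_new.max(), params.Cmin, 1e-12):
            raise NumericalStateError(f"negative concentration {c_new.min():.3e}")
        np.clip(c_new, 0.0, None, out=c_new)
        cumulative += uptake_rate * h
        c = c_new
        t += h

    out = replace(grid, cl=c)
    return out, cumulative


def _net_inflow(c, u, phi, n):
    """Net transport into each cell (outer face of the last cell is sealed)."""
    net = np.empty(n)
    net[0] = -u - phi[0]
    net[1:-1] = phi[:-1] - phi[1:]
    net[-1] = phi[-1]
    return net


def _backward_euler_step(
    c_old, h, params, bvol, d0, diff_coef, conv_coef, hair_area,
    newton_tol, max_newton,
):
    """One implicit step; returns (c_new, total uptake rate) or None on failure.

    resid_i = b*V_i*(c_i - c_i^old) - h*(net_i - sink_i); the Jacobian is
    tridiagonal with the Newton term dU/dC0 added at the root cell.
    """
    n = c_old.size
    c = c_old.copy()
    hairs_on = params.hair_surface_density > 0 and params.Imaxh > 0
    # phi[j] = -diff_coef[j]*(c[j+1]-c[j]) - conv_coef*c[j+1], face between j and j+1
    dl = diff_coef  # d phi[j] / d c[j]
    du_ = -diff_coef - conv_coef  # d phi[j] / d c[j+1]
    for _ in range(max_newton):
        u, du0 = _surface_uptake(c[0], d0, params)
        sink = hair_area * mm_influx(c, params.Imaxh, params.Kmh, params.Cmin)
        if hairs_on:
            dsink = hair_area * np.array(
                [_mm_deriv(ci, params.Imaxh, params.Kmh, params.Cmin) for ci in c]
            )
        else:
            dsink = np.zeros(n)
        phi = _interior_fluxes(c, diff_coef, conv_coef)
        resid = bvol * (c - c_old) - h * (_net_inflow(c, u, phi, n) - sink)

        diag = bvol + h * dsink
        diag[0] += h * (du0 + dl[0])
        diag[1:-1] += h * (dl[1:] - du_[:-1])
        diag[-1] += -h * du_[-1]
        sup = h * du_  # J[i, i+1], i = 0..n-2
        sub = -h * dl  # J[i+1, i], i = 0..n-2

        ab = np.zeros((3, n))
        ab[0, 1:] = sup
        ab[1, :] = diag
        ab[2, :-1] = sub
        try:
            delta = solve_banded((1, 1), ab, -resid)
        except Exception:
            return None
        c = c + delta
        if not np.all(np.isfinite(c)):
            return None
        if np.max(np.abs(delta)) < newton_tol:
            u, _ = _surface_uptake(c[0], d0, params)
            sink = hair_area * mm_influx(c, params.Imaxh, params.Kmh, params.Cmin)
            return c, u + float(np.sum(sink))
    return None


def solve_radial_reference(
    grid: RadialGrid,
    params: UptakeParams,
    duration: float,
    refine: int = 10,
    rtol: float = 1e-8,
) -> Tuple[RadialGrid, float]:
    """Reference solution on a ``refine``-times finer grid via stiff MOL integration.

    Independent of the production path: variable-order BDF time stepping
    (scipy) instead of backward Euler with Newton on the boundary.  Used as
    the accuracy oracle for :func:`solve_radial`.
    """
    fine = make_grid(grid.faces[0], grid.r1, 0.0, n_cells=grid.r.size * refine)
    fine.cl = np.interp(fine.r, grid.r, grid.cl)
    n, vol, d0, diff_coef, conv_coef, hair_mask = _assemble(fine, params)
    bvol = params.b * vol
    hair_area = vol * params.hair_surface_density * hair_mask

    def rhs(t, y):
        c = y[:-1]
        u, _ = _surface_uptake(max(c[0], 0.0), d0, params)
        ih0 = mm_influx(np.maximum(c, 0.0), params.Imaxh, params.Kmh, params.Cmin)
        sink = hair_area * ih0
        phi = _interior_fluxes(c, diff_coef, conv_coef)
        net = np.empty(n)
        net[0] = -u - phi[0]
        net[1:-1] = phi[:-1] - phi[1:]
        net[-1] = phi[-1]
        dc = (net - sink) / bvol
        return np.append(dc, u + np.sum(sink))

    pattern = sparse.lil_matrix((n + 1, n + 1))
    for i in range(n):
        for j in (i - 1, i, i + 1):
            if 0 <= j < n:
                pattern[i, j] = 1
    pattern[n, 0] = 1
    pattern[n, : min(n, len(hair_mask))] = 1
    y0 = np.append(fine.cl, 0.0)
    sol = solve_ivp(
        rhs, (0.0, duration), y0, method="BDF", rtol=rtol, atol=1e-14,
        jac_sparsity=pattern.tocsr(),
    )
    if not sol.success:
        raise NumericalStateError(f"reference integration failed: {sol.message}")
    c_end = np.maximum(sol.y[:-1, -1], 0.0)
    out = replace(fine, cl=c_end)
    return out, float(sol.y[-1, -1])


def uptake_per_layer(
    root_length_density: float,
    layer: LayerEnvironment,
    pools: PoolState,
    params: UptakeParams,
    *,
    duration: float = 86400.0,
    n_cells: int = 40,
    dt: Optional[float] = None,
) -> float:
    """Daily P uptake from one soil layer, kg P ha-1 d-1.

    The outer no-transfer radius is half the mean inter-root spacing,
    r1 = (pi * RLD)^(-1/2); the soluble (labile) pool maps to solution
    concentration through the buffer power.  Withdrawal never exceeds the
    soluble pool.
    """
    if root_length_density < 0:
        raise ValueError("root length density must be >= 0")
    if root_length_density == 0.0 or pools.soluble <= 0.0:
        return 0.0
    cl0 = units.pool_to_solution_conc(pools.soluble, layer.layer_thickness, params.b)
    if cl0 <= params.Cmin:
        return 0.0
    r1 = (math.pi * root_length_density) ** -0.5
    r1 = max(r1, 2.0 * params.r0)
    grid = make_grid(params.r0, r1, cl0, n_cells=n_cells)
    _, uptake_umol_cm = solve_radial(grid, params, duration, dt=dt)
    uptake = units.umol_per_cm_root_to_kg_ha(
        uptake_umol_cm, root_length_density, layer.layer_thickness
    )
    return min(uptake, pools.soluble)
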