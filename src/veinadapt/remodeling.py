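"""Tissue remodeling: immersed-boundary relaxation with mass sources.

The wall and its surroundings are a single highly viscous incompressible
medium on a staggered (MAC) grid.  The three elastic membranes exert
spring-tension forces spread to the grid through the regularized 4-point
cosine delta kernel, the medium velocity is advanced by a first-order
semi-implicit projection scheme (implicit diffusion, characteristics for
the convective term), and the pressure-correction Poisson problem carries
the local mass sources and sinks produced by the hourly cellular events.
Membranes and SMC particles are advected with the interpolated medium
velocity; SMCs additionally move actively under repulsion, matrix
invasion, chemotaxis and a bounded random walk.

Because the computational box is closed, the source field must integrate
to zero: wall-event sources are compensated by a sink placed either in the
lumen (inward remodeling, the lumen narrows) or in the external support
(outward remodeling), whichever the wall-energy criterion selects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from ._interp import bilinear
from .geometry import (EXTERNAL, INTIMA, LUMEN, MEDIA, AgentPopulation,
                       CellAgent, ECMField, InvalidGeometryError,
                       MembraneCurve, SimulationGrid, VesselCrossSection)
from .mechanics import FieldSet, _neumann_laplacian, lame_annulus_energy
from .params import MechanicsParams, RemodelingParams
from .plasticity import (APOPTOSIS, ECM_DEGRADATION, ECM_PRODUCTION,
                         MIGRATION, MITOSIS, EventBatch)

logger = logging.getLogger(__name__)

__all__ = [
    "IBMState", "StokesSolver",
    "peskin_delta_weights", "spread_to_grid", "interp_from_grid",
    "assemble_mass_sources", "spread_membrane_forces", "ibm_substep",
    "advect_membranes", "membrane_forces",
    "smc_velocity", "v_repulsion", "v_matrix_invasion", "v_chemotaxis",
    "v_random", "active_velocities", "inward_outward_adjust", "relax_tissue",
    "membrane_elastic_energy",
]


# ----------------------------------------------------------------------
# Regularized delta kernel (4-point cosine, Peskin)
# ----------------------------------------------------------------------

def _phi(r: np.ndarray) -> np.ndarray:
    """1D cosine kernel, support |r| < 2, exact partition of unity."""
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    m = np.abs(r) < 2.0
    out[m] = 0.25 * (1.0 + np.cos(np.pi * r[m] / 2.0))
    return out


def peskin_delta_weights(points: np.ndarray, x0: float, y0: float, h: float,
                         nx: int, ny: int):
    """4x4 stencil indices and tensor-product weights for each point.

    Returns (jj, ii, w) with shapes (m, 4), (m, 4), (m, 4, 4); w sums to 1
    per point whenever the stencil lies inside the grid.  The weights are
    the dimensionless kernel values; divide by h^2 for the delta function.
    """
    pts = np.atleast_2d(points)
    fx = (pts[:, 0] - x0) / h
    fy = (pts[:, 1] - y0) / h
    i0 = np.floor(fx).astype(int) - 1
    j0 = np.floor(fy).astype(int) - 1
    offs = np.arange(4)
    ii = i0[:, None] + offs[None, :]
    jj = j0[:, None] + offs[None, :]
    wx = _phi(fx[:, None] - ii)
    wy = _phi(fy[:, None] - jj)
    ii = np.clip(ii, 0, nx - 1)
    jj = np.clip(jj, 0, ny - 1)
    w = wy[:, :, None] * wx[:, None, :]
    return jj, ii, w


def spread_to_grid(points: np.ndarray, values: np.ndarray, x0: float,
                   y0: float, h: float, shape: tuple[int, int]) -> np.ndarray:
    """Spread Lagrangian values to a grid: f(x) = sum_l F_l delta_h(x - X_l)."""
    ny, nx = shape
    jj, ii, w = peskin_delta_weights(points, x0, y0, h, nx, ny)
    out = np.zeros(shape)
    vals = np.asarray(values, dtype=float)[:, None, None] * w / h ** 2
    np.add.at(out, (jj[:, :, None], ii[:, None, :]), vals)
    return out


def interp_from_grid(field: np.ndarray, points: np.ndarray, x0: float,
                     y0: float, h: float) -> np.ndarray:
    """Adjoint of :func:`spread_to_grid`: U(X_l) = sum_ij u_ij delta_h h^2."""
    ny, nx = field.shape
    jj, ii, w = peskin_delta_weights(points, x0, y0, h, nx, ny)
    return np.einsum("mab,mab->m", w, field[jj[:, :, None], ii[:, None, :]])


# ----------------------------------------------------------------------
# Staggered-grid projection solver
# ----------------------------------------------------------------------

@dataclass
class IBMState:
    """MAC velocity field, pressure correction and source density."""

    u: np.ndarray                   # (ny, nx+1)
    v: np.ndarray                   # (ny+1, nx)
    pressure_correction: np.ndarray  # (ny, nx)
    source_density: np.ndarray       # (ny, nx), 1/time

    @classmethod
    def zeros(cls, grid: SimulationGrid) -> "IBMState":
        return cls(u=np.zeros((grid.ny, grid.nx + 1)),
                   v=np.zeros((grid.ny + 1, grid.nx)),
                   pressure_correction=np.zeros((grid.ny, grid.nx)),
                   source_density=np.zeros((grid.ny, grid.nx)))


def _dirichlet_laplacian_1d(n: int) -> sp.dia_matrix:
    e = np.ones(n)
    return sp.diags([e[:-1], -2.0 * e, e[:-1]], [-1, 0, 1])


class StokesSolver:
    """Prefactorized operators for the semi-implicit projection scheme.

    Geometry and time step are fixed over a run, so the implicit-diffusion
    and pressure-Poisson factorizations are built once.
    """

    def __init__(self, grid: SimulationGrid, params: RemodelingParams):
        self.grid = grid
        self.params = params
        nx, ny, h = grid.nx, grid.ny, grid.h
        dt = params.dt_ibm
        nu = params.mu_tissue / params.rho

        Lu = (sp.kron(sp.eye(ny), _dirichlet_laplacian_1d(nx - 1))
              + sp.kron(_dirichlet_laplacian_1d(ny), sp.eye(nx - 1))) / h ** 2
        Lv = (sp.kron(sp.eye(ny - 1), _dirichlet_laplacian_1d(nx))
              + sp.kron(_dirichlet_laplacian_1d(ny - 1), sp.eye(nx))) / h ** 2
        self._solve_u = spla.factorized((sp.eye((nx - 1) * ny) - dt * nu * Lu).tocsc())
        self._solve_v = spla.factorized((sp.eye(nx * (ny - 1)) - dt * nu * Lv).tocsc())

        Lp = _neumann_laplacian(ny, nx, h).tolil()
        Lp[0, :] = 0.0
        Lp[0, 0] = 1.0          # pin one cell; compatible RHS keeps identity exact
        self._solve_p = spla.factorized(Lp.tocsc())

        # face coordinate origins and cached face/cell coordinate arrays
        self.u_origin = (grid.origin[0] - h / 2.0, grid.origin[1])
        self.v_origin = (grid.origin[0], grid.origin[1] - h / 2.0)
        Xu, Yu = np.meshgrid(self.u_origin[0] + h * np.arange(nx + 1),
                             self.u_origin[1] + h * np.arange(ny))
        self._u_pts = np.column_stack([Xu.ravel(), Yu.ravel()])
        Xv, Yv = np.meshgrid(self.v_origin[0] + h * np.arange(nx),
                             self.v_origin[1] + h * np.arange(ny + 1))
        self._v_pts = np.column_stack([Xv.ravel(), Yv.ravel()])
        Xc, Yc = grid.cell_centers()
        self._cell_pts = np.column_stack([Xc.ravel(), Yc.ravel()])

    # -- helpers -------------------------------------------------------
    def divergence(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        h = self.grid.h
        return (u[:, 1:] - u[:, :-1]) / h + (v[1:, :] - v[:-1, :]) / h

    def velocity_at(self, u: np.ndarray, v: np.ndarray, pts: np.ndarray,
                    kernel: bool = True) -> np.ndarray:
        """Medium velocity interpolated at points (delta kernel by default)."""
        if kernel:
            ux = interp_from_grid(u, pts, *self.u_origin, self.grid.h)
            vy = interp_from_grid(v, pts, *self.v_origin, self.grid.h)
        else:
            ux = bilinear(u, *self.u_origin, self.grid.h, pts)
            vy = bilinear(v, *self.v_origin, self.grid.h, pts)
        return np.column_stack([ux, vy])


def spread_membrane_forces(membranes, grid: SimulationGrid,
                           solver: StokesSolver | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Elastic membrane tension spread to the MAC velocity grids."""
    if solver is None:
        u_origin = (grid.origin[0] - grid.h / 2.0, grid.origin[1])
        v_origin = (grid.origin[0], grid.origin[1] - grid.h / 2.0)
    else:
        u_origin, v_origin = solver.u_origin, solver.v_origin
    f_u = np.zeros((grid.ny, grid.nx + 1))
    f_v = np.zeros((grid.ny + 1, grid.nx))
    for m in membranes:
        F = membrane_forces(m)
        f_u += spread_to_grid(m.points, F[:, 0], *u_origin, grid.h,
                              f_u.shape)
        f_v += spread_to_grid(m.points, F[:, 1], *v_origin, grid.h,
                              f_v.shape)
    return f_u, f_v


def membrane_forces(membrane: MembraneCurve) -> np.ndarray:
    """Net linear-spring force on each Lagrangian point (segments vs rest)."""
    vec = membrane.segment_vectors()
    length = np.linalg.norm(vec, axis=1)
    tang = vec / np.maximum(length[:, None], 1e-30)
    tension = membrane.stiffness * (length - membrane.rest_lengths) \
        / np.maximum(membrane.rest_lengths, 1e-30)
    pull = tension[:, None] * tang       # force on point i toward point i+1
    return pull - np.roll(pull, 1, axis=0)


def membrane_elastic_energy(membrane: MembraneCurve) -> float:
    """Quadratic spring energy of the membrane segments."""
    length = membrane.segment_lengths()
    strain = (length - membrane.rest_lengths) / np.maximum(membrane.rest_lengths, 1e-30)
    return float(0.5 * membrane.stiffness
                 * np.sum(strain ** 2 * membrane.rest_lengths))


def assemble_mass_sources(batch: EventBatch, grid: SimulationGrid,
                          params: RemodelingParams, r_smc: float,
                          r_ecm: float) -> np.ndarray:
    """Source density (1/time) from the hourly event batch.

    Each mitosis (ECM production) deposits one SMC (ECM) element area over
    its containing cell, released uniformly over the relaxation period
    delta_t; apoptosis and degradation are the matching sinks.
    """
    s = np.zeros((grid.ny, grid.nx))
    a_smc = math.pi * r_smc ** 2
    a_ecm = math.pi * r_ecm ** 2
    amount = {MITOSIS: a_smc, APOPTOSIS: -a_smc,
              ECM_PRODUCTION: a_ecm, ECM_DEGRADATION: -a_ecm}
    for ev in batch:
        if ev.kind == MIGRATION:
            continue
        x, y = ev.location
        i = int(np.clip(round((x - grid.origin[0]) / grid.h), 0, grid.nx - 1))
        j = int(np.clip(round((y - grid.origin[1]) / grid.h), 0, grid.ny - 1))
        s[j, i] += amount[ev.kind] / (grid.h ** 2 * params.delta_t)
    return s


def ibm_substep(state: IBMState, forces: tuple[np.ndarray, np.ndarray],
                params: RemodelingParams, solver: StokesSolver) -> IBMState:
    """One projection substep: predict, source-corrected project, correct.

    The corrector solves ΔΠ = (rho/dt)(∇·V* − s) with homogeneous Neumann
    walls, so the corrected velocity satisfies ∇·V = s exactly in the
    discrete sense.  An incompatible source integral (nonzero total with
    closed walls) is auto-balanced by subtracting its mean.
    """
    g = solver.grid
    dt = params.dt_ibm
    h = g.h
    f_u, f_v = forces
    u, v = state.u, state.v

    # CFL guard for the characteristics step
    vmax = max(np.abs(u).max(), np.abs(v).max(), 1e-30)
    if vmax * dt > 2.0 * h:
        logger.warning("IBM substep CFL exceeded: |V| dt = %.3g > 2h", vmax * dt)

    # -- predictor: characteristics for convection, implicit diffusion
    u_adv = _advect_component(u, v, dt, solver, which="u")
    v_adv = _advect_component(u, v, dt, solver, which="v")
    u_rhs = u_adv + dt / params.rho * f_u
    v_rhs = v_adv + dt / params.rho * f_v

    u_star = np.zeros_like(u)
    v_star = np.zeros_like(v)
    u_star[:, 1:-1] = solver._solve_u(u_rhs[:, 1:-1].ravel()).reshape(g.ny, g.nx - 1)
    v_star[1:-1, :] = solver._solve_v(v_rhs[1:-1, :].ravel()).reshape(g.ny - 1, g.nx)

    # -- corrector with mass sources
    s = state.source_density
    div = solver.divergence(u_star, v_star)
    rhs = (params.rho / dt) * (div - s)
    imbalance = rhs.mean()
    if abs(imbalance) * g.nx * g.ny * h ** 2 > 1e-9 * (np.abs(s).sum() * h ** 2 + 1e-30):
        logger.debug("projection RHS imbalance %.3g auto-balanced", imbalance)
    rhs = rhs - rhs.mean()
    rhs_flat = rhs.ravel().copy()
    rhs_flat[0] = 0.0
    Pi = solver._solve_p(rhs_flat).reshape(g.ny, g.nx)

    u_new = u_star.copy()
    v_new = v_star.copy()
    u_new[:, 1:-1] -= dt / params.rho * (Pi[:, 1:] - Pi[:, :-1]) / h
    v_new[1:-1, :] -= dt / params.rho * (Pi[1:, :] - Pi[:-1, :]) / h
    return IBMState(u=u_new, v=v_new, pressure_correction=Pi,
                    source_density=state.source_density)


def _advect_component(u: np.ndarray, v: np.ndarray, dt: float,
                      solver: StokesSolver, which: str) -> np.ndarray:
    """Semi-Lagrangian (method of characteristics) transport of one component."""
    g = solver.grid
    h = g.h
    if which == "u":
        x0, y0 = solver.u_origin
        ny, nx = u.shape
        fld, other, other_origin, pts = u, v, solver.v_origin, solver._u_pts
    else:
        x0, y0 = solver.v_origin
        ny, nx = v.shape
        fld, other, other_origin, pts = v, u, solver.u_origin, solver._v_pts
    here = fld.ravel()
    cross = bilinear(other, *other_origin, h, pts)
    vel = np.column_stack([here, cross]) if which == "u" \
        else np.column_stack([cross, here])
    dep = pts - dt * vel
    return bilinear(fld, x0, y0, h, dep).reshape(ny, nx)


def advect_membranes(membranes, state: IBMState, solver: StokesSolver,
                     dt_ibm: float, max_halvings: int = 5):
    """Move each Lagrangian point with the kernel-interpolated velocity.

    If a move produces a self-intersecting curve the step is retried with a
    halved time step (the membrane simply moves less this substep); after
    ``max_halvings`` failures the substep aborts.
    """
    out = []
    for m in membranes:
        vel = solver.velocity_at(state.u, state.v, m.points, kernel=True)
        dt = dt_ibm
        for attempt in range(max_halvings + 1):
            cand = MembraneCurve(m.points + dt * vel, m.rest_lengths.copy(),
                                 m.stiffness, m.porosity_threshold)
            if cand.is_simple():
                out.append(cand)
                break
            dt *= 0.5
            logger.warning("membrane self-intersection; halving dt to %.3g", dt)
        else:
            raise InvalidGeometryError("membrane self-intersects after max halvings")
    return out


# ----------------------------------------------------------------------
# SMC motility potentials
# ----------------------------------------------------------------------

def v_repulsion(agent: CellAgent, neighbors, params: RemodelingParams,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Cell-cell repulsion: linear decay to zero at distance 2 n_s R_SMC.

    Neighbors must belong to the same layer.  Coincident centers get a
    random direction at full magnitude (logged).
    """
    cutoff = 2.0 * params.n_s * agent.radius
    total = np.zeros(2)
    p = np.asarray(agent.position, dtype=float)
    for nb in neighbors:
        q = np.asarray(nb.position if hasattr(nb, "position") else nb, dtype=float)
        d = p - q
        dist = float(np.hypot(*d))
        if dist >= cutoff:
            continue
        mag = params.k_S * _repulsion_profile(dist, cutoff, params)
        if dist < 1e-12:
            logger.warning("coincident SMC centers; random repulsion direction")
            theta = (rng.random() * 2 * np.pi if rng is not None else 0.0)
            total += mag * np.array([np.cos(theta), np.sin(theta)])
        else:
            total += mag * d / dist
    return total


def _repulsion_profile(dist: float | np.ndarray, cutoff: float,
                       params: RemodelingParams):
    """Dimensionless amplitude profile: linear decay, or the optional
    truncated Lennard-Jones-like alternative behind the config switch."""
    lin = np.maximum(0.0, 1.0 - np.asarray(dist) / cutoff)
    if not params.lennard_jones_repulsion:
        return lin
    # soft LJ-style: steeper near contact, same cutoff and unit scale
    x = np.maximum(np.asarray(dist) / cutoff, 0.05)
    return np.clip((x ** -2 - 1.0) / (0.05 ** -2 - 1.0), 0.0, 1.0)


def v_matrix_invasion(agent: CellAgent, ecm: ECMField, occupied: np.ndarray,
                      grid: SimulationGrid, params: RemodelingParams
                      ) -> np.ndarray:
    """Attraction toward ECM-occupied, cell-free cells within 2 n_e R_SMC."""
    cutoff = 2.0 * params.n_e * agent.radius
    p = np.asarray(agent.position, dtype=float)
    rcells = int(math.ceil(cutoff / grid.h)) + 1
    i0 = int(round((p[0] - grid.origin[0]) / grid.h))
    j0 = int(round((p[1] - grid.origin[1]) / grid.h))
    ilo, ihi = max(0, i0 - rcells), min(grid.nx, i0 + rcells + 1)
    jlo, jhi = max(0, j0 - rcells), min(grid.ny, j0 + rcells + 1)
    xs = grid.origin[0] + grid.h * np.arange(ilo, ihi)
    ys = grid.origin[1] + grid.h * np.arange(jlo, jhi)
    X, Y = np.meshgrid(xs, ys)
    dx = X - p[0]
    dy = Y - p[1]
    dist = np.hypot(dx, dy)
    dens = ecm.density[jlo:jhi, ilo:ihi]
    free = ~occupied[jlo:jhi, ilo:ihi]
    wgt = params.k_E * np.maximum(0.0, 1.0 - dist / cutoff) * dens * free
    wgt[dist < 1e-12] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(dist > 0, dx / dist, 0.0)
        uy = np.where(dist > 0, dy / dist, 0.0)
    return np.array([float((wgt * ux).sum()), float((wgt * uy).sum())])


def v_chemotaxis(agent: CellAgent, G_grad: tuple[np.ndarray, np.ndarray],
                 grid: SimulationGrid, params: RemodelingParams) -> np.ndarray:
    """k_G times the growth-factor gradient at the agent position."""
    gx, gy = G_grad
    p = np.asarray(agent.position, dtype=float)[None, :]
    return params.k_G * np.array([
        float(bilinear(gx, grid.origin[0], grid.origin[1], grid.h, p)[0]),
        float(bilinear(gy, grid.origin[0], grid.origin[1], grid.h, p)[0])])


def v_random(rng: np.random.Generator, params: RemodelingParams,
             r_smc: float) -> np.ndarray:
    """Isotropic random motility bounded so |V_R| delta_t <= R_SMC."""
    theta = rng.random() * 2.0 * np.pi
    mag = rng.random() * params.random_motility * r_smc / params.delta_t
    return mag * np.array([np.cos(theta), np.sin(theta)])


def smc_velocity(agent: CellAgent, agents, ecm: ECMField, G_field: np.ndarray,
                 rng: np.random.Generator, params: RemodelingParams,
                 grid: SimulationGrid,
                 toggles: frozenset | set = frozenset({"random", "repulsion",
                                                       "invasion", "chemotaxis"}),
                 ) -> np.ndarray:
    """Active velocity of a single SMC: V_S + V_E + V_G + V_R."""
    neighbors = [a for a in agents
                 if a.id != agent.id and a.layer == agent.layer]
    occupied = _occupancy(grid, np.array([a.position for a in agents])
                          if agents else np.empty((0, 2)))
    total = np.zeros(2)
    if "repulsion" in toggles:
        total += v_repulsion(agent, neighbors, params, rng)
    if "invasion" in toggles:
        total += v_matrix_invasion(agent, ecm, occupied, grid, params)
    if "chemotaxis" in toggles:
        gy, gx = np.gradient(G_field, grid.h)
        total += v_chemotaxis(agent, (gx, gy), grid, params)
    if "random" in toggles:
        total += v_random(rng, params, agent.radius)
    return total


def _invasion_all(pop: AgentPopulation, ecm: ECMField, grid: SimulationGrid,
                  params: RemodelingParams) -> np.ndarray:
    """Vectorized matrix-invasion velocity for the whole population."""
    n = len(pop)
    cutoff = 2.0 * params.n_e * pop.radius
    rcells = int(math.ceil(cutoff / grid.h)) + 1
    offs = np.arange(-rcells, rcells + 1)
    offx, offy = np.meshgrid(offs, offs)
    offx, offy = offx.ravel(), offy.ravel()           # (K,)
    i0 = np.round((pop.pos[:, 0] - grid.origin[0]) / grid.h).astype(int)
    j0 = np.round((pop.pos[:, 1] - grid.origin[1]) / grid.h).astype(int)
    ii = np.clip(i0[:, None] + offx[None, :], 0, grid.nx - 1)
    jj = np.clip(j0[:, None] + offy[None, :], 0, grid.ny - 1)
    cx = grid.origin[0] + ii * grid.h
    cy = grid.origin[1] + jj * grid.h
    dx = cx - pop.pos[:, 0:1]
    dy = cy - pop.pos[:, 1:2]
    dist = np.hypot(dx, dy)
    occupied = _occupancy(grid, pop.pos)
    wgt = (params.k_E * np.maximum(0.0, 1.0 - dist / cutoff)
           * ecm.density[jj, ii] * ~occupied[jj, ii])
    wgt[dist < 1e-12] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(dist > 0, dx / dist, 0.0)
        uy = np.where(dist > 0, dy / dist, 0.0)
    return np.column_stack([(wgt * ux).sum(axis=1), (wgt * uy).sum(axis=1)])


def _occupancy(grid: SimulationGrid, positions: np.ndarray) -> np.ndarray:
    occ = np.zeros((grid.ny, grid.nx), dtype=bool)
    if len(positions):
        ii = np.clip(np.round((positions[:, 0] - grid.origin[0]) / grid.h
                              ).astype(int), 0, grid.nx - 1)
        jj = np.clip(np.round((positions[:, 1] - grid.origin[1]) / grid.h
                              ).astype(int), 0, grid.ny - 1)
        occ[jj, ii] = True
    return occ


def active_velocities(pop: AgentPopulation, ecm: ECMField, G_field: np.ndarray,
                      grid: SimulationGrid, params: RemodelingParams,
                      rng: np.random.Generator,
                      toggles: frozenset | set = frozenset({"random", "repulsion",
                                                            "invasion", "chemotaxis"}),
                      ) -> np.ndarray:
    """Vectorized active velocities for the whole population."""
    n = len(pop)
    out = np.zeros((n, 2))
    if n == 0:
        return out
    R = pop.radius
    if "repulsion" in toggles and n > 1:
        cutoff = 2.0 * params.n_s * R
        tree = cKDTree(pop.pos)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs):
            same = pop.layer[pairs[:, 0]] == pop.layer[pairs[:, 1]]
            pairs = pairs[same]
        if len(pairs):
            d = pop.pos[pairs[:, 0]] - pop.pos[pairs[:, 1]]
            dist = np.hypot(d[:, 0], d[:, 1])
            coincident = dist < 1e-12
            if coincident.any():
                logger.warning("coincident SMC centers; random repulsion direction")
                theta = rng.random(int(coincident.sum())) * 2 * np.pi
                d[coincident] = np.column_stack([np.cos(theta), np.sin(theta)])
                dist[coincident] = 1.0
            unit = d / dist[:, None]
            mag = params.k_S * _repulsion_profile(dist, cutoff, params)
            np.add.at(out, pairs[:, 0], mag[:, None] * unit)
            np.add.at(out, pairs[:, 1], -mag[:, None] * unit)
    if "invasion" in toggles:
        out += _invasion_all(pop, ecm, grid, params)
    if "chemotaxis" in toggles:
        gy, gx = np.gradient(G_field, grid.h)
        out[:, 0] += params.k_G * bilinear(gx, grid.origin[0], grid.origin[1],
                                           grid.h, pop.pos)
        out[:, 1] += params.k_G * bilinear(gy, grid.origin[0], grid.origin[1],
                                           grid.h, pop.pos)
    if "random" in toggles:
        theta = rng.random(n) * 2.0 * np.pi
        mag = rng.random(n) * params.random_motility * R / params.delta_t
        out[:, 0] += mag * np.cos(theta)
        out[:, 1] += mag * np.sin(theta)
    return out


# ----------------------------------------------------------------------
# Inward / outward remodeling choice
# ----------------------------------------------------------------------

def inward_outward_adjust(section: VesselCrossSection,
                          mechanics: MechanicsParams,
                          params: RemodelingParams,
                          net_source_area: float = 0.0) -> float:
    """Signed lumen-side mass term (mm^2 per relaxation period).

    The remodeling mode is selected by probing the wall energy with a trial
    inward and a trial outward perturbation of the lumen boundary (one SMC
    disc area): if the inward trial strictly lowers the closed-form
    thick-cylinder energy below both the unperturbed and the outward trial,
    the cycle remodels inward and the whole net wall-area change is
    accommodated on the lumen side (a lumen sink when the wall grows, a
    lumen source when it shrinks — so balanced turnover does not rectify
    into lumen drift); symmetrically for the outward trial.  A tie, or
    ``adjust_magnitude = 0``, leaves the accommodation to the external
    side and yields a zero lumen term.
    """
    if params.adjust_magnitude == 0.0 or net_source_area == 0.0:
        return 0.0
    A_lum = section.lumen_area()
    A_wall = section.wall_area()
    p_i, p_e = mechanics.p_internal, mechanics.p_external
    probe = math.pi * (0.5 * section.grid.h) ** 2 + abs(net_source_area)

    def energy(a_lum: float, a_wall: float) -> float:
        a = math.sqrt(max(a_lum, 1e-12) / math.pi)
        b = math.sqrt((max(a_lum, 1e-12) + a_wall) / math.pi)
        return lame_annulus_energy(a, b, p_i, p_e, mechanics.E, mechanics.nu)

    a_wall_new = A_wall + net_source_area
    e_none = energy(A_lum, a_wall_new)
    e_in = energy(A_lum - probe, a_wall_new)
    e_out = energy(A_lum + probe, a_wall_new)
    if e_in < e_none and e_in <= e_out:
        # inward remodeling: the wall reorganizes on the lumen side
        return -params.adjust_magnitude * net_source_area
    # outward remodeling (or an exact tie): the lumen is left alone and the
    # change is absorbed by the external support
    return 0.0


# ----------------------------------------------------------------------
# Full relaxation cycle
# ----------------------------------------------------------------------

def _place_daughter(section: VesselCrossSection, parent_pos: np.ndarray,
                    layer: int, r_smc: float, rng: np.random.Generator
                    ) -> np.ndarray:
    """Daughter at one cell diameter from the parent, inside the parent layer."""
    theta = rng.random(20) * 2.0 * np.pi
    cands = parent_pos + 2.0 * r_smc * np.column_stack([np.cos(theta),
                                                        np.sin(theta)])
    ok = np.nonzero(section.layer_of(cands) == layer)[0]
    if len(ok):
        return cands[ok[0]]
    # fall back: radially inward (toward the vessel axis)
    r = np.linalg.norm(parent_pos)
    direction = -parent_pos / r if r > 1e-12 else np.array([1.0, 0.0])
    return parent_pos + 2.0 * r_smc * direction


def _apply_events(section: VesselCrossSection, pop: AgentPopulation,
                  ecm: ECMField, batch: EventBatch,
                  rng: np.random.Generator
                  ) -> tuple[float, list[tuple[tuple[int, int], float]]]:
    """Mutate population and ECM per the batch.

    Returns the actually applied net area change (mm^2) and the per-cell
    shortfall of ECM degradation events that found too little matrix.
    """
    g = section.grid
    a_smc = math.pi * pop.radius ** 2
    a_ecm = ecm.element_area
    net = 0.0
    shortfalls: list[tuple[tuple[int, int], float]] = []
    dead: list[int] = []
    for ev in batch:
        if ev.kind == MITOSIS:
            idx = pop.index_of(ev.agent_id)
            layer = int(pop.layer[idx])
            pos = _place_daughter(section, pop.pos[idx], layer, pop.radius, rng)
            pop.add(pos, layer, mitosis_clock=0.0,
                    ecm_clock=rng.random() * 2.0)
            net += a_smc
        elif ev.kind == APOPTOSIS:
            dead.append(ev.agent_id)
            net -= a_smc
        elif ev.kind == ECM_PRODUCTION:
            j, i = ev.cell_index
            ecm.density[j, i] += a_ecm / g.h ** 2
            net += a_ecm
        elif ev.kind == ECM_DEGRADATION:
            j, i = ev.cell_index
            avail = ecm.density[j, i] * g.h ** 2
            removed = min(a_ecm, avail)
            ecm.density[j, i] -= removed / g.h ** 2
            net -= removed
            if removed < a_ecm:
                shortfalls.append(((j, i), a_ecm - removed))
        elif ev.kind == MIGRATION:
            idx = pop.index_of(ev.agent_id)
            iel = section.iel
            k = cKDTree(iel.points).query(pop.pos[idx][None, :])[1][0]
            q = iel.points[k]
            d = q - pop.pos[idx]
            dist = float(np.hypot(*d))
            if dist > 1e-12:
                pop.pos[idx] = q + 1.2 * pop.radius * d / dist
                pop.layer[idx] = INTIMA
    if dead:
        mask = np.isin(pop.ids, dead)
        pop.remove(mask)
    return net, shortfalls


def _constrain_agents(section: VesselCrossSection, pop: AgentPopulation,
                      old_pos: np.ndarray, active_disp: np.ndarray) -> None:
    """Keep agents inside their layer: reflect the active displacement at
    the offending membrane, falling back to the passive-only and then the
    previous position."""
    labels = section.layer_of(pop.pos)
    bad = np.nonzero(labels != pop.layer)[0]
    if len(bad) == 0:
        return
    # stage 1: reflect the active displacement at the crossed membrane
    cands = np.empty((len(bad), 2))
    for m, idx in enumerate(bad):
        label = labels[idx]
        if label == LUMEN:
            membrane = section.lumen_wall
        elif label == EXTERNAL:
            membrane = section.external_wall
        else:
            membrane = section.iel
        k = cKDTree(membrane.points).query(pop.pos[idx][None, :])[1][0]
        nbr = membrane.points[(k + 1) % len(membrane.points)] - membrane.points[k - 1]
        t = nbr / max(np.linalg.norm(nbr), 1e-30)
        nvec = np.array([-t[1], t[0]])
        d = active_disp[idx]
        reflected = d - 2.0 * float(d @ nvec) * nvec
        cands[m] = old_pos[idx] + (pop.pos[idx] - old_pos[idx] - d) + reflected
    ok = section.layer_of(cands) == pop.layer[bad]
    pop.pos[bad[ok]] = cands[ok]
    # stage 2: passive move only
    rem = bad[~ok]
    if len(rem):
        cands = pop.pos[rem] - active_disp[rem]
        ok2 = section.layer_of(cands) == pop.layer[rem]
        pop.pos[rem[ok2]] = cands[ok2]
        # stage 3: stay put
        pop.pos[rem[~ok2]] = old_pos[rem[~ok2]]


def relax_tissue(section: VesselCrossSection, pop: AgentPopulation,
                 ecm: ECMField, batch: EventBatch, fields: FieldSet,
                 mech_params: MechanicsParams, params: RemodelingParams,
                 rng: np.random.Generator,
                 solver: StokesSolver | None = None,
                 motility_toggles: frozenset | set = frozenset(
                     {"random", "repulsion", "invasion", "chemotaxis"}),
                 lumen_term: float | None = None) -> dict:
    """One full hourly remodeling cycle.

    Applies the event batch to agents and ECM, assembles the mass sources
    (with the energy-selected lumen-side term and the balancing sink in the
    external support), then runs the IBM substeps moving membranes, agents
    and ECM with the medium, agents additionally with their active
    motility.  Returns cycle diagnostics.
    """
    g = section.grid
    if solver is None:
        solver = StokesSolver(g, params)

    net, shortfalls = _apply_events(section, pop, ecm, batch, rng)
    if lumen_term is None:
        lumen_term = inward_outward_adjust(section, mech_params, params, net)

    s = assemble_mass_sources(batch, g, params, pop.radius, ecm.element_radius)
    # degradation events limited by available matrix: cancel the shortfall
    for (j, i), area in shortfalls:
        s[j, i] += area / (g.h ** 2 * params.delta_t)

    lum_mask = section.region_mask == LUMEN
    ext_mask = section.region_mask == EXTERNAL
    if lumen_term != 0.0 and lum_mask.any():
        s[lum_mask] += lumen_term / (lum_mask.sum() * g.h ** 2 * params.delta_t)
    residual = -(net + lumen_term)
    if ext_mask.any():
        s[ext_mask] += residual / (ext_mask.sum() * g.h ** 2 * params.delta_t)

    state = IBMState.zeros(g)
    state.source_density = s
    dt = params.dt_ibm
    for _ in range(params.substeps):
        forces = spread_membrane_forces(section.membranes(), g, solver)
        state = ibm_substep(state, forces, params, solver)
        new_membranes = advect_membranes(section.membranes(), state, solver, dt)
        section.lumen_wall, section.iel, section.external_wall = new_membranes

        if len(pop):
            old_pos = pop.pos.copy()
            passive = solver.velocity_at(state.u, state.v, pop.pos, kernel=True)
            act = active_velocities(pop, ecm, fields.G, g, params, rng,
                                    motility_toggles)
            pop.pos = pop.pos + dt * (passive + act)
            _constrain_agents(section, pop, old_pos, dt * act)

        # ECM density rides the medium (semi-Lagrangian)
        pts = solver._cell_pts
        vel = solver.velocity_at(state.u, state.v, pts, kernel=False)
        dep = pts - dt * vel
        ecm.density = bilinear(ecm.density, g.origin[0], g.origin[1], g.h,
                               dep).reshape(g.ny, g.nx)

    section.update_region_mask()
    section.assert_simple()
    wall = (section.region_mask == INTIMA) | (section.region_mask == MEDIA)
    ecm.density[~wall] = 0.0

    # membranes adapt plastically on the hourly scale
    if params.plastic_rate > 0:
        for m in section.membranes():
            cur = m.segment_lengths()
            m.rest_lengths = ((1.0 - params.plastic_rate) * m.rest_lengths
                              + params.plastic_rate * cur)

    return {"net_source_area": net, "lumen_term": lumen_term,
            "elastic_energy": sum(membrane_elastic_energy(m)
                                  for m in section.membranes())}
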