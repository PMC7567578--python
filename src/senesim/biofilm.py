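"""2D biofilm environment.

Cells grow attached to a flat substratum at the bottom of a rectangular
domain with periodic lateral boundaries. Substrate diffuses in from the
bulk liquid above through a concentration boundary layer of fixed
thickness ``b_L``; inside the biofilm it is consumed following Monod
kinetics. Because reaction-diffusion is much faster than growth, the
substrate field is solved to steady state at each step with the biomass
frozen, then the cells are stepped at their local (interpolated)
substrate concentrations, divide, and mechanical overlaps are relaxed by
shoving. The simulation stops when the front reaches ``h_max`` (rather
than detaching biomass).

Cells are disks in the plane whose area derives from their volume
assuming an out-of-plane slab thickness equal to the grid resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree

from .params import KineticParams, StrategyParams
from .population import Population

__all__ = [
    "BiofilmDomain",
    "BiofilmSim",
    "NODE_BIOFILM",
    "NODE_BOUNDARY",
    "NODE_BULK",
    "classify_nodes",
    "solve_substrate",
    "relax_overlaps",
    "biofilm_front",
    "biofilm_env",
    "step_biofilm",
    "run_biofilm",
]

log = logging.getLogger(__name__)

NODE_BIOFILM = 0
NODE_BOUNDARY = 1
NODE_BULK = 2

#: glucose diffusivity, m^2/s
D_G_DEFAULT = 6.7e-10
M2_PER_S_TO_UM2_PER_H = 1e12 * 3600.0


@dataclass(frozen=True)
class BiofilmDomain:
    """Geometry and transport parameters of the biofilm domain."""

    width: float = 256.0  # um
    height: float = 256.0  # um
    resolution: float = 4.0  # um, grid spacing (quasi-2D slab thickness)
    S_bulk: float = 0.003556  # g/L
    D_G: float = D_G_DEFAULT  # m^2/s
    b_L: float = 48.0  # um, boundary layer thickness
    h_max: float = 154.0  # um, stopping height
    shove_factor: float = 1.10

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0 or self.resolution <= 0:
            raise ValueError("domain dimensions must be positive")
        if self.h_max >= self.height:
            raise ValueError("h_max must be below the domain height")
        nx = self.width / self.resolution
        ny = self.height / self.resolution
        if abs(nx - round(nx)) > 1e-9 or abs(ny - round(ny)) > 1e-9:
            raise ValueError("width and height must be multiples of the resolution")

    @property
    def nx(self) -> int:
        return int(round(self.width / self.resolution))

    @property
    def ny(self) -> int:
        return int(round(self.height / self.resolution))

    @property
    def D_G_um2h(self) -> float:
        return self.D_G * M2_PER_S_TO_UM2_PER_H

    @property
    def node_volume(self) -> float:
        """um^3 of one grid node (slab thickness = resolution)."""
        return self.resolution**3


def _node_index(pop: Population, domain: BiofilmDomain):
    """Column/row of the node containing each cell center."""
    res = domain.resolution
    cx = np.floor(np.mod(pop.x, domain.width) / res).astype(np.int64)
    cy = np.clip(np.floor(pop.y / res).astype(np.int64), 0, domain.ny - 1)
    return cy, cx


def biomass_mask(pop: Population, domain: BiofilmDomain) -> np.ndarray:
    """(ny, nx) boolean mask of nodes containing any biomass."""
    mask = np.zeros((domain.ny, domain.nx), dtype=bool)
    if len(pop):
        cy, cx = _node_index(pop, domain)
        mask[cy, cx] = True
    return mask


def classify_nodes(pop_or_mask, domain: BiofilmDomain) -> np.ndarray:
    """Classify grid nodes as biofilm (contain biomass), boundary layer
    (within ``b_L`` of biomass; diffusion only) or bulk (farther than
    ``b_L``; substrate pinned at S_bulk).

    The distance is the node-center distance to the nearest biofilm
    node, computed with a periodic-in-x Euclidean distance transform.
    The substratum is the no-flux plane at the bottom edge.
    """
    if isinstance(pop_or_mask, Population):
        mask = biomass_mask(pop_or_mask, domain)
    else:
        mask = np.asarray(pop_or_mask, dtype=bool)
        if mask.shape != (domain.ny, domain.nx):
            raise ValueError("mask shape does not match the domain grid")
    cls = np.full(mask.shape, NODE_BULK, dtype=np.int8)
    if not mask.any():
        return cls
    # periodic in x: tile three times, keep the middle block
    tiled = np.tile(~mask, (1, 3))
    dist = distance_transform_edt(tiled, sampling=domain.resolution)
    dist = dist[:, domain.nx : 2 * domain.nx]
    cls[dist < domain.b_L] = NODE_BOUNDARY
    cls[mask] = NODE_BIOFILM
    return cls


def solve_substrate(
    domain: BiofilmDomain,
    u_max: np.ndarray,
    K_S: float,
    classification: np.ndarray | None = None,
    S_init: np.ndarray | None = None,
    tol: float = 1e-6,
    max_picard: int = 200,
) -> np.ndarray:
    """Steady-state substrate field of D_G lap(S) = u_max S/(K_S + S).

    ``u_max`` (g/L/h per node) is the maximum volumetric uptake from the
    biomass mapped to each node. Bulk nodes are Dirichlet at S_bulk, the
    bottom edge is no-flux (substratum), lateral boundaries periodic.
    The Monod nonlinearity is handled by Picard iteration (uptake
    linearized as u_max/(K_S + S_prev) * S), each linear system solved
    directly; the result satisfies a dimensionless residual
    max |D lap S - U(S)| h^2 / (D S_bulk) < ``tol`` and is nonnegative.
    """
    ny, nx = domain.ny, domain.nx
    u_max = np.asarray(u_max, dtype=float)
    if u_max.shape != (ny, nx):
        raise ValueError("u_max shape does not match the domain grid")
    cls = classification
    if cls is None:
        cls = classify_nodes(u_max > 0, domain)
    unknown = cls != NODE_BULK
    S = np.full((ny, nx), domain.S_bulk, dtype=float)
    if S_init is not None:
        S = np.clip(np.asarray(S_init, dtype=float).copy(), 0.0, domain.S_bulk)
        S[~unknown] = domain.S_bulk
    if not unknown.any():
        return S

    h2 = domain.resolution**2
    D = domain.D_G_um2h
    idx = -np.ones((ny, nx), dtype=np.int64)
    ids = np.flatnonzero(unknown.ravel())
    idx.ravel()[ids] = np.arange(ids.size)
    n = ids.size
    iy, ix = np.unravel_index(ids, (ny, nx))

    # neighbour bookkeeping (periodic x, mirror at bottom/top edges)
    def nb(dy, dx):
        jy = iy + dy
        jx = np.mod(ix + dx, nx)
        inside = (jy >= 0) & (jy < ny)
        return jy, jx, inside

    neighbours = [nb(0, 1), nb(0, -1), nb(1, 0), nb(-1, 0)]

    # assemble the constant part once: off-diagonal Laplacian couplings,
    # Dirichlet contributions to the rhs, and the diagonal neighbour count;
    # only the linearized-uptake diagonal changes across Picard iterations
    rows, cols, vals = [], [], []
    rhs = np.zeros(n)
    diag = np.zeros(n)
    for jy, jx, inside in neighbours:
        # inside-domain neighbours: either unknown (matrix entry) or
        # Dirichlet bulk (rhs); outside (below substratum / above top):
        # no-flux, term dropped entirely (mirror).
        diag[inside] += 1.0
        j = np.where(inside, idx[np.clip(jy, 0, ny - 1), jx], -1)
        m_unknown = inside & (j >= 0)
        rows.append(np.flatnonzero(m_unknown))
        cols.append(j[m_unknown])
        vals.append(np.full(m_unknown.sum(), -1.0))
        m_dirichlet = inside & (j < 0)
        rhs[m_dirichlet] += domain.S_bulk
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A0 = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    A0.sort_indices()
    diag0 = A0.diagonal()

    for it in range(max_picard):
        k = u_max / (K_S + np.maximum(S, 0.0))  # linearized uptake, 1/h
        A = A0.copy()
        A.setdiag(diag0 + k[iy, ix] * h2 / D)
        sol = spla.spsolve(A.tocsc(), rhs)
        S_new = S.copy()
        S_new[iy, ix] = sol
        converged = np.max(np.abs(S_new - S)) <= 1e-10 + 1e-8 * domain.S_bulk
        S = S_new
        if converged:
            break

    S = np.clip(S, 0.0, domain.S_bulk)
    res = substrate_residual(domain, S, u_max, K_S, cls)
    if res > tol:
        raise RuntimeError(
            f"substrate solver did not converge: residual {res:.3e} > {tol:g} "
            f"after {it + 1} Picard iterations"
        )
    return S


def _laplacian(domain: BiofilmDomain, S: np.ndarray) -> np.ndarray:
    """Discrete Laplacian with periodic x and no-flux bottom/top edges,
    in units of concentration per um^2 (divide-by-h^2 included)."""
    up = np.vstack([S[1:], S[-1:]])  # mirror at top edge
    down = np.vstack([S[:1], S[:-1]])  # mirror at bottom edge
    left = np.roll(S, 1, axis=1)
    right = np.roll(S, -1, axis=1)
    return (up + down + left + right - 4.0 * S) / domain.resolution**2


def substrate_residual(
    domain: BiofilmDomain,
    S: np.ndarray,
    u_max: np.ndarray,
    K_S: float,
    classification: np.ndarray,
) -> float:
    """Dimensionless steady-state residual over non-bulk nodes."""
    res = domain.D_G_um2h * _laplacian(domain, S) - u_max * S / (K_S + S)
    res[classification == NODE_BULK] = 0.0
    scale = domain.D_G_um2h * domain.S_bulk / domain.resolution**2
    return float(np.max(np.abs(res)) / scale)


def _shove_sweeps(x, y, r, pi, pj, jitter, W, target, tol, nsweeps):
    """Sequential (Gauss-Seidel) shove sweeps over a fixed pair list.

    Each overlapping pair is displaced symmetrically along its center
    line the moment it is visited, so corrections propagate within a
    sweep. Returns the worst post-sweep separation ratio seen.
    """
    worst = 1e30
    for _ in range(nsweeps):
        worst = 1e30
        for p in range(pi.shape[0]):
            i = pi[p]
            j = pj[p]
            dx = x[j] - x[i]
            if dx > 0.5 * W:
                dx -= W
            elif dx < -0.5 * W:
                dx += W
            dy = y[j] - y[i]
            dist = np.sqrt(dx * dx + dy * dy)
            want = target * (r[i] + r[j])
            ratio = dist / want
            if ratio < worst:
                worst = ratio
            if ratio < 1.0 - tol:
                if dist < 1e-12:
                    dx = np.cos(jitter[p]) * 1e-9
                    dy = np.sin(jitter[p]) * 1e-9
                    dist = 1e-9
                push = 0.5 * (want - dist) / dist
                ux = dx * push
                uy = dy * push
                x[i] -= ux
                y[i] -= uy
                x[j] += ux
                y[j] += uy
                if y[i] < r[i]:
                    y[i] = r[i]
                if y[j] < r[j]:
                    y[j] = r[j]
        if worst >= 1.0 - tol:
            break
    return worst


try:  # pragma: no cover
    import numba as _numba

    _shove_sweeps_jit = _numba.njit(cache=False)(_shove_sweeps)
except Exception:  # pragma: no cover
    _shove_sweeps_jit = _shove_sweeps


def relax_overlaps(
    pop: Population,
    domain: BiofilmDomain,
    rng: np.random.Generator,
    tol: float = 0.01,
    max_iter: int = 200,
) -> int:
    """Shove overlapping cells apart, in place.

    Pairs closer than ``shove_factor * (r_i + r_j)`` (with relative
    slack ``tol``) are displaced symmetrically along their center line
    until no such pair remains or the iteration cap is reached (logged,
    not fatal). Positions wrap laterally; cells never penetrate the
    substratum (y >= radius). Only positions change, so biomass is
    exactly conserved. Returns the number of sweeps used.
    """
    n = len(pop)
    if n < 2:
        return 0
    W = domain.width
    r = pop.radii("slab", domain.resolution)
    target = domain.shove_factor
    ybig = 1e9  # y is nonnegative and far below this; makes y effectively non-periodic
    slack = 1.3  # pair-list margin; the list stays valid over a few sweeps
    sweeps_per_list = 8
    it = 0
    while it < max_iter:
        pop.x = np.mod(pop.x, W)
        pts = np.column_stack([pop.x, pop.y])
        tree = cKDTree(pts, boxsize=[W, ybig])
        pairs = tree.query_pairs(r=slack * 2.0 * target * r.max(), output_type="ndarray")
        if pairs.size == 0:
            break
        nsweeps = min(sweeps_per_list, max_iter - it)
        jitter = rng.uniform(0.0, 2.0 * np.pi, size=pairs.shape[0])
        worst = _shove_sweeps_jit(
            pop.x, pop.y, r, pairs[:, 0], pairs[:, 1], jitter,
            W, target, tol, nsweeps,
        )
        it += nsweeps
        if worst >= 1.0 - tol:
            # the candidate list is resolved; one final fresh list
            # confirms global convergence
            pts = np.column_stack([np.mod(pop.x, W), pop.y])
            tree = cKDTree(pts, boxsize=[W, ybig])
            pairs = tree.query_pairs(r=target * 2.0 * r.max(), output_type="ndarray")
            if pairs.size == 0:
                break
            i, j = pairs[:, 0], pairs[:, 1]
            dx = pop.x[j] - pop.x[i]
            dx -= W * np.round(dx / W)
            dist = np.hypot(dx, pop.y[j] - pop.y[i])
            if np.all(dist >= target * (r[i] + r[j]) * (1.0 - tol)):
                break
    else:
        log.debug("shoving hit the iteration cap (%d sweeps)", max_iter)
    pop.x = np.mod(pop.x, W)
    return it


def biofilm_front(pop: Population, domain: BiofilmDomain) -> np.ndarray:
    """Per-lateral-column front height (um): the maximum top-of-cell
    height (y + radius) among cells in each grid column; empty columns
    are zero."""
    heights = np.zeros(domain.nx)
    if len(pop) == 0:
        return heights
    r = pop.radii("slab", domain.resolution)
    col = np.floor(np.mod(pop.x, domain.width) / domain.resolution).astype(np.int64)
    np.maximum.at(heights, col, pop.y + r)
    return heights


@dataclass
class BiofilmSim:
    """Mutable state of a biofilm simulation."""

    domain: BiofilmDomain
    pop: Population
    rng: np.random.Generator
    dt: float = 0.05  # h
    t: float = 0.0
    S_field: np.ndarray | None = None
    classification: np.ndarray | None = None
    stopped: bool = False  # set once the front reaches h_max


def biofilm_env(
    strategies: dict[str, StrategyParams],
    counts: dict[str, int],
    kp: KineticParams | None = None,
    domain: BiofilmDomain | None = None,
    seed: int = 0,
    placement: str = "random",
    dt: float = 0.05,
) -> BiofilmSim:
    """Initialise a biofilm with cells placed on the substratum.

    ``placement``: ``random`` x positions, ``equidistant`` spacing, or
    ``side_by_side`` contiguous blocks per strategy (equally spaced
    within each block).
    """
    kp = kp if kp is not None else KineticParams().with_(rho=201.0)
    domain = domain or BiofilmDomain()
    rng = np.random.default_rng(seed)
    pop = Population.fresh(kp, strategies, counts, rng, spatial=True)
    n = len(pop)
    if placement == "random":
        x = rng.uniform(0.0, domain.width, size=n)
    elif placement == "equidistant":
        x = (np.arange(n) + 0.5) * domain.width / n
    elif placement == "side_by_side":
        x = (np.arange(n) + 0.5) * domain.width / n
        x = x[np.argsort(pop.sid, kind="stable")]
    else:
        raise ValueError(f"unknown placement {placement!r}")
    pop.x = x
    pop.y = pop.radii("slab", domain.resolution)
    sim = BiofilmSim(domain=domain, pop=pop, rng=rng, dt=dt)
    relax_overlaps(pop, domain, rng)
    return sim


def _uptake_field(sim: BiofilmSim) -> np.ndarray:
    """Maximum volumetric uptake rate per node (g/L/h) from the cells'
    growth machinery mapped to their containing nodes."""
    domain, pop, kp = sim.domain, sim.pop, sim.pop.kp
    u = np.zeros((domain.ny, domain.nx))
    if len(pop) == 0:
        return u
    alive = pop.alive
    contrib = kp.mu_max * pop.pools[:, 0] * (1.0 - pop.Z) / kp.Y_mu / domain.node_volume
    contrib = np.where(alive, contrib, 0.0)
    cy, cx = _node_index(pop, domain)
    flat = np.bincount(cy * domain.nx + cx, weights=contrib, minlength=domain.ny * domain.nx)
    return u + flat.reshape(domain.ny, domain.nx)


def sample_field(domain: BiofilmDomain, field2d: np.ndarray, x, y) -> np.ndarray:
    """Bilinear interpolation of a node field at off-grid positions
    (periodic in x, clamped in y). Node centers sit at
    ((c + 0.5) h, (j + 0.5) h)."""
    res = domain.resolution
    gx = np.mod(x, domain.width) / res - 0.5
    gy = np.clip(y / res - 0.5, 0.0, domain.ny - 1.0)
    x0 = np.floor(gx).astype(np.int64)
    y0 = np.floor(gy).astype(np.int64)
    fx = gx - x0
    fy = gy - y0
    x0m = np.mod(x0, domain.nx)
    x1m = np.mod(x0 + 1, domain.nx)
    y0c = np.clip(y0, 0, domain.ny - 1)
    y1c = np.clip(y0 + 1, 0, domain.ny - 1)
    return (
        field2d[y0c, x0m] * (1 - fx) * (1 - fy)
        + field2d[y0c, x1m] * fx * (1 - fy)
        + field2d[y1c, x0m] * (1 - fx) * fy
        + field2d[y1c, x1m] * fx * fy
    )


def step_biofilm(sim: BiofilmSim) -> None:
    """One operator-split biofilm step: classify nodes, solve the
    substrate field with biomass frozen, step all cells at their local
    substrate, divide, shove, and check the stopping height."""
    if sim.stopped:
        return
    domain, pop = sim.domain, sim.pop
    cls = classify_nodes(pop, domain)
    u_max = _uptake_field(sim)
    S = solve_substrate(
        domain, u_max, pop.kp.K_S, classification=cls, S_init=sim.S_field
    )
    sim.classification = cls
    sim.S_field = S
    S_cells = sample_field(domain, S, pop.x, pop.y)
    pop.step(S_cells, sim.dt)
    pop.divide(sim.rng, place=True, geometry="slab", thickness=domain.resolution)
    # bounded relaxation per step: any residual overlap is resolved over
    # the following steps (growth per step is small)
    relax_overlaps(pop, domain, sim.rng, max_iter=60)
    sim.t += sim.dt
    front = biofilm_front(pop, domain)
    if front.max() >= domain.h_max:
        sim.stopped = True


def summarise(sim: BiofilmSim) -> list[dict]:
    """Per-strategy summary rows at the current time (biomass, counts,
    mean age, front height, roughness sigma_f over occupied columns)."""
    from .metrics import roughness

    front = biofilm_front(sim.pop, sim.domain)
    occupied = front > 0
    sig = roughness(front[occupied]) if occupied.any() else 0.0
    Z = sim.pop.Z
    rows = []
    for i, lab in enumerate(sim.pop.labels):
        m = sim.pop.sid == i
        rows.append(
            {
                "time": sim.t, "strategy": lab,
                "count": int(m.sum()),
                "biomass": float(sim.pop.P_tot[m].sum()),
                "mean_age": float(Z[m].mean()) if m.any() else np.nan,
                "height": float(front.max()),
                "sigma_f": float(sig),
            }
        )
    return rows


def run_biofilm(
    sim: BiofilmSim,
    t_max: float = 500.0,
    interval: float = 5.0,
) -> pd.DataFrame:
    """Run until the stopping height or ``t_max`` hours; returns the
    per-interval, per-strategy summary table (biomass, counts, front
    height, roughness sigma_f)."""
    rows = summarise(sim)
    next_out = sim.t + interval
    while not sim.stopped and sim.t < t_max - 1e-9:
        step_biofilm(sim)
        if sim.t >= next_out - 1e-9 or sim.stopped:
            rows.extend(summarise(sim))
            next_out = sim.t + interval
    return pd.DataFrame(rows)
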