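"""Single-cell growth, damage accumulation, and repair kinetics.

Each cell carries four protein pools: active growth machinery ``P_ga``,
active repair machinery ``P_ra``, and their damaged counterparts ``P_gd``
and ``P_rd`` (all in fg). The cell's age ``Z = P_dam / P_tot`` is the
damaged fraction of total protein; damage is always toxic, scaling down
synthesis by ``(1 - Z)``, and a cell with ``Z = 1`` is dead (it keeps its
volume but all kinetics stop).

Within a time step the local substrate concentration is frozen (the
environment updates it first, operator-split), and the pool ODEs

    dP_ga/dt = (1 - b) mu(S) P_ga (1 - Z) - A P_ga + Y_r r P_gd/P_dam
    dP_ra/dt =      b  mu(S) P_ga (1 - Z) - A P_ra + Y_r r P_rd/P_dam
    dP_gd/dt =  A P_ga - r P_gd/P_dam
    dP_rd/dt =  A P_ra - r P_rd/P_dam

are integrated with a classical fixed-step 4th-order Runge-Kutta scheme.
Here ``b`` is the allocation fraction of new synthesis routed to repair
machinery, ``A`` the damage accumulation rate, and ``r`` the total repair
flux (Michaelis-Menten-like in machinery and damaged protein),
apportioned pro rata across the two damaged pools. Repair has yield
``Y_r``; the complement ``(1 - Y_r) r`` is lost biomass, which shrinks
the cell unless the "styrofoam" variant converts it to inert volume.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .params import KineticParams, StrategyParams

__all__ = [
    "CellState",
    "monod_rate",
    "aging_rate",
    "repair_machinery",
    "repair_flux",
    "adaptive_beta",
    "cell_derivatives",
    "step_cell",
    "DEAD_Z",
]

log = logging.getLogger(__name__)

#: A cell is dead once its damaged fraction reaches 1 within this margin.
DEAD_Z = 1.0 - 1e-9

#: Pool clipping tolerance (fg): integration round-off below this is
#: silently zeroed, anything larger is logged.
CLIP_TOL = 1e-12


@dataclass
class CellState:
    """State of one cell.

    ``mu_net_prev`` is the net specific growth rate realised over the
    previous step (h^-1), used by the adaptive repair law; newborn cells
    inherit it from the parent. ``pole_generation`` counts consecutive
    old-pole inheritances and resets to zero in the new-pole daughter.
    """

    P_ga: float
    P_ra: float = 0.0
    P_gd: float = 0.0
    P_rd: float = 0.0
    V_inert: float = 0.0  # um^3 of inert "styrofoam" volume
    position: tuple[float, float] | None = None  # um, biofilm only
    pole_generation: int = 0
    strategy_id: str = ""
    mu_net_prev: float = 0.0

    @property
    def P_act(self) -> float:
        return self.P_ga + self.P_ra

    @property
    def P_dam(self) -> float:
        return self.P_gd + self.P_rd

    @property
    def P_tot(self) -> float:
        return self.P_ga + self.P_ra + self.P_gd + self.P_rd

    @property
    def Z(self) -> float:
        tot = self.P_tot
        return self.P_dam / tot if tot > 0 else 0.0

    @property
    def is_dead(self) -> bool:
        return self.Z >= DEAD_Z

    def volume(self, rho: float) -> float:
        """Cell volume in um^3 at biomass density ``rho`` g/L
        (1 g/L == 1 fg/um^3), including inert volume."""
        return self.P_tot / rho + self.V_inert

    def radius(self, rho: float, geometry: str = "sphere", thickness: float = 4.0) -> float:
        """Radius derived from volume: a sphere in well-mixed
        environments, a disk of out-of-plane ``thickness`` (the grid
        resolution) in the quasi-2D biofilm."""
        v = self.volume(rho)
        if geometry == "sphere":
            return (3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0)
        if geometry == "slab":
            return math.sqrt(v / (math.pi * thickness))
        raise ValueError(f"unknown geometry {geometry!r}")


def monod_rate(S, kp: KineticParams):
    """Gross specific growth rate mu(S) = mu_max S / (K_S + S), h^-1.

    Accepts scalars or arrays; rejects negative substrate.
    """
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentration must be >= 0")
    out = kp.mu_max * S / (kp.K_S + S)
    return float(out) if out.ndim == 0 else out


def aging_rate(mu_G, sp: StrategyParams):
    """Damage accumulation rate A (h^-1): the constant ``a`` or, when
    damage is a by-product of metabolism, ``a' * mu_G`` with ``mu_G`` the
    gross specific growth rate."""
    mu_G = np.asarray(mu_G, dtype=float)
    if np.any(mu_G < 0):
        raise ValueError("gross specific growth rate must be >= 0")
    if sp.aging_mode == "constant":
        out = np.broadcast_to(np.asarray(sp.a, dtype=float), mu_G.shape)
    else:
        out = sp.a_prime * mu_G
    return float(out) if out.ndim == 0 else np.asarray(out)


def repair_machinery(cell: CellState, sp: StrategyParams) -> float:
    """Effective amount of repair machinery (fg): zero without repair,
    the fixed fraction ``beta * P_act`` for fixed repair, or the actual
    active repair pool ``P_ra`` for adaptive repair."""
    if sp.repair_mode == "none":
        return 0.0
    if sp.repair_mode == "fixed":
        return sp.beta_fixed * cell.P_act
    return cell.P_ra


def repair_flux(machinery, P_dam):
    """Total repair rate (fg/h): Michaelis-Menten-like in both machinery
    and damaged protein, r = m * P_dam / (m + P_dam). Bounded by
    min(machinery, P_dam); zero when either is zero."""
    machinery = np.asarray(machinery, dtype=float)
    P_dam = np.asarray(P_dam, dtype=float)
    if np.any(machinery < 0) or np.any(P_dam < 0):
        raise ValueError("machinery and damaged protein must be >= 0")
    denom = machinery + P_dam
    out = np.where(denom > 0, machinery * P_dam / np.where(denom > 0, denom, 1.0), 0.0)
    return float(out) if out.ndim == 0 else out


def adaptive_beta(Z, Y_r, mu):
    """Optimal instantaneous allocation of new synthesis to repair
    machinery.

    The allocation maximises the instantaneous rate of active-protein
    production of a cell whose machinery composition tracks the
    allocation: with damaged-to-active ratio d = Z/(1-Z), production per
    unit active protein is

        f(b) = (1 - b) mu (1 - Z) + Y_r b d / (b + d),

    whose stationary point gives

        b_hat = d (sqrt(Y_r / (mu (1 - Z))) - 1),

    clamped to [0, 1]. ``mu`` is the cell's *net* specific growth rate
    from the previous step; non-positive ``mu`` returns 0 (no synthesis
    to allocate), and a dead cell (Z >= 1) returns maximal investment 1.

    Accepts scalars or arrays (broadcast).
    """
    Z, Y_r, mu = np.broadcast_arrays(
        np.asarray(Z, dtype=float), np.asarray(Y_r, dtype=float), np.asarray(mu, dtype=float)
    )
    if np.any(Z < 0) or np.any(Z > 1):
        raise ValueError("age Z must be in [0, 1]")
    out = np.ones_like(Z)  # Z >= 1 -> maximal investment
    interior = Z < 1.0
    z = Z[interior]
    m = mu[interior]
    yr = Y_r[interior]
    d = z / (1.0 - z)
    with np.errstate(divide="ignore", invalid="ignore"):
        root = np.sqrt(yr / (m * (1.0 - z)))
        b = np.where(m > 0, d * (root - 1.0), 0.0)
    out[interior] = np.clip(np.nan_to_num(b, nan=0.0, posinf=1.0), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _allocation(cell: CellState, sp: StrategyParams, Y_r: float) -> float:
    """Allocation fraction of new synthesis to repair machinery for this
    step: 0 (none), beta (fixed) or the adaptive optimum based on the
    previous step's net growth rate."""
    if sp.repair_mode == "none":
        return 0.0
    if sp.repair_mode == "fixed":
        return sp.beta_fixed
    return float(adaptive_beta(cell.Z, Y_r, max(cell.mu_net_prev, 0.0)))


def cell_derivatives(
    cell: CellState, S: float, sp: StrategyParams, kp: KineticParams
) -> tuple[float, float, float, float, float]:
    """Instantaneous rates of change (fg/h) of the four pools plus the
    substrate consumption rate (fg/h).

    Mass balance: dP_tot/dt = mu(S) P_ga (1-Z) - (1-Y_r) r.
    Dead cells have all rates zero but remain physically intact.
    """
    if S < 0:
        raise ValueError("substrate concentration must be >= 0")
    alloc = _allocation(cell, sp, kp.Y_r)
    A = float(aging_rate(monod_rate(S, kp), sp))
    d = _pool_rates(
        cell.P_ga, cell.P_ra, cell.P_gd, cell.P_rd,
        S, kp.mu_max, kp.K_S, kp.Y_mu, kp.Y_r, alloc, A,
        _machinery_mode(sp), sp.beta_fixed,
    )
    return d[:5]


def _machinery_mode(sp: StrategyParams) -> int:
    return {"none": 0, "fixed": 1, "adaptive": 2}[sp.repair_mode]


def _pool_rates(pga, pra, pgd, prd, S, mu_max, K_S, Y_mu, Y_r, alloc, A, mode, beta):
    """Scalar derivative evaluation shared by the single-cell surface and
    the test oracles. Returns (dga, dra, dgd, drd, dconsumption, dloss)."""
    tot = pga + pra + pgd + prd
    if tot <= 0.0:
        return (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    dam = pgd + prd
    Z = dam / tot
    if Z >= DEAD_Z:
        return (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    mu = mu_max * S / (K_S + S)
    syn = mu * pga * (1.0 - Z)
    if mode == 0:
        mach = 0.0
    elif mode == 1:
        mach = beta * (pga + pra)
    else:
        mach = pra
    denom = mach + dam
    r = mach * dam / denom if denom > 0.0 else 0.0
    if dam > 0.0:
        fg = pgd / dam
        fr = prd / dam
    else:
        fg = fr = 0.0
    dga = (1.0 - alloc) * syn - A * pga + Y_r * r * fg
    dra = alloc * syn - A * pra + Y_r * r * fr
    dgd = A * pga - r * fg
    drd = A * pra - r * fr
    return (dga, dra, dgd, drd, syn / Y_mu, (1.0 - Y_r) * r)


def _rk4_scalar(pga, pra, pgd, prd, S, dt, mu_max, K_S, Y_mu, Y_r, alloc, A, mode, beta):
    """One RK4 step of the pools plus quadratures of consumption and
    repair loss. Returns (pools..., consumed_fg, lost_fg)."""
    y = (pga, pra, pgd, prd)

    def f(y):
        return _pool_rates(*y, S, mu_max, K_S, Y_mu, Y_r, alloc, A, mode, beta)

    k1 = f(y)
    y2 = tuple(y[i] + 0.5 * dt * k1[i] for i in range(4))
    k2 = f(y2)
    y3 = tuple(y[i] + 0.5 * dt * k2[i] for i in range(4))
    k3 = f(y3)
    y4 = tuple(y[i] + dt * k3[i] for i in range(4))
    k4 = f(y4)
    out = [
        y[i] + dt / 6.0 * (k1[i] + 2 * k2[i] + 2 * k3[i] + k4[i]) for i in range(4)
    ]
    cons = dt / 6.0 * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
    loss = dt / 6.0 * (k1[5] + 2 * k2[5] + 2 * k3[5] + k4[5])
    return (*out, cons, loss)


def step_cell(
    cell: CellState, S: float, dt: float, sp: StrategyParams, kp: KineticParams
) -> tuple[CellState, float]:
    """Advance one cell by ``dt`` hours at frozen substrate ``S``.

    Returns the updated cell and the substrate consumed (fg). Updates
    ``mu_net_prev`` from the relative change of total protein; with the
    styrofoam variant, biomass lost to repair is converted to inert
    volume at density rho so the cell's volume never decreases. Pools
    are never driven below zero (round-off is clipped and logged).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    state = (cell.P_ga, cell.P_ra, cell.P_gd, cell.P_rd)
    if not all(math.isfinite(v) for v in state) or not math.isfinite(S):
        raise FloatingPointError(f"non-finite cell state {state} or S={S}")
    alloc = _allocation(cell, sp, kp.Y_r)
    A = float(aging_rate(monod_rate(S, kp), sp))
    pga, pra, pgd, prd, cons, loss = _rk4_scalar(
        *state, S, dt, kp.mu_max, kp.K_S, kp.Y_mu, kp.Y_r,
        alloc, A, _machinery_mode(sp), sp.beta_fixed,
    )
    pools = [pga, pra, pgd, prd]
    for i, v in enumerate(pools):
        if v < 0.0:
            if v < -1e-6:
                log.warning("pool %d clipped by %.3g fg in one step", i, -v)
            elif v < -CLIP_TOL:
                log.debug("pool %d clipped by %.3g fg", i, -v)
            pools[i] = 0.0
    new_tot = sum(pools)
    old_tot = cell.P_tot
    if new_tot > 0 and old_tot > 0 and not cell.is_dead:
        mu_net = math.log(new_tot / old_tot) / dt
    else:
        mu_net = 0.0
    v_inert = cell.V_inert + (loss / kp.rho if sp.styrofoam else 0.0)
    new = replace(
        cell,
        P_ga=pools[0], P_ra=pools[1], P_gd=pools[2], P_rd=pools[3],
        V_inert=v_inert, mu_net_prev=mu_net,
    )
    if not all(math.isfinite(v) for v in pools):
        raise FloatingPointError(f"integration produced non-finite pools {pools}")
    return new, cons
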