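"""Struct-of-arrays container for a population of cells.

All per-cell state lives in flat numpy arrays so that a whole population
can be advanced in one vectorized RK4 call per time step. Cells of
several strategies coexist; per-strategy parameters are gathered through
an integer strategy index. The scalar :class:`~senesim.kinetics.CellState`
surface remains available for single-cell work and testing; conversion
helpers are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import division as dv
from ._kernel import DEAD_Z, rk4_step
from .kinetics import CellState, adaptive_beta
from .params import KineticParams, StrategyParams

__all__ = ["Population"]

_MODE = {"none": 0, "fixed": 1, "adaptive": 2}
_AGING = {"constant": 0, "growth_proportional": 1}


@dataclass
class Population:
    """A population of cells sharing kinetic parameters ``kp``.

    ``strategies`` maps a label to its :class:`StrategyParams`; each cell
    carries an index into that (ordered) mapping. Spatial coordinates
    ``x``/``y`` are used only by the biofilm environment.
    """

    kp: KineticParams
    strategies: dict[str, StrategyParams]
    pools: np.ndarray  # (N, 4) fg
    sid: np.ndarray  # (N,) int strategy index
    v_inert: np.ndarray  # (N,) um^3
    pole_gen: np.ndarray  # (N,) int
    mu_net: np.ndarray  # (N,) h^-1, realised over previous step
    x: np.ndarray | None = None  # um
    y: np.ndarray | None = None  # um
    protected: np.ndarray | None = None  # bool, immune to random removal
    clipped: int = field(default=0)  # count of pool clippings (diagnostics)

    # ---- construction -------------------------------------------------
    @classmethod
    def empty(cls, kp, strategies, spatial=False):
        z = np.zeros(0)
        return cls(
            kp=kp, strategies=dict(strategies),
            pools=np.zeros((0, 4)), sid=np.zeros(0, dtype=np.int64),
            v_inert=z.copy(), pole_gen=np.zeros(0, dtype=np.int64), mu_net=z.copy(),
            x=z.copy() if spatial else None, y=z.copy() if spatial else None,
            protected=np.zeros(0, dtype=bool),
        )

    @classmethod
    def fresh(
        cls,
        kp: KineticParams,
        strategies: dict[str, StrategyParams],
        counts: dict[str, int],
        rng: np.random.Generator,
        mu_init: float = 0.0,
        spatial: bool = False,
    ) -> "Population":
        """New cells with all-active growth protein, initial masses drawn
        uniformly between half the division threshold and the threshold
        (a crude age-of-cycle spread), and no damage."""
        labels = list(strategies)
        n = sum(counts.get(k, 0) for k in labels)
        pools = np.zeros((n, 4))
        sid = np.zeros(n, dtype=np.int64)
        i = 0
        for si, lab in enumerate(labels):
            c = counts.get(lab, 0)
            pools[i : i + c, 0] = rng.uniform(0.5 * kp.P_div, kp.P_div, size=c)
            sid[i : i + c] = si
            i += c
        return cls(
            kp=kp, strategies=dict(strategies), pools=pools, sid=sid,
            v_inert=np.zeros(n), pole_gen=np.zeros(n, dtype=np.int64),
            mu_net=np.full(n, float(mu_init)),
            x=np.zeros(n) if spatial else None,
            y=np.zeros(n) if spatial else None,
            protected=np.zeros(n, dtype=bool),
        )

    # ---- derived quantities -------------------------------------------
    def __len__(self) -> int:
        return self.pools.shape[0]

    @property
    def labels(self) -> list[str]:
        return list(self.strategies)

    @property
    def P_tot(self) -> np.ndarray:
        return self.pools.sum(axis=1)

    @property
    def P_dam(self) -> np.ndarray:
        return self.pools[:, 2] + self.pools[:, 3]

    @property
    def Z(self) -> np.ndarray:
        tot = self.P_tot
        return np.where(tot > 0, self.P_dam / np.where(tot > 0, tot, 1.0), 0.0)

    @property
    def alive(self) -> np.ndarray:
        return (self.P_tot > 0) & (self.Z < DEAD_Z)

    def volumes(self) -> np.ndarray:
        return self.P_tot / self.kp.rho + self.v_inert

    def radii(self, geometry: str = "sphere", thickness: float = 4.0) -> np.ndarray:
        v = self.volumes()
        if geometry == "sphere":
            return (3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)
        return np.sqrt(v / (np.pi * thickness))

    def biomass_by_strategy(self) -> dict[str, float]:
        tot = self.P_tot
        return {
            lab: float(tot[self.sid == i].sum()) for i, lab in enumerate(self.labels)
        }

    def counts_by_strategy(self) -> dict[str, int]:
        return {lab: int((self.sid == i).sum()) for i, lab in enumerate(self.labels)}

    # ---- per-strategy parameter gathers -------------------------------
    def _sp_arrays(self):
        sps = list(self.strategies.values())
        mode = np.array([_MODE[s.repair_mode] for s in sps], dtype=np.int64)
        beta = np.array([s.beta_fixed for s in sps])
        aging = np.array([_AGING[s.aging_mode] for s in sps], dtype=np.int64)
        a = np.array([s.a for s in sps])
        ap = np.array([s.a_prime for s in sps])
        alpha = np.array([s.alpha for s in sps])
        styro = np.array([s.styrofoam for s in sps], dtype=bool)
        return mode, beta, aging, a, ap, alpha, styro

    # ---- stepping ------------------------------------------------------
    def step(self, S, dt: float) -> np.ndarray:
        """Advance every cell by ``dt`` at frozen substrate ``S`` (scalar
        or per-cell array). Returns per-cell substrate consumed (fg).

        The adaptive allocation fraction and the damage rate are
        evaluated once at the start of the step; cells are then
        independent and updated synchronously.
        """
        n = len(self)
        if n == 0:
            return np.zeros(0)
        S = np.broadcast_to(np.asarray(S, dtype=float), (n,)).copy()
        if np.any(S < 0):
            raise ValueError("substrate concentration must be >= 0")
        kp = self.kp
        mode_s, beta_s, aging_s, a_s, ap_s, _, styro_s = self._sp_arrays()
        mode = mode_s[self.sid]
        beta = beta_s[self.sid]
        mu_G = kp.mu_max * S / (kp.K_S + S)
        A = np.where(aging_s[self.sid] == 0, a_s[self.sid], ap_s[self.sid] * mu_G)
        alloc = np.where(mode == 1, beta, 0.0)
        ad = mode == 2
        if np.any(ad):
            alloc[ad] = adaptive_beta(
                self.Z[ad], kp.Y_r, np.maximum(self.mu_net[ad], 0.0)
            )
        alive_before = self.alive
        tot_before = self.P_tot
        cons, loss = rk4_step(
            self.pools, S, dt, kp.mu_max, kp.K_S, kp.Y_mu, kp.Y_r,
            alloc, A, mode, beta,
        )
        if not np.all(np.isfinite(self.pools)):
            raise FloatingPointError("population step produced non-finite pools")
        tot_after = self.P_tot
        ok = alive_before & (tot_before > 0) & (tot_after > 0)
        self.mu_net = np.where(
            ok, np.log(np.where(ok, tot_after / np.where(ok, tot_before, 1.0), 1.0)) / dt, 0.0
        )
        styro = styro_s[self.sid]
        if np.any(styro):
            self.v_inert = self.v_inert + np.where(styro, loss / kp.rho, 0.0)
        return cons

    # ---- division ------------------------------------------------------
    def divide(
        self,
        rng: np.random.Generator,
        place: bool = False,
        geometry: str = "slab",
        thickness: float = 4.0,
    ) -> int:
        """Split every cell at or above the division threshold.

        Old-pole daughters stay in place (index, position, protection);
        new-pole daughters are appended. With ``place=True`` the new
        daughter is placed one center-to-center diameter away in a
        uniformly random direction (overlaps are resolved later by
        shoving). Returns the number of divisions.
        """
        idx = np.flatnonzero((self.P_tot >= self.kp.P_div) & self.alive)
        k = idx.size
        if k == 0:
            return 0
        theta = dv.draw_theta(rng, self.kp, size=k)
        _, _, _, _, _, alpha_s, _ = self._sp_arrays()
        alpha = alpha_s[self.sid[idx]]
        old, new = dv.split_pools(self.pools[idx], theta, alpha)
        vi = self.v_inert[idx]
        self.pools[idx] = old
        self.v_inert[idx] = (1.0 - theta) * vi
        self.pole_gen[idx] += 1

        self.pools = np.concatenate([self.pools, new])
        self.v_inert = np.concatenate([self.v_inert, theta * vi])
        self.sid = np.concatenate([self.sid, self.sid[idx]])
        self.pole_gen = np.concatenate(
            [self.pole_gen, np.zeros(k, dtype=self.pole_gen.dtype)]
        )
        self.mu_net = np.concatenate([self.mu_net, self.mu_net[idx]])
        if self.protected is not None:
            self.protected = np.concatenate([self.protected, np.zeros(k, dtype=bool)])
        if self.x is not None:
            if place:
                r_all = self.radii(geometry, thickness)
                r_old = r_all[idx]
                r_new = r_all[-k:]
                ang = rng.uniform(0.0, 2.0 * np.pi, size=k)
                d = r_old + r_new
                nx = self.x[idx] + d * np.cos(ang)
                ny = np.maximum(self.y[idx] + d * np.sin(ang), r_new)
                self.x = np.concatenate([self.x, nx])
                self.y = np.concatenate([self.y, ny])
            else:
                self.x = np.concatenate([self.x, self.x[idx]])
                self.y = np.concatenate([self.y, self.y[idx]])
        return k

    # ---- removal -------------------------------------------------------
    def keep(self, mask: np.ndarray) -> None:
        """Retain only cells where ``mask`` is True."""
        self.pools = self.pools[mask]
        self.sid = self.sid[mask]
        self.v_inert = self.v_inert[mask]
        self.pole_gen = self.pole_gen[mask]
        self.mu_net = self.mu_net[mask]
        if self.protected is not None:
            self.protected = self.protected[mask]
        if self.x is not None:
            self.x = self.x[mask]
            self.y = self.y[mask]

    # ---- CellState interop ---------------------------------------------
    def cell(self, i: int) -> CellState:
        pos = (float(self.x[i]), float(self.y[i])) if self.x is not None else None
        return CellState(
            P_ga=float(self.pools[i, 0]), P_ra=float(self.pools[i, 1]),
            P_gd=float(self.pools[i, 2]), P_rd=float(self.pools[i, 3]),
            V_inert=float(self.v_inert[i]), position=pos,
            pole_generation=int(self.pole_gen[i]),
            strategy_id=self.labels[int(self.sid[i])],
            mu_net_prev=float(self.mu_net[i]),
        )

    def cells(self) -> list[CellState]:
        return [self.cell(i) for i in range(len(self))]
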