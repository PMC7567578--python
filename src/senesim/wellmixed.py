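"""Constant and chemostat (well-mixed) environments.

Constant environment: substrate is pinned, and the population is capped —
every division is matched by the removal of one uniformly random cell
(extrinsic mortality). Chemostat: substrate follows the standard balance
dS/dt = D (S_in - S) - consumption/V, and every cell is washed out
independently with probability D*dt per step. At steady state the
population-mean net specific growth rate equals the dilution rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import CellState, monod_rate, step_cell
from .division import draw_theta, should_divide, split_cell
from .metrics import CompetitionRecord
from .params import KineticParams, StrategyParams
from .population import Population

__all__ = [
    "WellMixedEnv",
    "constant_env",
    "chemostat_env",
    "step_constant",
    "step_chemostat",
    "run_wellmixed",
    "run_competition",
    "track_single_cell",
]

FG_PER_G = 1e15


@dataclass
class WellMixedEnv:
    """State of a well-mixed simulation (constant or chemostat)."""

    mode: str  # "constant" | "chemostat"
    pop: Population
    rng: np.random.Generator
    S: float  # g/L
    S_in: float = 0.00324  # g/L (inflow; equals the pinned S in constant mode)
    D: float = 0.3  # h^-1, dilution rate (chemostat)
    volume: float = 1e-6  # L (1 mm^3)
    pop_cap: int = 1000  # constant mode
    t: float = 0.0  # h
    dt: float = 0.01  # h

    def __post_init__(self):
        if self.mode not in ("constant", "chemostat"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.S < 0:
            raise ValueError("substrate must be >= 0")


def constant_env(
    strategies: dict[str, StrategyParams],
    counts: dict[str, int],
    kp: KineticParams | None = None,
    seed: int = 0,
    S: float = 0.00234,
    dt: float = 0.01,
) -> WellMixedEnv:
    """Constant environment at pinned substrate ``S`` (default equals
    K_S, i.e. cells grow at mu_max/2 gross). The cap equals the initial
    population size."""
    kp = kp or KineticParams()
    rng = np.random.default_rng(seed)
    pop = Population.fresh(kp, strategies, counts, rng, mu_init=monod_rate(S, kp))
    return WellMixedEnv(
        mode="constant", pop=pop, rng=rng, S=S, S_in=S, dt=dt, pop_cap=len(pop)
    )


def chemostat_env(
    strategies: dict[str, StrategyParams],
    counts: dict[str, int],
    kp: KineticParams | None = None,
    seed: int = 0,
    S_in: float = 0.00324,
    D: float = 0.3,
    volume: float = 1e-6,
    S0: float | None = None,
    dt: float = 0.01,
) -> WellMixedEnv:
    kp = kp or KineticParams()
    rng = np.random.default_rng(seed)
    S0 = S_in if S0 is None else S0
    pop = Population.fresh(kp, strategies, counts, rng, mu_init=monod_rate(S0, kp))
    return WellMixedEnv(
        mode="chemostat", pop=pop, rng=rng, S=S0, S_in=S_in, D=D,
        volume=volume, dt=dt,
    )


def step_constant(env: WellMixedEnv, dt: float | None = None) -> None:
    """One step of the constant environment: substrate unchanged, cells
    stepped synchronously, then one uniformly random cell (never a
    protected focal cell) removed per division so the population returns
    to the cap. Newborns are eligible for removal."""
    if env.mode != "constant":
        raise ValueError("step_constant requires a constant-mode environment")
    dt = env.dt if dt is None else dt
    pop = env.pop
    pop.step(env.S, dt)
    k = pop.divide(env.rng)
    if k > 0:
        n = len(pop)
        removable = np.flatnonzero(~pop.protected)
        excess = n - env.pop_cap
        if excess > 0:
            drop = env.rng.choice(removable, size=min(excess, removable.size), replace=False)
            mask = np.ones(n, dtype=bool)
            mask[drop] = False
            pop.keep(mask)
    env.t += dt


def step_chemostat(env: WellMixedEnv, dt: float | None = None) -> None:
    """One step of the chemostat.

    The substrate balance dS/dt = D (S_in - S) - C(S)/V is integrated
    over the step with RK4 using start-of-step biomass (operator split);
    cells are then stepped at the new, frozen concentration, divisions
    processed, and every cell independently washed out with probability
    D*dt.
    """
    if env.mode != "chemostat":
        raise ValueError("step_chemostat requires a chemostat-mode environment")
    dt = env.dt if dt is None else dt
    if env.D * dt > 1.0:
        raise ValueError("D*dt must not exceed 1")
    pop = env.pop
    kp = pop.kp
    # total uptake capacity from start-of-step biomass: C(S) = mu(S) W / Y_mu
    alive = pop.alive
    W = float((pop.pools[alive, 0] * (1.0 - pop.Z[alive])).sum())  # fg

    def dS(S):
        mu = kp.mu_max * S / (kp.K_S + S)
        return env.D * (env.S_in - S) - mu * W / kp.Y_mu / FG_PER_G / env.volume

    S = env.S
    k1 = dS(S)
    k2 = dS(max(S + 0.5 * dt * k1, 0.0))
    k3 = dS(max(S + 0.5 * dt * k2, 0.0))
    k4 = dS(max(S + dt * k3, 0.0))
    env.S = max(S + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)

    pop.step(env.S, dt)
    pop.divide(env.rng)
    n = len(pop)
    if n > 0:
        washed = env.rng.random(n) < env.D * dt
        if pop.protected is not None:
            washed &= ~pop.protected
        if washed.any():
            pop.keep(~washed)
    env.t += dt


def _summarise(env: WellMixedEnv) -> list[dict]:
    pop = env.pop
    rows = []
    Z = pop.Z
    for i, lab in enumerate(pop.labels):
        m = pop.sid == i
        mu = pop.mu_net[m]
        rows.append(
            {
                "time": env.t,
                "strategy": lab,
                "count": int(m.sum()),
                "biomass": float(pop.P_tot[m].sum()),
                "mu_mean": float(mu.mean()) if mu.size else np.nan,
                "mu_median": float(np.median(mu)) if mu.size else np.nan,
                "mu_iqr": float(np.subtract(*np.percentile(mu, [75, 25]))) if mu.size else np.nan,
                "mean_age": float(Z[m].mean()) if m.any() else np.nan,
                "S": env.S,
            }
        )
    return rows


def run_wellmixed(
    env: WellMixedEnv,
    t_end: float,
    interval: float = 1.0,
    stop_on_sole_survivor: bool = False,
) -> pd.DataFrame:
    """Run to ``t_end`` hours, recording per-strategy summaries every
    ``interval`` hours. Returns the tidy summary table."""
    step = step_constant if env.mode == "constant" else step_chemostat
    rows = _summarise(env)
    next_out = env.t + interval
    nsteps = int(round((t_end - env.t) / env.dt))
    for _ in range(nsteps):
        step(env)
        if env.t >= next_out - 1e-9:
            rows.extend(_summarise(env))
            next_out += interval
            if stop_on_sole_survivor and len(env.pop.strategies) > 1:
                counts = env.pop.counts_by_strategy()
                if sum(1 for v in counts.values() if v > 0) <= 1:
                    break
        if len(env.pop) == 0:
            break
    return pd.DataFrame(rows)


def run_competition(
    env: WellMixedEnv,
    t_end: float = 12000.0,
    interval: float = 1.0,
) -> CompetitionRecord:
    """Compete the strategies in ``env`` until sole survivor or
    ``t_end`` hours (the study's default horizon is 500 days), recording
    biomass trajectories. Requires at least two strategies."""
    if len(env.pop.strategies) < 2:
        raise ValueError("competition needs at least two strategies")
    table = run_wellmixed(env, t_end, interval, stop_on_sole_survivor=True)
    return CompetitionRecord.from_table(table)


def track_single_cell(
    sp: StrategyParams,
    kp: KineticParams | None = None,
    S: float = 0.00234,
    days: float = 3.0,
    dt: float = 0.01,
    seed: int = 0,
    follow: str = "old_pole",
) -> pd.DataFrame:
    """Follow one focal lineage in the constant environment.

    At each division the chosen pole's daughter is retained (the old
    pole by default, i.e. the damage-keeping cell under asymmetric
    division). Returns a per-step table of age, pools, allocation into
    repair, and net growth rate, with the division generation."""
    from .kinetics import adaptive_beta  # local to avoid cycle at import time

    kp = kp or KineticParams()
    rng = np.random.default_rng(seed)
    cell = CellState(P_ga=0.5 * kp.P_div, strategy_id="focal", mu_net_prev=monod_rate(S, kp))
    rows = []
    nsteps = int(round(days * 24.0 / dt))
    gen = 0
    for i in range(nsteps):
        t = i * dt
        beta_hat = (
            float(adaptive_beta(cell.Z, kp.Y_r, max(cell.mu_net_prev, 0.0)))
            if sp.repair_mode == "adaptive"
            else (sp.beta_fixed if sp.repair_mode == "fixed" else 0.0)
        )
        rows.append(
            {
                "time": t, "generation": gen, "Z": cell.Z,
                "P_tot": cell.P_tot, "P_ra": cell.P_ra,
                "beta_hat": beta_hat, "mu_net": cell.mu_net_prev,
            }
        )
        cell, _ = step_cell(cell, S, dt, sp, kp)
        if should_divide(cell, kp):
            theta = float(draw_theta(rng, kp))
            old, new = split_cell(cell, theta, sp)
            cell = old if follow == "old_pole" else new
            gen += 1
        if cell.is_dead:
            # dead cells stay in the record but nothing more happens
            pass
    return pd.DataFrame(rows)
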