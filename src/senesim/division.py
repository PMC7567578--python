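"""Division trigger and the symmetric/asymmetric split of the pools.

A cell divides once its total protein reaches the threshold ``P_div``
(derived from a 0.8 um threshold radius). The new-pole daughter inherits
a fraction ``theta`` of every pool (theta drawn per division from
Normal(0.5, 0.025), clamped), and additionally, with asymmetry ``alpha``,
a fraction ``alpha * theta`` of each damaged pool is shifted from the
new pole to the old pole, so at ``alpha = 1`` the new-pole daughter is
born rejuvenated. If the old pole cannot absorb all its damage (its
active pool would go negative), the overflow rule fills the old pole
with damaged protein and returns the excess to the new pole; the rule is
applied independently per machinery class (growth/repair), which keeps
every pool nonnegative and exactly conserved.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .kinetics import CellState
from .params import KineticParams, StrategyParams

__all__ = ["should_divide", "draw_theta", "split_pools", "split_cell"]

THETA_CLIP = (0.01, 0.99)


def should_divide(cell: CellState, kp: KineticParams) -> bool:
    """True iff total protein has reached ``P_div`` and the cell is alive
    (dead cells never divide)."""
    return cell.P_tot >= kp.P_div and not cell.is_dead


def draw_theta(rng: np.random.Generator, kp: KineticParams, size=None):
    """Baby mass fraction(s) ~ Normal(theta_mean, theta_sd), clamped away
    from 0 and 1."""
    theta = rng.normal(kp.theta_mean, kp.theta_sd, size=size)
    return np.clip(theta, *THETA_CLIP)


def split_pools(pools, theta, alpha):
    """Split parent pool array(s) into (old_pole, new_pole) pool arrays.

    ``pools`` has shape (..., 4) ordered (P_ga, P_ra, P_gd, P_rd);
    ``theta`` and ``alpha`` broadcast over the leading axes. Every pool
    is exactly conserved: parent = old + new, elementwise.
    """
    pools = np.asarray(pools, dtype=float)
    theta = np.asarray(theta, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(theta <= 0) or np.any(theta >= 1):
        raise ValueError("theta must lie strictly inside (0, 1)")
    ag, ar, dg, dr = (pools[..., i] for i in range(4))
    one_t = 1.0 - theta
    at = alpha * theta

    old = np.empty_like(pools)
    new = np.empty_like(pools)
    # regular split, per machinery class
    old[..., 0] = one_t * ag - at * dg
    old[..., 1] = one_t * ar - at * dr
    old[..., 2] = one_t * dg + at * dg
    old[..., 3] = one_t * dr + at * dr
    new[..., 0] = theta * ag + at * dg
    new[..., 1] = theta * ar + at * dr
    new[..., 2] = theta * dg - at * dg
    new[..., 3] = theta * dr - at * dr

    # damage overflow: if the old pole's active pool would go negative,
    # it is filled with damaged protein and the new pole takes the rest
    over_g = one_t * ag < at * dg
    over_r = one_t * ar < at * dr
    if np.any(over_g):
        og = np.broadcast_to(over_g, old[..., 0].shape)
        old[..., 0] = np.where(og, 0.0, old[..., 0])
        old[..., 2] = np.where(og, one_t * (ag + dg), old[..., 2])
        new[..., 0] = np.where(og, ag, new[..., 0])
        new[..., 2] = np.where(og, theta * dg - one_t * ag, new[..., 2])
    if np.any(over_r):
        orr = np.broadcast_to(over_r, old[..., 1].shape)
        old[..., 1] = np.where(orr, 0.0, old[..., 1])
        old[..., 3] = np.where(orr, one_t * (ar + dr), old[..., 3])
        new[..., 1] = np.where(orr, ar, new[..., 1])
        new[..., 3] = np.where(orr, theta * dr - one_t * ar, new[..., 3])
    return old, new


def split_cell(
    parent: CellState, theta: float, sp: StrategyParams
) -> tuple[CellState, CellState]:
    """Divide ``parent`` into (old_pole, new_pole) daughters.

    Inert volume is split (1 - theta):theta like the protein; the old
    pole increments its consecutive old-pole count, the new pole resets
    it. Both daughters inherit the parent's previous net growth rate.
    """
    if parent.is_dead:
        raise ValueError("dead cells do not divide")
    pools = np.array([parent.P_ga, parent.P_ra, parent.P_gd, parent.P_rd])
    old_p, new_p = split_pools(pools, theta, sp.alpha)
    old = replace(
        parent,
        P_ga=float(old_p[0]), P_ra=float(old_p[1]),
        P_gd=float(old_p[2]), P_rd=float(old_p[3]),
        V_inert=(1.0 - theta) * parent.V_inert,
        pole_generation=parent.pole_generation + 1,
    )
    new = replace(
        parent,
        P_ga=float(new_p[0]), P_ra=float(new_p[1]),
        P_gd=float(new_p[2]), P_rd=float(new_p[3]),
        V_inert=theta * parent.V_inert,
        pole_generation=0,
    )
    return old, new
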