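"""Vectorized RK4 integration kernel for whole populations.

Two equivalent implementations of the same step: a per-cell loop that is
JIT-compiled with numba when available, and a pure-numpy fallback. Both
integrate the four protein pools over one operator-split time step at
frozen per-cell substrate, together with quadratures of substrate
consumption and repair mass loss.

The allocation fraction ``alloc`` and the damage rate ``A`` are
evaluated once per step (outside the kernel) and held constant over the
RK4 stages; the repair machinery (which is part of the state) is
re-evaluated at every stage.
"""

from __future__ import annotations

import numpy as np

DEAD_Z = 1.0 - 1e-9


def _rk4_loop(pools, S, dt, mu_max, K_S, Y_mu, Y_r, alloc, A, mode, beta, out_cons, out_loss):
    n = pools.shape[0]
    for i in range(n):
        pga = pools[i, 0]
        pra = pools[i, 1]
        pgd = pools[i, 2]
        prd = pools[i, 3]
        Si = S[i]
        al = alloc[i]
        Ai = A[i]
        mi = mode[i]
        bi = beta[i]
        mu = mu_max * Si / (K_S + Si)

        # stage accumulators for the 4 pools + consumption + loss
        acc0 = 0.0
        acc1 = 0.0
        acc2 = 0.0
        acc3 = 0.0
        accc = 0.0
        accl = 0.0
        y0 = pga
        y1 = pra
        y2 = pgd
        y3 = prd
        for stage in range(4):
            tot = y0 + y1 + y2 + y3
            d0 = d1 = d2 = d3 = dc = dl = 0.0
            if tot > 0.0:
                dam = y2 + y3
                Z = dam / tot
                if Z < DEAD_Z:
                    syn = mu * y0 * (1.0 - Z)
                    if mi == 0:
                        mach = 0.0
                    elif mi == 1:
                        mach = bi * (y0 + y1)
                    else:
                        mach = y1
                    denom = mach + dam
                    r = mach * dam / denom if denom > 0.0 else 0.0
                    if dam > 0.0:
                        fg = y2 / dam
                        fr = y3 / dam
                    else:
                        fg = 0.0
                        fr = 0.0
                    d0 = (1.0 - al) * syn - Ai * y0 + Y_r * r * fg
                    d1 = al * syn - Ai * y1 + Y_r * r * fr
                    d2 = Ai * y0 - r * fg
                    d3 = Ai * y1 - r * fr
                    dc = syn / Y_mu
                    dl = (1.0 - Y_r) * r
            if stage == 0 or stage == 3:
                w = 1.0
            else:
                w = 2.0
            acc0 += w * d0
            acc1 += w * d1
            acc2 += w * d2
            acc3 += w * d3
            accc += w * dc
            accl += w * dl
            if stage < 3:
                h = 0.5 * dt if stage < 2 else dt
                y0 = pga + h * d0
                y1 = pra + h * d1
                y2 = pgd + h * d2
                y3 = prd + h * d3
        f = dt / 6.0
        v0 = pga + f * acc0
        v1 = pra + f * acc1
        v2 = pgd + f * acc2
        v3 = prd + f * acc3
        # clip integration round-off below zero
        pools[i, 0] = v0 if v0 > 0.0 else 0.0
        pools[i, 1] = v1 if v1 > 0.0 else 0.0
        pools[i, 2] = v2 if v2 > 0.0 else 0.0
        pools[i, 3] = v3 if v3 > 0.0 else 0.0
        out_cons[i] = f * accc
        out_loss[i] = f * accl


try:  # pragma: no cover - exercised implicitly wherever numba is installed
    import numba

    _rk4_compiled = numba.njit(cache=False)(_rk4_loop)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _rk4_compiled = None
    HAVE_NUMBA = False


def _rk4_numpy(pools, S, dt, mu_max, K_S, Y_mu, Y_r, alloc, A, mode, beta, out_cons, out_loss):
    """Vectorized twin of :func:`_rk4_loop` (same math, array ops)."""

    mu = mu_max * S / (K_S + S)

    def rates(y):
        y0, y1, y2, y3 = y
        tot = y0 + y1 + y2 + y3
        dam = y2 + y3
        safe_tot = np.where(tot > 0.0, tot, 1.0)
        Z = dam / safe_tot
        live = (tot > 0.0) & (Z < DEAD_Z)
        syn = mu * y0 * (1.0 - Z)
        mach = np.where(mode == 1, beta * (y0 + y1), np.where(mode == 2, y1, 0.0))
        denom = mach + dam
        r = np.where(denom > 0.0, mach * dam / np.where(denom > 0.0, denom, 1.0), 0.0)
        safe_dam = np.where(dam > 0.0, dam, 1.0)
        fg = np.where(dam > 0.0, y2 / safe_dam, 0.0)
        fr = np.where(dam > 0.0, y3 / safe_dam, 0.0)
        d0 = (1.0 - alloc) * syn - A * y0 + Y_r * r * fg
        d1 = alloc * syn - A * y1 + Y_r * r * fr
        d2 = A * y0 - r * fg
        d3 = A * y1 - r * fr
        dc = syn / Y_mu
        dl = (1.0 - Y_r) * r
        z = np.zeros_like(y0)
        return [
            np.where(live, d0, z), np.where(live, d1, z),
            np.where(live, d2, z), np.where(live, d3, z),
            np.where(live, dc, z), np.where(live, dl, z),
        ]

    y = [pools[:, j].copy() for j in range(4)]
    k1 = rates(y)
    k2 = rates([y[j] + 0.5 * dt * k1[j] for j in range(4)])
    k3 = rates([y[j] + 0.5 * dt * k2[j] for j in range(4)])
    k4 = rates([y[j] + dt * k3[j] for j in range(4)])
    f = dt / 6.0
    for j in range(4):
        v = y[j] + f * (k1[j] + 2 * k2[j] + 2 * k3[j] + k4[j])
        pools[:, j] = np.maximum(v, 0.0)
    out_cons[:] = f * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
    out_loss[:] = f * (k1[5] + 2 * k2[5] + 2 * k3[5] + k4[5])


def rk4_step(pools, S, dt, mu_max, K_S, Y_mu, Y_r, alloc, A, mode, beta):
    """Advance all cells by one step, in place.

    Parameters are per-cell arrays except the scalars ``dt`` and the
    kinetic constants. Returns ``(consumed, lost)`` in fg per cell.
    """
    n = pools.shape[0]
    cons = np.empty(n)
    loss = np.empty(n)
    impl = _rk4_compiled if _rk4_compiled is not None else _rk4_numpy
    impl(
        pools, S, float(dt), float(mu_max), float(K_S), float(Y_mu), float(Y_r),
        alloc, A, mode, beta, cons, loss,
    )
    return cons, loss
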