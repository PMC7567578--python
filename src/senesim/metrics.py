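"""Structure and fitness metrics.

Covers the dimensionless transport/consumption group delta^2 that
classifies biofilm growth regimes, front roughness sigma_f, the active
layer of near-maximally growing cells, log biomass ratios for
competitions, the exact binomial proportion test used on replicate win
counts, and per-strategy population summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "delta_squared",
    "roughness",
    "active_layer",
    "log_biomass_ratio",
    "proportion_test",
    "population_summary",
    "CompetitionRecord",
]


def delta_squared(
    S_bulk: float,
    D_G: float = 6.7e-10,
    Y_mu: float = 0.444,
    mu_max: float = 1.2,
    rho: float = 201.0,
    b_L: float = 48.0,
) -> float:
    """Ratio of maximum substrate transport to maximum consumption,

        delta^2 = S_bulk D_G Y_mu / (mu_max rho b_L^2).

    Low values mean transport-limited (rough, fingered) biofilms; high
    values growth-limited (smooth) ones. Units are reconciled
    internally: ``S_bulk`` and ``rho`` in g/L, ``D_G`` in m^2/s
    (converted to m^2/h), ``mu_max`` in h^-1, ``b_L`` in um (converted
    to m). The default parameters with S_bulk = 0.003556 g/L give the
    intermediate regime value 0.0069 (2 s.f.).
    """
    for name, v in [
        ("S_bulk", S_bulk), ("D_G", D_G), ("Y_mu", Y_mu),
        ("mu_max", mu_max), ("rho", rho), ("b_L", b_L),
    ]:
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be a positive finite number, got {v}")
    if D_G > 1e-7:
        raise ValueError("D_G looks unit-inconsistent: expected m^2/s (~1e-9)")
    if b_L < 1e-3:
        raise ValueError("b_L looks unit-inconsistent: expected micrometres")
    D_G_h = D_G * 3600.0  # m^2/h
    b_L_m = b_L * 1e-6  # m
    return S_bulk * D_G_h * Y_mu / (mu_max * rho * b_L_m**2)


def roughness(front_heights) -> float:
    """Biofilm front roughness sigma_f (um): the mean absolute deviation
    of per-column front heights from the mean front position."""
    h = np.asarray(front_heights, dtype=float)
    if h.size == 0:
        raise ValueError("need at least one front column")
    return float(np.abs(h - h.mean()).mean())


def active_layer(mu_net, frac: float = 0.95) -> np.ndarray:
    """Boolean mask of cells in the active layer: net specific growth
    rate within 5% of the population maximum at this time point. An
    all-dead population (max rate <= 0) has an empty active layer."""
    mu = np.asarray(mu_net, dtype=float)
    if mu.size == 0:
        raise ValueError("need at least one cell")
    top = mu.max()
    if top <= 0:
        return np.zeros_like(mu, dtype=bool)
    return mu >= frac * top


def log_biomass_ratio(biomass_a, biomass_b):
    """log10(biomass_a / biomass_b); antisymmetric under swapping the
    strategies, zero when they are equal. Requires both positive
    (the series terminates when a strategy goes extinct)."""
    a = np.asarray(biomass_a, dtype=float)
    b = np.asarray(biomass_b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("log biomass ratio requires positive biomasses")
    out = np.log10(a / b)
    return float(out) if out.ndim == 0 else out


def proportion_test(wins: int, n: int) -> float:
    """Exact two-sided binomial test of ``wins`` out of ``n`` against
    p = 1/2: the doubled smaller tail, capped at 1. 10 wins out of 10
    gives 2 * (1/2)^10 = 0.00195."""
    if n <= 0:
        raise ValueError("need at least one replicate")
    if not 0 <= wins <= n:
        raise ValueError("wins must lie in [0, n]")
    lo = stats.binom.cdf(wins, n, 0.5)
    hi = stats.binom.sf(wins - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lo, hi)))


def population_summary(
    df: pd.DataFrame,
    by: tuple[str, ...] = ("strategy", "pole_generation"),
) -> pd.DataFrame:
    """Quantile summaries of growth rate, age, and size per group.

    ``df`` is an agent table with columns ``mu_net``, ``Z``, ``P_tot``
    plus the grouping columns. Returns medians, interquartile ranges and
    counts per group.
    """
    if df.empty:
        raise ValueError("need at least one cell")
    by = [c for c in by if c in df.columns]
    if not by:
        by = [None]
        grouped = [(("all",), df)]
    else:
        grouped = df.groupby(by, sort=True)
    rows = []
    for key, g in grouped:
        if not isinstance(key, tuple):
            key = (key,)
        q = g["mu_net"].quantile([0.25, 0.5, 0.75])
        rows.append(
            {
                **dict(zip(by if by != [None] else ["group"], key)),
                "n": len(g),
                "mu_median": q.loc[0.5],
                "mu_iqr": q.loc[0.75] - q.loc[0.25],
                "age_median": g["Z"].median(),
                "size_median": g["P_tot"].median(),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CompetitionRecord:
    """Time courses and outcome of a two-strategy competition."""

    table: pd.DataFrame  # tidy: time, strategy, biomass, count, ...
    strategies: tuple[str, str]

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "CompetitionRecord":
        labs = tuple(table["strategy"].unique())
        if len(labs) != 2:
            raise ValueError(f"competition record needs exactly 2 strategies, got {labs}")
        return cls(table=table, strategies=labs)  # type: ignore[arg-type]

    def biomass_series(self) -> pd.DataFrame:
        return self.table.pivot_table(index="time", columns="strategy", values="biomass")

    def log_ratio(self) -> pd.Series:
        """log10 biomass ratio of strategy A over strategy B, defined
        while both have positive biomass."""
        wide = self.biomass_series()
        a, b = self.strategies
        m = (wide[a] > 0) & (wide[b] > 0)
        return pd.Series(
            np.log10(wide.loc[m, a] / wide.loc[m, b]), index=wide.index[m], name=f"log10({a}/{b})"
        )

    def winner(self, stable_frac: float = 0.2) -> str | None:
        """The winning strategy.

        If one strategy is extinct at the end, the survivor wins.
        Otherwise the strategy with the higher final biomass wins,
        provided the sign of the log ratio is stable over the final
        ``stable_frac`` of the run; a sign change there means no clear
        winner (None). Invariant to the labelling order.
        """
        wide = self.biomass_series()
        a, b = self.strategies
        last = wide.iloc[-1]
        if last[a] <= 0 and last[b] <= 0:
            return None
        if last[a] <= 0:
            return b
        if last[b] <= 0:
            return a
        lr = self.log_ratio()
        tail = lr.iloc[int(np.floor(len(lr) * (1.0 - stable_frac))):]
        if len(tail) == 0 or tail.iloc[-1] == 0:
            return None
        sign = np.sign(tail.iloc[-1])
        if np.any(np.sign(tail) == -sign):
            return None
        return a if sign > 0 else b
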