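"""Plotting helpers: age-coloured biofilm maps and log-ratio courses."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .biofilm import BiofilmSim
from .metrics import CompetitionRecord

__all__ = ["plot_biofilm", "plot_log_ratio"]

_CMAPS = ("autumn", "winter", "summer", "cool")


def plot_biofilm(sim: BiofilmSim, ax=None, color_by: str = "age"):
    """Scatter the cells of a biofilm, coloured by age (one colour
    gradient per strategy) or by active-layer membership."""
    from .metrics import active_layer

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6 * sim.domain.height / sim.domain.width))
    pop = sim.pop
    r = pop.radii("slab", sim.domain.resolution)
    size = (r * 72.0 / max(sim.domain.width, 1) * 6) ** 2
    if color_by == "age":
        for i, lab in enumerate(pop.labels):
            m = pop.sid == i
            ax.scatter(
                pop.x[m], pop.y[m], c=pop.Z[m], cmap=_CMAPS[i % len(_CMAPS)],
                vmin=0, vmax=1, s=size[m], lw=0, label=lab,
            )
    else:
        act = active_layer(pop.mu_net) if len(pop) else np.zeros(0, bool)
        ax.scatter(pop.x, pop.y, c=np.where(act, 1.0, 0.2), cmap="viridis",
                   vmin=0, vmax=1, s=size, lw=0)
    ax.set_xlim(0, sim.domain.width)
    ax.set_ylim(0, sim.domain.height)
    ax.set_xlabel("x (um)")
    ax.set_ylabel("height (um)")
    ax.set_aspect("equal")
    return ax


def plot_log_ratio(records, ax=None):
    """Log10 biomass-ratio time courses for one or more competition
    records (the zero line is the symmetry axis)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    if isinstance(records, (CompetitionRecord, pd.DataFrame)):
        records = [records]
    for rec in records:
        if isinstance(rec, pd.DataFrame):
            rec = CompetitionRecord.from_table(rec)
        lr = rec.log_ratio()
        ax.plot(lr.index, lr.values, alpha=0.8)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("log10 biomass ratio")
    return ax
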