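"""Scenario execution: build the environment from a config, run it with
periodic recording, write tables/metrics/snapshots, and resume
interrupted runs.

Outputs in the run directory:

* ``config.yaml`` -- the exact configuration executed
* ``summary.csv`` -- per-interval per-strategy summaries
* ``agents_final.csv`` -- full agent table at the end
* ``field_final.txt`` -- substrate field (biofilm only, plain text)
* ``focal.csv`` -- focal-lineage time series (tracking runs)
* ``metrics.json`` -- final metrics (biomass, counts, winner, ...)
* ``snapshot.json`` -- full state (including the RNG state) written at
  every output interval; a resumed run reproduces the uninterrupted one
  exactly
* ``manifest.json`` -- machine-readable index of the above
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biofilm import BiofilmDomain, BiofilmSim, biofilm_env, step_biofilm, summarise as bf_summarise
from .config import ScenarioConfig
from .metrics import log_biomass_ratio, CompetitionRecord
from .population import Population
from .wellmixed import (
    WellMixedEnv, constant_env, chemostat_env,
    step_constant, step_chemostat, track_single_cell, _summarise as wm_summarise,
)

__all__ = ["run_scenario", "resume_scenario", "build_environment"]


def build_environment(cfg: ScenarioConfig):
    """Construct the (unrun) environment/simulation object described by
    ``cfg``: a :class:`WellMixedEnv` or a :class:`BiofilmSim`."""
    return _build(cfg)


def _build(cfg: ScenarioConfig):
    if cfg.environment == "constant":
        env = constant_env(
            cfg.strategies, cfg.counts, kp=cfg.kinetics, seed=cfg.seed,
            S=cfg.env["S"], dt=cfg.dt,
        )
        if cfg.env.get("pop_cap"):
            env.pop_cap = int(cfg.env["pop_cap"])
        if cfg.track_focal and len(env.pop):
            env.pop.protected[0] = True
        return env
    if cfg.environment == "chemostat":
        return chemostat_env(
            cfg.strategies, cfg.counts, kp=cfg.kinetics, seed=cfg.seed,
            S_in=cfg.env["S_in"], D=cfg.env["D"], volume=cfg.env["volume"],
            dt=cfg.dt,
        )
    domain = BiofilmDomain(
        width=cfg.env["width"], height=cfg.env["height"],
        resolution=cfg.env["resolution"], S_bulk=cfg.env["S_bulk"],
        b_L=cfg.env["b_L"], h_max=cfg.env["h_max"],
        shove_factor=cfg.env["shove_factor"],
    )
    return biofilm_env(
        cfg.strategies, cfg.counts, kp=cfg.kinetics, domain=domain,
        seed=cfg.seed, placement=cfg.placement, dt=cfg.dt,
    )


def _pop_state(pop: Population) -> dict:
    d = {
        "pools": pop.pools.tolist(),
        "sid": pop.sid.tolist(),
        "v_inert": pop.v_inert.tolist(),
        "pole_gen": pop.pole_gen.tolist(),
        "mu_net": pop.mu_net.tolist(),
        "protected": pop.protected.tolist() if pop.protected is not None else None,
    }
    if pop.x is not None:
        d["x"] = pop.x.tolist()
        d["y"] = pop.y.tolist()
    return d


def _restore_pop(pop: Population, d: dict) -> None:
    n = len(d["sid"])
    pop.pools = np.asarray(d["pools"], dtype=float).reshape(n, 4)
    pop.sid = np.asarray(d["sid"], dtype=np.int64)
    pop.v_inert = np.asarray(d["v_inert"], dtype=float)
    pop.pole_gen = np.asarray(d["pole_gen"], dtype=np.int64)
    pop.mu_net = np.asarray(d["mu_net"], dtype=float)
    pop.protected = (
        np.asarray(d["protected"], dtype=bool) if d["protected"] is not None else None
    )
    if "x" in d:
        pop.x = np.asarray(d["x"], dtype=float)
        pop.y = np.asarray(d["y"], dtype=float)


def _agent_table(state, cfg: ScenarioConfig) -> pd.DataFrame:
    pop = state.pop
    geometry = "slab" if cfg.environment == "biofilm" else "sphere"
    thickness = cfg.env.get("resolution", 4.0)
    d = {
        "id": np.arange(len(pop)),
        "strategy": [pop.labels[i] for i in pop.sid],
        "P_ga": pop.pools[:, 0], "P_ra": pop.pools[:, 1],
        "P_gd": pop.pools[:, 2], "P_rd": pop.pools[:, 3],
        "P_tot": pop.P_tot, "Z": pop.Z,
        "mu_net": pop.mu_net,
        "pole_generation": pop.pole_gen,
        "radius": pop.radii(geometry, thickness),
        "V_inert": pop.v_inert,
    }
    if pop.x is not None:
        d["x"] = pop.x
        d["y"] = pop.y
    return pd.DataFrame(d)


def _final_metrics(state, cfg, table: pd.DataFrame) -> dict:
    pop = state.pop
    out = {
        "t_final": float(state.t),
        "counts": pop.counts_by_strategy(),
        "biomass": pop.biomass_by_strategy(),
    }
    if cfg.environment == "biofilm":
        last = table[table["time"] == table["time"].max()]
        out["height"] = float(last["height"].iloc[0])
        out["sigma_f"] = float(last["sigma_f"].iloc[0])
    labels = list(pop.strategies)
    if len(labels) == 2:
        a, b = labels
        ba, bb = out["biomass"][a], out["biomass"][b]
        out["log10_biomass_ratio"] = (
            log_biomass_ratio(ba, bb) if ba > 0 and bb > 0 else None
        )
        try:
            out["winner"] = CompetitionRecord.from_table(table).winner()
        except ValueError:
            out["winner"] = None
    return out


def run_scenario(cfg: ScenarioConfig, outdir) -> Path:
    """Execute ``cfg`` and write all outputs into ``outdir``.

    Deterministic given (config, seed). Returns the output directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.save(outdir / "config.yaml")
    if cfg.track_focal and sum(cfg.counts.values()) == 1:
        # dedicated single-lineage tracking run
        lab, sp = next(iter(cfg.strategies.items()))
        focal = track_single_cell(
            sp, kp=cfg.kinetics, S=cfg.env["S"], days=cfg.t_end / 24.0,
            dt=cfg.dt, seed=cfg.seed,
        )
        focal.to_csv(outdir / "focal.csv", index=False)
        _write_manifest(outdir, cfg, complete=True, files=["config.yaml", "focal.csv"])
        return outdir
    state = _build(cfg)
    rows = _record(state, cfg)
    return _run_loop(state, cfg, outdir, rows, next_out=state.t + cfg.output_interval)


def _record(state, cfg) -> list[dict]:
    if cfg.environment == "biofilm":
        return bf_summarise(state)
    return wm_summarise(state)


def _snapshot(state, cfg, rows, next_out, outdir):
    snap = {
        "t": float(state.t),
        "next_out": float(next_out),
        "rows": rows,
        "rng_state": state.rng.bit_generator.state,
        "pop": _pop_state(state.pop),
    }
    if cfg.environment == "chemostat":
        snap["S"] = float(state.S)
    if cfg.environment == "biofilm":
        snap["stopped"] = bool(state.stopped)
    tmp = outdir / "snapshot.json.tmp"
    tmp.write_text(json.dumps(snap))
    tmp.replace(outdir / "snapshot.json")


def _run_loop(state, cfg: ScenarioConfig, outdir: Path, rows, next_out) -> Path:
    t0 = time.time()
    is_biofilm = cfg.environment == "biofilm"
    if is_biofilm:
        stepper = lambda: step_biofilm(state)
    elif cfg.environment == "constant":
        stepper = lambda: step_constant(state)
    else:
        stepper = lambda: step_chemostat(state)
    while state.t < cfg.t_end - 1e-9:
        if is_biofilm and state.stopped:
            break
        stepper()
        if state.t >= next_out - 1e-9 or (is_biofilm and state.stopped):
            rows.extend(_record(state, cfg))
            next_out = state.t + cfg.output_interval
            _snapshot(state, cfg, rows, next_out, outdir)
            if cfg.stop_on_sole_survivor and len(cfg.strategies) > 1:
                alive = sum(1 for v in state.pop.counts_by_strategy().values() if v > 0)
                if alive <= 1:
                    break
        if len(state.pop) == 0:
            break
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "summary.csv", index=False)
    _agent_table(state, cfg).to_csv(outdir / "agents_final.csv", index=False)
    files = ["config.yaml", "summary.csv", "agents_final.csv", "metrics.json", "snapshot.json"]
    if is_biofilm and state.S_field is not None:
        np.savetxt(outdir / "field_final.txt", state.S_field)
        files.append("field_final.txt")
    metrics = _final_metrics(state, cfg, table)
    metrics["wall_seconds"] = round(time.time() - t0, 2)
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=1))
    _write_manifest(outdir, cfg, complete=True, files=files)
    return outdir


def _write_manifest(outdir, cfg, complete, files):
    (outdir / "manifest.json").write_text(
        json.dumps(
            {
                "package": "senesim",
                "version": __version__,
                "scenario": cfg.name,
                "seed": cfg.seed,
                "complete": complete,
                "files": files,
            },
            indent=1,
        )
    )


def resume_scenario(outdir) -> Path:
    """Continue an interrupted run from its last snapshot; the finished
    summaries equal those of an uninterrupted run."""
    outdir = Path(outdir)
    cfg = ScenarioConfig.load(outdir / "config.yaml")
    snap = json.loads((outdir / "snapshot.json").read_text())
    state = _build(cfg)
    state.t = snap["t"]
    state.rng.bit_generator.state = snap["rng_state"]
    _restore_pop(state.pop, snap["pop"])
    if cfg.environment == "chemostat":
        state.S = snap["S"]
    if cfg.environment == "biofilm":
        state.stopped = snap["stopped"]
        state.S_field = None  # re-solved on the next step
    return _run_loop(state, cfg, outdir, snap["rows"], snap["next_out"])
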