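"""Scenario configuration: a validated, serialisable description of one
simulation (environment, kinetics, strategy roster, initial placement,
stop condition, seed), plus a catalogue of named presets reproducing the
study's experimental setups at full and reduced (desk) scale.

The on-disk format is YAML with the same nesting as
:meth:`ScenarioConfig.to_dict`; unknown keys are rejected with the full
field path so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import KineticParams, StrategyParams, strategy

__all__ = ["ScenarioConfig", "ConfigError", "load_config", "save_config", "preset", "PRESETS"]

ENVIRONMENTS = ("constant", "chemostat", "biofilm")
PLACEMENTS = ("random", "equidistant", "side_by_side")

_ENV_DEFAULTS = {
    "constant": {"S": 0.00234, "pop_cap": None},
    "chemostat": {"S_in": 0.00324, "D": 0.3, "volume": 1e-6},
    "biofilm": {
        "width": 256.0, "height": 256.0, "resolution": 4.0,
        "S_bulk": 0.003556, "b_L": 48.0, "h_max": 154.0, "shove_factor": 1.10,
    },
}


class ConfigError(ValueError):
    """A configuration problem, reported with its field path."""


@dataclass
class ScenarioConfig:
    environment: str
    seed: int
    strategies: dict[str, StrategyParams]
    counts: dict[str, int]
    kinetics: KineticParams = field(default_factory=KineticParams)
    env: dict = field(default_factory=dict)
    dt: float | None = None  # default 0.01 well-mixed, 0.05 biofilm
    t_end: float | None = None  # hours; wellmixed default 12000 (500 d)
    output_interval: float | None = None  # default 1 h well-mixed, 5 h biofilm
    placement: str = "random"
    stop_on_sole_survivor: bool = False
    track_focal: bool = False  # protect and follow a focal old-pole cell
    name: str = "scenario"

    def __post_init__(self):
        if self.environment not in ENVIRONMENTS:
            raise ConfigError(
                f"environment: must be one of {ENVIRONMENTS}, got {self.environment!r}"
            )
        if self.placement not in PLACEMENTS:
            raise ConfigError(
                f"placement: must be one of {PLACEMENTS}, got {self.placement!r}"
            )
        if not isinstance(self.seed, int):
            raise ConfigError("seed: an integer seed is mandatory for reproducibility")
        if not self.strategies:
            raise ConfigError("strategies: at least one strategy is required")
        for lab in self.counts:
            if lab not in self.strategies:
                raise ConfigError(f"counts.{lab}: no such strategy in the roster")
        merged = dict(_ENV_DEFAULTS[self.environment])
        for k, v in self.env.items():
            if k not in merged:
                raise ConfigError(
                    f"env.{k}: unknown parameter for the {self.environment} environment"
                )
            merged[k] = v
        self.env = merged
        if self.dt is None:
            self.dt = 0.05 if self.environment == "biofilm" else 0.01
        if self.output_interval is None:
            self.output_interval = 5.0 if self.environment == "biofilm" else 1.0
        if self.t_end is None and self.environment != "biofilm":
            self.t_end = 12000.0  # 500 days
        if self.t_end is None:
            self.t_end = 500.0  # biofilm cap; height stop normally fires first
        if self.dt <= 0 or self.output_interval <= 0 or self.t_end <= 0:
            raise ConfigError("dt/t_end/output_interval: must be positive")

    # ---- (de)serialisation --------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "environment": self.environment,
            "seed": self.seed,
            "dt": self.dt,
            "t_end": self.t_end,
            "output_interval": self.output_interval,
            "placement": self.placement,
            "stop_on_sole_survivor": self.stop_on_sole_survivor,
            "track_focal": self.track_focal,
            "kinetics": {
                k: getattr(self.kinetics, k)
                for k in ("mu_max", "K_S", "Y_mu", "Y_r", "rho", "div_radius",
                          "P_div", "theta_mean", "theta_sd")
            },
            "env": dict(self.env),
            "strategies": {
                lab: dataclasses.asdict(sp) for lab, sp in self.strategies.items()
            },
            "counts": dict(self.counts),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)} | {"name"}
        for k in d:
            if k not in known:
                raise ConfigError(f"{k}: unknown configuration key")
        for req in ("environment", "seed", "strategies", "counts"):
            if req not in d:
                raise ConfigError(f"{req}: required key missing")
        kin = d.pop("kinetics", {})
        if not isinstance(kin, dict):
            raise ConfigError("kinetics: must be a mapping")
        kin_known = {f.name for f in dataclasses.fields(KineticParams)}
        for k in kin:
            if k not in kin_known:
                raise ConfigError(f"kinetics.{k}: unknown kinetic parameter")
        try:
            kinetics = KineticParams(**kin)
        except ValueError as e:
            raise ConfigError(f"kinetics: {e}") from None
        strats = {}
        sp_known = {f.name for f in dataclasses.fields(StrategyParams)}
        for lab, spd in d.pop("strategies").items():
            if not isinstance(spd, dict):
                raise ConfigError(f"strategies.{lab}: must be a mapping")
            for k in spd:
                if k not in sp_known:
                    raise ConfigError(f"strategies.{lab}.{k}: unknown strategy field")
            try:
                strats[lab] = StrategyParams(**spd)
            except ValueError as e:
                raise ConfigError(f"strategies.{lab}: {e}") from None
        try:
            return cls(kinetics=kinetics, strategies=strats, **d)
        except TypeError as e:
            raise ConfigError(str(e)) from None

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "ScenarioConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as e:
            raise ConfigError(f"malformed YAML: {e}") from None
        if not isinstance(raw, dict):
            raise ConfigError("top level: expected a mapping")
        return cls.from_dict(raw)


def load_config(path) -> ScenarioConfig:
    return ScenarioConfig.load(path)


def save_config(cfg: ScenarioConfig, path) -> None:
    cfg.save(path)


# ---------------------------------------------------------------------------
# Preset catalogue
# ---------------------------------------------------------------------------

#: Sensitivity-analysis values: one lower and one higher value per
#: parameter (half/double, ten-fold, or the literature extreme where one
#: exists, e.g. repair yield lowered to the growth yield).
SENSITIVITY_VALUES: dict[str, tuple[float, float]] = {
    "mu_max": (0.6, 2.4),
    "Y_mu": (0.222, 0.888),
    "Y_r": (0.444, 1.0),
    "P_div": (311.0, 1244.0),
    "S_bulk": (0.0003556, 0.03556),
    "K_S": (0.0000234, 0.0234),
    "a_prime": (0.11, 0.44),
}


def _prop(name: str, **kw) -> StrategyParams:
    return strategy(name, aging_mode="growth_proportional", **kw)


def preset(name: str, reduced: bool = False, seed: int = 0, **kw) -> ScenarioConfig:
    """Return a named scenario preset.

    Every preset has a reduced variant (smaller domain / population /
    horizon) that exercises the same code paths in minutes on one CPU.
    Extra keyword arguments override preset fields, e.g.
    ``preset("biofilm_proportional_aging", density=8)``.
    """
    try:
        builder = PRESETS[name.split(":")[0]]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    if ":" in name:
        kw.setdefault("param", name.split(":", 1)[1])
    cfg = builder(reduced=reduced, seed=seed, **kw)
    cfg.name = name + ("_reduced" if reduced else "")
    return cfg


def _single_cell_tracking(reduced, seed, strategy_name="DSAR"):
    """Follow one focal old-pole cell in the constant environment for
    three days (repair investment seesaw / growth-rate decline)."""
    return ScenarioConfig(
        environment="constant", seed=seed,
        strategies={strategy_name: _prop(strategy_name)},
        counts={strategy_name: 1},
        t_end=24.0 if reduced else 72.0,
        track_focal=True,
        stop_on_sole_survivor=False,
    )


def _population_structure(reduced, seed, strategy_name="AR"):
    """Single-strategy constant-environment population run to steady
    state (age/size/growth-rate distributions)."""
    n = 200 if reduced else 1000
    return ScenarioConfig(
        environment="constant", seed=seed,
        strategies={strategy_name: _prop(strategy_name)},
        counts={strategy_name: n},
        t_end=150.0 if reduced else 2400.0,
    )


def _wellmixed_competition(reduced, seed, pair=("AR", "DS"), environment="chemostat"):
    """Pairwise competition (500 cells each at full scale) run until a
    sole survivor or 500 days."""
    n = 60 if reduced else 500
    env = {}
    if environment == "chemostat" and reduced:
        env = {"volume": 1.5e-7}
    return ScenarioConfig(
        environment=environment, seed=seed,
        strategies={lab: _prop(lab) for lab in pair},
        counts={lab: n for lab in pair},
        env=env,
        t_end=400.0 if reduced else 12000.0,
        stop_on_sole_survivor=True,
    )


def _biofilm_structure_scan(reduced, seed, S_bulk=0.003556, n=8):
    """No-aging biofilm growth for the structure regimes (S_bulk in
    {0.014222, 0.003556, 0.000889} g/L at full scale)."""
    strat = StrategyParams(alpha=0.0, repair_mode="none", aging_mode="constant", a=0.0)
    env = {"S_bulk": S_bulk}
    if reduced:
        env.update({"width": 64.0, "height": 128.0, "h_max": 48.0})
    return ScenarioConfig(
        environment="biofilm", seed=seed,
        strategies={"NA": strat}, counts={"NA": n},
        env=env, placement="equidistant",
        kinetics=KineticParams(rho=201.0),
    )


def _biofilm_competition(reduced, seed, density=32, pair=("DS", "AR"),
                         aging="growth_proportional", styrofoam=False,
                         S_bulk=0.003556, placement="random", **kin):
    strats = {
        lab: strategy(lab, aging_mode=aging, styrofoam=styrofoam) for lab in pair
    }
    env = {"S_bulk": S_bulk}
    if reduced:
        env.update({"width": 64.0, "height": 128.0, "h_max": 36.0})
    counts = {lab: density // 2 for lab in pair}
    kinetics = KineticParams(rho=201.0, **kin) if kin else KineticParams(rho=201.0)
    return ScenarioConfig(
        environment="biofilm", seed=seed, strategies=strats, counts=counts,
        env=env, kinetics=kinetics, placement=placement,
    )


def _biofilm_constant_aging(reduced, seed, **kw):
    """Biofilm competitions with the constant damage rate a = 0.1 h^-1
    (with or without the styrofoam variant)."""
    kw.setdefault("aging", "constant")
    return _biofilm_competition(reduced, seed, **kw)


def _biofilm_proportional_aging(reduced, seed, **kw):
    """Biofilm competitions with damage proportional to the gross
    specific growth rate (a' = 0.22)."""
    kw.setdefault("aging", "growth_proportional")
    return _biofilm_competition(reduced, seed, **kw)


def _sensitivity(reduced, seed, param="K_S", which="low", **kw):
    """Biofilm DS-vs-AR competition with one parameter moved to its
    lower/higher sensitivity value; cells in side-by-side blocks at the
    highest initial density."""
    if param not in SENSITIVITY_VALUES:
        raise KeyError(
            f"unknown sensitivity parameter {param!r}; "
            f"available: {sorted(SENSITIVITY_VALUES)}"
        )
    lo, hi = SENSITIVITY_VALUES[param]
    value = lo if which == "low" else hi
    cfg = _biofilm_proportional_aging(reduced, seed, density=32, placement="random", **kw)
    if param == "S_bulk":
        cfg.env["S_bulk"] = value
    elif param == "a_prime":
        cfg.strategies = {
            lab: dataclasses.replace(sp, a_prime=value)
            for lab, sp in cfg.strategies.items()
        }
    else:
        cfg.kinetics = cfg.kinetics.with_(**{param: value})
    cfg.t_end = min(cfg.t_end, 500.0)
    return cfg


def _aging_calibration(reduced, seed):
    """Reference chemostat run for the a' calibration (constant aging,
    fixed repair); the scan itself lives in :mod:`senesim.calibrate`."""
    n = 250 if reduced else 1000
    env = {"volume": 1.5e-7} if reduced else {}
    return ScenarioConfig(
        environment="chemostat", seed=seed,
        strategies={"FR": strategy("FR", aging_mode="constant", a=0.1)},
        counts={"FR": n},
        env=env,
        t_end=120.0 if reduced else 2400.0,
    )


PRESETS = {
    "single_cell_tracking": _single_cell_tracking,
    "population_structure": _population_structure,
    "wellmixed_competition": _wellmixed_competition,
    "biofilm_structure_scan": _biofilm_structure_scan,
    "biofilm_constant_aging": _biofilm_constant_aging,
    "biofilm_proportional_aging": _biofilm_proportional_aging,
    "sensitivity": _sensitivity,
    "aging_calibration": _aging_calibration,
}
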