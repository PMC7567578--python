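"""Parameter containers for cells, strategies, and kinetics.

Units used throughout the package:

* protein pools -- femtograms (fg)
* lengths -- micrometres (um)
* volumes -- cubic micrometres (um^3) for cells, litres for vessels
* concentrations -- g/L (note 1 g/L == 1 fg/um^3, so biomass density in
  g/L can be used directly as fg per um^3)
* rates -- per hour (h^-1)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "StrategyParams",
    "KineticParams",
    "division_threshold",
    "STRATEGIES",
    "strategy",
]

#: Repair modes: no repair machinery, a fixed allocation fraction, or an
#: allocation recomputed each step from the sensed damage level.
REPAIR_MODES = ("none", "fixed", "adaptive")

#: Damage accumulation modes: a constant specific rate, or a rate
#: proportional to the gross specific growth rate (damage as a by-product
#: of metabolism).
AGING_MODES = ("constant", "growth_proportional")


@dataclass(frozen=True)
class StrategyParams:
    """One heritable strategy: division asymmetry plus repair/aging policy.

    Parameters
    ----------
    alpha : float
        Division asymmetry. 0 = fully symmetric (each daughter receives
        damage in proportion to inherited mass), 1 = fully asymmetric
        (the old-pole daughter receives all damage, the new-pole daughter
        is rejuvenated).
    repair_mode : str
        ``none``, ``fixed`` (constant fraction ``beta_fixed`` of active
        protein acts as repair machinery) or ``adaptive`` (repair
        machinery is the explicitly tracked active repair pool, built at
        a rate chosen to maximise active-protein production).
    beta_fixed : float
        Allocation fraction for ``fixed`` repair. The optimum for the
        default damage rate is 0.07.
    aging_mode : str
        ``constant`` (rate ``a``) or ``growth_proportional`` (rate
        ``a_prime`` times the gross specific growth rate).
    a : float
        Constant damage accumulation rate, h^-1.
    a_prime : float
        Proportionality constant for growth-proportional damage, h^-1
        per unit gross specific growth rate.
    styrofoam : bool
        If True, biomass lost to inefficient repair is replaced by inert,
        massless volume so the cell never shrinks.
    """

    alpha: float = 0.0
    repair_mode: str = "none"
    beta_fixed: float = 0.07
    aging_mode: str = "constant"
    a: float = 0.1
    a_prime: float = 0.22
    styrofoam: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.repair_mode not in REPAIR_MODES:
            raise ValueError(
                f"repair_mode must be one of {REPAIR_MODES}, got {self.repair_mode!r}"
            )
        if not 0.0 <= self.beta_fixed <= 1.0:
            raise ValueError(f"beta_fixed must be in [0, 1], got {self.beta_fixed}")
        if self.aging_mode not in AGING_MODES:
            raise ValueError(
                f"aging_mode must be one of {AGING_MODES}, got {self.aging_mode!r}"
            )
        if self.a < 0 or self.a_prime < 0:
            raise ValueError("damage accumulation rates must be >= 0")


def division_threshold(radius: float = 0.8, rho: float = 290.0) -> float:
    """Protein mass (fg) of a sphere of ``radius`` um at density ``rho`` g/L.

    The division trigger is a threshold cell radius of 0.8 um, equivalent
    to a volume of ~2.14 um^3; at the well-mixed biomass density of
    290 g/L this is ~620 fg. Since 1 g/L = 1 fg/um^3 the product of
    volume and density is already in fg.
    """
    if radius <= 0 or rho <= 0:
        raise ValueError("radius and rho must be positive")
    volume = 4.0 / 3.0 * math.pi * radius**3
    return volume * rho


@dataclass(frozen=True)
class KineticParams:
    """Growth, uptake and division parameters shared by all cells.

    Defaults are the study's E. coli-like parameter set: mu_max 1.2 h^-1,
    K_S 0.00234 g/L, growth yield 0.444 g/g, repair yield 0.8 g/g,
    biomass density 290 g/L (well-mixed) and a division threshold derived
    from a 0.8 um threshold radius. In the constant environment the fixed
    substrate level equals K_S, so cells there grow at mu_max/2 = 0.6 h^-1
    gross.
    """

    mu_max: float = 1.2  # h^-1
    K_S: float = 0.00234  # g/L
    Y_mu: float = 0.444  # g active protein per g substrate
    Y_r: float = 0.8  # g active protein per g damaged protein
    rho: float = 290.0  # g/L (dry mass density); 201 in biofilms
    div_radius: float = 0.8  # um, threshold radius triggering division
    P_div: float = field(default=None)  # type: ignore[assignment]  # fg; derived if None
    theta_mean: float = 0.5
    theta_sd: float = 0.025

    def __post_init__(self) -> None:
        for name in ("mu_max", "K_S", "Y_mu", "Y_r", "rho", "div_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 < self.Y_mu <= 1 and 0 < self.Y_r <= 1):
            raise ValueError("yields must be in (0, 1]")
        if self.P_div is None:
            object.__setattr__(
                self, "P_div", division_threshold(self.div_radius, self.rho)
            )
        elif self.P_div <= 0:
            raise ValueError("P_div must be strictly positive")

    def with_(self, **kw) -> "KineticParams":
        """Return a copy with fields replaced (P_div re-derived if rho
        changes and P_div is not given explicitly)."""
        if "rho" in kw and "P_div" not in kw:
            kw["P_div"] = None
        return replace(self, **kw)


# The six named strategy combinations: two division strategies crossed
# with three repair strategies. Names follow the field's shorthand:
# DS = damage segregation (asymmetric, no repair), NR = symmetric no
# repair, FR/AR = symmetric fixed/adaptive repair, DSFR/DSAR = asymmetric
# with fixed/adaptive repair.
STRATEGIES: dict[str, StrategyParams] = {
    "DS": StrategyParams(alpha=1.0, repair_mode="none"),
    "NR": StrategyParams(alpha=0.0, repair_mode="none"),
    "FR": StrategyParams(alpha=0.0, repair_mode="fixed"),
    "AR": StrategyParams(alpha=0.0, repair_mode="adaptive"),
    "DSFR": StrategyParams(alpha=1.0, repair_mode="fixed"),
    "DSAR": StrategyParams(alpha=1.0, repair_mode="adaptive"),
}


def strategy(name: str, **overrides) -> StrategyParams:
    """Look up a named strategy, optionally overriding fields
    (e.g. ``strategy("AR", aging_mode="growth_proportional")``)."""
    try:
        base = STRATEGIES[name]
    except KeyError:
        raise KeyError(
            f"unknown strategy {name!r}; known: {sorted(STRATEGIES)}"
        ) from None
    return replace(base, **overrides) if overrides else base
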