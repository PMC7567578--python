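# Methods

This note documents the model, its numerical treatment, the parameter
choices, and the design decisions that were genuinely open, in enough
detail to reimplement the package.

## Model

### Cell state and kinetics

A cell is four protein pools (fg): active growth machinery `P_ga`,
active repair machinery `P_ra`, and their damaged counterparts `P_gd`,
`P_rd`. "Protein" stands for all biomass. Derived quantities:
`P_act = P_ga + P_ra`, `P_dam = P_gd + P_rd`, `P_tot = P_act + P_dam`,
age `Z = P_dam / P_tot`. Damage is always toxic: synthesis is scaled by
`(1 - Z)`. A cell with `Z >= 1 - 1e-9` is dead: all kinetics stop, but
the cell keeps its volume and occupies space (cell-wall degradation is
slow on the simulated time scales). Mortality does not otherwise
increase with age — senescence here is purely loss of fecundity.

Only active growth machinery synthesises, at gross specific rate
`mu(S) = mu_max S / (K_S + S)` (Monod). A fraction `b` of new synthesis
is routed to repair machinery; both routes produce *active* protein.
Aging moves active protein to the corresponding damaged pool at rate
`A`; repair returns damaged protein to the corresponding active pool
with yield `Y_r = 0.8`, i.e. 20% of repaired mass is lost (the repair
resources come from endogenous metabolism). The total repair flux is
saturable in both machinery `m` and substrate-of-repair `P_dam`:
`r = m P_dam / (m + P_dam)`, apportioned pro rata across the two
damaged pools (`P_gd/P_dam`, `P_rd/P_dam`). This is the only form that
both reduces to the single-pool law and conserves mass:
`dP_tot/dt = mu(S) P_ga (1 - Z) - (1 - Y_r) r` exactly (a property
test enforces it to machine precision).

Repair machinery by strategy: none (`m = 0`), fixed (`m = beta P_act`,
`beta = 0.07`, the optimum for the default damage rate), adaptive
(`m = P_ra`, the explicitly tracked pool). Repair protein is stable: it
is never converted back into growth protein; `P_ra` declines only by
aging.

### Adaptive allocation

The adaptive strategy senses `Z` and re-chooses its allocation each
step to maximise the instantaneous rate of active-protein production.
For a cell whose machinery composition tracks the allocation (repair
machinery fraction `b` of active protein), production per unit active
protein is

    f(b) = (1 - b) mu (1 - Z) + Y_r b d / (b + d),   d = Z/(1 - Z).

`f` is concave; `df/db = 0` gives

    b_hat = d (sqrt(Y_r / (mu (1 - Z))) - 1),

clamped to [0, 1]. A brute-force grid argmax of `f` over 10^4 points is
kept as the independent oracle in the tests. `mu` here is the cell's
*net* specific growth rate realised over the previous step (computed
from the relative change of `P_tot`), not the gross Monod rate: the
benefit of repair must be weighed against what the cell actually
achieves. Non-positive `mu` returns `b_hat = 0` (no synthesis to
allocate); `Z >= 1` returns 1 by contract (irrelevant in practice —
such cells are dead). Newborn cells inherit the parent's previous net
rate; initial cells start with the Monod rate at the initial substrate
concentration.

### Damage accumulation

Two modes. Constant: `A = a = 0.1/h`, appropriate for spatially uniform
environments. Growth-proportional: `A = a' mu(S)` with the gross rate
`mu(S)` — damage as a by-product of metabolism, so the non-growing
cells deep in a biofilm neither accumulate damage nor shrink from
needless repair. The constant `a'` cannot be derived in closed form
(how far gross exceeds net growth depends on age, repair rate and
investment), so it is calibrated by simulation: chemostat runs with
constant aging give a steady-state mean age of ~0.145; scanning `a'` in
steps of 0.01 and matching that age yields `a' = 0.22` per unit gross
specific growth rate. `scripts/acceptance.py` recomputes this scan.

### Division

Trigger: `P_tot >= P_div`, where `P_div` is the mass of a sphere of
radius 0.8 um at the local biomass density (622 fg at 290 g/L; 431 fg
at the biofilm density of 201 g/L). The baby-mass fraction `theta` is
drawn per division from Normal(0.5, 0.025), clamped to (0.01, 0.99),
and applies to every pool and to inert volume; the normal jitter
belongs to `theta`, not to the threshold. With asymmetry `alpha`, an
additional `alpha theta` share of each damaged pool is shifted from the
new-pole to the old-pole daughter, so at `alpha = 1` the new pole is
born damage-free. If the old pole's active pool would go negative
("more damage than the old pole can take"), the overflow rule sets it
to zero, fills the old pole with damaged protein, and returns the
excess damage to the new pole. The overflow rule is applied
**independently per machinery class** (growth, repair): applying it to
both classes whenever either triggers would drive the new pole's
damaged pool of the non-triggering class negative. Per-class
application conserves every pool exactly and keeps all pools
nonnegative (property-tested). The old pole increments a consecutive
old-pole counter ("generation"); the new pole resets it.

### Environments

*Constant*: substrate pinned (default `S = K_S = 0.00234` g/L, so the
gross rate is `mu_max/2 = 0.6/h`); the population is capped — after
each step's divisions, as many uniformly random cells are removed as
there were divisions (newborns eligible; a protected focal cell, used
for lineage tracking, never). *Chemostat*: vessel of volume V;
`dS/dt = D (S_in - S) - C(S)/V`, `D = 0.3/h`, `S_in = 0.00324` g/L;
every cell is washed out independently with probability `D dt` per step
(with `dt = 0.01` h the Poisson correction `1 - exp(-D dt)` differs by
0.15%, ignored). *Biofilm*: see below. Dead cells remain physically
present and are subject to washout only.

`mu_max = 1.2/h` in all environments (the constant environment's 0.6/h
is the *realised* Monod rate at S = K_S, not a different `mu_max`).
This matters: at `mu_max = 0.6` a chemostat at D = 0.3/h cannot sustain
an aging, repairing population at all (the required gross rate ~0.45/h
exceeds the Monod rate at the inflow concentration), whereas at 1.2 the
steady state lands at `S* = 0.0014` g/L, gross rate 0.45/h, net rate =
D, mean age 0.145 — and the calibrated `a' = 0.1/0.45 = 0.22` follows.

### Biofilm

2D domain (default 256 x 256 um) with periodic lateral boundaries, an
inert substratum at the bottom (no-flux), and a 4 um grid for the
substrate field. Cells are disks whose area derives from volume
assuming an out-of-plane slab thickness equal to the grid resolution;
`rho = 201` g/L (lower than well-mixed, for EPS). Nodes are classified
as biofilm (contain biomass), boundary layer (node-center distance to
the nearest biofilm node < `b_L` = 48 um, periodic-in-x distance
transform), or bulk (pinned at `S_bulk`). Because reaction-diffusion is
fast relative to growth, each step solves the steady state
`D_G lap(S) = u_max S/(K_S + S)` with biomass frozen (`D_G` =
6.7e-10 m^2/s = 2.412e6 um^2/h; `u_max` maps each cell's
`mu_max P_ga (1 - Z)/Y_mu` to its containing node). The Monod
nonlinearity is Picard-linearised (`u_max/(K_S + S_prev)`), each linear
system solved sparsely and directly; the converged field satisfies a
dimensionless residual `|D lap S - U(S)| h^2 / (D S_bulk) < 1e-6` and
is clipped to `[0, S_bulk]`. Warm-starting from the previous field
keeps Picard to a few iterations. Cells read the field by bilinear
interpolation at their (off-grid) positions.

Each step: classify -> solve substrate -> step all cells (dt = 0.05 h)
-> divide (new pole placed one center-to-center distance away in a
random direction) -> shove. Shoving displaces any pair closer than
`S_f (r_i + r_j)` (`S_f = 1.10`, relative tolerance 1%) symmetrically
along its center line, sequentially (Gauss-Seidel, which propagates
pressure within a sweep); the pair list comes from a KD-tree and is
refreshed every few sweeps. Per step the sweeps are capped (60) —
residual overlaps are carried into the next step, where growth is small
— while the standalone relaxation used at initialisation and in tests
runs to full convergence. Shoving changes positions only; biomass is
conserved by construction. The simulation stops when the front (max of
per-column `y + r`) reaches `h_max = 154` um, rather than modelling
detachment.

Mass lost to repair shrinks cells (volume = `P_tot/rho + V_inert`).
The "styrofoam" variant books the lost mass as inert, massless volume
(`V_inert += (1 - Y_r) r dt / rho`), so cell volume never decreases —
a device to isolate the effect of shrinking on biofilm structure.

### Metrics

`delta^2 = S_bulk D_G Y_mu / (mu_max rho b_L^2)` (units reconciled:
D_G to m^2/h, b_L to m) classifies growth regimes: 0.0069 at `S_bulk =
0.003556` g/L (intermediate), 0.0017 at 0.000889 (rough,
transport-limited). Direct evaluation of the smooth-regime
concentration 0.014222 gives 0.0274; the package reports the computed
value. Roughness `sigma_f` is the mean absolute deviation of per-column
front heights from the mean front. The active layer is the set of cells
within 5% of the maximum net growth rate. Competition fitness is read
from log10 biomass ratios; the winner of a biofilm competition is the
strategy with more biomass at the stopping height, with the ratio's
sign required to be stable over the final 20% of the run (otherwise: no
winner). The proportion test on replicate wins is the exact binomial
against 1/2, doubled smaller tail capped at 1 — the form that yields
P = 0.00195 for 10/10 and P = 0.119 for 31/50.

## Numerics

* Integration: classical fixed-step RK4 within each operator-split
  agent step (dt = 0.01 h well-mixed, 0.05 h biofilm); substrate frozen
  during the agent step, and the chemostat substrate ODE integrated
  with RK4 using start-of-step biomass. The adaptive allocation and the
  damage rate are evaluated once per step; machinery (part of the
  state) is re-evaluated at each RK4 stage.
* The population is stored as struct-of-arrays; the RK4 kernel is one
  vectorized call per step (numba-JIT-compiled when numba is
  installed, with a pure-numpy twin otherwise; a test pins the two
  paths to each other at 1e-12).
* Pools are clipped at zero after each step; clips beyond integration
  round-off (1e-6 fg) are logged. Non-finite states abort.
* A single seeded `numpy` Generator drives each run. Draw order per
  step: theta draws for dividers (in index order), then daughter
  placement angles (biofilm), then removal/washout draws, then shove
  jitter. Cells are updated synchronously: with substrate frozen they
  are mutually independent within a step, so no per-agent call order
  is needed. Full state (including the RNG state) is snapshotted at
  every output interval; a resumed run reproduces the uninterrupted
  run's summaries exactly (bitwise, in the well-mixed environments).

## Scales used for testing and headline numbers

Chemostat quantities are computed at a reduced scale chosen so the
steady-state population is a few hundred cells: vessel volume 1.5e-7 L
(~270 cells), 120 h horizon with the last 30 h averaged — several
composition time constants past convergence. The reduced biofilm
competitions use a 64 um wide domain, 32 founder cells, and a 36 um
stopping height (~9 active-layer depths at the intermediate regime);
this preserves substrate-limited fingering competition while keeping a
replicate under a minute. The full-scale presets (256 um, 154 um,
500-day horizons) are provided and used identically, just longer.

## What the reduced scales do and do not show

The reduced chemostat is statistically equivalent to the full one (the
steady state is set by rates, not vessel size; only fluctuations are
larger). The reduced biofilm preserves the full-scale *direction* of
competition outcomes (repair beats segregation under substrate-limited
growth at high founder density; segregation wins under substrate
excess) but not the full-scale win *counts* or the absolute biofilm
architecture; fronts are lower and lateral neighbourhoods smaller, so
stochastic placement matters relatively more. Fitness differences that
need hundreds of hours to resolve (e.g. fixed vs adaptive repair, which
differ only slightly) are left to full-scale runs.

## Known limitations

* 3D domains, detachment/shear, EPS as an explicit species, fluid flow,
  and evolution of strategies are out of scope; strategies are
  inherited and fixed.
* The biofilm solver treats uptake node-wise (cells assigned to their
  containing node) and reads the field bilinearly; sub-grid positioning
  of uptake is not modelled.
* Shoving is overlap-relaxation, not mechanics: no friction, adhesion,
  or torque; per-step sweeps are capped, so transient overlaps of order
  1% of the target separation persist in rapidly growing regions.
* The exact binomial proportion test assumes independent replicates
  with a fair-coin null; it is applied only to seeded replicate wins.
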