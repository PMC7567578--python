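"""Unit and property tests for single-cell growth/damage/repair kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from senesim import (
    CellState,
    KineticParams,
    StrategyParams,
    adaptive_beta,
    aging_rate,
    cell_derivatives,
    monod_rate,
    repair_flux,
    repair_machinery,
    step_cell,
)
from senesim.kinetics import _allocation, _machinery_mode, _pool_rates, _rk4_scalar


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------
class TestMonod:
    def test_half_saturation(self, kp):
        assert monod_rate(kp.K_S, kp) == pytest.approx(0.5 * kp.mu_max)

    def test_zero_substrate(self, kp):
        assert monod_rate(0.0, kp) == 0.0

    def test_direct_evaluation(self):
        kp = KineticParams(mu_max=1.2, K_S=0.00234)
        expected = 1.2 * 0.003556 / (0.00234 + 0.003556)
        assert monod_rate(0.003556, kp) == pytest.approx(expected, rel=1e-12)

    def test_monotone_and_bounded(self, kp, rng):
        S = np.sort(rng.uniform(0, 1, size=50))
        mu = monod_rate(S, kp)
        assert np.all(np.diff(mu) >= 0)
        assert np.all(mu <= kp.mu_max)

    def test_negative_rejected(self, kp):
        with pytest.raises(ValueError):
            monod_rate(-0.001, kp)


class TestAgingRate:
    def test_constant_mode_ignores_growth(self):
        sp = StrategyParams(aging_mode="constant", a=0.1)
        for mu in (0.0, 0.3, 1.2):
            assert aging_rate(mu, sp) == pytest.approx(0.1)

    def test_proportional_zero_growth(self):
        sp = StrategyParams(aging_mode="growth_proportional", a_prime=0.22)
        assert aging_rate(0.0, sp) == 0.0

    def test_proportional_product(self):
        sp = StrategyParams(aging_mode="growth_proportional", a_prime=0.22)
        assert aging_rate(0.6, sp) == pytest.approx(0.132)


class TestRepairMachinery:
    def test_no_repair(self):
        cell = CellState(P_ga=90, P_ra=10)
        assert repair_machinery(cell, StrategyParams(repair_mode="none")) == 0.0

    def test_fixed_fraction_of_active(self):
        cell = CellState(P_ga=90, P_ra=10, P_gd=50)
        sp = StrategyParams(repair_mode="fixed", beta_fixed=0.07)
        assert repair_machinery(cell, sp) == pytest.approx(7.0)

    def test_adaptive_is_repair_pool(self):
        cell = CellState(P_ga=90, P_ra=12.0)
        assert repair_machinery(cell, StrategyParams(repair_mode="adaptive")) == 12.0


class TestRepairFlux:
    @pytest.mark.parametrize("mach,dam,expected", [
        (7.0, 0.0, 0.0),
        (0.0, 50.0, 0.0),
        (3.0, 3.0, 1.5),  # symmetric case: x/2
        (7.0, 50.0, 7.0 * 50.0 / 57.0),
    ])
    def test_values(self, mach, dam, expected):
        assert repair_flux(mach, dam) == pytest.approx(expected)

    @given(st.floats(0, 1e3), st.floats(0, 1e3))
    def test_bounded_by_both_substrates(self, mach, dam):
        r = repair_flux(mach, dam)
        assert 0.0 <= r <= min(mach, dam) + 1e-12


# ---------------------------------------------------------------------------
# adaptive allocation law
# ---------------------------------------------------------------------------
def production_rate(beta, Z, Y_r, mu):
    """Independent oracle: instantaneous active-protein production per
    unit active protein for allocation fraction ``beta``."""
    beta = np.asarray(beta, dtype=float)
    d = Z / (1.0 - Z)
    denom = beta + d
    repair_return = np.where(denom > 0, Y_r * beta * d / np.where(denom > 0, denom, 1.0), 0.0)
    return (1.0 - beta) * mu * (1.0 - Z) + repair_return


class TestAdaptiveBeta:
    def test_no_damage_no_investment(self):
        assert adaptive_beta(0.0, 0.8, 0.3) == 0.0

    def test_no_growth_no_allocation(self):
        assert adaptive_beta(0.4, 0.8, 0.0) == 0.0
        assert adaptive_beta(0.4, 0.8, -0.2) == 0.0

    def test_dead_cell_max_investment(self):
        assert adaptive_beta(1.0, 0.8, 0.3) == 1.0

    def test_matches_brute_force_argmax(self, rng):
        """The closed form agrees with a dense grid search of the
        production rate for 100 random (Z, Y_r, mu) triples."""
        grid = np.linspace(0.0, 1.0, 10_001)
        for _ in range(100):
            Z = rng.uniform(0.0, 0.95)
            Y_r = rng.uniform(0.3, 1.0)
            mu = rng.uniform(0.01, 1.2)
            rates = production_rate(grid, Z, Y_r, mu)
            brute = grid[np.argmax(rates)]
            assert adaptive_beta(Z, Y_r, mu) == pytest.approx(brute, abs=2e-4)

    def test_nondecreasing_in_age(self):
        Z = np.linspace(0.0, 0.99, 200)
        b = adaptive_beta(Z, 0.8, 0.3)
        assert np.all(np.diff(b) >= -1e-12)


# ---------------------------------------------------------------------------
# pool derivatives
# ---------------------------------------------------------------------------
class TestCellDerivatives:
    def test_pure_exponential_growth(self, kp):
        """No damage, no aging, no repair: dP_ga/dt = mu(S) P_ga."""
        sp = StrategyParams(repair_mode="none", aging_mode="constant", a=0.0)
        cell = CellState(P_ga=100.0)
        d = cell_derivatives(cell, kp.K_S, sp, kp)
        assert d[0] == pytest.approx(0.5 * kp.mu_max * 100.0)
        assert d[1] == d[2] == d[3] == 0.0

    def test_dead_cell_inert(self, kp, fr):
        cell = CellState(P_ga=0.0, P_gd=100.0, P_rd=20.0)
        assert cell_derivatives(cell, 0.01, fr, kp) == (0, 0, 0, 0, 0)

    def test_mass_balance(self, kp, rng, random_cell_factory):
        """dP_tot/dt = mu(S) P_ga (1-Z) - (1-Y_r) r, to machine precision,
        for all three repair modes."""
        for mode in ("none", "fixed", "adaptive"):
            sp = StrategyParams(repair_mode=mode, aging_mode="constant", a=0.13)
            for _ in range(30):
                cell = random_cell_factory()
                S = rng.uniform(0, 0.01)
                d = cell_derivatives(cell, S, sp, kp)
                syn = monod_rate(S, kp) * cell.P_ga * (1 - cell.Z)
                r = repair_flux(repair_machinery(cell, sp), cell.P_dam)
                assert sum(d[:4]) == pytest.approx(syn - (1 - kp.Y_r) * r, rel=1e-12, abs=1e-12)

    def test_consumption_is_synthesis_over_yield(self, kp, fr, random_cell_factory):
        cell = random_cell_factory()
        d = cell_derivatives(cell, 0.002, fr, kp)
        syn = monod_rate(0.002, kp) * cell.P_ga * (1 - cell.Z)
        assert d[4] == pytest.approx(syn / kp.Y_mu, rel=1e-12)

    def test_repair_pool_only_decreases_by_aging(self, kp, random_cell_factory):
        """Repair protein is never converted back to growth protein:
        with zero aging, dP_ra/dt >= 0 in every repair mode."""
        for mode in ("none", "fixed", "adaptive"):
            sp = StrategyParams(repair_mode=mode, aging_mode="constant", a=0.0)
            for _ in range(20):
                cell = random_cell_factory()
                d = cell_derivatives(cell, 0.003, sp, kp)
                assert d[1] >= -1e-12


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------
class TestStepCell:
    def test_exponential_closed_form(self, kp):
        """Without aging or repair, P_tot(t) = P0 exp(mu(S) t) to 1e-6
        relative over 10 h at dt = 0.01."""
        sp = StrategyParams(repair_mode="none", aging_mode="constant", a=0.0)
        S = kp.K_S
        mu = monod_rate(S, kp)
        cell = CellState(P_ga=1.0)
        for _ in range(1000):
            cell, _ = step_cell(cell, S, 0.01, sp, kp)
        assert cell.P_tot == pytest.approx(np.exp(mu * 10.0), rel=1e-6)

    def test_against_fine_step_reference(self, kp, random_cell_factory):
        """One dt=0.01 step agrees with a dt/1000 reference integration
        to 1e-4 relative error."""
        sp = StrategyParams(repair_mode="adaptive", aging_mode="growth_proportional")
        cell = random_cell_factory()
        S, dt = 0.002, 0.01
        coarse, _ = step_cell(cell, S, dt, sp, kp)
        alloc = _allocation(cell, sp, kp.Y_r)
        A = aging_rate(monod_rate(S, kp), sp)
        state = (cell.P_ga, cell.P_ra, cell.P_gd, cell.P_rd)
        for _ in range(1000):
            state = _rk4_scalar(
                *state, S, dt / 1000, kp.mu_max, kp.K_S, kp.Y_mu, kp.Y_r,
                alloc, A, _machinery_mode(sp), sp.beta_fixed,
            )[:4]
        fine = np.array(state)
        got = np.array([coarse.P_ga, coarse.P_ra, coarse.P_gd, coarse.P_rd])
        np.testing.assert_allclose(got, fine, rtol=1e-4, atol=1e-10)

    def test_styrofoam_conserves_volume_without_growth(self, kp):
        """At zero substrate (no growth) repair destroys mass; with the
        styrofoam variant the lost mass becomes inert volume and the
        total cell volume is exactly conserved."""
        sp = StrategyParams(repair_mode="adaptive", styrofoam=True,
                            aging_mode="growth_proportional")
        cell = CellState(P_ga=50.0, P_ra=30.0, P_gd=100.0, P_rd=20.0)
        v0 = cell.volume(kp.rho)
        for _ in range(100):
            cell, _ = step_cell(cell, 0.0, 0.01, sp, kp)
        assert cell.P_tot < 200.0  # mass was actually lost to repair
        assert cell.volume(kp.rho) == pytest.approx(v0, rel=1e-9)

    def test_shrinking_without_styrofoam(self, kp):
        sp = StrategyParams(repair_mode="adaptive", styrofoam=False,
                            aging_mode="growth_proportional")
        cell = CellState(P_ga=50.0, P_ra=30.0, P_gd=100.0, P_rd=20.0)
        v0 = cell.volume(kp.rho)
        for _ in range(100):
            cell, _ = step_cell(cell, 0.0, 0.01, sp, kp)
        assert cell.volume(kp.rho) < v0

    def test_pools_stay_nonnegative(self, kp, random_cell_factory):
        sp = StrategyParams(repair_mode="fixed", aging_mode="constant", a=0.5)
        for _ in range(20):
            cell = random_cell_factory()
            for _ in range(50):
                cell, _ = step_cell(cell, 0.001, 0.05, sp, kp)
            assert min(cell.P_ga, cell.P_ra, cell.P_gd, cell.P_rd) >= 0.0

    def test_mass_balance_over_step(self, kp, fr, random_cell_factory):
        """Integrated form: dP_tot = integral(growth) - (1-Y_r) integral(r).
        Growth integral equals Y_mu * consumed substrate."""
        cell = random_cell_factory()
        new, consumed = step_cell(cell, 0.003, 0.01, fr, kp)
        growth = consumed * kp.Y_mu
        # the repair loss integral is recoverable from the balance
        lost = growth - (new.P_tot - cell.P_tot)
        assert lost >= -1e-9  # repair can only lose mass
        # and matches the styrofoam bookkeeping on an identical cell
        sp2 = StrategyParams(**{**fr.__dict__, "styrofoam": True})
        new2, _ = step_cell(cell, 0.003, 0.01, sp2, kp)
        assert new2.V_inert * kp.rho == pytest.approx(lost, rel=1e-9, abs=1e-12)

    def test_damage_reaches_steady_state_with_symmetric_division(self, kp, fr):
        """Under fixed parameters the age Z of a (symmetrically
        dividing) lineage converges; division does not change Z, so the
        fraction dynamics alone must converge."""
        cell = CellState(P_ga=1.0, mu_net_prev=0.3)
        sp = StrategyParams(repair_mode="fixed", aging_mode="constant", a=0.1)
        zs = []
        for i in range(20000):
            cell, _ = step_cell(cell, kp.K_S, 0.01, sp, kp)
            # renormalise total mass to avoid overflow; fractions untouched
            if cell.P_tot > 1e6:
                scale = cell.P_tot
                cell.P_ga /= scale; cell.P_ra /= scale
                cell.P_gd /= scale; cell.P_rd /= scale
            if i % 100 == 0:
                zs.append(cell.Z)
        tail = np.array(zs[-20:])
        assert tail.std() < 1e-6
        assert 0.0 < tail.mean() < 1.0

    def test_nonfinite_state_aborts(self, kp, fr):
        cell = CellState(P_ga=np.nan)
        with pytest.raises(FloatingPointError):
            step_cell(cell, 0.001, 0.01, fr, kp)


# ---------------------------------------------------------------------------
# vectorized kernel consistency
# ---------------------------------------------------------------------------
class TestKernelConsistency:
    def _random_population(self, kp, rng, n=40):
        from senesim.population import Population

        strategies = {
            "DS": StrategyParams(alpha=1.0, repair_mode="none",
                                 aging_mode="growth_proportional"),
            "FR": StrategyParams(repair_mode="fixed", aging_mode="constant"),
            "AR": StrategyParams(repair_mode="adaptive",
                                 aging_mode="growth_proportional"),
        }
        pop = Population.fresh(kp, strategies, {k: n // 3 for k in strategies}, rng)
        pop.pools = rng.uniform(1.0, 300.0, size=pop.pools.shape)
        pop.mu_net = rng.uniform(-0.1, 0.6, size=len(pop))
        return pop, strategies

    def test_population_step_matches_scalar_step(self, kp, rng):
        """The vectorized population kernel and the scalar single-cell
        integrator produce the same pools for the same cells."""
        pop, strategies = self._random_population(kp, rng)
        cells = pop.cells()
        S, dt = 0.002, 0.01
        pop.step(S, dt)
        for i, cell in enumerate(cells):
            sp = strategies[cell.strategy_id]
            ref, _ = step_cell(cell, S, dt, sp, kp)
            got = pop.pools[i]
            np.testing.assert_allclose(
                got, [ref.P_ga, ref.P_ra, ref.P_gd, ref.P_rd],
                rtol=1e-9, atol=1e-9,
            )
            assert pop.mu_net[i] == pytest.approx(ref.mu_net_prev, abs=1e-9)

    def test_numba_and_numpy_paths_agree(self, kp, rng):
        from senesim import _kernel

        if not _kernel.HAVE_NUMBA:
            pytest.skip("numba not installed; only one kernel path exists")
        pop, _ = self._random_population(kp, rng, n=30)
        pools1 = pop.pools.copy()
        pools2 = pop.pools.copy()
        n = len(pop)
        args = (
            np.full(n, 0.002), 0.01, kp.mu_max, kp.K_S, kp.Y_mu, kp.Y_r,
            rng.uniform(0, 0.3, n), rng.uniform(0, 0.2, n),
            rng.integers(0, 3, n), np.full(n, 0.07),
        )
        c1, l1 = np.empty(n), np.empty(n)
        c2, l2 = np.empty(n), np.empty(n)
        _kernel._rk4_compiled(pools1, *args, c1, l1)
        _kernel._rk4_numpy(pools2, *args, c2, l2)
        np.testing.assert_allclose(pools1, pools2, rtol=1e-12, atol=1e-12)
        np.testing.assert_allclose(c1, c2, rtol=1e-12, atol=1e-15)
        np.testing.assert_allclose(l1, l2, rtol=1e-12, atol=1e-15)
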