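"""SSA, step-size selection and the synchronised tau-leap."""

import numpy as np
import pytest

from nichesim import (
    HSCSystem,
    LeapControl,
    NicheGrouping,
    PerturbationSpec,
    UnsupportedConfigurationError,
    immigration_death,
    leap_step,
    make_grid,
    pure_death,
    select_tau,
    simulate,
    simulate_ssa,
    ssa_step,
)


class TestSelectTau:
    # single-species decay: stoich (-1), propensity rate*x
    decay_stoich = np.array([[-1]], dtype=np.int64)

    def test_hand_example_large_population(self):
        # x=100, rate 1, eps=0.03: bound max(3,1)=3; mu=-100, sig2=100
        tau = select_tau(np.array([100.0]), np.array([100.0]), self.decay_stoich, 0.03)
        assert tau == pytest.approx(min(3 / 100, 9 / 100)) == pytest.approx(0.03)

    def test_hand_example_floor_engages(self):
        # x=10: bound max(0.3,1)=1; tau = min(1/10, 1/10)
        tau = select_tau(np.array([10.0]), np.array([10.0]), self.decay_stoich, 0.03)
        assert tau == pytest.approx(0.1)

    def test_homogeneity(self, table):
        props = np.linspace(0.1, 1.4, 14)
        counts = np.array([5, 100, 20, 20, 70, 250])
        t1 = select_tau(props, counts, table.stoich, 0.03)
        t2 = select_tau(2 * props, counts, table.stoich, 0.03)
        assert t2 == pytest.approx(t1 / 2)

    def test_all_zero_propensities_sentinel(self, table):
        assert np.isinf(select_tau(np.zeros(14), np.zeros(6), table.stoich, 0.03))


class TestSSAStep:
    def test_single_channel_always_chosen(self, single_lineage_system, rng):
        state = np.array([0, 0, 0, 0, 0, 100])
        dt, j, new = ssa_step(single_lineage_system, state, rng)
        assert j == 13  # only myeloid death is possible
        assert new[5] == 99 and dt > 0

    def test_absorbing_state(self, single_lineage_system, rng):
        state = np.zeros(6, dtype=np.int64)
        dt, j, new = ssa_step(single_lineage_system, state, rng)
        assert np.isinf(dt) and j is None

    def test_frozen_state_statistics(self, single_lineage_system, rng):
        """Waiting times and channel choices match the propensity vector.

        At a frozen state, waiting times are Exp(a0) and channel j is
        chosen with probability a_j/a0; checked over many draws against
        3-sigma multinomial/exponential error.
        """
        state = np.array([5, 40, 8, 10, 30, 60])
        a = single_lineage_system.propensities(state.reshape(-1, 1))[:, 0]
        a0 = a.sum()
        n = 100_000
        waits = np.empty(n)
        picks = np.zeros(14, dtype=int)
        for i in range(n):
            dt, j, _ = ssa_step(single_lineage_system, state, rng)
            waits[i] = dt
            picks[j] += 1
        assert abs(waits.mean() - 1 / a0) < 3 / (a0 * np.sqrt(n))
        p = a / a0
        sel = p > 0
        sigma = np.sqrt(p[sel] * (1 - p[sel]) / n)
        assert np.all(np.abs(picks[sel] / n - p[sel]) < 3 * sigma + 1e-12)


class TestSimulateSSA:
    def test_immigration_death_stationary_mean(self):
        fx = immigration_death(5.0, 0.1)  # stationary Poisson with mean 50
        omega = 300
        res = simulate_ssa(fx, np.zeros((1, omega), dtype=np.int64), make_grid(80, 40), seed=7)
        final = res.counts[-1, 0, :]
        target = fx.stationary_mean * (1 - np.exp(-0.1 * 80))
        se = np.sqrt(fx.stationary_variance / omega)
        assert abs(final.mean() - target) < 3 * se

    def test_absorbing_initial_state_constant(self):
        fx = pure_death(0.5)
        res = simulate_ssa(fx, np.zeros((1, 10), dtype=np.int64), make_grid(10, 2), seed=0)
        assert np.all(res.counts == 0)

    def test_determinism_under_equal_seeds(self, params):
        system = HSCSystem(params, NicheGrouping(5, 1))
        initial = system.founding_state()
        grid = make_grid(50, 10)
        r1 = simulate_ssa(system, initial, grid, seed=42)
        r2 = simulate_ssa(system, initial, grid, seed=42)
        assert np.array_equal(r1.counts, r2.counts)

    def test_refuses_coupled_groups(self, params):
        system = HSCSystem(params, NicheGrouping(4, 2))
        with pytest.raises(UnsupportedConfigurationError, match="uncoupled"):
            simulate_ssa(system, system.founding_state(), make_grid(10, 5), seed=0)


class TestLeapStep:
    def test_absorbing_metapopulation(self, rng):
        fx = pure_death(1.0)
        counts = np.zeros((1, 50), dtype=np.int64)
        new, tau, halvings = leap_step(fx, counts, LeapControl(), rng)
        assert np.isinf(tau) and np.array_equal(new, counts) and halvings == 0

    def test_bottleneck_lineage_sets_tau(self, rng):
        # one lineage with tenfold propensity dominates the a0 ranking
        fx = pure_death(1.0)
        counts = np.full((1, 8), 100, dtype=np.int64)
        counts[0, 3] = 1000
        control = LeapControl(epsilon=0.03)
        _, tau, _ = leap_step(fx, counts, control, rng)
        expected = select_tau(
            fx.propensities(counts)[:, 3], counts[:, 3], fx.stoich, 0.03
        )
        assert tau == pytest.approx(expected)

    def test_pure_death_ensemble_decay(self):
        """Tau-leap ensemble mean follows x0*exp(-c t) within 3 SE.

        The leap's O(epsilon) discretisation bias must sit well below
        the Monte-Carlo error for the closed form to be a fair oracle,
        hence the small epsilon here.
        """
        fx = pure_death(0.05)
        omega, x0, t = 1000, 200, 30.0
        res = simulate(
            fx,
            np.full((1, omega), x0, dtype=np.int64),
            make_grid(t, t / 2),
            seed=3,
            control=LeapControl(epsilon=0.003),
            record_signals=False,
        )
        final = res.counts[-1, 0, :]
        expected = fx.mean(t, x0)
        # binomial survival: var = x0 * s * (1-s)
        s = np.exp(-0.05 * t)
        se = np.sqrt(x0 * s * (1 - s) / omega)
        assert abs(final.mean() - expected) < 3 * se
        assert res.counts.min() >= 0

    def test_negativity_redo_keeps_counts_non_negative(self):
        # tiny populations with fast death force frequent redo candidates
        fx = pure_death(2.0)
        res = simulate(
            fx,
            np.full((1, 400), 3, dtype=np.int64),
            make_grid(4.0, 0.5),
            seed=9,
            control=LeapControl(epsilon=0.3),
            record_signals=False,
        )
        assert res.counts.min() >= 0


class TestSimulate:
    def test_grid_with_single_time_returns_initial(self, params):
        system = HSCSystem(params, NicheGrouping(3, 1))
        initial = system.founding_state()
        res = simulate(system, initial, np.array([0.0]), seed=1)
        assert np.array_equal(res.counts[0], initial)

    def test_determinism_under_equal_seeds(self, params):
        system = HSCSystem(params, NicheGrouping(10, 1))
        grid = make_grid(100, 20)
        runs = [
            simulate(system, system.founding_state(), grid, seed=5) for _ in range(2)
        ]
        assert np.array_equal(runs[0].counts, runs[1].counts)
        assert np.array_equal(runs[0].signals, runs[1].signals)

    def test_perturbation_applied_exactly_at_record_time(self, params):
        system = HSCSystem(params, NicheGrouping(20, 1))
        spec = PerturbationSpec(kind="even", time=150.0, even_fraction=0.375)
        grid = make_grid(200, 50)  # includes t = 150
        res = simulate(
            system, system.founding_state(), grid, seed=8, perturbations=[spec]
        )
        report = res.removals[0]
        recorded_M = res.at(150.0)[5]
        # recorded state reflects the removal: adding the per-lineage
        # removals back recovers the pre-removal total
        assert (recorded_M + report.removed).sum() == report.total_before
        assert recorded_M.sum() == report.total_before - report.total_removed
        assert report.total_removed > 0

    def test_carrying_capacity_never_exceeded(self, params):
        system = HSCSystem(params, NicheGrouping(30, 1))
        res = simulate(system, system.founding_state(), make_grid(300, 10), seed=2)
        assert res.counts[:, 0, :].max() <= params.K

    def test_coupled_run_records_group_shared_signals(self, params):
        system = HSCSystem(params, NicheGrouping(20, 10))
        res = simulate(system, system.founding_state(), make_grid(200, 40), seed=3)
        sig = res.signals[-1]  # (4, omega)
        assert np.all(sig.reshape(4, 2, 10) == sig.reshape(4, 2, 10)[:, :, :1])

    def test_tidy_dataframe_schema(self, params):
        system = HSCSystem(params, NicheGrouping(4, 2))
        res = simulate(system, system.founding_state(), make_grid(20, 10), seed=0)
        df = res.to_dataframe()
        assert list(df.columns) == [
            "time", "lineage", "group",
            "S", "MPP", "CLP", "CMP", "L", "M",
            "h1", "h2", "h3", "p",
        ]
        assert len(df) == res.times.size * 4
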