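"""Poisson population simulator and the empirical energy ledger."""

import math

import numpy as np
import pytest

from sparsenergy import (
    ATPBudget,
    NetworkConfig,
    SpikingSimConfig,
    calibrate_r,
    empirical_energy,
    empirical_r,
    simulate_population,
    sweep_sparseness,
)
from sparsenergy.spiking import expected_population


def _cfg(budget, N=100, A=30, duration=100.0, seed=0):
    return SpikingSimConfig(NetworkConfig(N, A), budget, duration=duration, seed=seed)


class TestSimulator:
    def test_same_seed_bitwise_identical(self, budget_3hz):
        a = simulate_population(_cfg(budget_3hz, seed=42)).spike_counts
        b = simulate_population(_cfg(budget_3hz, seed=42)).spike_counts
        assert np.array_equal(a, b)
        c = simulate_population(_cfg(budget_3hz, seed=43)).spike_counts
        assert not np.array_equal(a, c)

    def test_silent_population(self, budget_3hz):
        pop = simulate_population(_cfg(budget_3hz, A=0))
        assert not pop.spike_counts.any()

    def test_inactive_neurons_never_fire(self, budget_3hz):
        pop = simulate_population(_cfg(budget_3hz, N=50, A=20, seed=7))
        assert not pop.spike_counts[20:].any()

    def test_total_count_within_poisson_bounds(self, budget_3hz):
        """Total spikes ~ Poisson(A * rate * T): stay within 5 sigma of the mean."""
        pop = simulate_population(_cfg(budget_3hz, N=100, A=30, duration=1000.0, seed=3))
        mean = 30 * 3.0 * 1000.0
        assert abs(pop.spike_counts.sum() - mean) < 5 * math.sqrt(mean)


class TestEmpiricalEnergy:
    def test_noise_free_single_neuron_matches_analytic_total(self, budget_3hz):
        pop = expected_population(_cfg(budget_3hz, N=1, A=1, duration=1.0))
        total, bd = empirical_energy(pop)
        assert total == pytest.approx(34.98e8)
        assert tuple(round(100 * f) for f in bd.fractions) == (10, 29, 33, 28)

    def test_zero_spikes_leaves_fixed_costs(self, budget_3hz):
        pop = simulate_population(_cfg(budget_3hz, N=10, A=0))
        total, bd = empirical_energy(pop)
        assert total == pytest.approx(10 * 13.62e8)
        assert bd.frac_signaling == 0.0

    def test_ledger_conservation(self, budget_3hz):
        pop = simulate_population(_cfg(budget_3hz, seed=11))
        total, bd = empirical_energy(pop)
        assert sum(bd.absolute()) == pytest.approx(total, rel=1e-12)

    def test_monte_carlo_mean_within_three_standard_errors(self, budget_3hz):
        """Replicate means converge to the analytic rate at the Poisson rate."""
        n_reps, duration = 200, 100.0
        cfgs = [_cfg(budget_3hz, N=1, A=1, duration=duration, seed=s) for s in range(n_reps)]
        totals = [empirical_energy(simulate_population(c))[0] for c in cfgs]
        analytic = 34.98e8
        per_spike = budget_3hz.e_spike_gen + budget_3hz.e_propagation
        var_one = 3.0 * duration * per_spike**2 / duration**2
        se = math.sqrt(var_one / n_reps)
        assert abs(np.mean(totals) - analytic) < 3 * se


class TestEmpiricalRatio:
    def test_undefined_without_active_neurons(self, budget_3hz):
        pop = simulate_population(_cfg(budget_3hz, A=0))
        with pytest.raises(ValueError):
            empirical_r(pop)

    def test_noise_free_recovers_exact_ratio(self, budget_3hz):
        pop = expected_population(_cfg(budget_3hz, N=4, A=2, duration=10.0))
        assert empirical_r(pop) == pytest.approx(calibrate_r(budget_3hz).r, rel=1e-12)

    def test_long_duration_convergence(self, budget_3hz):
        pop = simulate_population(_cfg(budget_3hz, N=10, A=10, duration=1e5, seed=5))
        assert empirical_r(pop) == pytest.approx(1.57, rel=0.01)

    def test_error_shrinks_with_duration(self, budget_3hz):
        """Estimator spread scales ~ 1/sqrt(duration) over a x100 ladder."""
        def spread(duration):
            estimates = [
                empirical_r(simulate_population(_cfg(budget_3hz, N=5, A=5, duration=duration, seed=s)))
                for s in range(40)
            ]
            return np.std(estimates)

        short, long = spread(100.0), spread(10000.0)
        # expected shrink factor 10; allow generous Monte-Carlo slack
        assert long < short / 5


class TestSparsenessSweep:
    P_GRID = [round(0.05 * k, 2) for k in range(1, 11)]

    def test_noise_free_costs_equal_analytic(self, budget_3hz):
        df = sweep_sparseness(
            100, self.P_GRID, budget_3hz, duration=100.0, n_replicates=1, noise_free=True
        )
        r = calibrate_r(budget_3hz).r
        for _, row in df.iterrows():
            assert row["cost_fc_units"] == pytest.approx(
                100 * (1 + r * row["A"] / 100), rel=1e-12
            )

    def test_empirical_optimum_in_expected_band(self, budget_3hz):
        df = sweep_sparseness(
            100, self.P_GRID, budget_3hz, duration=200.0, n_replicates=10, seed=1
        )
        best_p = df.loc[df["cap_per_cost"].idxmax(), "p"]
        assert 0.25 <= best_p <= 0.45

    def test_deterministic_given_seed(self, budget_3hz):
        kwargs = dict(duration=50.0, n_replicates=3, seed=9)
        a = sweep_sparseness(50, [0.1, 0.3], budget_3hz, **kwargs)
        b = sweep_sparseness(50, [0.1, 0.3], budget_3hz, **kwargs)
        assert a.equals(b)

    def test_lower_ratio_raises_optimal_sparseness(self, budget_3hz):
        """Doubling resting rates halves r and shifts the argmax upward."""
        heavier_fixed = ATPBudget(
            budget_3hz.e_spike_gen,
            budget_3hz.e_propagation,
            2 * budget_3hz.e_rest_neuron,
            2 * budget_3hz.e_rest_glia,
            budget_3hz.glia_per_neuron,
            budget_3hz.firing_rate,
        )
        grid = [round(0.02 * k, 2) for k in range(1, 26)]
        base = sweep_sparseness(100, grid, budget_3hz, n_replicates=1, noise_free=True)
        heavy = sweep_sparseness(100, grid, heavier_fixed, n_replicates=1, noise_free=True)
        p_base = base.loc[base["cap_per_cost"].idxmax(), "p"]
        p_heavy = heavy.loc[heavy["cap_per_cost"].idxmax(), "p"]
        assert p_heavy > p_base
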