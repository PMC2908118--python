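"""Stochastic simulation: reproducibility, symmetry, occupancy, comparisons."""

import numpy as np
import pytest

from metapatch import (
    MetapopState,
    compare_groups,
    host_correlation,
    logistic_sim,
    nb_equilibrium,
    simulate,
    threshold_stats,
)
from metapatch.simulate import noise_draws
from reference_impls import reference_simulate


class TestSimulate:
    def test_same_seed_bitwise_identical(self, study_params, pair):
        a = simulate(study_params.replace(dH=0.1, dP=0.3), pair, n_steps=50,
                     burn_in=10, n_reps=3, seed=42)
        b = simulate(study_params.replace(dH=0.1, dP=0.3), pair, n_steps=50,
                     burn_in=10, n_reps=3, seed=42)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.H, rb.H)
            assert np.array_equal(ra.P, rb.P)

    def test_matches_naive_reference_bitwise(self, study_params, pair, square4):
        params = study_params.replace(dH=0.05, dP=0.4)
        for topo in (pair, square4):
            init = MetapopState(H=np.full(topo.n_patches, 100.0),
                                P=np.full(topo.n_patches, 100.0))
            runs = simulate(params, topo, n_steps=10, burn_in=0, n_reps=2, seed=7,
                            init=init)
            for rep, run in enumerate(runs):
                ref_H, ref_P = reference_simulate(params, topo, 10, init.H, init.P, 7, rep)
                assert np.array_equal(run.H, ref_H)
                assert np.array_equal(run.P, ref_P)

    def test_noise_free_symmetry_and_convergence(self, study_params, pair):
        """With sigma = 0 and symmetric initial conditions all patches stay
        identical and the trajectory damps onto the equilibrium by t = 500."""
        params = study_params.replace(sigma=0.0, dH=0.2, dP=0.2)
        (run,) = simulate(params, pair, n_steps=1000, burn_in=500, n_reps=1, seed=0)
        assert np.array_equal(run.H[:, 0], run.H[:, 1])
        assert np.array_equal(run.P[:, 0], run.P[:, 1])
        h_star, p_star = nb_equilibrium(params)
        assert abs(run.H[499, 0] - h_star) / h_star < 1e-3
        assert abs(run.P[499, 0] - p_star) / p_star < 1e-3

    def test_replicates_differ(self, study_params, pair):
        runs = simulate(study_params, pair, n_steps=20, burn_in=0, n_reps=2, seed=3)
        assert not np.array_equal(runs[0].H, runs[1].H)

    def test_noise_multipliers_mean_one(self):
        rng = np.random.default_rng(1)
        eps = noise_draws(rng, 0.4, 10**5)
        se = eps.std() / np.sqrt(eps.size)
        assert abs(eps.mean() - 1.0) < 3 * se


class TestHostCorrelation:
    def test_perfect_copy(self, study_params, pair):
        (run,) = simulate(study_params, pair, n_steps=100, burn_in=50, seed=5)
        run.H[:, 1] = run.H[:, 0]
        assert host_correlation(run) == pytest.approx(1.0)

    def test_constant_series_flagged(self, study_params, pair):
        (run,) = simulate(study_params.replace(sigma=0.0), pair, n_steps=600,
                          burn_in=500, seed=5)
        run.H[:, 0] = 7.0
        with pytest.warns(RuntimeWarning):
            assert np.isnan(host_correlation(run))

    def test_independent_patches_uncorrelated(self, study_params, pair):
        """No dispersal, noisy patches: mean correlation across replicates is
        within two standard errors of zero."""
        runs = simulate(study_params.replace(dH=0.0, dP=0.0), pair,
                        n_steps=1000, burn_in=500, n_reps=100, seed=11)
        corrs = np.array([host_correlation(r) for r in runs])
        se = corrs.std(ddof=1) / np.sqrt(len(corrs))
        assert abs(corrs.mean()) < 2 * se


class TestThresholdStats:
    def test_deterministic_equilibrium_never_crosses(self, study_params, pair):
        runs = simulate(study_params.replace(sigma=0.0), pair, n_steps=1000,
                        burn_in=500, seed=0)
        h_star, _ = nb_equilibrium(study_params)
        stats, summary = threshold_stats(runs, h_star / 10)
        assert stats[0].single_patch_events == 0
        assert stats[0].regional_event_time is None
        assert summary["prop_regional_events"] == 0.0

    def test_threshold_above_everything_forces_event(self, study_params, pair):
        runs = simulate(study_params, pair, n_steps=100, burn_in=50, seed=0)
        big = runs[0].H.max() * 2
        stats, _ = threshold_stats(runs, big)
        # regional event at the first retained step
        assert stats[0].regional_event_time == runs[0].burn_in + 1
        assert stats[0].persistence_time == 1

    def test_event_time_monotone_in_threshold(self, study_params, pair):
        """A larger threshold can only produce an earlier (or equal) regional
        event for a fixed trajectory."""
        runs = simulate(study_params.replace(sigma=0.5, dH=0.01, dP=0.1), pair,
                        n_steps=1000, burn_in=500, n_reps=5, seed=21)
        h_star, _ = nb_equilibrium(study_params)
        prev = None
        for frac in (2.0, 1.0, 0.75, 0.5, 0.25):
            stats, _ = threshold_stats(runs, h_star * frac)
            times = np.array([
                s.regional_event_time if s.regional_event_time is not None else np.inf
                for s in stats
            ])
            if prev is not None:
                assert np.all(times >= prev)
            prev = times


class TestLogistic:
    def test_carrying_capacity_fixed_point(self, pair):
        runs = logistic_sim(r_growth=1.0, K=30.0, sigma=0.0, dH=0.1, topology=pair,
                            n_steps=50, burn_in=0, seed=0)
        assert np.allclose(runs[0].H, 30.0)

    def test_monotone_approach_small_r(self, pair):
        runs = logistic_sim(r_growth=0.1, K=20.0, sigma=0.0, dH=0.0, topology=pair,
                            n_steps=200, burn_in=0, seed=0,
                            init_H=np.array([10.0, 10.0]))
        h = runs[0].H[:, 0]
        assert np.all(np.diff(h) > 0)
        assert h[-1] == pytest.approx(20.0, rel=1e-3)

    def test_default_K_is_host_equilibrium(self, study_params, pair):
        runs = logistic_sim(sigma=0.0, dH=0.0, topology=pair, n_steps=10,
                            burn_in=0, seed=0, nb_params_for_K=study_params)
        h_star, _ = nb_equilibrium(study_params)
        assert np.allclose(runs[0].H, h_star)


class TestCompareGroups:
    def test_identical_groups_zero(self):
        est, se = compare_groups([3, 4, 5], [3, 4, 5])
        assert est == pytest.approx(0.0)

    def test_doubling_gives_log_two(self):
        b = np.array([2.0, 5.0, 9.0])
        est, _ = compare_groups(2 * b, b)
        assert est == pytest.approx(np.log(2), rel=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(20, 50).astype(float)
        b = rng.poisson(10, 50).astype(float)
        est_ab, se_ab = compare_groups(a, b)
        est_ba, se_ba = compare_groups(b, a)
        assert est_ab == pytest.approx(-est_ba)
        assert se_ab == pytest.approx(se_ba)

    def test_zero_mean_flagged(self):
        with pytest.warns(RuntimeWarning):
            est, se = compare_groups([1.0, 2.0], [0.0, 0.0])
        assert np.isnan(est)
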