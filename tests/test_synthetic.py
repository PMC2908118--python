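"""Synthetic microcosm generators: reproducibility, truth, statistical structure."""

import numpy as np
import pytest

from metapatch import (
    ExperimentConfig,
    GeneratorTruth,
    NBParams,
    RickerTruth,
    generate_from_ricker,
    generate_mechanistic,
    series_to_frame,
)
from metapatch.synthetic import HOST_ALT, HOST_MAIN, PARASITOID, draw_weekly_beans


class TestExperimentConfig:
    def test_treatment_to_mean_mapping(self):
        # 'a'/'b': three beans for every host; 'c'/'d': 4:2 favouring the
        # inferior competitor (C. chinensis)
        ac = ExperimentConfig(assemblage="apparent_competition", treatment="c")
        assert ac.renewal_means == {HOST_MAIN: 2.0, HOST_ALT: 4.0}
        two = ExperimentConfig(assemblage="two_species", treatment="b")
        assert two.renewal_means == {HOST_MAIN: 3.0}
        assert two.stochastic_renewal

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig(treatment="x")
        with pytest.raises(ValueError):
            ExperimentConfig(assemblage="three_species")


class TestBeans:
    def test_poisson_moments(self):
        """Stochastic renewal delivers Poisson bean counts: over 10^4 weeks the
        sample mean and variance are both within 3 SE of the mean of 3."""
        rng = np.random.default_rng(0)
        beans = draw_weekly_beans(rng, 3.0, True, 10_000)
        se_mean = np.sqrt(3.0 / beans.size)
        assert abs(beans.mean() - 3.0) < 3 * se_mean
        # var of sample variance of Poisson(3): (mu + 2 mu^2) / n
        se_var = np.sqrt((3.0 + 2 * 9.0) / beans.size)
        assert abs(beans.var(ddof=1) - 3.0) < 3 * se_var

    def test_constant_renewal(self):
        rng = np.random.default_rng(0)
        assert (draw_weekly_beans(rng, 3.0, False, 100) == 3.0).all()


class TestMechanistic:
    def test_reproducible_byte_identical(self, tmp_path):
        cfg = ExperimentConfig(treatment="b", n_weeks=30, seed=9)
        from metapatch import write_series

        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_series(generate_mechanistic(cfg)[0], p1)
        write_series(generate_mechanistic(cfg)[0], p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_noise_free_symmetric_deterministic(self):
        cfg = ExperimentConfig(
            treatment="a", n_weeks=20, seed=0, demographic_noise=False,
            params=NBParams(sigma=0.0, dH=0.05, dP=0.3),
        )
        series, _ = generate_mechanistic(cfg)
        host = [s for s in series if s.species == HOST_MAIN and s.replicate == "rep1"]
        base = host[0].counts
        assert np.allclose(base, np.rint(base))  # integer counts
        for s in host[1:]:
            assert np.array_equal(s.counts, base)  # identical patches

    def test_apparent_competition_species_set(self):
        cfg = ExperimentConfig(assemblage="apparent_competition", treatment="d",
                               n_weeks=15, seed=1)
        series, truth = generate_mechanistic(cfg)
        assert {s.species for s in series} == {HOST_MAIN, HOST_ALT, PARASITOID}
        assert truth.params["assemblage"] == "apparent_competition"

    def test_truth_serialization_roundtrip(self):
        cfg = ExperimentConfig(n_weeks=10, seed=2)
        _, truth = generate_mechanistic(cfg)
        back = GeneratorTruth.from_json(truth.to_json())
        assert back.kind == "mechanistic"
        assert back.params == truth.params


class TestRickerGenerator:
    def test_fixed_point_solver(self):
        truth = RickerTruth(alpha=0.5, betas=(-0.5,), lags=(1.0,), thetas=(1.0,),
                            rho=0.0, sigma_replicate=0.0, sigma_patch=0.0,
                            sigma_error=0.05)
        n_star = truth.fixed_point()
        # alpha + beta * (N - 1) = 0  =>  N = 1 + alpha/|beta|
        assert n_star == pytest.approx(2.0, rel=1e-8)

    def test_series_fluctuate_about_fixed_point(self):
        truth = RickerTruth(alpha=0.5, betas=(-0.5,), lags=(1.0,), thetas=(1.0,),
                            rho=0.0, sigma_replicate=0.0, sigma_patch=0.0,
                            sigma_error=0.05)
        series, _ = generate_from_ricker(truth, 1, 4, 200, seed=3, round_counts=False)
        for s in series:
            assert s.counts[50:].mean() == pytest.approx(truth.fixed_point(), rel=0.1)

    def test_explosive_parameters_rejected(self):
        bad = RickerTruth(alpha=0.5, betas=(-3.0,), lags=(1.0,), thetas=(0.0,),
                          rho=0.0, sigma_replicate=0.0, sigma_patch=0.0,
                          sigma_error=0.1)
        with pytest.raises(ValueError, match="explosive"):
            generate_from_ricker(bad, 1, 4, 20, seed=0)

    def test_invalid_rho_rejected(self):
        bad = RickerTruth(alpha=0.5, betas=(-0.02,), lags=(1.0,), thetas=(1.0,),
                          rho=-0.5, sigma_replicate=0.0, sigma_patch=0.0,
                          sigma_error=0.1)
        with pytest.raises(ValueError, match="rho"):
            generate_from_ricker(bad, 1, 4, 20, seed=0)

    @staticmethod
    def _pairwise_residual_corr(truth, seed, n_weeks=200):
        series, _ = generate_from_ricker(truth, 1, 4, n_weeks, seed=seed,
                                         round_counts=False)
        # growth-rate residual structure shows up in log first differences
        logs = np.column_stack([np.diff(np.log(s.counts)) for s in series])
        c = np.corrcoef(logs.T)
        iu = np.triu_indices(4, k=1)
        return c[iu]

    def test_zero_rho_gives_uncorrelated_patches(self):
        truth = RickerTruth(alpha=0.5, betas=(-0.02,), lags=(1.0,), thetas=(1.0,),
                            rho=0.0, sigma_replicate=0.0, sigma_patch=0.0,
                            sigma_error=0.2)
        corr = np.concatenate(
            [self._pairwise_residual_corr(truth, seed) for seed in range(5)]
        )
        assert np.abs(corr).mean() < 0.1

    def test_negative_rho_recovered_in_residuals(self):
        """Monte-Carlo check of the exchangeable sampler: generated pairwise
        correlations average near the requested rho = -0.3."""
        truth = RickerTruth(alpha=0.5, betas=(-0.02,), lags=(1.0,), thetas=(1.0,),
                            rho=-0.3, sigma_replicate=0.0, sigma_patch=0.0,
                            sigma_error=0.2)
        corr = np.concatenate(
            [self._pairwise_residual_corr(truth, seed) for seed in range(10)]
        )
        assert corr.mean() == pytest.approx(-0.3, abs=0.05)

    def test_exchangeable_cholesky_valid_for_admissible_rho(self):
        from metapatch.synthetic import _exchangeable_chol

        for rho in np.linspace(-1 / 3 + 1e-6, 0.999, 25):
            chol = _exchangeable_chol(4, rho)
            assert np.all(np.isfinite(chol))

    def test_long_format_roundtrip(self, tmp_path):
        from metapatch import read_series, write_series

        truth = RickerTruth(alpha=0.5, betas=(-0.02,), lags=(1.0,), thetas=(1.0,),
                            rho=-0.06, sigma_replicate=0.0, sigma_patch=0.05,
                            sigma_error=0.2)
        series, _ = generate_from_ricker(truth, 2, 4, 25, seed=4)
        path = tmp_path / "series.csv"
        write_series(series, path)
        back = read_series(path)
        assert series_to_frame(back).equals(series_to_frame(series))
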