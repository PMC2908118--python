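"""Hierarchical ML fit: likelihood oracle, OLS reduction, selection machinery."""

import numpy as np
import pandas as pd
import pytest

from metapatch import (
    LagSpec,
    LaggedRickerModel,
    RickerTruth,
    aic_weights,
    build_dataset,
    evidence_ratio,
    fit_hierarchical,
    generate_from_ricker,
    select_lag_model,
)
from metapatch.hierarchical import default_candidate_lag_sets
from metapatch.ricker import RegressionDataset
from reference_impls import brute_force_loglike


def toy_dataset(n_weeks=12, n_patches=2, n_reps=1, seed=0) -> RegressionDataset:
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(n_reps):
        for i in range(n_patches):
            for t in range(n_weeks):
                rows.append(
                    {
                        "replicate": f"rep{j}",
                        "patch": f"patch{i}",
                        "week": float(t),
                        "response": rng.normal(),
                        "lag_1": rng.uniform(1, 3),
                    }
                )
    return RegressionDataset(table=pd.DataFrame(rows), lag_spec=LagSpec((1.0,), (1.0,)))


class TestLikelihood:
    @pytest.mark.parametrize("rho", [0.0, -0.3, 0.4])
    def test_matches_brute_force_mvn(self, rho):
        """Model log-likelihood equals a brute-force multivariate-normal
        evaluation on a 2-patch single-replicate toy within 1e-8."""
        ds = toy_dataset()
        m = LaggedRickerModel(ds)
        beta = np.array([0.3, -0.05])
        ours = m.loglike(beta, 0.1, 0.2, rho, 0.8)
        ref = brute_force_loglike(ds.table, beta, 0.1, 0.2, rho, 0.8)
        assert ours == pytest.approx(ref, abs=1e-8)

    def test_ragged_block_matches_brute_force(self):
        # drop a few rows so the fast eigenbasis path cannot be used
        ds = toy_dataset()
        ds.table = ds.table.drop(index=[3, 17]).reset_index(drop=True)
        m = LaggedRickerModel(ds)
        beta = np.array([0.1, 0.02])
        ours = m.loglike(beta, 0.15, 0.1, -0.25, 0.5)
        ref = brute_force_loglike(ds.table, beta, 0.15, 0.1, -0.25, 0.5)
        assert ours == pytest.approx(ref, abs=1e-8)


class TestFit:
    def test_reduces_to_ols_when_held_iid(self):
        """Holding both random intercepts at zero and rho at zero, the GLS
        fixed effects coincide with ordinary least squares."""
        ds = toy_dataset(seed=5)
        m = LaggedRickerModel(ds)
        res = m.fit(hold={"sigma_replicate": 0.0, "sigma_patch": 0.0, "rho": 0.0})
        X = m.exog
        ols = np.linalg.lstsq(X, m.endog, rcond=None)[0]
        assert np.allclose(res.fe_params.to_numpy(), ols, atol=1e-6)

    def test_rho_respects_exchangeable_bound(self):
        """Fitted rho stays above -1/(n_patches - 1) even when the generating
        patches are strongly negatively coupled."""
        truth = RickerTruth(alpha=0.5, betas=(-0.02,), lags=(1.0,), thetas=(1.0,),
                            rho=-0.3, sigma_replicate=0.0, sigma_patch=0.0,
                            sigma_error=0.2)
        series, _ = generate_from_ricker(truth, 2, 4, 40, seed=1)
        ds = build_dataset(series, LagSpec((1.0,), (1.0,)))
        res = fit_hierarchical(ds)
        assert res.rho >= -1.0 / 3.0

    def test_single_patch_rho_unidentifiable(self, series_factory):
        rng = np.random.default_rng(0)
        series = [series_factory(rng.integers(5, 40, 30))]
        ds = build_dataset(series, LagSpec((1.0,), (1.0,)))
        with pytest.raises(ValueError, match="not identifiable"):
            fit_hierarchical(ds)

    def test_parameter_recovery_single_seed(self):
        truth = RickerTruth(alpha=0.5, betas=(-0.02,), lags=(1.0,), thetas=(1.0,),
                            rho=-0.06, sigma_replicate=0.0, sigma_patch=0.0,
                            sigma_error=0.2)
        series, _ = generate_from_ricker(truth, 4, 4, 60, seed=11)
        ds = build_dataset(series, LagSpec((1.0,), (1.0,)))
        res = fit_hierarchical(ds)
        ci = res.conf_int()
        assert ci.loc["intercept", "lower"] <= truth.alpha <= ci.loc["intercept", "upper"]
        assert ci.loc["lag_1", "lower"] <= truth.betas[0] <= ci.loc["lag_1", "upper"]
        assert res.sigma_error == pytest.approx(0.2, abs=0.03)
        assert np.isfinite(res.rho_se)

    def test_aic_consistency(self):
        ds = toy_dataset(seed=2)
        res = LaggedRickerModel(ds).fit(compute_rho_se=False)
        assert res.aic == pytest.approx(-2 * res.llf + 2 * res.df_model)

    def test_summary_renders(self):
        ds = toy_dataset(seed=2)
        res = LaggedRickerModel(ds).fit(compute_rho_se=False)
        text = res.summary()
        assert "rho" in text and "intercept" in text


class TestAicWeights:
    def test_two_models(self):
        w = aic_weights([100.0, 102.0])
        assert w[0] == pytest.approx(np.e / (np.e + 1), abs=1e-4)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_model(self):
        assert aic_weights([57.0]) == pytest.approx([1.0])

    def test_equal_aics_equal_weights(self):
        assert np.allclose(aic_weights([10.0, 10.0, 10.0]), 1 / 3)

    def test_shift_invariance(self):
        a = np.array([100.0, 103.0, 111.0])
        assert np.allclose(aic_weights(a), aic_weights(a + 57.0))


class TestEvidenceRatio:
    def test_delta_aic_two_gives_e(self):
        w = aic_weights([100.0, 102.0])
        assert evidence_ratio(w[0], w[1]) == pytest.approx(np.exp(1.0), rel=1e-6)

    def test_delta_aic_four_gives_e_squared(self):
        w = aic_weights([100.0, 104.0])
        assert evidence_ratio(w[0], w[1]) == pytest.approx(np.exp(2.0), rel=1e-6)

    def test_equal_weights(self):
        assert evidence_ratio(0.5, 0.5) == pytest.approx(1.0)

    def test_zero_denominator(self):
        with pytest.warns(RuntimeWarning):
            assert np.isinf(evidence_ratio(0.5, 0.0))


class TestSelectLagModel:
    def test_single_candidate_trivially_selected(self):
        truth = RickerTruth(alpha=0.5, betas=(-0.02,), lags=(1.0,), thetas=(1.0,),
                            rho=0.0, sigma_replicate=0.0, sigma_patch=0.0,
                            sigma_error=0.2)
        series, _ = generate_from_ricker(truth, 2, 4, 40, seed=0)
        table, results = select_lag_model(series, [(1.0,)])
        assert len(table) == 1
        assert table.loc[0, "weight"] == pytest.approx(1.0)
        assert table.loc[0, "best"]

    def test_recovers_true_single_lag(self):
        truth = RickerTruth(alpha=0.5, betas=(-0.05,), lags=(1.0,), thetas=(1.0,),
                            rho=0.0, sigma_replicate=0.0, sigma_patch=0.0,
                            sigma_error=0.15)
        series, _ = generate_from_ricker(truth, 4, 4, 60, seed=2)
        table, _ = select_lag_model(series, [(1.0,), (2.0,), (3.0,)])
        assert table.loc[0, "lags"] == (1.0,)

    def test_default_candidate_space(self):
        cands = default_candidate_lag_sets()
        assert (1.0,) in cands and (1.0, 3.5) in cands
        assert all(b - a >= 1.5 for c in cands if len(c) == 2 for a, b in [c])
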