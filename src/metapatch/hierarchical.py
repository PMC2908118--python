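"""Hierarchical fit of the time-lagged Ricker model.

The linearized Ricker regression (see :mod:`metapatch.ricker`) is embedded in
a hierarchical structure mirroring the experimental design: patches nested
within replicate metapopulations. The marginal model for the response vector
of replicate j is multivariate normal with

    y = X beta + u_rep + u_patch + eps

where u_rep ~ N(0, sigma_replicate^2) is a replicate-level intercept
deviation, u_patch ~ N(0, sigma_patch^2) a patch-level intercept deviation,
and the residuals eps of the patches observed in the same replicate in the
same week are exchangeable with correlation rho (compound symmetry) and
variance sigma_error^2. rho is the patchwise spatial correlation: negative
values mean asynchronous local dynamics after accounting for the shared
density-dependent structure. Positive definiteness of the exchangeable block
bounds rho below by -1/(n_patches - 1) (-1/3 for four patches).

Estimation is by maximum likelihood (not REML) so that AICs are comparable
across fixed-effect (lag) structures; fixed effects are profiled out by GLS
inside the variance-parameter optimization. Model selection across candidate
lag structures uses AIC weights, w_m = exp(-Delta_m/2) / sum exp(-Delta/2);
the ratio of two weights (evidence ratio) exceeds e = 2.718 exactly when the
AIC difference exceeds 2.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize as sopt
from scipy.special import expit, logit

from .ricker import LagSpec, RegressionDataset, build_dataset, optimize_theta
from .series import PatchTimeSeries

__all__ = [
    "HierarchicalStructure",
    "LaggedRickerModel",
    "LaggedRickerResults",
    "fit_hierarchical",
    "aic_weights",
    "evidence_ratio",
    "select_lag_model",
    "default_candidate_lag_sets",
]



@dataclass(frozen=True)
class HierarchicalStructure:
    """Random-effect and residual-correlation structure of the fit.

    Patch and replicate intercept deviations are each optional; the
    exchangeable residual correlation rho across patches within a replicate
    at the same week is always part of the model (it is the quantity of
    scientific interest) unless held fixed at a value via ``fit``.
    """

    replicate_intercept: bool = True
    patch_intercept: bool = True


class ConvergenceError(RuntimeError):
    """Raised when the variance-parameter optimization fails, carrying the
    optimizer trace in ``result``."""

    def __init__(self, message: str, result=None):
        super().__init__(message)
        self.result = result


class LaggedRickerModel:
    """Hierarchical time-lagged Ricker model bound to a regression dataset.

    Parameters
    ----------
    dataset:
        A :class:`RegressionDataset` from :func:`metapatch.ricker.build_dataset`.
    structure:
        Which random intercept terms to include (default: both).
    """

    def __init__(
        self,
        dataset: RegressionDataset,
        structure: HierarchicalStructure | None = None,
    ):
        self.dataset = dataset
        self.structure = structure or HierarchicalStructure()
        tbl = dataset.table
        if tbl.empty:
            raise ValueError("empty dataset")
        self.endog = tbl["response"].to_numpy(dtype=float)
        cols = dataset.covariate_columns
        self.exog = np.column_stack(
            [np.ones(len(tbl))] + [tbl[c].to_numpy(dtype=float) for c in cols]
        )
        self.exog_names = ["intercept"] + cols
        self.nobs = len(tbl)

        self._blocks = []
        n_patch_max = 1
        for rep, grp in tbl.groupby("replicate", sort=True):
            idx = grp.index.to_numpy()
            patches = grp["patch"].to_numpy()
            weeks = grp["week"].to_numpy()
            n_patch_max = max(n_patch_max, len(np.unique(patches)))
            block = self._make_block(idx, patches, weeks)
            self._blocks.append(block)
        self.n_patches = n_patch_max
        self.rho_min = -1.0 / (self.n_patches - 1) if self.n_patches > 1 else None

    def _make_block(self, idx, patches, weeks) -> dict:
        """Per-replicate likelihood workspace.

        For a complete balanced block (every patch observed in every week)
        the covariance is a sum of Kronecker products of identity and
        all-ones matrices in the week and patch factors, so it is
        diagonalized once by a fixed orthonormal basis with four eigenvalue
        classes; each likelihood evaluation is then O(n k). Ragged blocks
        fall back to an explicit Cholesky factorization per evaluation.
        """
        u_weeks, week_code = np.unique(weeks, return_inverse=True)
        u_patch, patch_code = np.unique(patches, return_inverse=True)
        T, p = len(u_weeks), len(u_patch)
        n = len(idx)
        balanced = n == T * p and len({(w, q) for w, q in zip(week_code, patch_code)}) == n
        if balanced and p > 1 and T > 1:
            order = np.lexsort((patch_code, week_code))  # week-major, patch fastest
            rows = idx[order]

            def ones_basis(m: int) -> np.ndarray:
                a = np.column_stack([np.ones(m), np.eye(m)[:, : m - 1]])
                q, _ = np.linalg.qr(a)
                return q  # first column = 1/sqrt(m)

            q = np.kron(ones_basis(T), ones_basis(p))
            lam_t = np.repeat(np.where(np.arange(T) == 0, float(T), 0.0), p)
            lam_p = np.tile(np.where(np.arange(p) == 0, float(p), 0.0), T)
            return {
                "kind": "eigen",
                "rows": rows,
                "xt": q.T @ self.exog[rows],
                "yt": q.T @ self.endog[rows],
                "lam_t": lam_t,
                "lam_p": lam_p,
            }
        same_patch = patches[:, None] == patches[None, :]
        same_week = np.isclose(weeks[:, None], weeks[None, :])
        return {
            "kind": "dense",
            "rows": idx,
            "n": n,
            "same_patch_flat": np.flatnonzero(same_patch),
            "cross_flat": np.flatnonzero(same_week & ~same_patch),
            "buf": np.empty((n, n)),
        }

    # ---- likelihood -----------------------------------------------------

    def _sigma_block(self, block, sr2, sp2, rho, se2) -> np.ndarray:
        n = block["n"]
        sig = block["buf"]
        sig.fill(sr2)
        if sp2:
            sig.flat[block["same_patch_flat"]] += sp2
        if rho:
            sig.flat[block["cross_flat"]] += se2 * rho
        sig.flat[:: n + 1] += se2
        return sig

    @staticmethod
    def _eigvals(block, sr2, sp2, rho, se2) -> np.ndarray:
        """Eigenvalues of the block covariance in the precomputed basis."""
        lam_t, lam_p = block["lam_t"], block["lam_p"]
        return sr2 * lam_t * lam_p + sp2 * lam_t + se2 * (1.0 - rho) + se2 * rho * lam_p

    def _gls_pieces(self, sr2: float, sp2: float, rho: float, se2: float):
        """GLS with fixed effects profiled out.

        Returns (logdet, quad, beta, xtvix_inv) for the covariance built from
        the given components, or None if the covariance is not positive
        definite. quad is the GLS residual quadratic form e' Sigma^-1 e.
        """
        k = self.exog.shape[1]
        xtvix = np.zeros((k, k))
        xtviy = np.zeros(k)
        ytviy = 0.0
        logdet = 0.0
        for block in self._blocks:
            rows = block["rows"]
            if block["kind"] == "eigen":
                lam = self._eigvals(block, sr2, sp2, rho, se2)
                if (lam <= 0).any():
                    return None
                logdet += float(np.sum(np.log(lam)))
                w = 1.0 / lam
                xt, yt = block["xt"], block["yt"]
                xtvix += xt.T @ (w[:, None] * xt)
                xtviy += xt.T @ (w * yt)
                ytviy += yt @ (w * yt)
                continue
            sig = self._sigma_block(block, sr2, sp2, rho, se2)
            try:
                c, low = sla.cho_factor(sig, lower=True, check_finite=False)
            except sla.LinAlgError:
                return None
            logdet += 2.0 * np.sum(np.log(np.diag(c)))
            xj = self.exog[rows]
            yj = self.endog[rows]
            vix = sla.cho_solve((c, low), xj, check_finite=False)
            viy = sla.cho_solve((c, low), yj, check_finite=False)
            xtvix += xj.T @ vix
            xtviy += xj.T @ viy
            ytviy += yj @ viy
        try:
            xtvix_inv = np.linalg.inv(xtvix)
        except np.linalg.LinAlgError:
            return None
        beta = xtvix_inv @ xtviy
        quad = ytviy - beta @ xtviy
        return logdet, quad, beta, xtvix_inv

    def _gls(self, sr2: float, sp2: float, rho: float, se2: float):
        """Profile fixed effects out by GLS; returns (loglik, beta, XtViX_inv)."""
        out = self._gls_pieces(sr2, sp2, rho, se2)
        if out is None:
            return None
        logdet, quad, beta, xtvix_inv = out
        ll = -0.5 * (self.nobs * np.log(2.0 * np.pi) + logdet + quad)
        return ll, beta, xtvix_inv

    def _scale_profiled_loglike(self, g_rep: float, g_patch: float, rho: float):
        """Log-likelihood with fixed effects and the residual scale profiled
        out analytically. g_rep, g_patch are variance ratios relative to
        sigma_error^2. Returns (loglik, sigma_error_hat) or None."""
        out = self._gls_pieces(g_rep, g_patch, rho, 1.0)
        if out is None:
            return None
        logdet_v, quad_v, _, _ = out
        if quad_v <= 0:
            return None
        n = self.nobs
        se2_hat = quad_v / n
        ll = -0.5 * (n * np.log(2.0 * np.pi) + logdet_v + n * np.log(se2_hat) + n)
        return ll, float(np.sqrt(se2_hat))

    def loglike(
        self,
        beta: np.ndarray,
        sigma_replicate: float,
        sigma_patch: float,
        rho: float,
        sigma_error: float,
    ) -> float:
        """Exact marginal log-likelihood at given fixed effects and variance
        parameters (used directly by the brute-force likelihood checks)."""
        beta = np.asarray(beta, dtype=float)
        resid = self.endog - self.exog @ beta
        sr2, sp2, se2 = sigma_replicate**2, sigma_patch**2, sigma_error**2
        ll = 0.0
        for block in self._blocks:
            rows = block["rows"]
            if block["kind"] == "eigen":
                lam = self._eigvals(block, sr2, sp2, rho, se2)
                et = block["yt"] - block["xt"] @ beta
                ll -= 0.5 * (
                    len(rows) * np.log(2.0 * np.pi)
                    + float(np.sum(np.log(lam)))
                    + float(np.sum(et**2 / lam))
                )
                continue
            sig = self._sigma_block(block, sr2, sp2, rho, se2)
            c, low = sla.cho_factor(sig, lower=True, check_finite=False)
            e = resid[rows]
            ll -= 0.5 * (
                len(rows) * np.log(2.0 * np.pi)
                + 2.0 * np.sum(np.log(np.diag(c)))
                + e @ sla.cho_solve((c, low), e, check_finite=False)
            )
        return float(ll)

    def profile_loglike(
        self,
        sigma_replicate: float,
        sigma_patch: float,
        rho: float,
        sigma_error: float,
    ) -> float:
        """Log-likelihood with fixed effects profiled out by GLS."""
        out = self._gls(sigma_replicate**2, sigma_patch**2, rho, sigma_error**2)
        return -np.inf if out is None else out[0]

    # ---- fitting --------------------------------------------------------

    def _free_names(self, hold: dict) -> list[str]:
        free = []
        if self.structure.replicate_intercept and "sigma_replicate" not in hold:
            free.append("sigma_replicate")
        if self.structure.patch_intercept and "sigma_patch" not in hold:
            free.append("sigma_patch")
        if "rho" not in hold:
            free.append("rho")
        if "sigma_error" not in hold:
            free.append("sigma_error")
        return free

    def _pack(self, values: dict, free: list[str]) -> np.ndarray:
        z = []
        lo = self.rho_min if self.rho_min is not None else -1.0
        for name in free:
            v = values[name]
            if name == "rho":
                frac = np.clip((v - lo) / (1.0 - lo), 1e-6, 1 - 1e-6)
                z.append(logit(frac))
            else:
                z.append(np.log(max(v, 1e-8) ** 2))
        return np.array(z)

    def _unpack(self, z: np.ndarray, free: list[str], hold: dict) -> dict:
        lo = self.rho_min if self.rho_min is not None else -1.0
        vals = {
            "sigma_replicate": 0.0,
            "sigma_patch": 0.0,
            "rho": 0.0,
            "sigma_error": 1.0,
        }
        vals.update(hold)
        for name, zi in zip(free, z):
            if name == "rho":
                vals[name] = lo + (1.0 - lo) * float(expit(zi))
            else:
                vals[name] = float(np.sqrt(np.exp(zi)))
        return vals

    def fit(
        self,
        hold: dict | None = None,
        start: dict | None = None,
        maxiter: int = 200,
        compute_rho_se: bool = True,
    ) -> "LaggedRickerResults":
        """Maximum-likelihood fit.

        Parameters
        ----------
        hold:
            Variance parameters to fix rather than estimate, e.g.
            ``{"sigma_replicate": 0.0, "rho": 0.0}``. Held parameters do not
            count as free parameters in the AIC.
        start:
            Optional starting values (same keys as ``hold``).
        """
        hold = dict(hold or {})
        if not self.structure.replicate_intercept:
            hold.setdefault("sigma_replicate", 0.0)
        if not self.structure.patch_intercept:
            hold.setdefault("sigma_patch", 0.0)
        free = self._free_names(hold)
        if "rho" in free and self.n_patches < 2:
            raise ValueError(
                "patchwise correlation rho is not identifiable with a single "
                "patch per replicate; hold rho at a fixed value instead"
            )

        # start from the OLS residual scale
        beta0, res0, *_ = np.linalg.lstsq(self.exog, self.endog, rcond=None)
        resid0 = self.endog - self.exog @ beta0
        s0 = float(np.std(resid0)) or 1.0
        init = {
            "sigma_replicate": 0.1 * s0,
            "sigma_patch": 0.1 * s0,
            "rho": 0.0,
            "sigma_error": 0.95 * s0,
        }
        init.update(start or {})

        # When the residual scale is free and no other sigma is held at a
        # nonzero value, both the fixed effects and sigma_error profile out
        # analytically, leaving at most three search dimensions (variance
        # ratios and rho).
        profiled_scale = "sigma_error" in free and all(
            hold.get(n, 0.0) == 0.0 for n in ("sigma_replicate", "sigma_patch")
        )
        if profiled_scale:
            free_ratio = [n for n in free if n != "sigma_error"]
            lo = self.rho_min if self.rho_min is not None else -1.0

            def unpack_ratio(z: np.ndarray) -> dict:
                g = {"sigma_replicate": 0.0, "sigma_patch": 0.0, "rho": hold.get("rho", 0.0)}
                for name, zi in zip(free_ratio, z):
                    if name == "rho":
                        g[name] = lo + (1.0 - lo) * float(expit(zi))
                    else:
                        g[name] = float(np.exp(zi))
                return g

            z0 = []
            for name in free_ratio:
                if name == "rho":
                    frac = np.clip((init["rho"] - lo) / (1.0 - lo), 1e-6, 1 - 1e-6)
                    z0.append(logit(frac))
                else:
                    z0.append(np.log(max(init[name] / init["sigma_error"], 1e-4) ** 2))
            z0 = np.array(z0)

            def nll(z: np.ndarray) -> float:
                g = unpack_ratio(z)
                out = self._scale_profiled_loglike(
                    g["sigma_replicate"], g["sigma_patch"], g["rho"]
                )
                return 1e12 if out is None else -out[0]

            if free_ratio:
                opt = sopt.minimize(
                    nll, z0, method="Powell",
                    options={"maxiter": maxiter * len(free_ratio),
                             "xtol": 1e-4, "ftol": 1e-9},
                )
                g = unpack_ratio(opt.x)
            else:
                opt = None
                g = unpack_ratio(np.array([]))
            out = self._scale_profiled_loglike(
                g["sigma_replicate"], g["sigma_patch"], g["rho"]
            )
            if out is None:
                raise ConvergenceError("covariance singular at optimum", result=opt)
            _, se_hat = out
            v = {
                "sigma_replicate": float(np.sqrt(g["sigma_replicate"])) * se_hat,
                "sigma_patch": float(np.sqrt(g["sigma_patch"])) * se_hat,
                "rho": g["rho"],
                "sigma_error": se_hat,
            }
        else:
            z0 = self._pack(init, free)

            def nll(z: np.ndarray) -> float:
                v = self._unpack(z, free, hold)
                ll = self.profile_loglike(
                    v["sigma_replicate"], v["sigma_patch"], v["rho"], v["sigma_error"]
                )
                return -ll if np.isfinite(ll) else 1e12

            opt = sopt.minimize(nll, z0, method="Powell",
                                options={"maxiter": maxiter * max(len(free), 1),
                                         "xtol": 1e-6, "ftol": 1e-10})
            if not np.isfinite(opt.fun):
                raise ConvergenceError("variance optimization diverged", result=opt)
            v = self._unpack(opt.x, free, hold)
        out = self._gls(v["sigma_replicate"] ** 2, v["sigma_patch"] ** 2, v["rho"], v["sigma_error"] ** 2)
        if out is None:
            raise ConvergenceError("covariance singular at optimum", result=opt)
        ll, beta, cov_beta = out

        flags = []
        if opt is not None and not opt.success:
            flags.append(f"optimizer: {opt.message}")
        for name in ("sigma_replicate", "sigma_patch"):
            if name in free and v[name] < 1e-4 * v["sigma_error"]:
                flags.append(f"{name} at boundary (~0)")
        if "rho" in free and self.rho_min is not None:
            if v["rho"] - self.rho_min < 1e-3 * (1 - self.rho_min) or 1.0 - v["rho"] < 1e-3:
                flags.append("rho at boundary")

        rho_se = np.nan
        if "rho" in free and compute_rho_se:
            rho_se = self._rho_se(v, free, hold)

        df = self.exog.shape[1] + len(free)
        return LaggedRickerResults(
            model=self,
            fe_params=pd.Series(beta, index=self.exog_names),
            bse=pd.Series(np.sqrt(np.diag(cov_beta)), index=self.exog_names),
            cov_params=cov_beta,
            sigma_replicate=v["sigma_replicate"],
            sigma_patch=v["sigma_patch"],
            sigma_error=v["sigma_error"],
            rho=v["rho"],
            rho_se=rho_se,
            llf=float(ll),
            df_model=df,
            converged=bool(np.isfinite(ll)),
            boundary_flags=flags,
            held=hold,
        )

    def _rho_se(self, v: dict, free: list[str], hold: dict) -> float:
        """Standard error of rho from the curvature of the profile
        log-likelihood in the variance parameters (observed information)."""
        names = list(free)
        x0 = np.array([v[n] for n in names])
        steps = np.array([max(1e-4, 1e-3 * abs(x)) for x in x0])

        def pll(x: np.ndarray) -> float:
            vals = dict(hold)
            vals.update({n: xi for n, xi in zip(names, x)})
            for n in ("sigma_replicate", "sigma_patch", "sigma_error"):
                vals.setdefault(n, v[n])
            vals.setdefault("rho", v["rho"])
            if vals["sigma_error"] <= 0:
                return -np.inf
            if self.rho_min is not None and not (self.rho_min < vals["rho"] < 1.0):
                return -np.inf
            return self.profile_loglike(
                abs(vals["sigma_replicate"]), abs(vals["sigma_patch"]),
                vals["rho"], vals["sigma_error"],
            )

        k = len(names)
        hess = np.zeros((k, k))
        f0 = pll(x0)
        if not np.isfinite(f0):
            return np.nan
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = steps[i]
                ej = np.zeros(k); ej[j] = steps[j]
                fpp = pll(x0 + ei + ej)
                fpm = pll(x0 + ei - ej)
                fmp = pll(x0 - ei + ej)
                fmm = pll(x0 - ei - ej)
                if not all(np.isfinite([fpp, fpm, fmp, fmm])):
                    return np.nan
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
        try:
            cov = np.linalg.inv(-hess)
        except np.linalg.LinAlgError:
            return np.nan
        i_rho = names.index("rho")
        var = cov[i_rho, i_rho]
        return float(np.sqrt(var)) if var > 0 else np.nan


@dataclass
class LaggedRickerResults:
    """Maximum-likelihood estimates from a hierarchical lagged-Ricker fit."""

    model: LaggedRickerModel
    fe_params: pd.Series
    bse: pd.Series
    cov_params: np.ndarray
    sigma_replicate: float
    sigma_patch: float
    sigma_error: float
    rho: float
    rho_se: float
    llf: float
    df_model: int
    converged: bool
    boundary_flags: list = field(default_factory=list)
    held: dict = field(default_factory=dict)

    @property
    def alpha(self) -> float:
        """Fixed intercept: average net reproductive rate at x = 0."""
        return float(self.fe_params["intercept"])

    @property
    def betas(self) -> pd.Series:
        """Fixed slopes on the Box-Cox-transformed lagged abundances."""
        return self.fe_params.drop("intercept")

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.df_model

    @property
    def n_obs(self) -> int:
        return self.model.nobs

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "lower": self.fe_params - z * self.bse,
                "upper": self.fe_params + z * self.bse,
            }
        )

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Hierarchical time-lagged Ricker model (ML)",
            "=" * 58,
            f"n_obs: {self.n_obs}   log-likelihood: {self.llf:.4f}   AIC: {self.aic:.4f}",
            f"free parameters: {self.df_model}   converged: {self.converged}",
            "-" * 58,
            f"{'term':<14}{'estimate':>12}{'std err':>12}{'[0.025':>10}{'0.975]':>10}",
        ]
        for name in self.fe_params.index:
            lines.append(
                f"{name:<14}{self.fe_params[name]:>12.4f}{self.bse[name]:>12.4f}"
                f"{ci.loc[name, 'lower']:>10.4f}{ci.loc[name, 'upper']:>10.4f}"
            )
        lines += [
            "-" * 58,
            f"sigma_replicate: {self.sigma_replicate:.4f}   sigma_patch: {self.sigma_patch:.4f}"
            f"   sigma_error: {self.sigma_error:.4f}",
            f"patchwise spatial correlation rho: {self.rho:.4f} (SE {self.rho_se:.4f})",
        ]
        if self.held:
            lines.append(f"held fixed: {self.held}")
        if self.boundary_flags:
            lines.append("flags: " + "; ".join(self.boundary_flags))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "betas": {k: float(v) for k, v in self.betas.items()},
            "se": {k: float(v) for k, v in self.bse.items()},
            "sigma_replicate": self.sigma_replicate,
            "sigma_patch": self.sigma_patch,
            "sigma_error": self.sigma_error,
            "rho": self.rho,
            "rho_se": float(self.rho_se),
            "log_likelihood": self.llf,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "df_model": self.df_model,
            "converged": self.converged,
            "boundary_flags": list(self.boundary_flags),
            "lags": list(self.model.dataset.lag_spec.lags),
            "thetas": list(self.model.dataset.lag_spec.thetas),
        }


def fit_hierarchical(
    dataset: RegressionDataset,
    structure: HierarchicalStructure | None = None,
    **fit_kwargs,
) -> LaggedRickerResults:
    """Fit the hierarchical lagged-Ricker model to an assembled dataset."""
    return LaggedRickerModel(dataset, structure).fit(**fit_kwargs)


def aic_weights(aic_values) -> np.ndarray:
    """Akaike weights w_m = exp(-Delta_m/2) / sum_m' exp(-Delta_m'/2)."""
    aics = np.asarray(aic_values, dtype=float)
    if aics.size == 0:
        raise ValueError("need at least one AIC value")
    delta = aics - aics.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def evidence_ratio(w_m: float, w_m_prime: float) -> float:
    """Ratio of Akaike weights w_m / w_m'; > e signals substantial support."""
    if w_m <= 0:
        raise ValueError("numerator weight must be > 0")
    if w_m_prime == 0.0:
        warnings.warn("zero denominator weight; evidence ratio infinite",
                      RuntimeWarning, stacklevel=2)
        return float("inf")
    return float(w_m / w_m_prime)


def default_candidate_lag_sets(
    lags=(0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0),
    min_separation: float = 1.5,
) -> list[tuple[float, ...]]:
    """All single lags plus all pairs separated by at least ``min_separation``
    weeks (so the two covariates act on distinguishable time scales)."""
    singles = [(t,) for t in lags]
    pairs = [
        (a, b) for a, b in itertools.combinations(lags, 2) if b - a >= min_separation
    ]
    return singles + pairs


def _collect_pairs(series_set, tau: float, min_week: float):
    """Raw (response, lagged abundance) pairs over a common response window."""
    from .ricker import interpolate_half_weeks, net_reproductive_rate

    ys, xs = [], []
    for s in series_set:
        weeks_t, r = net_reproductive_rate(s)
        interp = interpolate_half_weeks(s)
        lookup = dict(zip(interp.weeks.tolist(), interp.counts.tolist()))
        for t, r_t in zip(weeks_t, r):
            if t < min_week or not np.isfinite(r_t):
                continue
            v = lookup.get(round(float(t - tau) * 2) / 2)
            if v is None:
                continue
            ys.append(float(r_t))
            xs.append(float(v))
    return np.array(ys), np.array(xs)


def select_lag_model(
    series_set: list[PatchTimeSeries],
    candidate_lag_sets: list[tuple[float, ...]] | None = None,
    structure: HierarchicalStructure | None = None,
    screen_maxiter: int = 80,
    **fit_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Fit every candidate lag structure and rank by AIC weight.

    Box-Cox exponents are optimized once per lag on the common response
    window (the window implied by the largest candidate lag), so all
    candidates are fitted to the same responses and AICs are commensurable.

    Returns
    -------
    table:
        DataFrame ranked by AIC with columns lags, thetas, aic, delta_aic,
        weight, evidence_ratio_best_vs_this, converged.
    results:
        Mapping from the candidate lag tuple to its fitted results object.
    """
    if candidate_lag_sets is None:
        candidate_lag_sets = default_candidate_lag_sets()
    all_lags = sorted({tau for cand in candidate_lag_sets for tau in cand})
    if not all_lags:
        raise ValueError("no candidate lags")
    first_week = min(s.weeks[0] for s in series_set)
    min_week = first_week + max(all_lags)

    thetas: dict[float, float] = {}
    for tau in all_lags:
        y, x = _collect_pairs(series_set, tau, min_week)
        thetas[tau] = optimize_theta(y, x)

    rows, results = [], {}
    for cand in candidate_lag_sets:
        cand = tuple(sorted(float(t) for t in cand))
        spec = LagSpec(lags=cand, thetas=tuple(thetas[t] for t in cand))
        try:
            ds = build_dataset(series_set, spec, min_response_week=min_week)
            # screening pass: capped iterations, no rho-SE Hessian; the
            # selected model is refitted in full below
            res = LaggedRickerModel(ds, structure).fit(
                compute_rho_se=False, maxiter=screen_maxiter, **fit_kwargs
            )
        except (ConvergenceError, ValueError) as exc:
            warnings.warn(f"candidate {cand} dropped: {exc}", RuntimeWarning, stacklevel=2)
            continue
        results[cand] = res
        rows.append(
            {
                "lags": cand,
                "thetas": tuple(round(thetas[t], 4) for t in cand),
                "aic": res.aic,
                "log_likelihood": res.llf,
                "converged": res.converged,
            }
        )
    if not rows:
        raise RuntimeError("no candidate model converged")
    table = pd.DataFrame(rows)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    w = aic_weights(table["aic"].to_numpy())
    table["weight"] = w
    table["evidence_ratio_best_vs_this"] = w.max() / w
    table = table.sort_values("aic", kind="mergesort").reset_index(drop=True)
    table["best"] = [i == 0 for i in range(len(table))]
    best_cand = table.loc[0, "lags"]
    best = results[best_cand]
    results[best_cand] = best.model.fit(**fit_kwargs)
    return table, results
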