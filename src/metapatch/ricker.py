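"""Time-lagged linearized Ricker regression dataset construction.

The linearized Ricker model regresses the weekly net reproductive rate

    r_t = ln(N_{t+1} / N_t)

on Box-Cox-transformed adult abundances lagged by tau weeks,

    x_{t-tau} = (N_{t-tau}^theta - 1) / theta    (ln N at theta = 0),

with tau up to four weeks (a little over one host generation) and half-week
lags obtained by linear interpolation of the weekly counts. theta is the
transformation that best linearizes the relationship for each lagged series,
found by profile likelihood.

Zero counts: transitions touching a zero use a 0.5 shift (N + 0.5) inside
the logarithm and the Box-Cox transform; transitions where the population is
extinct in both weeks carry no growth information and are dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import PatchTimeSeries

__all__ = [
    "LagSpec",
    "RegressionDataset",
    "net_reproductive_rate",
    "interpolate_half_weeks",
    "boxcox",
    "optimize_theta",
    "build_dataset",
]

logger = logging.getLogger(__name__)

#: Additive shift applied inside log/Box-Cox when a count of zero is involved.
ZERO_SHIFT = 0.5


@dataclass(frozen=True)
class LagSpec:
    """Lags (weeks, multiples of 0.5 in [0.5, 4]) with their Box-Cox exponents."""

    lags: tuple[float, ...]
    thetas: tuple[float, ...]

    def __post_init__(self) -> None:
        lags = tuple(float(t) for t in self.lags)
        thetas = tuple(float(t) for t in self.thetas)
        if len(lags) != len(thetas):
            raise ValueError("need one theta per lag")
        if len(set(lags)) != len(lags) or list(lags) != sorted(lags):
            raise ValueError("lags must be distinct and sorted")
        for tau in lags:
            if not (0.5 <= tau <= 4.0) or (2 * tau) != int(2 * tau):
                raise ValueError(f"lags must be half-week multiples in [0.5, 4], got {tau}")
        if not all(np.isfinite(thetas)):
            raise ValueError("thetas must be finite")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "thetas", thetas)


@dataclass
class RegressionDataset:
    """Aligned response/covariate table for the hierarchical Ricker fit.

    ``table`` has one row per (replicate, patch, usable week) with columns
    replicate, patch, week, response, and one ``lag_<tau>`` column per lag.
    ``drop_counts`` records how many candidate rows each filter removed.
    """

    table: pd.DataFrame
    lag_spec: LagSpec
    drop_counts: dict = field(default_factory=dict)

    @property
    def covariate_columns(self) -> list[str]:
        return [_lag_col(tau) for tau in self.lag_spec.lags]

    @property
    def n_obs(self) -> int:
        return len(self.table)


def _lag_col(tau: float) -> str:
    return f"lag_{tau:g}"


def _shifted(values: np.ndarray) -> np.ndarray:
    """Apply the zero-count shift: values of zero become ZERO_SHIFT."""
    v = np.asarray(values, dtype=float)
    return np.where(v > 0, v, v + ZERO_SHIFT)


def net_reproductive_rate(
    series: PatchTimeSeries, zero_shift: float = ZERO_SHIFT
) -> tuple[np.ndarray, np.ndarray]:
    """Weekly net reproductive rate r_t = ln(N_{t+1}/N_t).

    Returns (weeks, r) where weeks are the transition start times; r has one
    fewer element than the input series. Transitions touching a zero count
    use the shift (N + zero_shift) inside the log; transitions with zero
    counts in both weeks are returned as NaN (no growth information).
    """
    if len(series) < 2:
        raise ValueError("need at least two time points")
    n0 = series.counts[:-1].copy()
    n1 = series.counts[1:].copy()
    both_zero = (n0 == 0) & (n1 == 0)
    touch_zero = (n0 == 0) | (n1 == 0)
    n0 = np.where(touch_zero, n0 + zero_shift, n0)
    n1 = np.where(touch_zero, n1 + zero_shift, n1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.log(n1 / n0)
    r[both_zero] = np.nan
    if both_zero.all():
        warnings.warn(
            f"series {series.key} is extinct throughout; empty response",
            RuntimeWarning,
            stacklevel=2,
        )
    return series.weeks[:-1], r


def interpolate_half_weeks(series: PatchTimeSeries) -> PatchTimeSeries:
    """Resample a weekly series to a 0.5-week grid by linear interpolation.

    Values at observed weeks are unchanged; the value at w + 0.5 is the mean
    of the values at w and w + 1. Gaps in the weekly grid are interpolated
    across, with a logged warning.
    """
    w = series.weeks
    if len(series) < 2:
        raise ValueError("need at least two weekly observations to interpolate")
    gaps = np.diff(w)
    if np.any(gaps > 1.0):
        logger.warning(
            "series %s has gaps in its weekly grid; interpolating across them",
            series.key,
        )
    new_weeks = np.arange(w[0], w[-1] + 0.25, 0.5)
    new_counts = np.interp(new_weeks, w, series.counts)
    return PatchTimeSeries(
        replicate=series.replicate,
        patch=series.patch,
        species=series.species,
        treatment=series.treatment,
        weeks=new_weeks,
        counts=new_counts,
    )


def boxcox(x, theta: float):
    """Box-Cox power transform: (x^theta - 1)/theta, ln x at theta = 0.

    Continuous in theta; requires x > 0 (zero handling happens upstream).
    """
    x = np.asarray(x, dtype=float)
    if (x <= 0).any():
        raise ValueError("Box-Cox transform requires strictly positive values")
    if theta == 0.0:
        out = np.log(x)
    else:
        out = (np.power(x, theta) - 1.0) / theta
    return out if out.ndim else float(out)


def optimize_theta(
    response: np.ndarray,
    lagged_abundance: np.ndarray,
    bounds: tuple[float, float] = (-2.0, 2.0),
    tol: float = 1e-3,
) -> float:
    """Box-Cox exponent maximizing the profile likelihood of a simple linear
    regression of the response on the transformed lagged abundance.

    A coarse grid over ``bounds`` is followed by bounded scalar refinement.
    If the covariate is (numerically) constant the profile is flat; theta = 1
    is returned with a warning.
    """
    from scipy import optimize as sopt

    y = np.asarray(response, dtype=float)
    x = np.asarray(lagged_abundance, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if y.size < 5:
        raise ValueError("need at least 5 paired observations")
    if np.ptp(x) == 0.0 or np.ptp(x) / max(abs(x.mean()), 1e-300) < 1e-12:
        warnings.warn(
            "constant lagged abundance; Box-Cox profile is flat, returning theta=1",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0

    n = y.size

    def nll(theta: float) -> float:
        z = boxcox(_shifted(x), theta)
        A = np.column_stack([np.ones(n), z])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(np.sum((y - A @ coef) ** 2))
        if rss <= 0:
            rss = 1e-300
        return 0.5 * n * np.log(rss / n)

    grid = np.linspace(bounds[0], bounds[1], 41)
    vals = [nll(t) for t in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = sopt.minimize_scalar(nll, bounds=(lo, hi), method="bounded", options={"xatol": tol})
    return float(res.x)


def build_dataset(
    series_set: list[PatchTimeSeries],
    lag_spec: LagSpec,
    min_response_week: float | None = None,
) -> RegressionDataset:
    """Assemble the aligned regression table for a set of patch series.

    One row per (replicate, patch, usable transition start week t): the
    response is r_t and the covariates are Box-Cox-transformed interpolated
    abundances at t - tau for each lag tau. Rows with an undefined response
    or any undefined covariate are dropped and counted. ``min_response_week``
    restricts the response window (used to keep AICs commensurable when
    comparing lag structures with different maximal lags).

    All series must share the weekly sampling grid.
    """
    if not series_set:
        raise ValueError("empty series set")
    drop = {"response_undefined": 0, "covariate_out_of_range": 0, "window_restricted": 0}
    rows = []
    max_lag = max(lag_spec.lags) if lag_spec.lags else 0.0
    for s in series_set:
        weeks_t, r = net_reproductive_rate(s)
        interp = interpolate_half_weeks(s) if len(s) >= 2 else s
        lookup = dict(zip(interp.weeks.tolist(), interp.counts.tolist()))
        first_week = s.weeks[0]
        for t, r_t in zip(weeks_t, r):
            if min_response_week is not None and t < min_response_week:
                drop["window_restricted"] += 1
                continue
            if not np.isfinite(r_t):
                drop["response_undefined"] += 1
                continue
            if t - max_lag < first_week - 1e-9:
                drop["covariate_out_of_range"] += 1
                continue
            row = {"replicate": s.replicate, "patch": s.patch, "week": float(t), "response": float(r_t)}
            ok = True
            for tau, theta in zip(lag_spec.lags, lag_spec.thetas):
                v = lookup.get(round(float(t - tau) * 2) / 2)
                if v is None:
                    ok = False
                    break
                row[_lag_col(tau)] = float(boxcox(_shifted(np.array([v]))[0], theta))
            if not ok:
                drop["covariate_out_of_range"] += 1
                continue
            rows.append(row)
    if not rows:
        raise ValueError(f"no usable rows after alignment; drop counts: {drop}")
    cols = ["replicate", "patch", "week", "response"] + [_lag_col(t) for t in lag_spec.lags]
    table = pd.DataFrame(rows, columns=cols)
    for key, n in drop.items():
        if n:
            logger.info("build_dataset dropped %d rows (%s)", n, key)
    return RegressionDataset(table=table, lag_spec=lag_spec, drop_counts=drop)
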