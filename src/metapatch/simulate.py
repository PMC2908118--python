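"""Stochastic metapopulation simulation and occupancy statistics.

Runs the noisy Nicholson-Bailey map (see :mod:`metapatch.nbmodel`) on a small
patch lattice, with lognormal mean-one environmental noise applied to host
recruitment, independently across patches and time steps. A Ricker-logistic
host-only variant serves as the parasitoid-free null model: its carrying
capacity is set to the host equilibrium of the host-parasitoid system, so the
two models fluctuate around the same abundance and differ only in the
regulating mechanism (delayed trophic regulation vs. direct intraspecific
competition).

The study protocol is 1000 time steps with the first 500 discarded as
burn-in, patches initialised at 100 hosts and 100 parasitoids, 100 replicates
per dispersal scenario.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .lattice import LatticeTopology, pair_topology
from .nbmodel import (
    EXTINCTION_FLOOR,
    MetapopState,
    NBParams,
    NumericalOverflowError,
    _local_update,
    nb_equilibrium,
)

__all__ = [
    "SimulationRun",
    "ThresholdStats",
    "simulate",
    "logistic_sim",
    "host_correlation",
    "correlation_surface",
    "threshold_stats",
    "compare_groups",
    "replicate_rng",
]


def replicate_rng(seed: int, rep: int) -> np.random.Generator:
    """Deterministic child generator for replicate ``rep`` of a run seeded
    with ``seed``: ``PCG64(SeedSequence((seed, rep)))``."""
    return np.random.default_rng(np.random.SeedSequence((seed, rep)))


def noise_draws(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    """Mean-one lognormal noise multipliers: log-sd sigma, log-mean -sigma^2/2."""
    if sigma == 0.0:
        return np.ones(size)
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


@dataclass
class SimulationRun:
    """One replicate trajectory.

    ``H`` and ``P`` have shape (n_steps, n_patches) and record the state
    after steps 1..n_steps; the initial state is kept separately. The
    analysis window excludes the first ``burn_in`` steps.
    """

    params: object
    topology: LatticeTopology
    H: np.ndarray
    P: np.ndarray
    burn_in: int
    seed: int
    replicate: int = 0
    H0: np.ndarray | None = None
    P0: np.ndarray | None = None

    @property
    def n_steps(self) -> int:
        return self.H.shape[0]

    @property
    def retained_H(self) -> np.ndarray:
        """Host trajectory after discarding the burn-in (steps burn_in+1..n)."""
        return self.H[self.burn_in :]

    @property
    def retained_P(self) -> np.ndarray:
        return self.P[self.burn_in :]


def _run_one(
    params: NBParams,
    topology: LatticeTopology,
    n_steps: int,
    init_H: np.ndarray,
    init_P: np.ndarray,
    rng: np.random.Generator,
    replicate: int,
) -> tuple[np.ndarray, np.ndarray]:
    n_patches = topology.n_patches
    eps = noise_draws(rng, params.sigma, (n_steps, n_patches))
    mix = topology.mixing_matrix
    H = np.empty((n_steps, n_patches))
    P = np.empty((n_steps, n_patches))
    h, p = init_H.copy(), init_P.copy()
    for t in range(n_steps):
        h, p = _local_update(h, p, params, eps[t])
        if params.dH > 0:
            h = (1.0 - params.dH) * h + params.dH * (h @ mix)
        if params.dP > 0:
            p = (1.0 - params.dP) * p + params.dP * (p @ mix)
        if not (np.all(np.isfinite(h)) and np.all(np.isfinite(p))):
            bad = np.where(~np.isfinite(h) | ~np.isfinite(p))[0][0]
            raise NumericalOverflowError(
                f"non-finite abundance in replicate {replicate}, patch {bad}, step {t + 1}"
            )
        h[h < EXTINCTION_FLOOR] = 0.0
        p[p < EXTINCTION_FLOOR] = 0.0
        H[t] = h
        P[t] = p
    return H, P


def simulate(
    params: NBParams,
    topology: LatticeTopology | None = None,
    n_steps: int = 1000,
    burn_in: int = 500,
    n_reps: int = 1,
    seed: int = 0,
    init: MetapopState | None = None,
) -> list[SimulationRun]:
    """Simulate ``n_reps`` independent replicates of the stochastic model.

    Replicate r draws its noise from a generator seeded by the deterministic
    child seed ``SeedSequence((seed, r))``, so any replicate can be
    reproduced in isolation and the set is invariant to execution order.
    """
    if topology is None:
        topology = pair_topology()
    if not n_steps > burn_in >= 0:
        raise ValueError("need n_steps > burn_in >= 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if init is None:
        init = MetapopState(
            H=np.full(topology.n_patches, 100.0),
            P=np.full(topology.n_patches, 100.0),
        )
    if init.H.size != topology.n_patches:
        raise ValueError("initial state does not match topology")

    runs = []
    for r in range(n_reps):
        rng = replicate_rng(seed, r)
        H, P = _run_one(params, topology, n_steps, init.H, init.P, rng, r)
        runs.append(
            SimulationRun(
                params=params,
                topology=topology,
                H=H,
                P=P,
                burn_in=burn_in,
                seed=seed,
                replicate=r,
                H0=init.H.copy(),
                P0=init.P.copy(),
            )
        )
    return runs


@dataclass(frozen=True)
class LogisticParams:
    """Ricker-logistic host-only null model parameters."""

    r_growth: float
    K: float
    sigma: float
    dH: float

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("carrying capacity K must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.dH <= 1.0:
            raise ValueError("dH must be in [0, 1]")


def logistic_sim(
    r_growth: float = 1.967,
    K: float | None = None,
    sigma: float = 0.1,
    dH: float = 0.0,
    topology: LatticeTopology | None = None,
    n_steps: int = 1000,
    burn_in: int = 500,
    n_reps: int = 1,
    seed: int = 0,
    init_H: np.ndarray | None = None,
    nb_params_for_K: NBParams | None = None,
) -> list[SimulationRun]:
    """Host-only Ricker-logistic simulation (no parasitoids).

    Per patch, ``H' = H * exp(r_growth * (1 - H/K)) * eps`` followed by host
    dispersal. By default the carrying capacity K is the host equilibrium of
    the noise-free host-parasitoid model (``nb_params_for_K``, default study
    parameters), matching the protocol of comparing the two regulation modes
    at equal equilibrium abundance. The default r_growth = 1.967 matches the
    damping strength of the host-parasitoid map (|1 - r| equals its spectral
    radius 0.967), so the two regulation modes also damp perturbations at the
    same rate.
    """
    if topology is None:
        topology = pair_topology()
    if K is None:
        H_star, _ = nb_equilibrium(nb_params_for_K or NBParams(sigma=sigma))
        K = H_star
    lp = LogisticParams(r_growth=r_growth, K=K, sigma=sigma, dH=dH)
    if init_H is None:
        init_H = np.full(topology.n_patches, float(K))
    init_H = np.asarray(init_H, dtype=float)
    mix = topology.mixing_matrix

    runs = []
    for r in range(n_reps):
        rng = replicate_rng(seed, r)
        eps = noise_draws(rng, sigma, (n_steps, topology.n_patches))
        H = np.empty((n_steps, topology.n_patches))
        h = init_H.copy()
        for t in range(n_steps):
            h = h * np.exp(r_growth * (1.0 - h / K)) * eps[t]
            if dH > 0:
                h = (1.0 - dH) * h + dH * (h @ mix)
            if not np.all(np.isfinite(h)):
                bad = int(np.where(~np.isfinite(h))[0][0])
                raise NumericalOverflowError(
                    f"non-finite abundance in replicate {r}, patch {bad}, step {t + 1}"
                )
            h[h < EXTINCTION_FLOOR] = 0.0
            H[t] = h
        runs.append(
            SimulationRun(
                params=lp,
                topology=topology,
                H=H,
                P=np.zeros_like(H),
                burn_in=burn_in,
                seed=seed,
                replicate=r,
                H0=init_H.copy(),
            )
        )
    return runs


def host_correlation(run: SimulationRun, patch_pair: tuple[int, int] = (0, 1)) -> float:
    """Pearson correlation of host abundances between two patches over the
    retained (post burn-in) window; NaN with a warning if either series is
    constant."""
    i, j = patch_pair
    x = run.retained_H[:, i]
    y = run.retained_H[:, j]
    if x.size < 3:
        raise ValueError("retained window must contain at least 3 steps")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        warnings.warn(
            f"constant host series in patch pair {patch_pair}; correlation undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class ThresholdStats:
    """Sub-threshold occupancy statistics for one run.

    ``single_patch_events`` counts retained steps on which exactly one patch's
    host abundance is below the threshold. ``regional_event_time`` is the
    first step (1-based, absolute) at which every patch is simultaneously
    below the threshold, or None if that never happens in the retained
    window. ``persistence_time`` measures steps from the end of burn-in to
    the regional event, censored at the retained window length when no event
    occurs.
    """

    threshold: float
    single_patch_events: int
    regional_event_time: int | None
    persistence_time: int
    mean_host_abundance: np.ndarray


def threshold_stats(
    runs: Sequence[SimulationRun], threshold: float
) -> tuple[list[ThresholdStats], dict]:
    """Per-run occupancy statistics plus a group summary (means across runs)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    out = []
    for run in runs:
        H = run.retained_H
        below = H < threshold
        n_below = below.sum(axis=1)
        single = int((n_below == 1).sum())
        all_below = np.where(n_below == H.shape[1])[0]
        if all_below.size:
            # absolute 1-based step index of the regional event
            event = int(all_below[0]) + run.burn_in + 1
            persistence = int(all_below[0]) + 1
        else:
            event = None
            persistence = H.shape[0]
        out.append(
            ThresholdStats(
                threshold=threshold,
                single_patch_events=single,
                regional_event_time=event,
                persistence_time=persistence,
                mean_host_abundance=H.mean(axis=0),
            )
        )
    summary = {
        "threshold": threshold,
        "n_runs": len(out),
        "mean_single_patch_events": float(np.mean([s.single_patch_events for s in out])),
        "mean_persistence_time": float(np.mean([s.persistence_time for s in out])),
        "prop_regional_events": float(
            np.mean([s.regional_event_time is not None for s in out])
        ),
        "mean_host_abundance": float(
            np.mean([s.mean_host_abundance.mean() for s in out])
        ),
    }
    return out, summary


def correlation_surface(
    params: NBParams,
    dH_grid: Sequence[float],
    dP_grid: Sequence[float],
    n_reps: int = 100,
    seed: int = 0,
    topology: LatticeTopology | None = None,
    n_steps: int = 1000,
    burn_in: int = 500,
):
    """Mean between-patch host correlation over a dispersal-proportion grid.

    For each (dH, dP) cell, two-patch replicates are simulated and the
    patch-pair host correlation averaged across replicates. Also reports the
    mean relative asymmetry in patch mean abundance, which diagnoses
    source-sink behaviour (one patch suppressed, sustained by immigration).

    Returns a tidy DataFrame with one row per grid cell.
    """
    import pandas as pd

    if topology is None:
        topology = pair_topology()
    rows = []
    for dH in dH_grid:
        for dP in dP_grid:
            p = params.replace(dH=float(dH), dP=float(dP))
            runs = simulate(
                p, topology, n_steps=n_steps, burn_in=burn_in, n_reps=n_reps, seed=seed
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                corrs = np.array([host_correlation(run) for run in runs])
            means = np.array([run.retained_H.mean(axis=0) for run in runs])
            denom = means.mean(axis=1)
            asym = np.abs(means[:, 0] - means[:, 1]) / np.where(denom > 0, denom, np.nan)
            rows.append(
                {
                    "dH": float(dH),
                    "dP": float(dP),
                    "mean_correlation": float(np.nanmean(corrs)),
                    "se_correlation": float(
                        np.nanstd(corrs, ddof=1) / np.sqrt(np.sum(~np.isnan(corrs)))
                    ),
                    "mean_abundance_patch0": float(means[:, 0].mean()),
                    "mean_abundance_patch1": float(means[:, 1].mean()),
                    "mean_relative_asymmetry": float(np.nanmean(asym)),
                    "n_reps": n_reps,
                }
            )
    return pd.DataFrame(rows)


def compare_groups(
    counts_A: Sequence[float], counts_B: Sequence[float]
) -> tuple[float, float]:
    """Log ratio of group means with a delta-method standard error.

    Positive estimates mean group A exceeds group B. Used to compare
    occupancy statistics (event counts, persistence times) between
    simulation arms.
    """
    a = np.asarray(counts_A, dtype=float)
    b = np.asarray(counts_B, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    ma, mb = a.mean(), b.mean()
    if mb == 0.0 or ma == 0.0:
        warnings.warn("zero group mean; log ratio undefined", RuntimeWarning, stacklevel=2)
        return float("nan"), float("nan")
    est = float(np.log(ma / mb))
    var_a = a.var(ddof=1) / a.size if a.size > 1 else 0.0
    var_b = b.var(ddof=1) / b.size if b.size > 1 else 0.0
    se = float(np.sqrt(var_a / ma**2 + var_b / mb**2))
    return est, se
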