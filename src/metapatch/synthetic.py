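"""Synthetic microcosm-like metapopulation datasets.

Two generators produce weekly adult-count series with the statistical
structure the inference modules assume, emulating four-patch square-lattice
bruchid/parasitoid microcosms (4 replicates, 1-2 host species plus a
parasitoid, constant vs. Poisson weekly resource renewal):

* :func:`generate_mechanistic` runs the stochastic Nicholson-Bailey update
  rules on the lattice, with host fecundity scaled each week by resource
  delivery, an optional second host coupled only through the shared
  parasitoid (apparent competition), and Poisson sampling converting
  continuous abundances to integer counts.
* :func:`generate_from_ricker` simulates the hierarchical time-lagged Ricker
  model forward, so that the inference machinery can be validated against
  known ("truth") parameter values.

Every generated dataset carries a :class:`GeneratorTruth` recording exactly
the parameters used.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .lattice import disperse, square4_topology
from .nbmodel import EXTINCTION_FLOOR, NBParams
from .ricker import boxcox
from .series import PatchTimeSeries

__all__ = [
    "ExperimentConfig",
    "GeneratorTruth",
    "RickerTruth",
    "generate_mechanistic",
    "generate_from_ricker",
]

TREATMENTS = ("a", "b", "c", "d")

HOST_MAIN = "C_maculatus"
HOST_ALT = "C_chinensis"
PARASITOID = "A_calandrae"


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one simulated microcosm experiment.

    The treatment letter sets the weekly bean renewal regime: 'a' constant
    three beans per patch, 'b' Poisson with mean three, 'c' constant with the
    main host (C. maculatus) on two beans and the alternative host on four,
    'd' the 'c' means delivered Poisson.
    """

    assemblage: str = "two_species"  # or "apparent_competition"
    treatment: str = "a"
    n_replicates: int = 4
    n_weeks: int = 80
    demographic_noise: bool = True
    seed: int = 0
    params: NBParams = field(default_factory=lambda: NBParams(dH=0.05, dP=0.3))
    R_alt: float = 2.718  # fecundity of the alternative host

    def __post_init__(self) -> None:
        if self.assemblage not in ("two_species", "apparent_competition"):
            raise ValueError(f"unknown assemblage {self.assemblage!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}")
        if self.n_replicates < 1 or self.n_weeks < 2:
            raise ValueError("need n_replicates >= 1 and n_weeks >= 2")

    @property
    def stochastic_renewal(self) -> bool:
        return self.treatment in ("b", "d")

    @property
    def renewal_means(self) -> dict[str, float]:
        """Long-run average beans per patch per week for each host species."""
        if self.treatment in ("a", "b"):
            means = {HOST_MAIN: 3.0, HOST_ALT: 3.0}
        else:  # 'c', 'd': 4:2 chinensis:maculatus, favouring the inferior host
            means = {HOST_MAIN: 2.0, HOST_ALT: 4.0}
        if self.assemblage == "two_species":
            return {HOST_MAIN: means[HOST_MAIN]}
        return means


@dataclass
class GeneratorTruth:
    """Parameters actually used to generate a dataset (serialized with it)."""

    kind: str
    params: dict

    def to_json(self, path=None) -> str:
        text = json.dumps({"kind": self.kind, "params": self.params}, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "GeneratorTruth":
        d = json.loads(text)
        return cls(kind=d["kind"], params=d["params"])


@dataclass(frozen=True)
class RickerTruth:
    """Generative parameter set for the hierarchical lagged-Ricker process."""

    alpha: float
    betas: tuple[float, ...]
    lags: tuple[float, ...]
    thetas: tuple[float, ...]
    rho: float
    sigma_replicate: float
    sigma_patch: float
    sigma_error: float

    def __post_init__(self) -> None:
        if len(self.betas) != len(self.lags) or len(self.thetas) != len(self.lags):
            raise ValueError("betas, lags and thetas must have equal length")
        for s in (self.sigma_replicate, self.sigma_patch, self.sigma_error):
            if s < 0:
                raise ValueError("variance components must be >= 0")

    def fixed_point(self) -> float:
        """Abundance N* where alpha + sum_k beta_k * boxcox(N*, theta_k) = 0."""
        from scipy.optimize import brentq

        def f(n: float) -> float:
            return self.alpha + sum(
                b * boxcox(n, th) for b, th in zip(self.betas, self.thetas)
            )

        return float(brentq(f, 1e-6, 1e9))

    def to_truth(self) -> GeneratorTruth:
        return GeneratorTruth(kind="ricker", params=asdict(self))


def _check_stationary(truth: RickerTruth, threshold: float = 1.0) -> None:
    """Reject explosive parameter sets: the log-abundance linearization about
    the fixed point must not amplify perturbations (|1 + sum elasticities|
    must stay below ``threshold`` + 1 margin)."""
    n_star = truth.fixed_point()
    elastic = sum(
        b * n_star**th for b, th in zip(truth.betas, truth.thetas)
    )  # d r / d ln N at N*
    if abs(1.0 + elastic) >= 1.0 + threshold:
        raise ValueError(
            f"explosive parameter set: |1 + sum(beta_k * N*^theta_k)| = "
            f"{abs(1.0 + elastic):.3f} at N* = {n_star:.3f}"
        )


def _exchangeable_chol(n: int, rho: float) -> np.ndarray:
    """Cholesky factor of the unit-variance exchangeable correlation matrix."""
    if n > 1 and not (-1.0 / (n - 1) < rho < 1.0):
        raise ValueError(f"rho must lie in (-1/{n - 1}, 1) for {n} patches")
    corr = np.full((n, n), rho)
    np.fill_diagonal(corr, 1.0)
    return np.linalg.cholesky(corr)


def _interp_half(history: np.ndarray, t_index: float) -> np.ndarray:
    """Value of per-patch history at a (possibly half-integer) week offset."""
    lo = int(np.floor(t_index))
    frac = t_index - lo
    if frac == 0.0:
        return history[lo]
    return (1.0 - frac) * history[lo] + frac * history[lo + 1]


def generate_from_ricker(
    truth: RickerTruth,
    n_replicates: int = 4,
    n_patches: int = 4,
    n_weeks: int = 60,
    seed: int = 0,
    species: str = HOST_MAIN,
    treatment: str = "synthetic",
    round_counts: bool = True,
) -> tuple[list[PatchTimeSeries], GeneratorTruth]:
    """Simulate the hierarchical lagged-Ricker process forward.

    Log-abundance in each patch grows by r_t = alpha + sum_k beta_k *
    boxcox(N at t - tau_k, theta_k) + replicate deviation + patch deviation
    + residual, where the residuals of the patches of one replicate in the
    same week are multivariate normal with exchangeable correlation rho.
    Half-integer lags read linearly interpolated abundances. Series start at
    the deterministic fixed point; counts are rounded to integers on output.
    """
    _check_stationary(truth)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 9001)))
    n_star = truth.fixed_point()
    max_lag = max(truth.lags)
    chol = _exchangeable_chol(n_patches, truth.rho)

    out = []
    for j in range(n_replicates):
        u_rep = rng.normal(0.0, truth.sigma_replicate)
        u_patch = rng.normal(0.0, truth.sigma_patch, size=n_patches)
        n_hist = np.full((n_weeks, n_patches), float(n_star))
        start = int(np.ceil(max_lag))
        eps = (chol @ rng.normal(size=(n_patches, n_weeks))).T * truth.sigma_error
        for t in range(start, n_weeks - 1):
            r_t = np.full(n_patches, truth.alpha) + u_rep + u_patch + eps[t]
            for b, tau, th in zip(truth.betas, truth.lags, truth.thetas):
                lagged = _interp_half(n_hist, t - tau)
                lagged = np.where(lagged > 0, lagged, lagged + 0.5)
                r_t += b * boxcox(lagged, th)
            n_hist[t + 1] = np.clip(n_hist[t] * np.exp(r_t), 0.0, 1e12)
        counts = np.rint(n_hist) if round_counts else n_hist
        for i in range(n_patches):
            out.append(
                PatchTimeSeries(
                    replicate=f"rep{j + 1}",
                    patch=f"patch{i + 1}",
                    species=species,
                    treatment=treatment,
                    weeks=np.arange(1.0, n_weeks + 1.0),
                    counts=counts[:, i],
                )
            )
    meta = truth.to_truth()
    meta.params.update(
        {"n_replicates": n_replicates, "n_patches": n_patches, "n_weeks": n_weeks,
         "seed": seed, "fixed_point": n_star}
    )
    return out, meta


def draw_weekly_beans(
    rng: np.random.Generator, mean: float, stochastic: bool, size
) -> np.ndarray:
    """Weekly bean delivery per patch: constant, or independent Poisson with
    the same long-run mean under stochastic renewal."""
    if stochastic:
        return rng.poisson(mean, size=size).astype(float)
    return np.full(size, float(mean))


def generate_mechanistic(
    config: ExperimentConfig,
) -> tuple[list[PatchTimeSeries], GeneratorTruth]:
    """Microcosm-like dataset from the mechanistic lattice model.

    Runs the stochastic Nicholson-Bailey update rules on the four-patch
    square lattice. Host fecundity is scaled each week by (beans delivered /
    mean beans), so resource renewal acts on recruitment; under stochastic
    renewal the weekly bean count is Poisson. In the apparent-competition
    assemblage a second host with its own fecundity shares the parasitoid
    (attacks partitioned by relative host availability) but does not interact
    with the first host directly. Abundances are reported as integer counts:
    Poisson sampling around the continuous value when ``demographic_noise``
    is on, plain rounding otherwise.
    """
    topo = square4_topology()
    p = config.params
    hosts = list(config.renewal_means)
    renewal = config.renewal_means
    fecundity = {HOST_MAIN: p.R, HOST_ALT: config.R_alt}

    # noise-free single-patch equilibrium of the one-host system as the
    # initial density for hosts and the parasitoid
    from .nbmodel import nb_equilibrium

    h0, p0 = nb_equilibrium(p)

    out = []
    for j in range(config.n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, j)))
        H = {sp: np.full(topo.n_patches, h0) for sp in hosts}
        P = np.full(topo.n_patches, p0)
        rec_H = {sp: [H[sp].copy()] for sp in hosts}
        rec_P = [P.copy()]
        for _ in range(config.n_weeks - 1):
            # weekly resource delivery scales host fecundity
            mult = {}
            for sp in hosts:
                mean_beans = renewal[sp]
                beans = draw_weekly_beans(
                    rng, mean_beans, config.stochastic_renewal, topo.n_patches
                )
                mult[sp] = beans / mean_beans
            # parasitoid pressure partitioned by relative host availability
            total_h = sum(H[sp] for sp in hosts)
            new_P = np.zeros(topo.n_patches)
            new_H = {}
            for sp in hosts:
                with np.errstate(invalid="ignore", divide="ignore"):
                    share = np.where(total_h > 0, H[sp] / np.where(total_h > 0, total_h, 1.0), 0.0)
                p_eff = P * share
                eps = (
                    rng.lognormal(-0.5 * p.sigma**2, p.sigma, size=topo.n_patches)
                    if p.sigma > 0
                    else np.ones(topo.n_patches)
                )
                escape = np.exp(-p.a * p_eff)
                new_H[sp] = fecundity[sp] * mult[sp] * eps * H[sp] * escape + p.S * H[sp]
                new_P += p.c * H[sp] * (1.0 - escape)
            for sp in hosts:
                h = disperse(new_H[sp], p.dH, topo)
                h[h < EXTINCTION_FLOOR] = 0.0
                H[sp] = h
            P = disperse(new_P, p.dP, topo)
            P[P < EXTINCTION_FLOOR] = 0.0
            for sp in hosts:
                rec_H[sp].append(H[sp].copy())
            rec_P.append(P.copy())

        weeks = np.arange(1.0, config.n_weeks + 1.0)
        arrays = {sp: np.array(rec_H[sp]) for sp in hosts}
        arrays[PARASITOID] = np.array(rec_P)
        for sp, arr in arrays.items():
            counts = (
                rng.poisson(arr).astype(float)
                if config.demographic_noise
                else np.rint(arr)
            )
            for i in range(topo.n_patches):
                out.append(
                    PatchTimeSeries(
                        replicate=f"rep{j + 1}",
                        patch=f"patch{i + 1}",
                        species=sp,
                        treatment=config.treatment,
                        weeks=weeks,
                        counts=counts[:, i],
                    )
                )
    truth = GeneratorTruth(
        kind="mechanistic",
        params={
            "assemblage": config.assemblage,
            "treatment": config.treatment,
            "n_replicates": config.n_replicates,
            "n_weeks": config.n_weeks,
            "demographic_noise": config.demographic_noise,
            "seed": config.seed,
            "renewal_means": renewal,
            "R": p.R, "R_alt": config.R_alt if len(hosts) > 1 else None,
            "a": p.a, "S": p.S, "c": p.c, "sigma": p.sigma,
            "dH": p.dH, "dP": p.dP,
            "init_host": h0, "init_parasitoid": p0,
        },
    )
    return out, truth
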