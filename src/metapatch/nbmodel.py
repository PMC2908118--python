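"""Nicholson-Bailey host-parasitoid local dynamics with host carry-over.

The local (single patch) map is the classic discrete-time Nicholson-Bailey
system, stabilised by letting a fixed proportion S of hosts escape parasitism
and survive to the next time step (a density-independent refuge in time,
independent of host self-regulation):

    H' = R * eps * H * exp(-a * P) + S * H
    P' = c * H * (1 - exp(-a * P))

where R is host fecundity, a the parasitoid attack rate, c the conversion
efficiency of parasitised hosts into parasitoids, and eps a multiplicative,
mean-one environmental noise term on host population growth. Without the
carry-over term (S = 0) the nontrivial equilibrium is unstable (diverging
oscillations); a sufficiently large S produces damped oscillations, so that
abundance fluctuations in the stochastic model are noise-driven rather than
deterministic cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .lattice import LatticeTopology, disperse

__all__ = [
    "NBParams",
    "MetapopState",
    "nb_step",
    "nb_equilibrium",
    "local_stability",
    "nb_jacobian",
]

#: Abundances below this are clamped to zero (extinction is absorbing).
EXTINCTION_FLOOR = 1e-12


@dataclass(frozen=True)
class NBParams:
    """Parameters of the stochastic Nicholson-Bailey metapopulation model.

    Attributes
    ----------
    R:
        Host fecundity per time step (> 0). The study value is e = 2.718.
    a:
        Parasitoid attack rate per parasitoid per time step (> 0).
    S:
        Proportion of hosts escaping parasitism and surviving to the next
        step (0 <= S < 1). The stabilising carry-over mechanism.
    c:
        Parasitoid conversion efficiency (> 0), default 1.
    sigma:
        Standard deviation of log environmental noise on host growth (>= 0).
        Noise multipliers are lognormal with mean one.
    dH, dP:
        Proportions of hosts / parasitoids dispersing per time step, in [0, 1].
    """

    R: float = 2.718
    a: float = 0.1
    S: float = 0.7
    c: float = 1.0
    sigma: float = 0.1
    dH: float = 0.0
    dP: float = 0.0

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise ValueError(f"host fecundity R must be > 0, got {self.R}")
        if not self.a > 0:
            raise ValueError(f"attack rate a must be > 0, got {self.a}")
        if not 0.0 <= self.S < 1.0:
            raise ValueError(f"host survival S must satisfy 0 <= S < 1, got {self.S}")
        if not self.c > 0:
            raise ValueError(f"conversion efficiency c must be > 0, got {self.c}")
        if self.sigma < 0:
            raise ValueError(f"noise scale sigma must be >= 0, got {self.sigma}")
        for name in ("dH", "dP"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"dispersal proportion {name} must be in [0, 1], got {v}")

    def replace(self, **kwargs) -> "NBParams":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass
class MetapopState:
    """Host and parasitoid abundances on each patch at one time step."""

    H: np.ndarray
    P: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.H = np.atleast_1d(np.asarray(self.H, dtype=float))
        self.P = np.atleast_1d(np.asarray(self.P, dtype=float))
        if self.H.shape != self.P.shape:
            raise ValueError("H and P must have the same number of patches")
        if self.H.size < 1:
            raise ValueError("at least one patch is required")
        if not (np.all(np.isfinite(self.H)) and np.all(np.isfinite(self.P))):
            raise ValueError("abundances must be finite")
        if (self.H < 0).any() or (self.P < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.t < 0:
            raise ValueError("time index must be >= 0")


class NumericalOverflowError(FloatingPointError):
    """Raised when the map produces a non-finite abundance."""


def _local_update(
    H: np.ndarray, P: np.ndarray, params: NBParams, eps: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    escape = np.exp(-params.a * P)
    H_new = params.R * eps * H * escape + params.S * H
    P_new = params.c * H * (1.0 - escape)
    return H_new, P_new


def nb_step(
    state: MetapopState,
    params: NBParams,
    topology: LatticeTopology,
    noise_draws: np.ndarray,
) -> MetapopState:
    """Advance the metapopulation one time step.

    Local host-parasitoid dynamics act first on every patch, then fixed
    proportions dH of hosts and dP of parasitoids disperse simultaneously
    along the lattice edges (equal split among neighbours, so total
    abundance is conserved by dispersal).

    Parameters
    ----------
    noise_draws:
        One strictly positive multiplier per patch, applied to host
        recruitment (not the surviving fraction S*H).
    """
    eps = np.asarray(noise_draws, dtype=float)
    if eps.shape != state.H.shape:
        raise ValueError("need exactly one noise draw per patch")
    if (eps <= 0).any():
        raise ValueError("noise multipliers must be strictly positive")

    H_new, P_new = _local_update(state.H, state.P, params, eps)
    H_new = disperse(H_new, params.dH, topology)
    P_new = disperse(P_new, params.dP, topology)

    for label, arr in (("host", H_new), ("parasitoid", P_new)):
        bad = ~np.isfinite(arr)
        if bad.any():
            patch = int(np.where(bad)[0][0])
            raise NumericalOverflowError(
                f"non-finite {label} abundance in patch {patch} at step {state.t + 1}"
            )
    H_new[H_new < EXTINCTION_FLOOR] = 0.0
    P_new[P_new < EXTINCTION_FLOOR] = 0.0
    return MetapopState(H=H_new, P=P_new, t=state.t + 1)


def nb_equilibrium(params: NBParams) -> tuple[float, float]:
    """Locate the nontrivial fixed point of the noise-free single-patch map.

    Solves (H, P) = map(H, P) numerically. A positive fixed point requires
    growth above replacement, R > 1 - S; otherwise a ValueError is raised.
    The returned point satisfies one deterministic step to a relative
    residual below 1e-9.
    """
    if params.R <= 1.0 - params.S:
        raise ValueError(
            f"no positive equilibrium: need R > 1 - S, got R={params.R}, S={params.S}"
        )

    # At the host equilibrium R*exp(-aP) + S = 1, giving a starting guess
    # for the 2-d root solve.
    p0 = np.log(params.R / (1.0 - params.S)) / params.a
    h0 = max(p0, 1.0)

    def residual(z: np.ndarray) -> np.ndarray:
        H, P = z
        Hn, Pn = _local_update(np.array([H]), np.array([P]), params, np.array([1.0]))
        return np.array([Hn[0] - H, Pn[0] - P])

    sol = optimize.root(residual, x0=np.array([h0, p0]), tol=1e-13)
    if not sol.success or (sol.x <= 0).any():
        raise ValueError(f"equilibrium search failed: {sol.message}")
    H_star, P_star = float(sol.x[0]), float(sol.x[1])
    res = np.abs(residual(sol.x)) / max(H_star, P_star)
    if res.max() > 1e-9:
        raise ValueError("equilibrium residual exceeds 1e-9 relative")
    return H_star, P_star


def nb_jacobian(params: NBParams, H: float, P: float) -> np.ndarray:
    """Jacobian of the noise-free single-patch map at (H, P)."""
    escape = np.exp(-params.a * P)
    return np.array(
        [
            [params.R * escape + params.S, -params.a * params.R * H * escape],
            [params.c * (1.0 - escape), params.a * params.c * H * escape],
        ]
    )


def local_stability(params: NBParams) -> float:
    """Spectral radius of the map's Jacobian at the nontrivial equilibrium.

    A value below 1 indicates damped oscillations: perturbations decay and
    sustained fluctuations in the stochastic model are purely noise-driven.
    """
    H_star, P_star = nb_equilibrium(params)
    eigvals = np.linalg.eigvals(nb_jacobian(params, H_star, P_star))
    return float(np.max(np.abs(eigvals)))
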