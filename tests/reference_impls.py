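"""Independent reference implementations used as test oracles.

These deliberately avoid the production code paths: the simulator reference
uses explicit Python loops over patches, and the likelihood reference builds
each covariance matrix entry by entry and evaluates the density with scipy's
multivariate normal.
"""

import numpy as np
from scipy.stats import multivariate_normal

from metapatch.simulate import noise_draws, replicate_rng


def reference_simulate(params, topology, n_steps, init_H, init_P, seed, rep):
    """Naive step-by-step simulator: pure-Python loops over patches.

    Draws its noise identically to the production simulator (one vector per
    step from the replicate child generator) but computes the local dynamics
    and dispersal with explicit loops.
    """
    rng = replicate_rng(seed, rep)
    n = topology.n_patches
    H = [float(x) for x in init_H]
    P = [float(x) for x in init_P]
    out_H, out_P = [], []
    mix = topology.mixing_matrix
    for t in range(n_steps):
        eps = noise_draws(rng, params.sigma, n)
        newH, newP = [], []
        for i in range(n):
            escape = float(np.exp(-params.a * P[i]))
            newH.append(params.R * float(eps[i]) * H[i] * escape + params.S * H[i])
            newP.append(params.c * H[i] * (1.0 - escape))
        for values, d in ((newH, params.dH), (newP, params.dP)):
            if d > 0:
                staying = []
                for j in range(n):
                    inflow = 0.0
                    for i in range(n):
                        inflow += values[i] * mix[i, j]
                    staying.append((1.0 - d) * values[j] + d * inflow)
                values[:] = staying
        for i in range(n):
            if newH[i] < 1e-12:
                newH[i] = 0.0
            if newP[i] < 1e-12:
                newP[i] = 0.0
        H, P = newH, newP
        out_H.append(list(H))
        out_P.append(list(P))
    return np.array(out_H), np.array(out_P)


def brute_force_loglike(table, beta, s_rep, s_patch, rho, s_err):
    """Entry-by-entry covariance construction plus scipy's MVN density."""
    ll = 0.0
    for _, grp in table.groupby("replicate"):
        X = np.column_stack([np.ones(len(grp)), grp["lag_1"].to_numpy()])
        e = grp["response"].to_numpy() - X @ beta
        pa, wk = grp["patch"].to_numpy(), grp["week"].to_numpy()
        n = len(grp)
        cov = np.empty((n, n))
        for a in range(n):
            for b in range(n):
                v = s_rep**2
                if pa[a] == pa[b]:
                    v += s_patch**2
                if a == b:
                    v += s_err**2
                elif wk[a] == wk[b] and pa[a] != pa[b]:
                    v += rho * s_err**2
                cov[a, b] = v
        ll += multivariate_normal.logpdf(e, mean=np.zeros(n), cov=cov)
    return ll
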