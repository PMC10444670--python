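"""Independent brute-force oracles for the likelihood maximizations.

These deliberately avoid the package's Newton machinery: a coarse grid
search over the parameter box followed by a Nelder-Mead polish of the raw
multinomial log-likelihood, written directly from its definition.
"""

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp


def loglik_direct(theta, X, counts):
    """Σ n_y x_y'θ − n·ln Σ_B exp(x_y'θ), straight from the definition."""
    eta = X @ np.asarray(theta, dtype=float)
    return float(counts @ eta - counts.sum() * logsumexp(eta))


def grid_polish(X, counts, lo=-3.0, hi=3.0, step=1.0):
    """Coarse grid + Nelder-Mead polish maximizer (e <= 4 intended)."""
    e = X.shape[1]
    if e == 0:
        return np.empty(0), loglik_direct(np.empty(0), X, counts)
    grid = np.arange(lo, hi + 1e-9, step)
    best, best_ll = None, -np.inf
    for point in itertools.product(grid, repeat=e):
        ll = loglik_direct(np.array(point), X, counts)
        if ll > best_ll:
            best, best_ll = np.array(point), ll
    res = minimize(lambda t: -loglik_direct(t, X, counts), best,
                   method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    return res.x, -res.fun


def oracle_groupwise(Xs, counts_list):
    """Maximize Eq.-style per-group likelihoods independently; returns
    (thetas, total model loglik Σ_p ln L_p)."""
    thetas, total = [], 0.0
    for X, c in zip(Xs, counts_list):
        th, ll = grid_polish(X, c)
        thetas.append(th)
        total += ll
    return thetas, total


def oracle_common(Xs, counts_list):
    """Maximize the shared-θ total likelihood over the groups."""
    e = Xs[0].shape[1]

    def neg(th):
        return -sum(loglik_direct(th, X, c) for X, c in zip(Xs, counts_list))

    grid = np.arange(-3.0, 3.0 + 1e-9, 1.0)
    best, best_v = None, np.inf
    for point in itertools.product(grid, repeat=e):
        v = neg(np.array(point))
        if v < best_v:
            best, best_v = np.array(point), v
    res = minimize(neg, best, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    return res.x, -res.fun
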