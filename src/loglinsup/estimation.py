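"""Maximum likelihood estimation of log-linear subpopulation models.

The multinomial log-likelihood over a chosen support B is

    l(θ) = Σ_{y∈O} n_y f(y; θ) − n · ln κ_B(θ),   κ_B(θ) = Σ_{y∈B} exp f(y; θ),

where only the observed patterns O ⊆ B carry counts but every pattern of B
enters the normalizing constant κ_B — retaining zero-count patterns in B is
the entire point of support choice.  The primary maximizer is a damped
Newton iteration with analytic gradient and Hessian (the problem is concave
for any linear f); an equivalent Poisson log-linear route, ln μ_y = δ +
f(y; θ), is available for cross-checking and yields the same estimating
equations.

Aliased (rank-deficient) design columns on the bound support are detected
and dropped; all degrees-of-freedom bookkeeping downstream uses the
effective number of free parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .model_specs import ModelSpec
from .patterns import Partition, SupportSet

__all__ = [
    "FitResult",
    "GroupFit",
    "fit",
    "loglik_saturated",
    "loglik_value",
    "standard_errors",
    "fit_groupwise",
    "fit_common_theta",
    "SupportViolationError",
    "EmptyGroupError",
    "BoundaryError",
]


class SupportViolationError(ValueError):
    """An observed pattern is missing from the model support B."""


class EmptyGroupError(ValueError):
    """A partition group contains no observations; its likelihood is undefined."""


class BoundaryError(ValueError):
    """The MLE lies on the boundary (some saturated estimates at -inf)."""


# ---------------------------------------------------------------------------
# rank handling

def estimable_columns(X: np.ndarray, base: np.ndarray | None = None,
                      tol: float = 1e-8) -> np.ndarray:
    """Boolean mask of columns of X not aliased with ``base`` or each other.

    Greedy left-to-right Gram-Schmidt: a column is kept if its residual after
    projection on the span of the base columns and previously kept columns
    exceeds ``tol`` times its own norm.  Mirrors the first-wins aliasing of
    standard GLM software.
    """
    nrows = X.shape[0]
    basis: list = []
    if base is not None:
        for j in range(base.shape[1]):
            v = base[:, j].astype(float).copy()
            for b in basis:
                v -= (b @ v) * b
            nv = np.linalg.norm(v)
            if nv > tol:
                basis.append(v / nv)
    keep = np.zeros(X.shape[1], dtype=bool)
    for j in range(X.shape[1]):
        v = X[:, j].astype(float).copy()
        norm0 = np.linalg.norm(v)
        if norm0 == 0.0:
            continue
        for b in basis:
            v -= (b @ v) * b
        nv = np.linalg.norm(v)
        if nv > tol * max(norm0, 1.0):
            basis.append(v / nv)
            keep[j] = True
    return keep


# ---------------------------------------------------------------------------
# results

@dataclass
class FitResult:
    """Estimates and diagnostics of a subpopulation-model fit over B."""

    spec: ModelSpec
    support: SupportSet
    theta: np.ndarray            # length e; NaN at non-estimable positions
    se: np.ndarray               # length e; NaN where non-estimable
    estimable_mask: np.ndarray   # length e bool
    loglik: float                # multinomial log-likelihood at the MLE
    kappa: float                 # κ_B at the MLE
    delta: float                 # δ = ln(n / κ_B)
    n: int
    fitted_probs: dict           # pattern -> P̂(Y=y | B)
    converged: bool
    n_iter: int
    grad_norm: float
    method: str = "newton"

    @property
    def e_nominal(self) -> int:
        return self.spec.e

    @property
    def e_effective(self) -> int:
        return int(self.estimable_mask.sum())

    @property
    def theta_z(self) -> np.ndarray:
        """θ with zeros in the aliased positions (valid for prediction on B)."""
        t = self.theta.copy()
        t[~self.estimable_mask] = 0.0
        return t

    def prob_vector(self) -> np.ndarray:
        return np.array([self.fitted_probs[p] for p in self.support.patterns])

    def to_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "n": int(self.n),
            "loglik": float(self.loglik),
            "kappa": float(self.kappa),
            "delta": float(self.delta),
            "converged": bool(self.converged),
            "e_nominal": int(self.e_nominal),
            "e_effective": int(self.e_effective),
            "parameters": [
                {
                    "name": nm,
                    "estimate": None if np.isnan(th) else float(th),
                    "se": None if np.isnan(s) else float(s),
                    "estimable": bool(m),
                }
                for nm, th, s, m in zip(
                    self.spec.parameter_names, self.theta, self.se, self.estimable_mask
                )
            ],
        }


@dataclass
class GroupFit:
    """Fit of a partition-based generalization.

    ``kind == "groupwise"`` — independent per-group parameter vectors θ_p
    (first generalization); ``kind == "common"`` — a single θ shared across
    groups with group-specific intercepts δ_p (second generalization).  In
    both, the group probabilities have closed-form MLEs n_p / n, and

        loglik_total = Σ_p ln L̂_p + Σ_p n_p ln(n_p/n)        (groupwise)
        loglik_total = ln L̂_C  + Σ_p n_p ln(n_p/n)           (common)
    """

    kind: str
    partition: Partition
    spec: ModelSpec
    n: int
    n_p: list
    loglik_model: float          # Σ_p ln L̂_p, or ln L̂_C
    fits: list = field(default_factory=list)       # groupwise: per-group FitResult
    theta: np.ndarray | None = None                # common: shared estimate
    se: np.ndarray | None = None
    estimable_mask: np.ndarray | None = None
    deltas: list = field(default_factory=list)     # common: per-group intercepts
    fitted_probs: list = field(default_factory=list)  # common: per-group dicts
    converged: bool = True

    @property
    def g(self) -> int:
        return self.partition.g

    @property
    def pi(self) -> np.ndarray:
        return np.array(self.n_p, dtype=float) / self.n

    @property
    def loglik_groups(self) -> float:
        """Σ_p n_p ln(n_p/n), the maximized group-membership likelihood."""
        np_arr = np.array(self.n_p, dtype=float)
        return float(np.sum(np_arr * np.log(np_arr / self.n)))

    @property
    def loglik_total(self) -> float:
        return self.loglik_model + self.loglik_groups

    @property
    def e_effective(self) -> int:
        if self.kind == "groupwise":
            return int(sum(f.e_effective for f in self.fits))
        return int(self.estimable_mask.sum())


# ---------------------------------------------------------------------------
# core maximizer

def _neg_parts(theta, X, counts, n):
    eta = X @ theta
    lse = logsumexp(eta)
    ll = float(counts @ eta - n * lse)
    p = np.exp(eta - lse)
    return ll, p


def _newton(X, counts, n, *, gtol=1e-9, ltol=1e-12, maxit=500):
    """Damped Newton ascent of the multinomial log-likelihood.

    Returns (theta, loglik, probs, converged, iters, grad_norm).  Start at
    θ = 0 (the uniform distribution over B), a safe interior point.
    """
    m = X.shape[1]
    theta = np.zeros(m)
    ll, p = _neg_parts(theta, X, counts, n)
    grad = X.T @ counts - n * (X.T @ p)
    it = 0
    for it in range(1, maxit + 1):
        gnorm = float(np.max(np.abs(grad))) if m else 0.0
        if gnorm <= gtol:
            return theta, ll, p, True, it - 1, gnorm
        Xp = X.T @ p
        H = n * ((X.T * p) @ X - np.outer(Xp, Xp))
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-8 * np.eye(m), grad)
        scale = 1.0
        for _ in range(40):
            cand = theta + scale * step
            ll_new, p_new = _neg_parts(cand, X, counts, n)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        theta, p = cand, p_new
        rel = abs(ll_new - ll) / (abs(ll) + 1.0)
        ll = ll_new
        grad = X.T @ counts - n * (X.T @ p)
        if rel <= ltol and float(np.max(np.abs(grad))) <= 1e-6:
            return theta, ll, p, True, it, float(np.max(np.abs(grad)))
    gnorm = float(np.max(np.abs(grad))) if m else 0.0
    return theta, ll, p, gnorm <= 1e-6, maxit, gnorm


def _fit_poisson(X, counts):
    """Poisson log-linear route: ln μ_y = δ + x(y)'θ over the cells of B."""
    import statsmodels.api as sm

    M = np.column_stack([np.ones(X.shape[0]), X])
    res = sm.GLM(counts, M, family=sm.families.Poisson()).fit(tol=1e-12, maxiter=300)
    return np.asarray(res.params[1:], dtype=float)


def _aligned_counts(freq: SupportSet, B: SupportSet) -> np.ndarray:
    fmap = freq.freq or {}
    members = set(B.patterns)
    for p, v in fmap.items():
        if v > 0 and p not in members:
            raise SupportViolationError(
                f"observed pattern {p} (count {v}) is not in the model support B"
            )
    return np.array([fmap.get(p, 0) for p in B.patterns], dtype=float)


def loglik_saturated(counts) -> float:
    """Maximized saturated log-likelihood  Σ n_y ln n_y − n ln n  (0·ln0 = 0)."""
    if isinstance(counts, SupportSet):
        counts = counts.counts()
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative counts")
    n = c.sum()
    if n < 1:
        raise ValueError("empty sample")
    pos = c[c > 0]
    return float(np.sum(pos * np.log(pos)) - n * np.log(n))


def loglik_value(theta, freq: SupportSet, B: SupportSet, spec: ModelSpec) -> float:
    """Multinomial log-likelihood  Σ n_y f(y;θ) − n ln κ_B  at a given θ."""
    counts = _aligned_counts(freq, B)
    X = spec.design_matrix(B.patterns)
    ll, _ = _neg_parts(np.asarray(theta, dtype=float), X, counts, counts.sum())
    return ll


def _saturated_closed_form(counts, B, spec):
    if np.any(counts <= 0):
        raise BoundaryError(
            "saturated MLE needs positive counts on every pattern of B; "
            "zero-count cells push estimates to -inf"
        )
    n = counts.sum()
    p = counts / n
    logp = np.log(p)
    if spec.coding == "reference":
        theta = logp[1:] - logp[0]
    else:  # sum_zero
        theta = (logp - logp.mean())[:-1]
    ll = float(np.sum(counts * logp))
    return theta, ll, p


def fit(freq: SupportSet, B: SupportSet, spec: ModelSpec, *,
        method: str = "newton", compute_se: bool = True,
        gtol: float = 1e-9, maxit: int = 500,
        allow_singleton: bool = False) -> FitResult:
    """Maximize the subpopulation likelihood over support B.

    Parameters
    ----------
    freq : SupportSet
        Observed patterns with counts (role O).  Every positive-count
        pattern must lie in B.
    B : SupportSet
        The model support; zero-count members are retained and shape κ_B.
    spec : ModelSpec
        The model family.  A saturated spec is (re)bound to B.
    method : str
        ``"newton"`` (default, analytic-derivative ascent) or ``"poisson"``
        (Poisson log-linear route; same estimating equations).
    """
    if len(B) < (1 if allow_singleton else 2):
        raise ValueError("support B needs at least 2 patterns")
    counts = _aligned_counts(freq, B)
    n = counts.sum()
    if n < 1:
        raise ValueError("no observations")
    spec = spec.bind_support(B) if spec.family == "saturated" else spec

    if spec.family == "saturated":
        theta_full, ll, p = _saturated_closed_form(counts, B, spec)
        mask = np.ones(spec.e, dtype=bool)
        X = spec.design_matrix(B.patterns)
        se = _se_from_probs(X, p, n, mask) if compute_se else np.full(spec.e, np.nan)
        kappa = float(np.sum(np.exp(X @ theta_full)))
        return FitResult(spec, B, theta_full, se, mask, ll, kappa,
                         float(np.log(n / kappa)), int(n),
                         dict(zip(B.patterns, p)), True, 0, 0.0, "closed_form")

    X = spec.design_matrix(B.patterns)
    mask = estimable_columns(X, base=np.ones((X.shape[0], 1)))
    Xe = X[:, mask]
    if method == "poisson":
        theta_e = _fit_poisson(Xe, counts)
        ll, p = _neg_parts(theta_e, Xe, counts, n)
        converged, n_iter = True, 0
        grad = Xe.T @ counts - n * (Xe.T @ p)
        gnorm = float(np.max(np.abs(grad))) if theta_e.size else 0.0
    elif method == "newton":
        theta_e, ll, p, converged, n_iter, gnorm = _newton(
            Xe, counts, n, gtol=gtol, maxit=maxit)
    else:
        raise ValueError(f"unknown method {method!r}")
    if not converged:
        warnings.warn(f"fit did not converge (grad norm {gnorm:.2e})", RuntimeWarning)

    theta = np.full(spec.e, np.nan)
    theta[mask] = theta_e
    se = np.full(spec.e, np.nan)
    if compute_se:
        se[mask] = _se_from_probs(Xe, p, n, np.ones(Xe.shape[1], dtype=bool))
    eta = Xe @ theta_e
    kappa = float(np.exp(logsumexp(eta)))
    return FitResult(spec, B, theta, se, mask, float(ll), kappa,
                     float(np.log(n / kappa)), int(n),
                     dict(zip(B.patterns, p)), bool(converged), n_iter, gnorm, method)


def _se_from_probs(Xe, p, n, mask):
    """SEs from the subpopulation Fisher information I_B = X'(diag(p) − pp')X."""
    if Xe.shape[1] == 0:
        return np.empty(0)
    Xp = Xe.T @ p
    info = (Xe.T * p) @ Xe - np.outer(Xp, Xp)
    try:
        cov = np.linalg.inv(n * info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(n * info)
    d = np.diag(cov).copy()
    d[d < 0] = np.nan
    return np.sqrt(d)


def standard_errors(result: FitResult) -> np.ndarray:
    """Recompute SEs of a fit from the Fisher information at θ̂."""
    spec, B = result.spec, result.support
    X = spec.design_matrix(B.patterns)[:, result.estimable_mask]
    p = result.prob_vector()
    se = np.full(spec.e, np.nan)
    se[result.estimable_mask] = _se_from_probs(
        X, p, result.n, np.ones(X.shape[1], dtype=bool))
    return se


# ---------------------------------------------------------------------------
# partition-based generalizations

def _group_counts(freq: SupportSet, partition: Partition):
    fmap = freq.freq or {}
    out = []
    for idx, grp in enumerate(partition.groups):
        c = np.array([fmap.get(p, 0) for p in grp.patterns], dtype=float)
        if c.sum() < 1:
            raise EmptyGroupError(
                f"partition group {idx} has no observations; its likelihood "
                "is undefined for fitting"
            )
        out.append(c)
    return out


def fit_groupwise(freq: SupportSet, partition: Partition, spec: ModelSpec,
                  **kw) -> GroupFit:
    """First generalization: independent θ_p per partition group.

    Each group's likelihood L_p is maximized separately over its own
    support B_p; group probabilities have the closed-form MLE n_p/n.
    """
    counts = _group_counts(freq, partition)
    n = int(sum(c.sum() for c in counts))
    fits, n_p = [], []
    for grp, c in zip(partition.groups, counts):
        sub = SupportSet(grp.patterns, grp.levels,
                         {p: int(v) for p, v in zip(grp.patterns, c)})
        fits.append(fit(sub, grp, spec, allow_singleton=True, **kw))
        n_p.append(int(c.sum()))
    ll_model = float(sum(f.loglik for f in fits))
    return GroupFit("groupwise", partition, spec, n, n_p, ll_model, fits=fits,
                    converged=all(f.converged for f in fits))


def fit_common_theta(freq: SupportSet, partition: Partition, spec: ModelSpec,
                     *, gtol: float = 1e-9, maxit: int = 500) -> GroupFit:
    """Second generalization: one shared θ, one intercept δ_p per group.

    Maximizes  ln L_C(θ) = Σ_p [ Σ_{y∈O_p} n_y f(y;θ) − n_p ln κ_{B_p}(θ) ].
    """
    if spec.family == "saturated":
        raise ValueError("the common-θ generalization is for parametric families")
    counts = _group_counts(freq, partition)
    n = int(sum(c.sum() for c in counts))
    n_p = [int(c.sum()) for c in counts]
    Xs = [spec.design_matrix(grp.patterns) for grp in partition.groups]

    # aliasing relative to the group intercepts
    nrow = sum(X.shape[0] for X in Xs)
    G = np.zeros((nrow, len(Xs)))
    off = 0
    for j, X in enumerate(Xs):
        G[off:off + X.shape[0], j] = 1.0
        off += X.shape[0]
    Xstack = np.vstack(Xs)
    mask = estimable_columns(Xstack, base=G)
    Xe = [X[:, mask] for X in Xs]
    m = int(mask.sum())

    theta = np.zeros(m)
    def parts(th):
        ll = 0.0
        ps = []
        for X, c, npp in zip(Xe, counts, n_p):
            eta = X @ th
            lse = logsumexp(eta)
            ll += float(c @ eta - npp * lse)
            ps.append(np.exp(eta - lse))
        return ll, ps

    ll, ps = parts(theta)
    converged, it, gnorm = True, 0, 0.0
    for it in range(1, maxit + 1):
        grad = np.zeros(m)
        H = np.zeros((m, m))
        for X, c, npp, p in zip(Xe, counts, n_p, ps):
            Xp = X.T @ p
            grad += X.T @ c - npp * Xp
            H += npp * ((X.T * p) @ X - np.outer(Xp, Xp))
        gnorm = float(np.max(np.abs(grad))) if m else 0.0
        if gnorm <= gtol:
            break
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-8 * np.eye(m), grad)
        scale = 1.0
        for _ in range(40):
            cand = theta + scale * step
            ll_new, ps_new = parts(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        rel = abs(ll_new - ll) / (abs(ll) + 1.0)
        theta, ll, ps = cand, ll_new, ps_new
        if rel <= 1e-12:
            grad = np.zeros(m)
            for X, c, npp, p in zip(Xe, counts, n_p, ps):
                grad += X.T @ c - npp * (X.T @ p)
            gnorm = float(np.max(np.abs(grad))) if m else 0.0
            break
    else:
        converged = gnorm <= 1e-6
        if not converged:
            warnings.warn(
                f"common-θ fit did not converge (grad norm {gnorm:.2e})",
                RuntimeWarning)

    # Fisher information of the common fit (θ block, given intercepts)
    H = np.zeros((m, m))
    for X, npp, p in zip(Xe, n_p, ps):
        Xp = X.T @ p
        H += npp * ((X.T * p) @ X - np.outer(Xp, Xp))
    se = np.full(spec.e, np.nan)
    if m:
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        d = np.diag(cov).copy()
        d[d < 0] = np.nan
        se[mask] = np.sqrt(d)

    theta_full = np.full(spec.e, np.nan)
    theta_full[mask] = theta
    deltas = []
    probs = []
    for X, npp, p in zip(Xe, n_p, ps):
        kappa_p = float(np.exp(logsumexp(X @ theta)))
        deltas.append(float(np.log(npp / kappa_p)))
        probs.append(p)
    fitted = [dict(zip(grp.patterns, p))
              for grp, p in zip(partition.groups, probs)]
    return GroupFit("common", partition, spec, n, n_p, float(ll),
                    theta=theta_full, se=se, estimable_mask=mask,
                    deltas=deltas, fitted_probs=fitted, converged=converged)
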