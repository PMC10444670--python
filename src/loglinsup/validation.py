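"""Out-of-sample frequency prediction and g-fold cross-validation.

A fitted parameter vector θ̂ predicts the frequency of pattern y in a
validation sample of size n0 drawn from the subpopulation defined by B0 as

    n̂_y = n0 · exp f(y; θ̂) / Σ_{y∈B0} exp f(y; θ̂).

With no validation sample, the groups of a partition of B serve as g folds:
for each fold p the model is refitted on the complement D_p = B \\ B_p and
the left-out patterns are scored.  Fit quality is summarized by the
mean-squared error over predicted counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .estimation import EmptyGroupError, fit
from .model_specs import ModelSpec
from .patterns import Partition, SupportSet

__all__ = ["PredictionReport", "predict_frequencies", "cross_validate"]


@dataclass
class PredictionReport:
    """Predicted (and optionally observed) counts over a target support."""

    support: SupportSet
    predicted: dict              # pattern -> n̂_y
    total: float                 # declared total (n0, or n for CV)
    mode: str                    # out_of_sample | cv_fold
    observed: dict | None = None
    fold: int | None = None

    @property
    def mse(self) -> float:
        if self.observed is None:
            raise ValueError("no observed counts to score against")
        diffs = [(self.observed.get(p, 0) - self.predicted[p]) ** 2
                 for p in self.predicted]
        return float(np.mean(diffs))

    def predicted_vector(self) -> np.ndarray:
        return np.array([self.predicted[p] for p in self.support.patterns])


def predict_frequencies(theta, spec: ModelSpec, B0: SupportSet, n0: float,
                        observed=None) -> PredictionReport:
    """Predicted frequencies  n̂_y = n0 · exp f(y;θ̂) / κ_B0  over B0."""
    if len(B0) == 0:
        raise ValueError("empty target support B0")
    if n0 < 1:
        raise ValueError("n0 must be at least 1")
    theta = np.asarray(theta, dtype=float)
    X = spec.design_matrix(B0.patterns)
    eta = X @ theta
    probs = np.exp(eta - logsumexp(eta))
    pred = {p: float(n0 * pr) for p, pr in zip(B0.patterns, probs)}
    obs = None
    if observed is not None:
        fmap = observed.freq if hasattr(observed, "freq") else dict(observed)
        obs = {p: fmap.get(p, 0) for p in B0.patterns}
    return PredictionReport(B0, pred, float(n0), "out_of_sample", obs)


def cross_validate(freq: SupportSet, partition: Partition, spec: ModelSpec,
                   mode: str = "n_over_B", **fit_kw):
    """g-fold cross-validation over the groups of a partition of B.

    For each fold p the model is fitted on the training complement
    D_p = B \\ B_p (with the counts observed there) and the held-out
    patterns of B_p are scored.  Two scalings of the predicted count:

    ``"n_over_B"`` (default)
        ñ_y = n · exp f(y; θ̃_p) / κ_B — the total sample scaled over the
        full support.
    ``"np_over_Bp"``
        ñ_y = n_p · exp f(y; θ̃_p) / κ_{B_p} — the fold's own count scaled
        within its group.

    Returns ``(reports, overall_mse)`` with one report per fold and the
    mean-squared error  Σ_B (n_y − ñ_y)² / |B|.
    """
    if mode not in ("n_over_B", "np_over_Bp"):
        raise ValueError(f"unknown CV scaling mode {mode!r}")
    B = partition.parent
    fmap = freq.freq or {}
    n = sum(fmap.values())
    reports = []
    sq = {}
    for idx, grp in enumerate(partition.groups):
        held = set(grp.patterns)
        train_pats = [p for p in B.patterns if p not in held]
        D_p = SupportSet(train_pats, B.levels,
                         {p: fmap.get(p, 0) for p in train_pats})
        if D_p.n < 1:
            raise EmptyGroupError(
                f"fold {idx}: removing group {idx} leaves no observations")
        spec_p = spec.bind_support(D_p)
        res = fit(D_p, D_p, spec_p, **fit_kw)
        theta = res.theta_z
        if mode == "n_over_B":
            target, total = B, n
        else:
            target, total = grp, sum(fmap.get(p, 0) for p in grp.patterns)
        X = spec_p.design_matrix(target.patterns)
        eta = X @ theta
        probs = np.exp(eta - logsumexp(eta))
        pred = {p: float(total * pr) for p, pr in zip(target.patterns, probs)
                if p in held}
        obs = {p: fmap.get(p, 0) for p in pred}
        rep = PredictionReport(grp, pred, float(total), "cv_fold", obs, fold=idx)
        reports.append(rep)
        sq.update({p: (obs[p] - pred[p]) ** 2 for p in pred})
    overall = float(np.mean([sq[p] for p in B.patterns]))
    return reports, overall
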