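"""Exact data generation under a log-linear model with true support S.

Sampling is exact: the support S is enumerated, the pattern probabilities
``exp f(y; θ0) / κ_S`` are computed with log-sum-exp centering (the Ising
generator's pairwise parameters sit near 30, so the raw exponentials
overflow), and n i.i.d. categorical draws are taken.

Two study generators are built in, both for binary variables:

``cn-ER`` — conditional normal extended Rasch:
    f(y) = Σ β_i y_i + σ2 · t(t−1)/2 with t = Σ y_i; defaults
    β = (−3.5, −2.5, −1.5, −0.5, 0.5) for k=5,
    β = (−5.0, −4.5, ..., −0.5) for k=10, σ2 = 0.63.

``Ising`` — pairwise interaction model:
    f(y) = Σ β_i y_i + Σ_{i<j} σ_ij y_i y_j with the same β defaults and
    σ_ij drawn once per configuration from Normal(0.30, 0.5) for k=5 and
    Normal(0.30, 0.1) for k=10, then held fixed across replicate datasets
    so that bias against θ0 is well defined.  (Association parameters on
    the order of 30 would make the all-ones pattern carry essentially all
    probability; the weak-association scale is the one that produces the
    observed-pattern counts these study conditions are defined by.)

A restricted true support S ⊂ A is obtained by dropping the lowest-
probability patterns of A down to a target cardinality (ties broken by
canonical pattern order); the study's restricted supports have |S| = 15
(k=5 cn-ER), 19 (k=5 Ising), 202 (k=10 cn-ER) and 198 (k=10 Ising).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .model_specs import ModelSpec
from .patterns import SupportSet, enumerate_full_support

__all__ = [
    "GeneratorConfig",
    "STUDY_BETAS",
    "STUDY_SIGMA2",
    "ISING_SIGMA_NORMAL",
    "STUDY_RESTRICTED_SIZE",
    "build_cn_er",
    "build_ising",
    "restrict_support",
    "pattern_probabilities",
    "sample_dataset",
]

#: Main-effect vectors of the simulation-study generators.
STUDY_BETAS = {
    5: (-3.5, -2.5, -1.5, -0.5, 0.5),
    10: (-5.0, -4.5, -4.0, -3.5, -3.0, -2.5, -2.0, -1.5, -1.0, -0.5),
}

#: Second-order association of the cn-ER generator.
STUDY_SIGMA2 = 0.63

#: Normal(mean, sd) from which the Ising pairwise parameters are drawn.
ISING_SIGMA_NORMAL = {5: (0.30, 0.5), 10: (0.30, 0.1)}

#: Cardinality of the restricted true support per (k, family).
STUDY_RESTRICTED_SIZE = {
    (5, "cn_er"): 15,
    (5, "ising"): 19,
    (10, "cn_er"): 202,
    (10, "ising"): 198,
}


@dataclass
class GeneratorConfig:
    """A model, true parameter values, true support, and sample size."""

    spec: ModelSpec
    theta0: np.ndarray
    S: SupportSet
    n: int
    seed: int | None = None

    def __post_init__(self):
        self.theta0 = np.asarray(self.theta0, dtype=float)
        if self.theta0.shape != (self.spec.e,):
            raise ValueError(
                f"theta0 has length {self.theta0.size}, expected e={self.spec.e}")
        if len(self.S) == 0:
            raise ValueError("empty true support S")


def build_cn_er(k: int, betas=None, sigma2: float = STUDY_SIGMA2):
    """cn-ER generator fragment: (spec, theta0) for k binary variables."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if betas is None:
        betas = STUDY_BETAS[k]
    betas = tuple(float(b) for b in betas)
    if len(betas) != k:
        raise ValueError(f"betas has length {len(betas)}, expected k={k}")
    spec = ModelSpec("cn_er", (2,) * k)
    theta0 = np.array(betas + (float(sigma2),))
    return spec, theta0


def build_ising(k: int, betas=None, mu: float | None = None,
                sd: float | None = None, seed: int | None = None):
    """Ising generator fragment with σ_ij ~ Normal(mu, sd), drawn once.

    The same seed reproduces the same σ_ij matrix; the draw happens once
    per configuration, never per replicate dataset.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if betas is None:
        betas = STUDY_BETAS[k]
    betas = tuple(float(b) for b in betas)
    if len(betas) != k:
        raise ValueError(f"betas has length {len(betas)}, expected k={k}")
    if mu is None or sd is None:
        mu0, sd0 = ISING_SIGMA_NORMAL.get(k, (0.30, 0.5))
        mu = mu0 if mu is None else mu
        sd = sd0 if sd is None else sd
    rng = np.random.default_rng(seed)
    sigmas = rng.normal(mu, sd, size=k * (k - 1) // 2)
    spec = ModelSpec("ising", (2,) * k)
    theta0 = np.concatenate([np.array(betas), sigmas])
    return spec, theta0


def pattern_probabilities(spec: ModelSpec, theta0, S: SupportSet) -> np.ndarray:
    """Exact probabilities exp f(y;θ0)/κ_S over the patterns of S."""
    theta0 = np.asarray(theta0, dtype=float)
    eta = spec.design_matrix(S.patterns) @ theta0
    return np.exp(eta - logsumexp(eta))


def restrict_support(spec: ModelSpec, theta0, target_size: int,
                     levels=None) -> SupportSet:
    """True support S: A minus its lowest-probability patterns.

    Keeps the ``target_size`` most probable patterns under θ0 (ties broken
    by canonical order) and returns them in canonical order.
    """
    levels = tuple(levels) if levels is not None else spec.levels
    A = enumerate_full_support(levels)
    if not 2 <= target_size <= len(A):
        raise ValueError(f"target_size must be in [2, {len(A)}]")
    probs = pattern_probabilities(spec, theta0, A)
    order = np.lexsort((np.arange(len(A)), -probs))  # prob desc, index asc
    keep = sorted(order[:target_size])
    return SupportSet([A.patterns[i] for i in keep], levels)


def sample_dataset(config: GeneratorConfig, rng=None) -> np.ndarray:
    """n i.i.d. score patterns from the exact distribution over S.

    Returns an n × k integer response matrix; reproducible from
    ``config.seed`` (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    probs = pattern_probabilities(config.spec, config.theta0, config.S)
    idx = rng.choice(len(config.S), size=config.n, p=probs)
    return config.S.matrix()[idx]
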