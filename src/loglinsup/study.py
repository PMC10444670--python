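"""Monte-Carlo harness for estimator quality and test calibration.

A *condition* is a cell of the study grid: number of binary variables k,
generator family (cn-ER or Ising), sample size n, true-support condition
(S = A or a restricted S ⊂ A), and the support policy used at fit time
(B = O and/or B = A).  For each condition, R replicate datasets are drawn
exactly; the data-generation model (or a deliberately misspecified family,
for power runs) is refitted to each, the five goodness-of-fit tests are run
at a nominal level with a random g-group partition of B, and the harness
accumulates

* median and range of |O| across replicates,
* average absolute bias, average MSE and average empirical variance of the
  parameter estimators (per parameter, then averaged),
* the average of squared estimated standard errors, and
* the rejection rate of each test.

Replicate seeds derive from one root seed through a spawning sequence, so
any single replicate can be re-run in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimation import EmptyGroupError, fit, fit_common_theta, fit_groupwise
from .gof import run_all_tests
from .model_specs import ModelSpec
from .patterns import make_support, observed_support, partition_support
from .simulate import (
    GeneratorConfig,
    STUDY_RESTRICTED_SIZE,
    build_cn_er,
    build_ising,
    restrict_support,
    sample_dataset,
)

__all__ = ["PolicyMetrics", "ConditionResult", "rejection_rate", "run_condition"]

TESTS = ("CS", "LRs", "LR1", "LR2", "LR12")


def rejection_rate(decisions) -> float:
    """Fraction of rejected replicates."""
    decisions = list(decisions)
    if not decisions:
        raise ValueError("no decisions")
    return float(sum(bool(d) for d in decisions) / len(decisions))


@dataclass
class PolicyMetrics:
    """Per-support-policy (B = O or B = A) accumulated results."""

    policy: str
    rejection: dict = field(default_factory=dict)   # test -> rate
    avg_abs_bias: float | None = None
    avg_mse: float | None = None
    avg_var: float | None = None
    avg_sq_se: float | None = None
    n_estimates: int = 0          # replicates entering the estimator summaries
    n_excluded: int = 0           # converged-but-not-fully-estimable etc.
    n_test_reps: int = 0

    def to_dict(self) -> dict:
        return {
            "policy": self.policy,
            "rejection": dict(self.rejection),
            "avg_abs_bias": self.avg_abs_bias,
            "avg_mse": self.avg_mse,
            "avg_var": self.avg_var,
            "avg_sq_se": self.avg_sq_se,
            "n_estimates": self.n_estimates,
            "n_excluded": self.n_excluded,
            "n_test_reps": self.n_test_reps,
        }


@dataclass
class ConditionResult:
    k: int
    family: str
    fit_family: str
    n: int
    support: str                  # "A" or "subset"
    R: int
    seed: int
    g: int
    alpha: float
    median_O: float
    range_O: tuple
    policies: dict                # policy -> PolicyMetrics
    n_failed: int = 0

    def to_dict(self) -> dict:
        return {
            "k": self.k, "family": self.family, "fit_family": self.fit_family,
            "n": self.n, "support": self.support, "R": self.R,
            "seed": self.seed, "g": self.g, "alpha": self.alpha,
            "median_O": self.median_O, "range_O": list(self.range_O),
            "n_failed": self.n_failed,
            "policies": {k: v.to_dict() for k, v in self.policies.items()},
        }


def _generator(k, family, support, seed):
    if family == "cn_er":
        spec, theta0 = build_cn_er(k)
    elif family == "ising":
        spec, theta0 = build_ising(k, seed=seed)
    else:
        raise ValueError(f"unknown generator family {family!r}")
    if support == "A":
        from .patterns import enumerate_full_support
        S = enumerate_full_support((2,) * k)
    elif support == "subset":
        S = restrict_support(spec, theta0, STUDY_RESTRICTED_SIZE[(k, family)])
    else:
        raise ValueError(f"unknown support condition {support!r}")
    return spec, theta0, S


def _fit_spec(fit_family, k) -> ModelSpec:
    if fit_family == "cn_er":
        return ModelSpec("cn_er", (2,) * k)
    if fit_family == "ising":
        return ModelSpec("ising", (2,) * k)
    if fit_family == "extended_rasch":
        return ModelSpec("extended_rasch", (2,) * k)
    raise ValueError(f"unknown fit family {fit_family!r}")


def run_condition(*, k: int, family: str, n: int, support: str = "A",
                  b_policies=("O",), fit_family: str | None = None,
                  R: int = 2000, seed: int = 0, g: int = 2,
                  alpha: float = 0.05, run_tests: bool = True,
                  compute_se: bool = True) -> ConditionResult:
    """Run one study condition for R replicates.

    ``fit_family`` defaults to the generator family (type-I error runs);
    passing a different family gives power runs, in which case the
    estimator-quality summaries are skipped (bias against θ0 is undefined
    under misspecification).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    fit_family = fit_family or family
    correctly_specified = fit_family == family
    root = np.random.SeedSequence(seed)
    ss_cfg, ss_reps = root.spawn(2)
    gen_spec, theta0, S = _generator(
        k, family, support, seed=ss_cfg.generate_state(1)[0] % (2**31))
    fspec = _fit_spec(fit_family, k)
    rep_seeds = ss_reps.spawn(R)

    sizes_O = []
    thetas = {pol: [] for pol in b_policies}
    sq_ses = {pol: [] for pol in b_policies}
    excluded = {pol: 0 for pol in b_policies}
    rejs = {pol: {t: [] for t in TESTS} for pol in b_policies}
    n_failed = 0

    for r in range(R):
        rng = np.random.default_rng(rep_seeds[r])
        try:
            data = sample_dataset(GeneratorConfig(gen_spec, theta0, S, n), rng=rng)
            O = observed_support(data, (2,) * k)
            sizes_O.append(len(O))
            for pol in b_policies:
                B = O if pol == "O" else make_support(O, "A")
                res = fit(O, B, fspec, compute_se=compute_se)
                if correctly_specified:
                    if res.converged and res.estimable_mask.all():
                        th = res.theta.copy()
                        thetas[pol].append(th)
                        if compute_se:
                            sq_ses[pol].append(res.se ** 2)
                    else:
                        excluded[pol] += 1
                if run_tests:
                    part = None
                    for attempt in range(100):
                        pseed = int(rng.integers(2**31))
                        cand = partition_support(B, "random", g=g, seed=pseed)
                        if all(any((O.freq or {}).get(p, 0) > 0
                                   for p in grp.patterns)
                               for grp in cand.groups):
                            part = cand
                            break
                    if part is None:
                        raise EmptyGroupError("no partition with observed "
                                              "patterns in every group")
                    gw = fit_groupwise(O, part, fspec, compute_se=False)
                    ct = fit_common_theta(O, part, fspec)
                    tests = run_all_tests(res, O, gw, ct, force=True)
                    for t in TESTS:
                        rejs[pol][t].append(tests[t].p_value < alpha)
        except Exception:
            n_failed += 1
            continue

    policies = {}
    for pol in b_policies:
        pm = PolicyMetrics(policy=pol)
        if run_tests and rejs[pol]["CS"]:
            pm.rejection = {t: rejection_rate(rejs[pol][t]) for t in TESTS}
            pm.n_test_reps = len(rejs[pol]["CS"])
        if correctly_specified and thetas[pol]:
            T = np.vstack(thetas[pol])           # (reps, e)
            dev = T - theta0
            bias_j = dev.mean(axis=0)
            mse_j = (dev ** 2).mean(axis=0)
            var_j = mse_j - bias_j ** 2
            pm.avg_abs_bias = float(np.mean(np.abs(bias_j)))
            pm.avg_mse = float(np.mean(mse_j))
            pm.avg_var = float(np.mean(var_j))
            if sq_ses[pol]:
                pm.avg_sq_se = float(np.mean(np.vstack(sq_ses[pol])))
            pm.n_estimates = T.shape[0]
        pm.n_excluded = excluded[pol]
        policies[pol] = pm

    if not sizes_O:
        raise RuntimeError("every replicate failed")
    return ConditionResult(
        k=k, family=family, fit_family=fit_family, n=n, support=support,
        R=R, seed=seed, g=g, alpha=alpha,
        median_O=float(np.median(sizes_O)),
        range_O=(int(min(sizes_O)), int(max(sizes_O))),
        policies=policies, n_failed=n_failed)
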