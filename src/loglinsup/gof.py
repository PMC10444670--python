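"""Goodness-of-fit tests for log-linear subpopulation models.

Five tests, all referred to a chi-square upper tail:

========  ==========================================================  ==============
id        null vs alternative                                         df
========  ==========================================================  ==============
``CS``    Pearson chi-square of the fitted model over B               |B| − 1 − e
``LRs``   fitted model vs the saturated subpopulation model           |B| − 1 − e
``LR1``   fitted model vs its first generalization (per-group θ_p)    (g−1)(e+1)
``LR2``   fitted model vs its second generalization (shared θ,        g − 1
          group intercepts)
``LR12``  second generalization vs first generalization               (g−1)e
========  ==========================================================  ==============

The CS and LRs statistics are only approximately chi-square when expected
cell counts are adequate; by default both refuse to run when more than 20%
of expected counts fall below 5 (override with ``force=True``).  The
partition tests LR1/LR2/LR12 have no such gate — their df depend only on g
and e, not on |B| — which is precisely their appeal on sparse supports.

All df bookkeeping uses the *effective* number of free parameters after
aliased columns have been dropped; the nominal df is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimation import FitResult, GroupFit, loglik_saturated

__all__ = [
    "TestResult",
    "pearson_test",
    "lr_saturated_test",
    "lr_test_first_gen",
    "lr_test_second_gen",
    "lr_test_gen1_vs_gen2",
    "run_all_tests",
    "SparseCellWarning",
    "SparseCellError",
]


class SparseCellWarning(UserWarning):
    """Expected counts are too sparse for the classical chi-square tests."""


class SparseCellError(ValueError):
    """Classical chi-square test refused on a sparse table (override with force)."""


@dataclass
class TestResult:
    test: str                 # CS | LRs | LR1 | LR2 | LR12
    statistic: float
    df: int                   # effective df
    p_value: float
    df_nominal: int
    e_effective: int
    partition: str | None = None

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": float(self.statistic),
            "df": int(self.df),
            "df_nominal": int(self.df_nominal),
            "p_value": float(self.p_value),
            "e_effective": int(self.e_effective),
            "partition": self.partition,
        }


def _pvalue(stat: float, df: int) -> float:
    if df <= 0:
        return 1.0
    return float(stats.chi2.sf(stat, df))


def _clip(stat: float, tol: float = 1e-10) -> float:
    if stat < -tol:
        raise ValueError(f"negative test statistic {stat}")
    return max(stat, 0.0)


def _sparse_gate(expected: np.ndarray, test: str, force: bool):
    frac = float(np.mean(expected < 5.0))
    if frac > 0.2:
        msg = (f"{test}: {frac:.0%} of expected counts are below 5; the "
               "chi-square approximation is unreliable (pass force=True to run)")
        if not force:
            raise SparseCellError(msg)
        warnings.warn(msg, SparseCellWarning)


def _counts_on_B(freq, B) -> np.ndarray:
    """Counts aligned with the patterns of B (zeros where unobserved)."""
    if freq is None:
        return B.counts()
    if hasattr(freq, "freq"):
        fmap = freq.freq or {}
        return np.array([fmap.get(p, 0) for p in B.patterns], dtype=float)
    return np.asarray(freq, dtype=float)


def pearson_test(result: FitResult, freq=None, B=None, *, force: bool = False) -> TestResult:
    """Pearson chi-square  Σ_B (n_y − n π̂_y|B)² / (n π̂_y|B)."""
    B = B or result.support
    counts = _counts_on_B(freq, B)
    probs = result.prob_vector()
    if np.any(probs <= 0):
        raise ValueError("a fitted probability is zero; Pearson statistic undefined")
    n = result.n
    expected = n * probs
    _sparse_gate(expected, "CS", force)
    stat = _clip(float(np.sum((counts - expected) ** 2 / expected)))
    e = result.e_effective
    df = len(B) - 1 - e
    return TestResult("CS", stat, df, _pvalue(stat, df),
                      len(B) - 1 - result.e_nominal, e)


def lr_saturated_test(result: FitResult, freq=None, B=None, *,
                      force: bool = False) -> TestResult:
    """Likelihood ratio against the saturated subpopulation model."""
    B = B or result.support
    counts = _counts_on_B(freq, B)
    expected = result.n * result.prob_vector()
    _sparse_gate(expected, "LRs", force)
    stat = _clip(2.0 * (loglik_saturated(counts) - result.loglik))
    e = result.e_effective
    df = len(B) - 1 - e
    return TestResult("LRs", stat, df, _pvalue(stat, df),
                      len(B) - 1 - result.e_nominal, e)


def _check_match(result: FitResult, groupfit: GroupFit):
    if groupfit.n != result.n:
        raise ValueError("fit and group fit are based on different samples")
    parent = set(groupfit.partition.parent.patterns)
    if parent != set(result.support.patterns):
        raise ValueError("partition parent differs from the fit support B")


def lr_test_first_gen(result: FitResult, groupfit: GroupFit) -> TestResult:
    """LR1: the fitted model against its first generalization.

    Statistic  −2[ ln L̂_B − (Σ_p ln L̂_p + Σ_p n_p ln(n_p/n)) ];
    df = Σ_p e_p + (g−1) − e, nominally (g−1)(e+1).
    """
    if groupfit.kind != "groupwise":
        raise ValueError("LR1 needs a groupwise (per-group θ_p) fit")
    _check_match(result, groupfit)
    stat = _clip(-2.0 * (result.loglik - groupfit.loglik_total))
    g = groupfit.g
    e = result.e_effective
    df = groupfit.e_effective + (g - 1) - e
    df_nom = (g - 1) * (result.e_nominal + 1)
    return TestResult("LR1", stat, df, _pvalue(stat, df), df_nom, e,
                      groupfit.partition.describe())


def lr_test_second_gen(result: FitResult, groupfit: GroupFit) -> TestResult:
    """LR2: the fitted model against its second generalization.

    Statistic  −2[ ln L̂_B − (ln L̂_C + Σ_p n_p ln(n_p/n)) ];  df = g − 1
    (adjusted by any difference between the common-fit and null-fit
    effective parameter counts).
    """
    if groupfit.kind != "common":
        raise ValueError("LR2 needs a common-θ fit")
    _check_match(result, groupfit)
    stat = _clip(-2.0 * (result.loglik - groupfit.loglik_total))
    g = groupfit.g
    df = groupfit.e_effective + (g - 1) - result.e_effective
    return TestResult("LR2", stat, df, _pvalue(stat, df), g - 1,
                      result.e_effective, groupfit.partition.describe())


def lr_test_gen1_vs_gen2(groupfit_first: GroupFit,
                         groupfit_second: GroupFit) -> TestResult:
    """LR12: second generalization against the first.

    Statistic  −2[ ln L̂_C − Σ_p ln L̂_p ];  df = Σ_p e_p − e_C, nominally
    (g−1)e.  With B the full binary cube, an extended Rasch model, and a
    partition by total score this is Andersen's conditional LR test.
    """
    if groupfit_first.kind != "groupwise" or groupfit_second.kind != "common":
        raise ValueError("LR12 needs a groupwise fit and a common-θ fit")
    p1, p2 = groupfit_first.partition, groupfit_second.partition
    if [g.patterns for g in p1.groups] != [g.patterns for g in p2.groups]:
        raise ValueError("the two group fits use different partitions")
    stat = _clip(-2.0 * (groupfit_second.loglik_model - groupfit_first.loglik_model))
    df = groupfit_first.e_effective - groupfit_second.e_effective
    df_nom = (p1.g - 1) * groupfit_first.spec.e
    return TestResult("LR12", stat, df, _pvalue(stat, df), df_nom,
                      groupfit_second.e_effective, p1.describe())


def run_all_tests(result: FitResult, freq, groupfit_first: GroupFit,
                  groupfit_second: GroupFit, *, force: bool = True) -> dict:
    """All five tests on one fitted model; returns {test id: TestResult}."""
    return {
        "CS": pearson_test(result, freq, force=force),
        "LRs": lr_saturated_test(result, freq, force=force),
        "LR1": lr_test_first_gen(result, groupfit_first),
        "LR2": lr_test_second_gen(result, groupfit_second),
        "LR12": lr_test_gen1_vs_gen2(groupfit_first, groupfit_second),
    }
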