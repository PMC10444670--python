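"""Model families as design-matrix builders.

Every model here is a log-linear model ``P(Y=y | B) ∝ exp f(y; θ)`` with
``f(y; θ) = x(y)'θ`` linear in the parameters.  A :class:`ModelSpec` maps a
score pattern to its design row ``x(y)`` and knows its number of free
parameters ``e`` (the normalization constant δ is never counted).

Families
--------
``saturated``
    One free log-probability per pattern of a bound support B; ``e = |B|−1``.
    Reference-cell coding by default (first pattern of B is the reference);
    sum-zero coding available for cross-checking reparameterization
    invariance.
``two_way``
    Dummy main effects plus all two-way association terms
    ``x_is · x_jt`` (i<j); ``order=1`` drops the associations, giving the
    mutual-independence model.
``ising``
    Binary variables: main effects ``y_i`` plus pairwise products
    ``y_i y_j`` (i<j); ``e = k + k(k−1)/2``.
``epcm`` / ``extended_rasch``
    Extended partial credit model: dummy main effects plus one association
    parameter ``σ_r`` per order r = 2..k multiplying the polynomial
    ``p_r(1'y) = C(1'y, r)``.  With all variables binary this is the
    extended Rasch model; ``e = Σ m_i + k − 1``.
``cn_er``
    Conditional normal extended Rasch: binary main effects plus a single
    second-order term ``σ2 · 1'y(1'y−1)/2``; ``e = k + 1``.
``custom``
    User-supplied ``pattern -> row`` callable with a declared ``e``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .patterns import SupportSet

__all__ = [
    "ModelSpec",
    "dummy_scores",
    "polynomial_p_r",
    "design_row",
    "design_matrix",
    "f_value",
    "FamilyMismatchError",
]

FAMILIES = ("saturated", "two_way", "ising", "epcm", "extended_rasch", "cn_er", "custom")


class FamilyMismatchError(ValueError):
    """Model family incompatible with the declared levels."""


def dummy_scores(pattern, levels) -> np.ndarray:
    """Concatenated dummy blocks ``x_i = (x_i1, ..., x_im_i)``.

    ``x_is = 1`` iff ``y_i = s`` for s = 1..m_i; category 0 is the reference
    and maps to an all-zero block.
    """
    out = np.zeros(sum(m - 1 for m in levels))
    off = 0
    for y, m in zip(pattern, levels):
        if not 0 <= y < m:
            raise ValueError(f"code {y} out of range 0..{m-1}")
        if y > 0:
            out[off + y - 1] = 1.0
        off += m - 1
    return out


def polynomial_p_r(r: int, t: int) -> float:
    """rth-order association polynomial ``p_r(t) = C(t, r)``.

    Equals ``(r!)^{-1} prod_{v=0}^{r-1} (t - v)`` for integer total score t.
    """
    if r < 2:
        raise ValueError("association order r must be >= 2")
    return float(math.comb(int(t), r)) if t >= 0 else float(
        np.prod([t - v for v in range(r)]) / math.factorial(r)
    )


def _check_binary(levels, family):
    if any(m != 2 for m in levels):
        raise FamilyMismatchError(
            f"family {family!r} needs binary variables (all m_i = 1), got levels {levels}"
        )


@dataclass
class ModelSpec:
    """A model family bound to per-variable category counts.

    Parameters
    ----------
    family : str
        One of ``saturated, two_way, ising, epcm, extended_rasch, cn_er,
        custom``.
    levels : sequence of int
        Category counts ``m_i + 1`` per variable.
    order : int
        For ``two_way``: 1 (independence) or 2 (default).  For ``epcm``: the
        maximum association order (default k).
    support : SupportSet, optional
        Required for ``saturated``: the support B the coding spans.
    coding : str
        Saturated coding: ``"reference"`` (default) or ``"sum_zero"``.
    row_fn, custom_e : for ``custom`` family.
    """

    family: str
    levels: tuple
    order: int | None = None
    support: SupportSet | None = None
    coding: str = "reference"
    row_fn: object = None
    custom_e: int | None = None
    _names: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.levels = tuple(int(m) for m in self.levels)
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        k = len(self.levels)
        if self.family in ("ising", "extended_rasch", "cn_er"):
            _check_binary(self.levels, self.family)
        if self.family == "saturated" and self.support is None:
            raise ValueError("saturated family needs a bound support B")
        if self.family == "custom" and (self.row_fn is None or self.custom_e is None):
            raise ValueError("custom family needs row_fn and custom_e")
        if self.family == "two_way" and self.order is None:
            self.order = 2
        if self.family in ("epcm", "extended_rasch") and self.order is None:
            self.order = k
        self._names = self._build_names()

    @property
    def k(self) -> int:
        return len(self.levels)

    @property
    def e(self) -> int:
        """Number of free parameters (normalization excluded)."""
        return len(self._names)

    @property
    def parameter_names(self) -> list:
        return list(self._names)

    def _build_names(self) -> list:
        k, lv = self.k, self.levels
        if self.family == "saturated":
            pats = self.support.patterns
            return [f"beta[{','.join(map(str, p))}]" for p in pats[1:]]
        if self.family == "custom":
            return [f"c{j}" for j in range(self.custom_e)]
        if self.family == "ising":
            return [f"beta{i+1}" for i in range(k)] + [
                f"sigma{i+1}{j+1}" for i in range(k) for j in range(i + 1, k)
            ]
        if self.family == "cn_er":
            return [f"beta{i+1}" for i in range(k)] + ["sigma2"]
        names = [f"beta{i+1}{s}" for i in range(k) for s in range(1, lv[i])]
        if self.family == "two_way" and self.order >= 2:
            names += [
                f"sigma{i+1}{j+1}[{s},{t}]"
                for i in range(k) for j in range(i + 1, k)
                for s in range(1, lv[i]) for t in range(1, lv[j])
            ]
        if self.family in ("epcm", "extended_rasch"):
            names += [f"sigma{r}" for r in range(2, self.order + 1)]
        return names

    # -- design ---------------------------------------------------------

    def design_row(self, pattern) -> np.ndarray:
        pattern = tuple(int(c) for c in pattern)
        k, lv = self.k, self.levels
        for i, c in enumerate(pattern):
            if not 0 <= c < lv[i]:
                raise ValueError(f"code {c} out of range in pattern {pattern}")
        fam = self.family
        if fam == "custom":
            row = np.asarray(self.row_fn(pattern), dtype=float)
            if row.shape != (self.custom_e,):
                raise ValueError("custom row_fn returned a row of the wrong length")
            return row
        if fam == "saturated":
            pats = self.support.patterns
            try:
                idx = pats.index(pattern)
            except ValueError:
                raise ValueError(f"pattern {pattern} not in the bound support") from None
            row = np.zeros(len(pats) - 1)
            if self.coding == "reference":
                if idx > 0:
                    row[idx - 1] = 1.0
            elif self.coding == "sum_zero":
                if idx < len(pats) - 1:
                    row[idx] = 1.0
                else:
                    row[:] = -1.0
            else:
                raise ValueError(f"unknown saturated coding {self.coding!r}")
            return row
        if fam == "ising":
            y = np.asarray(pattern, dtype=float)
            pair = [y[i] * y[j] for i in range(k) for j in range(i + 1, k)]
            return np.concatenate([y, pair])
        if fam == "cn_er":
            y = np.asarray(pattern, dtype=float)
            t = y.sum()
            return np.concatenate([y, [t * (t - 1) / 2.0]])
        x = dummy_scores(pattern, lv)
        if fam == "two_way":
            if self.order < 2:
                return x
            blocks = []
            off = np.cumsum([0] + [m - 1 for m in lv])
            for i in range(k):
                xi = x[off[i]:off[i + 1]]
                for j in range(i + 1, k):
                    xj = x[off[j]:off[j + 1]]
                    blocks.append(np.outer(xi, xj).ravel())
            return np.concatenate([x] + blocks)
        if fam in ("epcm", "extended_rasch"):
            t = int(sum(pattern))
            poly = [polynomial_p_r(r, t) for r in range(2, self.order + 1)]
            return np.concatenate([x, poly])
        raise AssertionError(fam)

    def design_matrix(self, patterns) -> np.ndarray:
        rows = [self.design_row(p) for p in patterns]
        return np.vstack(rows) if rows else np.empty((0, self.e))

    def bind_support(self, B: SupportSet) -> "ModelSpec":
        """Return a copy of a saturated spec bound to a (new) support B."""
        if self.family != "saturated":
            return self
        return ModelSpec("saturated", self.levels, support=B, coding=self.coding)


def design_row(pattern, spec: ModelSpec) -> np.ndarray:
    return spec.design_row(pattern)


def design_matrix(patterns, spec: ModelSpec) -> np.ndarray:
    return spec.design_matrix(patterns)


def f_value(pattern, theta, spec: ModelSpec) -> float:
    """Linear predictor ``f(y; θ) = x(y)'θ``."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.e,):
        raise ValueError(f"theta has length {theta.size}, expected e={spec.e}")
    return float(spec.design_row(pattern) @ theta)
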