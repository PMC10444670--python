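"""Score patterns, supports, and partitions of a support.

A *score pattern* is a joint outcome ``y = (y1, ..., yk)`` of ``k``
categorical variables with codes ``0..m_i`` per variable.  A *support* is an
ordered, duplicate-free collection of patterns, optionally carrying observed
frequencies.  The distinguished supports are

* ``A`` — the full Cartesian product of the per-variable code sets,
* ``O`` — the set of patterns observed in a sample (all counts positive),
* ``B`` — the analyst-chosen support of the subpopulation model, usually
  ``O`` itself or a superset of it.

Partitions of ``B`` into ``g >= 2`` disjoint groups drive the partition-based
likelihood-ratio tests and g-fold cross-validation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Pattern",
    "SupportSet",
    "Partition",
    "pattern_key",
    "parse_pattern",
    "full_support_size",
    "enumerate_full_support",
    "observed_support",
    "make_support",
    "partition_support",
    "MATERIALIZATION_CAP",
    "InvalidLevelsError",
    "MaterializationCapError",
    "ValidationError",
    "DegenerateSupportError",
    "InvalidPartitionError",
]

Pattern = tuple  # tuple[int, ...]

#: Default ceiling on the number of patterns that may be materialized when
#: enumerating the full Cartesian support A.  Size-only queries are closed
#: form and never materialize.
MATERIALIZATION_CAP = 10**6


class InvalidLevelsError(ValueError):
    """A per-variable category count is below 2."""


class MaterializationCapError(ValueError):
    """Enumerating A would exceed the materialization cap."""


class ValidationError(ValueError):
    """A response code is out of range or a file is malformed."""


class DegenerateSupportError(ValueError):
    """A constructed support has fewer than 2 patterns."""


class InvalidPartitionError(ValueError):
    """A partition request is infeasible or produced an empty group."""


def pattern_key(codes) -> str:
    """Canonical key of a pattern: comma-joined codes, e.g. ``"0,2,1"``."""
    return ",".join(str(int(c)) for c in codes)


def parse_pattern(key: str) -> Pattern:
    return tuple(int(c) for c in key.split(","))


def _check_levels(levels) -> tuple:
    levels = tuple(int(m) for m in levels)
    if any(m < 2 for m in levels):
        raise InvalidLevelsError(
            f"every variable needs >= 2 categories, got levels {levels}"
        )
    return levels


@dataclass
class SupportSet:
    """An ordered set of score patterns with optional frequencies.

    Parameters
    ----------
    patterns : list of tuple
        Distinct patterns in canonical order (the order given at
        construction is preserved; library constructors emit lexicographic
        order with the last variable varying fastest).
    levels : tuple of int
        Number of categories ``m_i + 1`` per variable.
    freq : dict, optional
        Mapping pattern -> nonnegative integer count ``n_y``.  Patterns kept
        in the support with count 0 are meaningful: they shape the
        normalizing constant ``kappa_B``.
    """

    patterns: list
    levels: tuple
    freq: dict | None = None

    def __post_init__(self):
        self.patterns = [tuple(int(c) for c in p) for p in self.patterns]
        self.levels = tuple(int(m) for m in self.levels)
        if len(set(self.patterns)) != len(self.patterns):
            raise ValidationError("duplicate patterns in support")
        k = len(self.levels)
        for p in self.patterns:
            if len(p) != k:
                raise ValidationError(f"pattern {p} has length {len(p)}, expected {k}")
            for i, c in enumerate(p):
                if not 0 <= c < self.levels[i]:
                    raise ValidationError(
                        f"code {c} out of range 0..{self.levels[i]-1} "
                        f"in pattern {p}, variable {i}"
                    )
        if self.freq is not None:
            self.freq = {tuple(p): int(v) for p, v in self.freq.items()}
            members = set(self.patterns)
            for p, v in self.freq.items():
                if v < 0:
                    raise ValidationError(f"negative count for pattern {p}")
                if v > 0 and p not in members:
                    raise ValidationError(f"pattern {p} has freq>0 but is not in support")

    @property
    def k(self) -> int:
        return len(self.levels)

    @property
    def size(self) -> int:
        return len(self.patterns)

    def __len__(self) -> int:
        return len(self.patterns)

    def __contains__(self, pattern) -> bool:
        return tuple(pattern) in set(self.patterns)

    @property
    def n(self) -> int:
        """Total observed count over the support."""
        if self.freq is None:
            return 0
        return int(sum(self.freq.values()))

    def counts(self) -> np.ndarray:
        """Counts aligned with ``self.patterns`` (0 where no frequency)."""
        if self.freq is None:
            return np.zeros(len(self.patterns), dtype=np.int64)
        return np.array([self.freq.get(p, 0) for p in self.patterns], dtype=np.int64)

    def matrix(self) -> np.ndarray:
        """Patterns stacked as an ``|B| x k`` integer array."""
        return np.array(self.patterns, dtype=np.int64).reshape(len(self.patterns), self.k)

    def restrict(self, patterns) -> "SupportSet":
        """Sub-support on the given patterns (order preserved from self)."""
        keep = set(tuple(p) for p in patterns)
        sub = [p for p in self.patterns if p in keep]
        freq = None
        if self.freq is not None:
            freq = {p: self.freq.get(p, 0) for p in sub}
        return SupportSet(sub, self.levels, freq)


def full_support_size(levels) -> int:
    """Cardinality of A, ``prod(m_i + 1)``, without materializing it."""
    return math.prod(_check_levels(levels))


def enumerate_full_support(levels, cap: int = MATERIALIZATION_CAP) -> SupportSet:
    """Enumerate the full Cartesian support A in lexicographic order.

    The last variable varies fastest.  Refuses to materialize more than
    ``cap`` patterns; use :func:`full_support_size` for size-only queries.
    """
    levels = _check_levels(levels)
    size = math.prod(levels)
    if size > cap:
        raise MaterializationCapError(
            f"|A| = {size} exceeds the materialization cap {cap}; "
            "use full_support_size for a size-only query or raise the cap"
        )
    pats = list(itertools.product(*[range(m) for m in levels]))
    return SupportSet(pats, levels)


def observed_support(responses, levels) -> SupportSet:
    """Tabulate an ``n x k`` response matrix into the observed support O.

    Returns a SupportSet carrying the pattern frequencies ``n_y``; patterns
    appear in canonical lexicographic order.
    """
    levels = _check_levels(levels)
    arr = np.asarray(responses)
    if arr.size == 0:
        raise ValidationError("empty response matrix")
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if arr.shape[1] != len(levels):
        raise ValidationError(
            f"response matrix has {arr.shape[1]} columns, expected {len(levels)}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValidationError("non-integer response codes")
        arr = arr.astype(np.int64)
    for j, m in enumerate(levels):
        bad = np.where((arr[:, j] < 0) | (arr[:, j] >= m))[0]
        if bad.size:
            r = int(bad[0])
            raise ValidationError(
                f"code {arr[r, j]} out of range 0..{m-1} at row {r}, column {j}"
            )
    freq: dict = {}
    for row in arr:
        p = tuple(int(c) for c in row)
        freq[p] = freq.get(p, 0) + 1
    pats = sorted(freq)
    return SupportSet(pats, levels, freq)


def make_support(observed: SupportSet, mode: str, extras=None, n0: int | None = None,
                 cap: int = MATERIALIZATION_CAP) -> SupportSet:
    """Construct the model support B from the observed support O.

    Modes
    -----
    ``"O"``
        B = O, the observed patterns themselves.
    ``"A"``
        B = the full Cartesian support (unobserved patterns get count 0).
    ``"O_plus"``
        B = O together with the ``extras`` patterns (count 0).
    ``"min_freq"``
        B = the observed patterns with ``n_y >= n0``.
    """
    if mode == "O":
        return observed
    if mode == "A":
        full = enumerate_full_support(observed.levels, cap=cap)
        freq = {p: observed.freq.get(p, 0) if observed.freq else 0
                for p in full.patterns}
        return SupportSet(full.patterns, observed.levels, freq)
    if mode == "O_plus":
        if extras is None:
            raise ValidationError("O_plus mode needs a list of extra patterns")
        extra = [tuple(int(c) for c in p) for p in extras]
        members = set(observed.patterns)
        pats = sorted(members | set(extra))
        freq = {p: (observed.freq.get(p, 0) if observed.freq else 0) for p in pats}
        return SupportSet(pats, observed.levels, freq)
    if mode == "min_freq":
        if n0 is None:
            raise ValidationError("min_freq mode needs n0")
        if observed.freq is None:
            raise ValidationError("min_freq mode needs observed frequencies")
        pats = [p for p in observed.patterns if observed.freq.get(p, 0) >= n0]
        if len(pats) < 2:
            raise DegenerateSupportError(
                f"min_freq({n0}) leaves {len(pats)} pattern(s); need at least 2"
            )
        freq = {p: observed.freq[p] for p in pats}
        return SupportSet(pats, observed.levels, freq)
    raise ValidationError(f"unknown support mode {mode!r}")


@dataclass
class Partition:
    """Disjoint groups ``B_1, ..., B_g`` covering a parent support B."""

    groups: list  # list[SupportSet]
    scheme: str
    parent: SupportSet
    seed: int | None = None
    labels: list = field(default_factory=list)  # one descriptor per group

    def __post_init__(self):
        if len(self.groups) < 2:
            raise InvalidPartitionError("a partition needs g >= 2 groups")
        seen: set = set()
        total = 0
        for grp in self.groups:
            if len(grp) == 0:
                raise InvalidPartitionError("empty partition group")
            for p in grp.patterns:
                if p in seen:
                    raise InvalidPartitionError(f"pattern {p} in two groups")
                seen.add(p)
            total += len(grp)
        if total != len(self.parent) or seen != set(self.parent.patterns):
            raise InvalidPartitionError("groups do not cover the parent support")

    @property
    def g(self) -> int:
        return len(self.groups)

    def describe(self) -> str:
        return f"{self.scheme}(g={self.g}" + (
            f", seed={self.seed})" if self.seed is not None else ")"
        )


def partition_support(B: SupportSet, scheme: str, *, g: int | None = None,
                      z=None, w=None, cuts: int | None = None,
                      seed: int | None = None,
                      max_redraws: int = 1000) -> Partition:
    """Partition the support B into groups for the partition LR tests.

    Schemes
    -------
    ``"random"``
        Seeded i.i.d. uniform group labels over ``g`` groups, redrawn until
        every group is non-empty (at most ``max_redraws`` redraws).
    ``"subvector"``
        Groups indexed by the distinct observed values ``c_p`` of the
        subvector ``z`` (variable indices).
    ``"weighted_sum"``
        Groups indexed by the distinct values ``t_p`` of ``w'y`` with binary
        weights ``w``.
    ``"percentile"``
        ``cuts`` right-open percentile bins ``[d_{p-1}, d_p)`` of ``w'y``,
        the last bin closed.
    """
    pats = B.patterns
    if scheme == "random":
        if g is None or g < 2:
            raise InvalidPartitionError("random scheme needs g >= 2")
        if g > len(pats):
            raise InvalidPartitionError(
                f"cannot split {len(pats)} patterns into {g} non-empty groups"
            )
        rng = np.random.default_rng(seed)
        for _ in range(max_redraws):
            labels = rng.integers(0, g, size=len(pats))
            if len(np.unique(labels)) == g:
                break
        else:
            raise InvalidPartitionError(f"no non-empty assignment in {max_redraws} draws")
        groups = [B.restrict([p for p, l in zip(pats, labels) if l == i])
                  for i in range(g)]
        return Partition(groups, "random", B, seed=seed, labels=list(range(g)))

    if scheme == "subvector":
        if z is None or len(z) == 0:
            raise InvalidPartitionError("subvector scheme needs a non-empty index set z")
        z = [int(i) for i in z]
        values = sorted({tuple(p[i] for i in z) for p in pats})
        if len(values) < 2:
            raise InvalidPartitionError("subvector z takes a single value on B")
        groups = [B.restrict([p for p in pats if tuple(p[i] for i in z) == c])
                  for c in values]
        return Partition(groups, "subvector", B, labels=values)

    if scheme in ("weighted_sum", "percentile"):
        if w is None or len(w) == 0:
            raise InvalidPartitionError(f"{scheme} scheme needs a weight vector w")
        w = np.asarray(w, dtype=np.int64)
        if w.shape != (B.k,) or not np.all((w == 0) | (w == 1)):
            raise InvalidPartitionError("w must be a binary vector of length k")
        t = B.matrix() @ w
        if scheme == "weighted_sum":
            values = sorted(set(int(v) for v in t))
            if len(values) < 2:
                raise InvalidPartitionError("w'y takes a single value on B")
            groups = [B.restrict([p for p, v in zip(pats, t) if v == tv])
                      for tv in values]
            return Partition(groups, "weighted_sum", B, labels=values)
        # percentile bins of w'y in B
        if cuts is None or cuts < 2:
            raise InvalidPartitionError("percentile scheme needs cuts >= 2")
        qs = np.percentile(t, np.linspace(0, 100, cuts + 1))
        groups, labels = [], []
        for p_idx in range(cuts):
            lo, hi = qs[p_idx], qs[p_idx + 1]
            if p_idx < cuts - 1:
                sel = [p for p, v in zip(pats, t) if lo <= v < hi]
            else:
                sel = [p for p, v in zip(pats, t) if lo <= v <= hi]
            if not sel:
                raise InvalidPartitionError(
                    f"percentile bin [{lo}, {hi}) is empty; choose fewer cuts"
                )
            groups.append(B.restrict(sel))
            labels.append((float(lo), float(hi)))
        return Partition(groups, "percentile", B, labels=labels)

    raise InvalidPartitionError(f"unknown partition scheme {scheme!r}")
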