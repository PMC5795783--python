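"""Hypergeometric gene-set overlap testing with Bonferroni correction.

The test asks how surprising it is to see ``k`` or more genes in common
between a set of ``n1`` and a set of ``n2`` genes drawn from a universe of
``N`` annotated genes: the upper-tail probability

    P(X >= k) = sum_{i=k}^{min(n1,n2)} C(n1,i) C(N-n1, n2-i) / C(N,n2).

The upper tail is inclusive, matching standard over-representation usage
(note that R's ``phyper`` defaults to the lower tail). The universe size N
is always an explicit argument: it is a property of the annotation, not of
the two sets, and no default is baked in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Set

from scipy.stats import hypergeom


@dataclass(frozen=True)
class HypergeomResult:
    """Sizes, overlap and raw/Bonferroni-adjusted upper-tail probability."""

    universe_size: int
    set1_size: int
    set2_size: int
    overlap: int
    p_value: float
    m_tests: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.overlap <= min(self.set1_size, self.set2_size):
            raise ValueError("overlap must satisfy 0 <= k <= min(n1, n2)")
        if max(self.set1_size, self.set2_size) > self.universe_size:
            raise ValueError("set sizes cannot exceed the universe size")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value must lie in (0, 1]")
        if self.m_tests < 1:
            raise ValueError("m_tests must be >= 1")

    @property
    def p_bonferroni(self) -> float:
        return min(1.0, self.p_value * self.m_tests)


def hypergeom_overlap(
    universe_size: int, set1_size: int, set2_size: int, overlap: int, m_tests: int = 1
) -> HypergeomResult:
    """Exact upper-tail overlap probability ``P(X >= k)``.

    Computed via the survival function of the hypergeometric distribution
    (log-space internally, so it is numerically stable for large N);
    deterministic for given integers.
    """
    N, n1, n2, k = universe_size, set1_size, set2_size, overlap
    for name, v in (("universe_size", N), ("set1_size", n1), ("set2_size", n2), ("overlap", k)):
        if not isinstance(v, (int,)) or isinstance(v, bool):
            raise TypeError(f"{name} must be an integer, got {v!r}")
    if N < 0 or n1 < 0 or n2 < 0 or k < 0:
        raise ValueError("sizes must be non-negative")
    if n1 > N or n2 > N:
        raise ValueError(f"set sizes ({n1}, {n2}) cannot exceed universe {N}")
    if k > min(n1, n2):
        raise ValueError(f"overlap {k} exceeds min(n1, n2) = {min(n1, n2)}")
    # P(X >= k) = sf(k - 1); exactly 1.0 at k = 0
    p = 1.0 if k == 0 else float(hypergeom.sf(k - 1, N, n1, n2))
    p = min(1.0, max(p, 5e-324))  # clamp into (0, 1] against underflow
    return HypergeomResult(N, n1, n2, k, p, m_tests)


def overlap_test(
    universe: Iterable[str], set1: Iterable[str], set2: Iterable[str], m_tests: int = 1
) -> HypergeomResult:
    """Hypergeometric overlap of two concrete gene sets within a universe.

    Genes outside the universe are dropped from both sets before counting.
    """
    u = set(universe)
    if not u:
        raise ValueError("universe must be non-empty")
    s1, s2 = set(set1) & u, set(set2) & u
    return hypergeom_overlap(len(u), len(s1), len(s2), len(s1 & s2), m_tests)


def bonferroni_adjust(p_values: Sequence[float], m: Optional[int] = None) -> List[float]:
    """Bonferroni family-wise adjustment ``min(1, p * m)``, order preserved.

    ``m`` defaults to the number of p-values submitted in the family.
    """
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    if m is None:
        m = len(p_values)
    if m < 0:
        raise ValueError("family size m must be >= 0")
    return [min(1.0, p * m) for p in p_values]
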