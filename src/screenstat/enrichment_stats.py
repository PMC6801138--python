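"""Exact null distribution for guide identities of randomly picked clones.

The null model: a pooled library of ``N = m * c`` clones in which each of
``m`` distinct guides is carried by exactly ``c`` clones.  Picking ``k``
clones uniformly without replacement induces a distribution over the
*pattern* of guide multiplicities among the picks — a multivariate
hypergeometric collapsed to an integer partition of ``k``.  The two extreme
patterns carry the screen's inference:

* all distinct, ``[1]*k``:  P = C(m,k) * c**k / C(N,k)
* all the same, ``[k]``:    P = m * C(c,k) / C(N,k)

A neutral (unselected) pool yields all-distinct picks with high probability;
all-same picks under the null are so improbable that observing them implies
strong enrichment of one guide.  The general pattern probability is

    P(pattern) = m! / (prod_j a_j! * (m-d)!) * prod_i C(c, l_i) / C(N, k)

where ``l`` are the pattern entries, ``d`` their number, and ``a_j`` counts
entries equal to ``j``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Iterator

import numpy as np
from scipy.special import gammaln

__all__ = [
    "UniformLibraryNull",
    "PickOutcome",
    "EnrichmentReport",
    "prob_all_distinct",
    "prob_all_same",
    "pattern_probability",
    "pattern_probabilities",
    "partitions",
    "monte_carlo_patterns",
    "enrichment_report",
]


@dataclass(frozen=True)
class UniformLibraryNull:
    """Equal-copy library: m distinct guides, c copies each, N = m*c clones."""

    m: int
    c: int

    def __post_init__(self) -> None:
        if self.m < 1 or self.c < 1:
            raise ValueError("m and c must be positive integers")

    @property
    def N(self) -> int:
        return self.m * self.c


@dataclass(frozen=True)
class PickOutcome:
    """An observed multiset of picked-clone guide identities.

    ``pattern`` is the multiplicity partition, e.g. five clones all carrying
    one guide -> (5,); five clones with five different guides -> (1,1,1,1,1).
    """

    pattern: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.pattern or any(x < 1 for x in self.pattern):
            raise ValueError("pattern entries must be positive integers")
        object.__setattr__(self, "pattern", tuple(sorted(self.pattern, reverse=True)))

    @property
    def k(self) -> int:
        return sum(self.pattern)

    @classmethod
    def from_guide_ids(cls, guide_ids: Iterable[str]) -> "PickOutcome":
        counts: dict[str, int] = {}
        for g in guide_ids:
            counts[g] = counts.get(g, 0) + 1
        if not counts:
            raise ValueError("no picked guides supplied")
        return cls(tuple(counts.values()))


def _check_k(null: UniformLibraryNull, k: int) -> None:
    if k < 1:
        raise ValueError("k must be a positive integer")
    if k > null.N:
        raise ValueError(f"cannot pick k={k} clones from a pool of {null.N}")


def _log_comb(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def prob_all_distinct(null: UniformLibraryNull, k: int) -> float:
    """P(k picked clones carry k distinct guides) = C(m,k) c^k / C(N,k)."""
    _check_k(null, k)
    if k > null.m:
        return 0.0
    if null.N <= 10_000:
        return float(
            Fraction(math.comb(null.m, k) * null.c**k, math.comb(null.N, k))
        )
    log_p = _log_comb(null.m, k) + k * math.log(null.c) - _log_comb(null.N, k)
    return math.exp(log_p)


def prob_all_same(null: UniformLibraryNull, k: int) -> float:
    """P(k picked clones all carry one guide) = m C(c,k) / C(N,k).

    Zero (not an error) when k exceeds the copy number c: the pool cannot
    physically yield k clones of one guide.
    """
    _check_k(null, k)
    if k > null.c:
        return 0.0
    if null.N <= 10_000:
        return float(Fraction(null.m * math.comb(null.c, k), math.comb(null.N, k)))
    log_p = (
        math.log(null.m) + _log_comb(null.c, k) - _log_comb(null.N, k)
    )
    return math.exp(log_p)


def _normalize_pattern(pattern: Iterable[int]) -> tuple[int, ...]:
    pat = tuple(sorted(int(x) for x in pattern), )
    if not pat or pat[0] < 1:
        raise ValueError("pattern entries must be positive integers")
    return tuple(sorted(pat, reverse=True))


def pattern_probability(null: UniformLibraryNull, pattern: Iterable[int]) -> float:
    """Exact probability that k picks realize the given multiplicity pattern.

    The pattern is an unordered multiset; entry order does not matter.
    Patterns requiring more copies of one guide than ``c``, or more distinct
    guides than ``m``, have probability 0.
    """
    pat = _normalize_pattern(pattern)
    k = sum(pat)
    _check_k(null, k)
    d = len(pat)
    if d > null.m or pat[0] > null.c:
        return 0.0
    mult: dict[int, int] = {}
    for x in pat:
        mult[x] = mult.get(x, 0) + 1
    # number of ways to assign distinct guides to the pattern slots
    ways = Fraction(math.factorial(null.m))
    ways /= math.factorial(null.m - d)
    for a in mult.values():
        ways /= math.factorial(a)
    for lam in pat:
        ways *= math.comb(null.c, lam)
    return float(ways / math.comb(null.N, k))


def partitions(k: int) -> Iterator[tuple[int, ...]]:
    """All integer partitions of k in decreasing-entry form."""

    def _gen(rest: int, cap: int, acc: list[int]) -> Iterator[tuple[int, ...]]:
        if rest == 0:
            yield tuple(acc)
            return
        for first in range(min(rest, cap), 0, -1):
            acc.append(first)
            yield from _gen(rest - first, first, acc)
            acc.pop()

    yield from _gen(k, k, [])


def pattern_probabilities(null: UniformLibraryNull, k: int) -> dict[tuple[int, ...], float]:
    """Map every partition of k to its exact probability (sums to 1)."""
    _check_k(null, k)
    return {pat: pattern_probability(null, pat) for pat in partitions(k)}


def _draw_picks(rng: np.random.Generator, N: int, k: int, reps: int) -> np.ndarray:
    """reps x k clone indices sampled without replacement, vectorised.

    Draws with replacement and redraws the (few) rows containing duplicates;
    for k << N the rejection rate is tiny.
    """
    picks = rng.integers(0, N, size=(reps, k))
    while True:
        sorted_rows = np.sort(picks, axis=1)
        dup = (np.diff(sorted_rows, axis=1) == 0).any(axis=1)
        if not dup.any():
            return picks
        picks[dup] = rng.integers(0, N, size=(int(dup.sum()), k))


def monte_carlo_patterns(
    null: UniformLibraryNull, k: int, reps: int, seed: int
) -> dict[tuple[int, ...], tuple[float, float]]:
    """Simulate k picks without replacement; map pattern -> (estimate, SE).

    Clone j carries guide ``j // c``.  Deterministic given the seed; every
    partition of k appears in the result, unobserved ones with estimate 0.
    """
    _check_k(null, k)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    picks = _draw_picks(rng, null.N, k, reps)
    guides = picks // null.c
    counts: dict[tuple[int, ...], int] = {pat: 0 for pat in partitions(k)}
    for row in guides:
        _, cnt = np.unique(row, return_counts=True)
        pat = tuple(sorted(cnt.tolist(), reverse=True))
        counts[pat] += 1
    out: dict[tuple[int, ...], tuple[float, float]] = {}
    for pat, n in counts.items():
        p = n / reps
        se = math.sqrt(p * (1.0 - p) / reps)
        out[pat] = (p, se)
    return out


@dataclass(frozen=True)
class EnrichmentReport:
    """Verdict on an observed pick pattern against the equal-copy null."""

    pattern: tuple[int, ...]
    point_probability: float
    tail_probability: float
    alpha: float
    reject: bool


def enrichment_report(
    observed: PickOutcome, null: UniformLibraryNull, alpha: float = 0.05
) -> EnrichmentReport:
    """Exact test of the observed pick pattern against the uniform null.

    The tail aggregates patterns at least as concentrated as the observed
    one: larger maximum multiplicity, or equal maximum multiplicity with
    probability no larger than the observed pattern's.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if observed.pattern[0] > null.c:
        raise ValueError(
            f"observed multiplicity {observed.pattern[0]} exceeds copies per guide {null.c}"
        )
    probs = pattern_probabilities(null, observed.k)
    p_obs = probs[observed.pattern]
    obs_max = observed.pattern[0]
    tail = 0.0
    for pat, p in probs.items():
        if pat[0] > obs_max or (pat[0] == obs_max and p <= p_obs):
            tail += p
    return EnrichmentReport(
        pattern=observed.pattern,
        point_probability=p_obs,
        tail_probability=min(tail, 1.0),
        alpha=alpha,
        reject=tail < alpha,
    )
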