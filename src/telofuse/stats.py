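"""Enrichment of subtelomere involvement under a uniform-recombination null.

The null model assumes rearrangement junctions are uniformly distributed
along the genome. With subtelomeric genome fraction ``f = S/G``, the
probability that at least one of the two mates of an interchromosomal
pair falls in a subtelomere is ``q = 1 - (1 - f)^2``.

Two explicit test variants are provided, because "a hypergeometric test
against a uniform null" admits more than one parameterization:

* pair-binomial (default): the count k of interchromosomal pairs with at
  least one subtelomeric mate is Binomial(n, q) under the null;
* mate-hypergeometric: the count m of subtelomeric mate positions among
  the 2n mates is Hypergeometric(population G, successes S, draws 2n),
  treating mate positions as draws of single base pairs without
  replacement.

At genome scale (G >= 1e7, n <= 1e5) the without-replacement correction
is negligible and the two variants agree closely. Upper-tail p-values
are computed in log space so values far below the double-precision floor
are still reported meaningfully (the linear-scale value is floored at
1e-300 and flagged).

Two libraries are compared on the 2x2 table (k, n-k per library) with a
Pearson chi-square test (df=1, two-sided; Yates continuity correction
optional and off by default since all expected cells are large in the
motivating data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import special as spsp
from scipy import stats as sps

#: Smallest p-value reported on the linear scale; smaller values are
#: floored here and ``underflowed`` is set (log10_p stays exact).
P_FLOOR = 1e-300


class StatsInputError(ValueError):
    """Raised for out-of-range or inconsistent test inputs."""


def pair_null_prob(f: float) -> float:
    """Null probability q that >=1 of two uniform positions is subtelomeric.

    ``q = 1 - (1 - f)**2`` for subtelomeric genome fraction ``f``.
    """
    if not 0.0 <= f <= 1.0:
        raise StatsInputError(f"fraction f must be in [0, 1], got {f}")
    return 1.0 - (1.0 - f) ** 2


@dataclass(frozen=True)
class UniformNull:
    """Uniform-recombination null for a given subtelomere annotation.

    Attributes
    ----------
    f
        Subtelomeric genome fraction S/G.
    q
        Pair-level probability that >=1 of 2 uniform positions is
        subtelomeric, ``1 - (1-f)^2``.
    """

    f: float
    q: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", pair_null_prob(self.f))

    @classmethod
    def from_genome(cls, total_subtelomeric: int, total_length: int) -> "UniformNull":
        if total_subtelomeric < 0 or total_length <= 0:
            raise StatsInputError("need S >= 0 and G > 0")
        if total_subtelomeric > total_length:
            raise StatsInputError("subtelomeric span S cannot exceed genome size G")
        return cls(total_subtelomeric / total_length)


@dataclass(frozen=True)
class TestResult:
    """Outcome of an enrichment or comparison test.

    ``p`` is the (upper-tail or two-sided) p-value floored at
    :data:`P_FLOOR`; ``log10_p`` is exact. ``effect`` is the fold
    enrichment: observed proportion over its null expectation (or over
    the second library for comparisons).
    """

    method: str
    statistic: float
    p: float
    log10_p: float
    effect: float
    underflowed: bool = False

    def p_string(self) -> str:
        if self.underflowed:
            return f"< {P_FLOOR:.0e}"
        return f"{self.p:.4g}"

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p": self.p,
            "log10_p": self.log10_p,
            "effect": self.effect,
            "underflowed": self.underflowed,
        }


def _result_from_logp(
    method: str, statistic: float, log_p: float, effect: float
) -> TestResult:
    log_p = min(log_p, 0.0)
    log10_p = log_p / math.log(10.0)
    p = math.exp(log_p) if log_p > math.log(P_FLOOR) else 0.0
    underflowed = p < P_FLOOR
    if underflowed:
        p = P_FLOOR
    return TestResult(method, statistic, p, log10_p, effect, underflowed)


def binom_log_sf(k: int, n: int, q: float) -> float:
    """log P(X >= k) for X ~ Binomial(n, q), stable far below the
    double-precision floor.

    Computed as a log-sum-exp over the pmf from k to n via gammaln;
    ``scipy.stats.binom.logsf`` returns -inf once the linear-scale tail
    underflows, which happens routinely at genome-scale counts.
    """
    if k <= 0:
        return 0.0
    if k > n:
        return -math.inf
    if q <= 0.0:
        return -math.inf
    if q >= 1.0:
        return 0.0
    j = np.arange(k, n + 1)
    log_pmf = (
        spsp.gammaln(n + 1)
        - spsp.gammaln(j + 1)
        - spsp.gammaln(n - j + 1)
        + j * math.log(q)
        + (n - j) * math.log1p(-q)
    )
    return float(spsp.logsumexp(log_pmf))


EnrichmentMethod = Literal["pair-binomial", "mate-hypergeometric"]


def enrichment_test(
    n: int,
    k: int,
    null: UniformNull,
    method: EnrichmentMethod = "pair-binomial",
    *,
    m: int | None = None,
    G: int | None = None,
    S: int | None = None,
) -> TestResult:
    """Upper-tail test of subtelomere enrichment against the uniform null.

    Parameters
    ----------
    n
        Interchromosomal pairs examined.
    k
        Interchromosomal pairs with at least one subtelomeric mate.
    null
        The uniform-recombination null (supplies q and f).
    method
        ``"pair-binomial"``: p = P(X >= k), X ~ Binomial(n, q).
        ``"mate-hypergeometric"``: p = P(Y >= m), Y ~ Hypergeometric with
        population ``G`` bp, ``S`` subtelomeric successes and ``2n``
        draws; requires ``m`` (subtelomeric mate count), ``G`` and ``S``.

    Returns
    -------
    TestResult
        With ``effect = (k/n) / q``, the observed/expected ratio.
    """
    if not 0 <= k <= n:
        raise StatsInputError(f"need 0 <= k <= n, got k={k}, n={n}")
    if n == 0:
        raise StatsInputError("n must be positive")
    effect = (k / n) / null.q if null.q > 0 else math.inf

    if method == "pair-binomial":
        log_p = binom_log_sf(k, n, null.q)
        return _result_from_logp("pair-binomial", float(k), log_p, effect)

    if method == "mate-hypergeometric":
        if m is None or G is None or S is None:
            raise StatsInputError(
                "mate-hypergeometric requires m, G and S"
            )
        if not 0 <= m <= 2 * n:
            raise StatsInputError(f"need 0 <= m <= 2n, got m={m}, n={n}")
        if not 0 <= S <= G:
            raise StatsInputError(f"need 0 <= S <= G, got S={S}, G={G}")
        log_p = float(sps.hypergeom.logsf(m - 1, G, S, 2 * n))
        return _result_from_logp("mate-hypergeometric", float(m), log_p, effect)

    raise StatsInputError(f"unknown method {method!r}")


@dataclass(frozen=True)
class TwoLibraryTable:
    """Counts (k, n) from two libraries for fold and chi-square comparison.

    ``k`` = subtelomeric interchromosomal pairs, ``n`` = interchromosomal
    pairs; library A is conventionally the mutant/test library and B the
    control.
    """

    k1: int
    n1: int
    k2: int
    n2: int

    def __post_init__(self) -> None:
        for k, n, label in ((self.k1, self.n1, "A"), (self.k2, self.n2, "B")):
            if n <= 0:
                raise StatsInputError(f"library {label}: n must be positive")
            if not 0 <= k <= n:
                raise StatsInputError(
                    f"library {label}: need 0 <= k <= n, got k={k}, n={n}"
                )

    def cells(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (
            (self.k1, self.n1 - self.k1),
            (self.k2, self.n2 - self.k2),
        )


def fold_enrichment(table: TwoLibraryTable) -> float:
    """Ratio of subtelomeric proportions, (k1/n1) / (k2/n2).

    Raises if k2 = 0 (the ratio is undefined; use
    :func:`compare_libraries` instead).
    """
    if table.k2 == 0:
        raise StatsInputError(
            "fold enrichment undefined when the reference library has k=0; "
            "use compare_libraries for a significance test"
        )
    return (table.k1 / table.n1) / (table.k2 / table.n2)


def compare_libraries(
    table: TwoLibraryTable, continuity_correction: bool = False
) -> TestResult:
    """Pearson chi-square test on the 2x2 table (k, n-k) x (library A, B).

    df=1, two-sided. Continuity (Yates) correction is off by default;
    expected cells are far above 5 in the motivating data.
    """
    (a, b), (c, d) = table.cells()
    for margin, label in (
        (a + b, "row A"),
        (c + d, "row B"),
        (a + c, "subtelomeric column"),
        (b + d, "non-subtelomeric column"),
    ):
        if margin == 0:
            raise StatsInputError(f"zero margin in 2x2 table ({label})")
    chi2, _, dof, _ = sps.chi2_contingency(
        [[a, b], [c, d]], correction=continuity_correction
    )
    assert dof == 1
    log_p = float(sps.chi2.logsf(chi2, 1))
    effect = (
        (table.k1 / table.n1) / (table.k2 / table.n2)
        if table.k2 > 0
        else math.inf
    )
    method = "chi-square" + ("+yates" if continuity_correction else "")
    return _result_from_logp(method, float(chi2), log_p, effect)
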