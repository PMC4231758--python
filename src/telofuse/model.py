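"""Model/results interface over the enrichment machinery.

`FusionEnrichment` wraps one library's scan counts together with the
reference geometry; `fit()` evaluates the uniform-recombination null and
returns a `FusionEnrichmentResults` carrying the enrichment tests, a
moment estimate of the telomeric-junction mixture fraction theta with
its standard error, and a text `summary()`.

The mixture model: each interchromosomal junction is "telomeric" (both
partners at chromosome termini, so the pair is subtelomeric with
probability ~1) with probability theta, or uniform (subtelomeric with
probability q = 1-(1-f)^2) otherwise. Hence

    P(pair subtelomeric) = theta + (1 - theta) q
    theta_hat = (k/n - q) / (1 - q)

with delta-method standard error SE(k/n) / (1 - q). theta_hat below 0
or above 1 is reported as computed (a diagnostic, not clipped).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .genome import ChromosomeSet, SubtelomereMap, build_subtelomere_map
from .scan import ScanCounts
from .stats import (
    TestResult,
    TwoLibraryTable,
    UniformNull,
    compare_libraries,
    enrichment_test,
    fold_enrichment,
)


def estimate_theta(n: int, k: int, q: float) -> tuple[float, float]:
    """Moment estimate of the telomeric mixture fraction and its SE.

    ``theta_hat = (k/n - q)/(1 - q)``; SE by the delta method from the
    binomial variance of k/n.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= q < 1.0:
        raise ValueError(f"q must be in [0, 1), got {q}")
    p_hat = k / n
    theta_hat = (p_hat - q) / (1.0 - q)
    se = math.sqrt(p_hat * (1.0 - p_hat) / n) / (1.0 - q)
    return theta_hat, se


class FusionEnrichment:
    """Subtelomere-enrichment model for one library's scan counts.

    Parameters
    ----------
    counts
        Scan tallies (n interchromosomal pairs, k subtelomeric pairs,
        m subtelomeric mates).
    chromosomes
        Reference geometry used for the uniform null.
    window
        Subtelomere window W in bp; defaults to the window recorded in
        ``counts`` or 100 kb.
    """

    def __init__(
        self,
        counts: ScanCounts,
        chromosomes: ChromosomeSet,
        window: Optional[int] = None,
    ) -> None:
        self.counts = counts
        self.chromosomes = chromosomes
        if window is None:
            window = counts.window if counts.window is not None else 100_000
        self.submap: SubtelomereMap = build_subtelomere_map(chromosomes, window)
        self.null = UniformNull(self.submap.fraction)

    def fit(self) -> "FusionEnrichmentResults":
        """Evaluate both enrichment variants and the theta estimate."""
        c = self.counts
        G = self.chromosomes.total_length
        S = self.submap.total_subtelomeric
        binom = enrichment_test(c.n_inter, c.k_subtel, self.null)
        hyper = enrichment_test(
            c.n_inter,
            c.k_subtel,
            self.null,
            method="mate-hypergeometric",
            m=c.m_subtel_mates,
            G=G,
            S=S,
        )
        theta_hat, theta_se = estimate_theta(c.n_inter, c.k_subtel, self.null.q)
        return FusionEnrichmentResults(self, binom, hyper, theta_hat, theta_se)


@dataclass
class FusionEnrichmentResults:
    """Fitted enrichment results for one library."""

    model: FusionEnrichment
    pair_binomial: TestResult
    mate_hypergeometric: TestResult
    theta_hat: float
    theta_se: float

    @property
    def counts(self) -> ScanCounts:
        return self.model.counts

    @property
    def f(self) -> float:
        return self.model.null.f

    @property
    def q(self) -> float:
        return self.model.null.q

    def theta_conf_int(self, z: float = 1.959964) -> tuple[float, float]:
        """Normal-approximation confidence interval for theta (default 95%)."""
        return (self.theta_hat - z * self.theta_se, self.theta_hat + z * self.theta_se)

    def compare(
        self, other: "FusionEnrichmentResults", continuity_correction: bool = False
    ) -> tuple[float, TestResult]:
        """Fold enrichment and chi-square comparison against ``other``.

        Both libraries must share the same reference geometry.
        """
        if self.model.chromosomes.entries != other.model.chromosomes.entries:
            raise ValueError("libraries were scanned against different genomes")
        table = TwoLibraryTable(
            self.counts.k_subtel,
            self.counts.n_inter,
            other.counts.k_subtel,
            other.counts.n_inter,
        )
        fold = fold_enrichment(table) if table.k2 > 0 else math.nan
        return fold, compare_libraries(table, continuity_correction)

    def summary(self) -> str:
        c = self.counts
        lo, hi = self.theta_conf_int()
        lines = [
            "Subtelomere fusion enrichment",
            "=" * 45,
            f"interchromosomal pairs (n)     {c.n_inter:>12d}",
            f"subtelomeric pairs (k)         {c.k_subtel:>12d}",
            f"subtelomeric mates (m)         {c.m_subtel_mates:>12d}",
            f"window W (bp)                  {self.model.submap.window:>12d}",
            f"subtelomeric fraction f        {self.f:>12.6f}",
            f"null pair probability q        {self.q:>12.6f}",
            f"fold vs null (k/n)/q           {self.pair_binomial.effect:>12.3f}",
            f"theta_hat (telomeric fraction) {self.theta_hat:>12.4f}",
            f"  std err                      {self.theta_se:>12.4f}",
            f"  95% CI                  [{lo:>8.4f}, {hi:>8.4f}]",
            f"pair-binomial p                {self.pair_binomial.p_string():>12s}"
            f"  (log10 p = {self.pair_binomial.log10_p:.1f})",
            f"mate-hypergeometric p          {self.mate_hypergeometric.p_string():>12s}"
            f"  (log10 p = {self.mate_hypergeometric.log10_p:.1f})",
        ]
        return "\n".join(lines)
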