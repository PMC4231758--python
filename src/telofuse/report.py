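"""Human-readable and JSON analysis reports.

A report is a pure function of saved scan counts, the genome table and
the analysis parameters: re-running on the same inputs reproduces it
byte for byte, and every number it shows is taken from a ScanCounts or
TestResult field (the formatter recomputes nothing).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

from .genome import ChromosomeSet
from .model import FusionEnrichment, FusionEnrichmentResults
from .scan import SCHEMA_VERSION, ScanCounts

_METHOD_KEYS = {
    "pair-binomial": "pair_binomial",
    "mate-hypergeometric": "mate_hypergeometric",
}


def _library_section(results: FusionEnrichmentResults) -> dict:
    c = results.counts
    return {
        "counts": c.to_dict(),
        "f": results.f,
        "q": results.q,
        "theta_hat": results.theta_hat,
        "theta_se": results.theta_se,
        "pair_binomial": results.pair_binomial.to_dict(),
        "mate_hypergeometric": results.mate_hypergeometric.to_dict(),
    }


def build_report(
    counts_a: ScanCounts,
    chromosomes: ChromosomeSet,
    window: int = 100_000,
    counts_b: Optional[ScanCounts] = None,
    continuity_correction: bool = False,
    method: str = "pair-binomial",
) -> dict:
    """Assemble the full analysis report as a JSON-serializable dict.

    Per library: the scan counts, the null (f, q), both enrichment
    variants and the theta estimate. With two libraries: the fold
    enrichment and the chi-square comparison. All parameters are echoed
    for reproducibility.
    """
    if method not in _METHOD_KEYS:
        raise ValueError(f"unknown method {method!r}")
    results_a = FusionEnrichment(counts_a, chromosomes, window).fit()
    report = {
        "schema_version": SCHEMA_VERSION,
        "parameters": {
            "window": window,
            "method": method,
            "continuity_correction": continuity_correction,
            "genome": {
                "chromosomes": [
                    {"name": name, "length": length}
                    for name, length in chromosomes.entries
                ],
                "total_length": chromosomes.total_length,
            },
        },
        "library_a": _library_section(results_a),
    }
    if counts_b is not None:
        results_b = FusionEnrichment(counts_b, chromosomes, window).fit()
        fold, chi = results_a.compare(results_b, continuity_correction)
        report["library_b"] = _library_section(results_b)
        report["comparison"] = {
            "fold_enrichment": fold,
            "chi_square": chi.to_dict(),
        }
    return report


def _fmt_test(section: dict) -> str:
    p = f"< 1e-300" if section["underflowed"] else f"{section['p']:.4g}"
    return (
        f"stat={section['statistic']:.4g}  p={p}  "
        f"log10(p)={section['log10_p']:.1f}  effect={section['effect']:.3f}"
    )


def render_text(report: dict) -> str:
    """Format a report dict as the human-readable summary."""
    params = report["parameters"]
    lines = [
        "telofuse analysis report",
        "========================",
        f"window W = {params['window']} bp, MAPQ filter on scan inputs, "
        f"method = {params['method']}",
        f"genome: {len(params['genome']['chromosomes'])} chromosomes, "
        f"G = {params['genome']['total_length']} bp",
        "",
    ]
    labels = [("library_a", "Library A")]
    if "library_b" in report:
        labels.append(("library_b", "Library B"))
    for key, label in labels:
        section = report[key]
        c = section["counts"]
        lines += [
            f"{label}:",
            f"  pairs seen / passing     {c['pairs_seen']} / {c['pairs_passing']}",
            f"  interchromosomal n       {c['n_inter']}",
            f"  subtelomeric pairs k     {c['k_subtel']}",
            f"  subtelomeric mates m     {c['m_subtel_mates']}",
            f"  f = {section['f']:.6f}   q = {section['q']:.6f}",
            f"  theta_hat = {section['theta_hat']:.4f} "
            f"(se {section['theta_se']:.4f})",
            f"  pair-binomial        {_fmt_test(section['pair_binomial'])}",
            f"  mate-hypergeometric  {_fmt_test(section['mate_hypergeometric'])}",
            "",
        ]
    if "comparison" in report:
        comp = report["comparison"]
        lines += [
            "Comparison (A vs B):",
            f"  fold enrichment      {comp['fold_enrichment']:.3f}",
            f"  chi-square           {_fmt_test(comp['chi_square'])}",
            "",
        ]
    return "\n".join(lines)


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(report, handle, indent=2)
        handle.write("\n")
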