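"""Per-pathway Fisher's exact enrichment, multiplicity control, consensus.

Each pathway yields one 2x2 table per comparison cohort:

              carrier   non-carrier
    case         a          b
    comparison   c          d

The default alternative is ``greater`` (excess carriage in cases), the
exact conditional upper-tail hypergeometric probability.  Benjamini-
Hochberg adjustment is applied across pathways within each comparison
(and across pathways for the Monte Carlo p); raw p-values are always
kept alongside.  A pathway reaches *consensus* when it is significant
against every comparison cohort and in the pooled Monte Carlo test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FisherResult",
    "EnrichmentResult",
    "fisher_enrichment",
    "adjust_pvalues",
    "call_consensus",
    "odds_ratio_label",
]


@dataclass(frozen=True)
class FisherResult:
    set_id: str
    comparison_cohort_id: str
    table: tuple[int, int, int, int]  # (a, b, c, d)
    p_value: float
    odds_ratio: float  # may be inf (b*c == 0 < a*d) or nan (both products 0)
    alternative: str = "greater"


@dataclass
class EnrichmentResult:
    set_id: str
    fisher: dict[str, FisherResult]          # keyed by comparison cohort id
    mc_p: float
    mc_iterations: int
    adjusted_p: dict[str, float]             # per comparison cohort
    mc_adjusted_p: float
    consensus: bool


def fisher_enrichment(
    a: int, b: int, c: int, d: int, alternative: str = "greater"
) -> tuple[float, float]:
    """Fisher's exact test on the 2x2 table ((a, b), (c, d)).

    Returns ``(p_value, odds_ratio)`` with the sample odds ratio
    ``(a*d)/(b*c)``; ``inf`` when only the denominator vanishes, ``nan``
    when both products are zero (the table carries no information).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be non-negative")
    if a + b == 0 or c + d == 0:
        raise ValueError("both row margins must be positive")
    if alternative not in ("greater", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    scipy_alt = "two-sided" if alternative == "two_sided" else "greater"
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative=scipy_alt).pvalue)
    ad, bc = a * d, b * c
    if bc == 0:
        odds = math.nan if ad == 0 else math.inf
    else:
        odds = ad / bc
    return min(p, 1.0), odds


def fisher_greater_pvalues(
    a: np.ndarray, n_case: int, c: np.ndarray, n_comp: int
) -> np.ndarray:
    """Vectorized upper-tail Fisher p over many tables with shared margins.

    ``a``/``c`` are carrier counts in the case and comparison cohorts.
    Identical to :func:`fisher_enrichment` with ``greater`` (the
    upper-tail hypergeometric survival function at a-1).
    """
    a = np.asarray(a, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    total = n_case + n_comp
    return np.minimum(stats.hypergeom.sf(a - 1, total, a + c, n_case), 1.0)


def odds_ratio_label(odds: float) -> str:
    """Render an odds ratio for TSV output ('inf'/'nan' sentinels)."""
    if math.isnan(odds):
        return "nan"
    if math.isinf(odds):
        return "inf"
    return format(odds, ".6g")


def adjust_pvalues(
    pvalues: Sequence[float], method: str = "benjamini_hochberg"
) -> np.ndarray:
    """Multiplicity adjustment preserving input order.

    ``benjamini_hochberg`` is the standard step-up FDR procedure,
    ``bonferroni`` multiplies by m and caps at 1, ``none`` is identity.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    if method == "benjamini_hochberg":
        return multipletests(p, method="fdr_bh")[1]
    if method == "bonferroni":
        return multipletests(p, method="bonferroni")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


def call_consensus(
    result: EnrichmentResult,
    alpha: float = 0.05,
    require_all_comparisons: bool = True,
    primary_comparison: str | None = None,
) -> bool:
    """Consensus = significant vs pooled (Monte Carlo) AND vs comparisons.

    With ``require_all_comparisons`` every per-comparison adjusted p must
    clear ``alpha``; otherwise only the designated primary comparison is
    required.
    """
    if not result.mc_adjusted_p < alpha:
        return False
    if require_all_comparisons:
        return all(p < alpha for p in result.adjusted_p.values())
    if primary_comparison is None:
        raise ValueError(
            "primary_comparison required when require_all_comparisons=False"
        )
    return result.adjusted_p[primary_comparison] < alpha
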