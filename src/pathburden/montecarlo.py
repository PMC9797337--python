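"""Monte Carlo permutation validation of pathway enrichment.

The case cohort is compared against the *pooled* comparison cohorts:
each permutation reassigns case labels at random — a pseudo-case set of
size ``n_case`` drawn without replacement from the combined pool — and
recomputes the case carrier count.  Because the carrier data are binary
and both margins are fixed by the permutation scheme, the carrier count
of a random size-``n_case`` subset is exactly hypergeometric, and each
iteration is realized as one hypergeometric draw; the permutation null
therefore coincides with the one-sided Fisher null, which is the basis
of the convergence cross-checks in the test-suite.

Empirical p uses the add-one (Davison-Hinkley) estimator
``(1 + #{draws >= observed}) / (1 + B)``: always valid, never zero.

Reproducibility: each pathway gets its own counter-based generator
(Philox) keyed by the global seed and a hash of the pathway id, so
results are independent of pathway iteration order and of how work is
scheduled across threads.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "MCConfig",
    "MCResult",
    "mc_pathway_test",
    "mc_standard_error",
    "pathway_rng",
]

_BATCH = 20_000


@dataclass(frozen=True)
class MCConfig:
    """Permutation-test settings.

    ``adaptive_alpha`` enables early stopping for clearly non-significant
    pathways: iteration ends once the Wilson 99% lower bound of the
    empirical p exceeds twice the threshold.  Pathways that look
    significant always run to the full ``iterations`` so the minimum
    attainable p, 1/(1+B), is preserved for multiplicity adjustment.
    """

    iterations: int = 100_000
    seed: int = 0
    statistic: str = "case_carrier_count"
    adaptive_alpha: float | None = None

    def __post_init__(self) -> None:
        if self.iterations < 100:
            raise ValueError("iterations must be >= 100 (estimator too coarse)")
        if self.statistic != "case_carrier_count":
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.adaptive_alpha is not None and not 0 < self.adaptive_alpha < 1:
            raise ValueError("adaptive_alpha must be in (0, 1)")


@dataclass(frozen=True)
class MCResult:
    set_id: str
    observed_statistic: int
    empirical_p: float
    iterations_used: int
    seed: int
    standard_error: float


def mc_standard_error(p_hat: float, iterations: int) -> float:
    """Binomial standard error sqrt(p(1-p)/B) of the empirical p."""
    if not 0 < p_hat <= 1:
        raise ValueError("p_hat must be in (0, 1]")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    return math.sqrt(p_hat * (1.0 - p_hat) / iterations)


def pathway_rng(seed: int, set_id: str) -> np.random.Generator:
    """Counter-based generator keyed by (seed, pathway id hash)."""
    key = np.array(
        [np.uint64(seed & 0xFFFFFFFFFFFFFFFF),
         np.uint64(zlib.crc32(set_id.encode()) | (len(set_id) << 32))],
        dtype=np.uint64,
    )
    return np.random.Generator(np.random.Philox(key=key))


def _wilson_lower(k: int, n: int, z: float = 2.576) -> float:
    """Wilson score 99% lower bound for a binomial proportion."""
    if n == 0:
        return 0.0
    p = k / n
    z2 = z * z
    denom = 1.0 + z2 / n
    centre = p + z2 / (2 * n)
    half = z * math.sqrt(p * (1 - p) / n + z2 / (4 * n * n))
    return max(0.0, (centre - half) / denom)


def mc_pathway_test(
    case_flags: Sequence[int] | np.ndarray,
    pooled_flags: Sequence[int] | np.ndarray,
    cfg: MCConfig,
    set_id: str = "",
) -> MCResult:
    """Permutation test of the case carrier count vs the pooled cohorts.

    Degenerate input (every sample a carrier, or none) is constant under
    permutation: empirical p is exactly 1 with zero iterations consumed.
    """
    case = np.asarray(case_flags)
    pooled = np.asarray(pooled_flags)
    for name, arr in (("case_flags", case), ("pooled_flags", pooled)):
        if arr.size == 0:
            raise ValueError(f"{name} is empty")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} entries must be binary")
    n_case = case.size
    total = n_case + pooled.size
    n_carriers = int(case.sum() + pooled.sum())
    observed = int(case.sum())

    if n_carriers == 0 or n_carriers == total:
        return MCResult(set_id, observed, 1.0, 0, cfg.seed, 0.0)

    rng = pathway_rng(cfg.seed, set_id)
    exceed = 0
    used = 0
    while used < cfg.iterations:
        batch = min(_BATCH, cfg.iterations - used)
        # carrier count of a random n_case-subset drawn without replacement
        draws = rng.hypergeometric(n_carriers, total - n_carriers,
                                   n_case, size=batch)
        exceed += int((draws >= observed).sum())
        used += batch
        if (
            cfg.adaptive_alpha is not None
            and used < cfg.iterations
            and _wilson_lower(exceed, used) > 2.0 * cfg.adaptive_alpha
        ):
            break
    p_hat = (1.0 + exceed) / (1.0 + used)
    return MCResult(
        set_id=set_id,
        observed_statistic=observed,
        empirical_p=p_hat,
        iterations_used=used,
        seed=cfg.seed,
        standard_error=mc_standard_error(p_hat, used),
    )
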