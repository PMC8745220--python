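"""Case-control allele-frequency comparison.

Two-proportion z-test on allele counts with a pooled variance estimate
(z^2 equals the Pearson chi-square statistic without continuity correction
on the 2x2 allele table), a Bonferroni family-wise threshold alpha/m, and a
three-band significance tiering: significant (p < alpha/m), borderline
(alpha/m <= p < mult*alpha/m, mult = 5 by default), nominal (up to 0.05),
else non-significant.

By convention m counts the distinct variants tested, not variant x
comparison pairs (configurable).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .consequence import PrioritizedVariant
from .io_formats import FrequencyTable, ValidationError

logger = logging.getLogger("varfunnel")

SIGNIFICANT = "significant"
BORDERLINE = "borderline"
NOMINAL = "nominal"
NS = "ns"
NOT_EVALUABLE = "not_evaluable"

M_DISTINCT_VARIANTS = "distinct_variants"
M_VARIANT_COMPARISONS = "variant_comparisons"


@dataclass(frozen=True)
class TestFamilyConfig:
    __test__ = False  # not a pytest class, despite the name

    alpha: float = 0.05
    m: int = 1
    borderline_mult: float = 5.0
    nominal_level: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.m < 1:
            raise ValidationError("m must be >= 1")
        if self.borderline_mult < 1:
            raise ValidationError("borderline_mult must be >= 1")

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(self.alpha, self.m)


@dataclass
class AfTestResult:
    variant_key: str
    comparison: tuple[str, str]  # (affected population, control population)
    p1: float
    p2: float
    n1: int
    n2: int
    z: float
    p_two_sided: float
    tier: str
    degenerate: bool = False  # pooled proportion 0 or 1


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float, bool]:
    """Pooled two-proportion z statistic and two-sided normal p-value.

    Returns ``(z, p, degenerate)``; the degenerate flag is set when the
    pooled proportion is 0 or 1 (no information: z = 0, p = 1).
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1:
            raise ValidationError("allele number must be >= 1")
        if not 0 <= x <= n:
            raise ValidationError(f"allele count {x} outside [0, {n}]")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0, True
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return z, min(p, 1.0), False


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test family-wise threshold alpha/m."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    return alpha / m


def tier(p: float, cfg: TestFamilyConfig) -> str:
    """Significance band for a two-sided p-value under the family config.

    Strict < for significance, so p exactly at the threshold is borderline.
    """
    t = cfg.threshold
    if p < t:
        return SIGNIFICANT
    if p < cfg.borderline_mult * t:
        return BORDERLINE
    if p < cfg.nominal_level:
        return NOMINAL
    return NS


def run_family(
    variants: list[PrioritizedVariant],
    freqs: FrequencyTable,
    comparisons: list[tuple[str, str]],
    alpha: float = 0.05,
    borderline_mult: float = 5.0,
    nominal_level: float = 0.05,
    m_convention: str = M_DISTINCT_VARIANTS,
) -> tuple[list[AfTestResult], TestFamilyConfig]:
    """One z-test per variant per (affected, control) population pair.

    The Bonferroni m defaults to the number of distinct variants tested;
    results are attached to each variant's ``test_results``.  Pairs with a
    missing frequency produce a ``not_evaluable`` marker result.
    """
    if m_convention == M_DISTINCT_VARIANTS:
        m = len({pv.key for pv in variants})
    elif m_convention == M_VARIANT_COMPARISONS:
        m = len(variants) * len(comparisons)
    else:
        raise ValidationError(f"unknown m convention: {m_convention}")
    cfg = TestFamilyConfig(
        alpha=alpha, m=max(m, 1),
        borderline_mult=borderline_mult, nominal_level=nominal_level,
    )
    results: list[AfTestResult] = []
    for pv in variants:
        for pop1, pop2 in comparisons:
            rec1 = freqs.get(pv.key, pop1)
            rec2 = freqs.get(pv.key, pop2)
            if rec1 is None or rec2 is None:
                res = AfTestResult(
                    variant_key=pv.key, comparison=(pop1, pop2),
                    p1=math.nan, p2=math.nan, n1=0, n2=0,
                    z=math.nan, p_two_sided=math.nan, tier=NOT_EVALUABLE,
                )
            else:
                z, p, degenerate = two_proportion_z(
                    rec1.allele_count, rec1.allele_number,
                    rec2.allele_count, rec2.allele_number,
                )
                res = AfTestResult(
                    variant_key=pv.key, comparison=(pop1, pop2),
                    p1=rec1.freq, p2=rec2.freq,
                    n1=rec1.allele_number, n2=rec2.allele_number,
                    z=z, p_two_sided=p, tier=tier(p, cfg), degenerate=degenerate,
                )
            pv.test_results.append(res)
            results.append(res)
    logger.info(
        "run_family: %d variants x %d comparisons, Bonferroni m=%d, threshold %g",
        len(variants), len(comparisons), cfg.m, cfg.threshold,
    )
    return results, cfg
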