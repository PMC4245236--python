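"""Mass-isotopomer ratios, normalization and group statistics.

Ratio-based quantitation divides a 12C abundance by the abundance of its
fully 13C-labeled internal-standard counterpart; when the standard is below
the detection limit the ratio is *undefined* (``None``), not zero.
Group comparisons use the equal-variance two-sample Student's t-test with
Benjamini-Hochberg multiple-testing correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceRecord",
    "RatioResult",
    "isotopomer_ratio",
    "normalize",
    "fold_change",
    "group_test",
    "bh_adjust",
    "group_means",
]


@dataclass(frozen=True)
class AbundanceRecord:
    spectrum_id: str
    ion_label: str
    c12_abundance: float
    c13_abundance: float | None = None
    abundance_kind: str = "area"  # intensity | area | baseline_corrected_area
    normalizer: float = 1.0
    sample: str = "s1"
    group: str = ""

    def __post_init__(self):
        if self.c12_abundance < 0:
            raise ValueError("negative c12 abundance")
        if self.c13_abundance is not None and self.c13_abundance < 0:
            raise ValueError("negative c13 abundance")
        if self.normalizer <= 0:
            raise ValueError(f"normalizer must be positive, got {self.normalizer}")
        if self.abundance_kind not in (
            "intensity",
            "area",
            "baseline_corrected_area",
        ):
            raise ValueError(f"unknown abundance kind {self.abundance_kind!r}")


@dataclass(frozen=True)
class RatioResult:
    normalized_c12: float
    ratio: float | None  # None = undefined (13C standard missing / zero)

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def isotopomer_ratio(rec: AbundanceRecord) -> RatioResult:
    """12C/13C abundance quotient; undefined when the labeled counterpart is
    missing or zero."""
    norm12 = rec.c12_abundance / rec.normalizer
    if rec.c13_abundance is None or rec.c13_abundance == 0:
        return RatioResult(normalized_c12=norm12, ratio=None)
    return RatioResult(
        normalized_c12=norm12, ratio=rec.c12_abundance / rec.c13_abundance
    )


def normalize(abundance: float, normalizer: float) -> float:
    """Divide an abundance by the sample's biomass / optical density."""
    if abundance < 0:
        raise ValueError("negative abundance")
    if normalizer <= 0:
        raise ValueError(f"normalizer must be positive, got {normalizer}")
    return abundance / normalizer


def _clean(values: Sequence[float | None], label: str) -> list[float]:
    vals = [v for v in values if v is not None and not math.isnan(v)]
    dropped = len(values) - len(vals)
    if dropped:
        logger.info("%s: %d undefined value(s) excluded", label, dropped)
    return vals


def group_means(
    group_a: Sequence[float | None], group_b: Sequence[float | None]
) -> tuple[float, float]:
    a = _clean(group_a, "group_a")
    b = _clean(group_b, "group_b")
    if not a or not b:
        raise ValueError("fold change requires non-empty groups")
    return float(np.mean(a)), float(np.mean(b))


def fold_change(
    group_a: Sequence[float | None], group_b: Sequence[float | None]
) -> float:
    """Ratio of group means, mean(a) / mean(b)."""
    ma, mb = group_means(group_a, group_b)
    if mb == 0:
        raise ValueError("zero denominator group mean")
    return ma / mb


def group_test(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Equal-variance two-sample Student's t-test p-value."""
    a = _clean(list(group_a), "group_a")
    b = _clean(list(group_b), "group_b")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t-test requires >= 2 samples per group")
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values: p_(i) * m / i with a running
    minimum from the largest rank down, capped at 1, original order kept."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    out = np.empty(m)
    out[order] = ranked
    return [float(v) for v in out]
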