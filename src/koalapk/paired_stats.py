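"""Exact Wilcoxon matched-pairs signed-rank testing and median/range
summaries.

The signed-rank test ranks the absolute pre/post differences (zeros dropped,
mid-ranks on ties) and sums the ranks of the positive differences (W+).
For n <= 25 effective pairs the two-sided p-value comes from the exact null
distribution over all 2^n equiprobable sign assignments of the realized rank
vector (computed by convolution, which is arithmetically identical to full
enumeration); beyond that a tie-corrected normal approximation with
continuity correction is used.  The two-sided p is twice the smaller tail,
capped at 1 - for six pairs that all move the same way this gives
2/64 = 0.03125.

No multiple-testing correction is applied: panels are tested analyte by
analyte at the 0.05 level, so users screening many analytes should interpret
marginal p-values accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "PairedPanel",
    "WilcoxonResult",
    "wilcoxon_exact",
    "wilcoxon_from_differences",
    "median_range",
]

EXACT_LIMIT = 25  # largest n for which the exact null distribution is used


@dataclass(frozen=True)
class PairedPanel:
    """Per-subject pre/post values of one analyte."""

    analyte: str
    units: str
    subjects: tuple[str, ...]
    pre: np.ndarray
    post: np.ndarray

    def __post_init__(self) -> None:
        pre = np.asarray(self.pre, dtype=float)
        post = np.asarray(self.post, dtype=float)
        object.__setattr__(self, "pre", pre)
        object.__setattr__(self, "post", post)
        if pre.ndim != 1 or pre.shape != post.shape:
            raise ValidationError("pre and post must be 1-d and equal length")
        if pre.size < 2:
            raise ValidationError("a paired panel needs at least 2 subjects")
        if len(self.subjects) != pre.size:
            raise ValidationError("subjects must align with the value arrays")


@dataclass(frozen=True)
class WilcoxonResult:
    """Signed-rank statistic and two-sided p-value."""

    w_plus: float
    n_effective: int
    p_two_sided: float
    exact: bool


def _exact_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Counts of W+ (on the doubled-rank grid) over all sign assignments.

    ``ranks2`` are the mid-ranks doubled to integers.  dist[s] counts the
    sign vectors whose positive-rank sum equals s/2; the total is 2^n.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    return dist


def wilcoxon_from_differences(d: np.ndarray) -> WilcoxonResult:
    """Signed-rank test on an array of paired differences."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    if n < 2:
        raise ValidationError("need >= 2 nonzero differences after zero removal")
    ranks = stats.rankdata(np.abs(d))  # mid-ranks on ties
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_LIMIT:
        ranks2 = np.rint(2 * ranks).astype(int)
        dist = _exact_distribution(ranks2)
        w2 = int(round(2 * w_plus))
        denom = 2.0**n
        tail_ge = dist[w2:].sum() / denom
        tail_le = dist[: w2 + 1].sum() / denom
        p = min(1.0, 2.0 * min(tail_ge, tail_le))
        return WilcoxonResult(w_plus=w_plus, n_effective=n, p_two_sided=p, exact=True)

    # tie-corrected normal approximation with continuity correction
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return WilcoxonResult(w_plus=w_plus, n_effective=n, p_two_sided=p, exact=False)


def wilcoxon_exact(panel: PairedPanel) -> WilcoxonResult:
    """Exact signed-rank test of post - pre for one panel."""
    d = panel.post - panel.pre
    if np.all(d == 0):
        raise ValidationError(f"{panel.analyte}: all differences are zero")
    return wilcoxon_from_differences(d)


def median_range(values) -> tuple[float, float, float]:
    """(median, min, max); even n takes the mean of the central pair."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("median_range of empty input")
    return float(np.median(v)), float(v.min()), float(v.max())
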