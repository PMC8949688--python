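"""Matched and unmatched group comparison of SF-36 scores.

Assembles, for any two groups of scored respondents, the standard
comparison table: per-scale medians/IQRs, means/SDs, bootstrap CIs of the
mean, the mean difference, a two-sided Wilcoxon-Mann-Whitney rank test,
Cohen's effect size

    d = (mean_2 - mean_1) / ((sd_1 + sd_2) / 2),

banded at |d| >= 0.2 / 0.5 / 0.8 (small / medium / large), and the 5-point
clinical-relevance threshold (a mean score difference strictly greater
than 5 points on the 0-100 scale is regarded as clinically and socially
relevant).  The effect-size denominator is the arithmetic mean of the two
group SDs, numerically close to the root-mean-square pooled SD when the
SDs are similar; see docs/methods.md for the choice.
Response rates between arms are compared with a chi-square
test of independence, or Fisher's exact test when expected cell counts
are small.
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import SCALE_ORDER

__all__ = [
    "REPORT_ROWS",
    "wilcoxon_rank_test",
    "cohen_effect_size",
    "cohen_band",
    "mean_ci",
    "compare_groups",
    "compare_proportions",
    "format_p",
]

#: Rows of the comparison table: the 8 scales plus both component summaries.
REPORT_ROWS = SCALE_ORDER + ("PCS", "MCS")

#: Clinical-relevance threshold on a 0-100 SF-36 scale (points).
RELEVANCE_THRESHOLD = 5.0


class RankTestResult(NamedTuple):
    statistic: float  # rank sum of the first sample (midranks)
    p_value: float


def wilcoxon_rank_test(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 20
) -> RankTestResult:
    """Two-sided Wilcoxon-Mann-Whitney rank-sum test.

    Uses exact permutation enumeration of the rank-sum distribution (with
    midranks, so ties are handled) when ``n1 + n2 <= exact_limit``;
    otherwise the normal approximation with tie-corrected variance and
    continuity correction.  Two identical constant samples give p = 1 by
    convention (with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical in both groups; p = 1", stacklevel=2)
        return RankTestResult(w, 1.0)
    if n <= exact_limit:
        sums = np.fromiter(
            (sum(c) for c in combinations(ranks, n1)), dtype=float
        )
        lo = np.mean(sums <= w + 1e-9)
        hi = np.mean(sums >= w - 1e-9)
        return RankTestResult(w, min(1.0, 2.0 * min(lo, hi)))
    mean_w = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    diff = w - mean_w
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var_w)
    return RankTestResult(w, float(2.0 * stats.norm.sf(abs(z))))


def cohen_effect_size(mean_t: float, sd_t: float, mean_c: float, sd_c: float) -> float:
    """Standardized difference ``(mean_t - mean_c) / ((sd_t + sd_c) / 2)``."""
    if sd_t < 0 or sd_c < 0:
        raise ValueError("SDs must be nonnegative")
    pooled = (sd_t + sd_c) / 2.0
    if pooled == 0:
        raise ZeroDivisionError("both SDs are zero; effect size undefined")
    return (mean_t - mean_c) / pooled


def cohen_band(d: float) -> str:
    """Band an effect size: negligible < 0.2 <= small < 0.5 <= medium < 0.8 <= large."""
    a = abs(d)
    if a >= 0.8:
        return "large"
    if a >= 0.5:
        return "medium"
    if a >= 0.2:
        return "small"
    return "negligible"


def mean_ci(
    values: Sequence[float],
    level: float = 0.95,
    reps: int = 10_000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Sample mean with a bootstrap percentile confidence interval."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(reps, len(x)))
    means = x[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(x.mean()), float(lo), float(hi)


def compare_groups(
    scored_1: pd.DataFrame,
    scored_2: pd.DataFrame,
    label_1: str = "internet",
    label_2: str = "telephone",
    reps: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Comparison table for two groups of scored respondents.

    ``scored_*`` are frames from :func:`sf36mode.scoring.score_cohort`.
    The mean difference and effect size are oriented ``group 2 - group 1``
    (telephone minus internet by default).  Rows with fewer than 2 valid
    scores in either group are flagged not computable.
    """
    rows = []
    for j, name in enumerate(REPORT_ROWS):
        a = scored_1[name].dropna().to_numpy(dtype=float)
        b = scored_2[name].dropna().to_numpy(dtype=float)
        row: dict = {"measure": name, f"n_{label_1}": len(a), f"n_{label_2}": len(b)}
        if len(a) < 2 or len(b) < 2:
            row["computable"] = False
            rows.append(row)
            continue
        row["computable"] = True
        for label, v, off in ((label_1, a, 0), (label_2, b, 1)):
            mean, lo, hi = mean_ci(v, reps=reps, seed=seed + 2 * j + off)
            row[f"median_{label}"] = float(np.median(v))
            row[f"q1_{label}"] = float(np.quantile(v, 0.25))
            row[f"q3_{label}"] = float(np.quantile(v, 0.75))
            row[f"mean_{label}"] = mean
            row[f"sd_{label}"] = float(np.std(v, ddof=1))
            row[f"ci_low_{label}"] = lo
            row[f"ci_high_{label}"] = hi
        diff = row[f"mean_{label_2}"] - row[f"mean_{label_1}"]
        d = cohen_effect_size(
            row[f"mean_{label_2}"], row[f"sd_{label_2}"],
            row[f"mean_{label_1}"], row[f"sd_{label_1}"],
        )
        row["mean_difference"] = diff
        row["p_value"] = wilcoxon_rank_test(b, a).p_value
        row["effect_size"] = d
        row["exceeds_5pt"] = bool(abs(diff) > RELEVANCE_THRESHOLD)
        row["cohen_band"] = cohen_band(d)
        rows.append(row)
    return pd.DataFrame(rows)


class ProportionComparison(NamedTuple):
    rate_1: float
    rate_2: float
    statistic: float
    p_value: float
    method: str


def compare_proportions(k1: int, n1: int, k2: int, n2: int) -> ProportionComparison:
    """Compare two response rates k1/n1 vs k2/n2.

    Chi-square test of independence without continuity correction when all
    expected cell counts are >= 5, otherwise Fisher's exact two-sided test.
    """
    if n1 <= 0 or n2 <= 0 or not (0 <= k1 <= n1) or not (0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n, n > 0")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected >= 5).all():
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return ProportionComparison(k1 / n1, k2 / n2, float(chi2), float(p), "chi2")
    odds, p = stats.fisher_exact(table.astype(int), alternative="two-sided")
    return ProportionComparison(k1 / n1, k2 / n2, float(odds), float(p), "fisher")


def format_p(p: float) -> str:
    """Report-style p value: '<.001' floor, otherwise 2 significant figures."""
    if p < 0.001:
        return "<.001"
    return f"{p:.2g}".lstrip("0") if p < 1 else "1.0"
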