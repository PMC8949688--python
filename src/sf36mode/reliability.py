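"""Internal-consistency checking of SF-36 scales via Cronbach's alpha.

Cronbach's alpha for a k-item scale is

    alpha = k/(k-1) * (1 - sum_i var(item_i) / var(total)),

computed on complete cases (listwise deletion per scale) with sample
variances (n-1 denominator).  A scale is conventionally acceptable when
alpha > 0.7, the gate used when validating survey data.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .scoring import SCALE_ORDER, ScoringSpec

__all__ = ["cronbach_alpha", "reliability_report", "ALPHA_ACCEPTABLE"]

#: Acceptability threshold: alpha must be strictly greater than this.
ALPHA_ACCEPTABLE = 0.7


class UndefinedAlphaError(ValueError):
    """Total score has zero variance, so alpha is undefined."""


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha of an ``n x k`` matrix of calibrated item values.

    Rows are persons (complete cases), columns are the items of one scale.
    Items with zero variance are retained with a warning; zero total
    variance raises :class:`UndefinedAlphaError`.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need an n x k matrix with k >= 2 items")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 complete cases")
    if np.isnan(x).any():
        raise ValueError("item matrix must contain complete cases only")
    item_var = x.var(axis=0, ddof=1)
    if (item_var == 0).any():
        warnings.warn(
            f"{int((item_var == 0).sum())} item(s) with zero variance retained",
            stacklevel=2,
        )
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise UndefinedAlphaError("total score has zero variance")
    k = x.shape[1]
    return k / (k - 1) * (1.0 - item_var.sum() / total_var)


def _calibrated_items(df: pd.DataFrame, scale: str, spec: ScoringSpec) -> pd.DataFrame:
    cols = {}
    for item_id in spec.scale_items[scale]:
        col = pd.to_numeric(df[f"item_{item_id}"], errors="coerce")
        cols[item_id] = col.map(spec.recode_tables[item_id])
    return pd.DataFrame(cols, index=df.index)


def reliability_report(
    df: pd.DataFrame,
    spec: ScoringSpec | None = None,
    group_col: str | None = None,
) -> pd.DataFrame:
    """Per-scale alpha table for a cohort of item responses.

    ``df`` holds ``item_1..item_36`` columns; with ``group_col`` the report
    is computed within each group (e.g. per survey arm) as well as pooled.
    Returns columns: group, scale, k, n, alpha, acceptable.
    """
    spec = spec or ScoringSpec.default()
    groups: list[tuple[str, pd.DataFrame]] = [("pooled", df)]
    if group_col is not None:
        groups += [(str(g), sub) for g, sub in df.groupby(group_col, observed=True)]
    rows = []
    for label, sub in groups:
        for s in SCALE_ORDER:
            items = _calibrated_items(sub, s, spec).dropna()
            alpha = cronbach_alpha(items.to_numpy()) if len(items) >= 3 else np.nan
            rows.append(
                {
                    "group": label,
                    "scale": s,
                    "k": len(spec.scale_items[s]),
                    "n": len(items),
                    "alpha": alpha,
                    "acceptable": bool(alpha > ALPHA_ACCEPTABLE)
                    if not np.isnan(alpha)
                    else False,
                }
            )
    return pd.DataFrame(rows)
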