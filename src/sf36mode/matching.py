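"""Propensity-score matching of survey responders across two arms.

The propensity model is a maximum-likelihood logistic regression for
membership in the treated group (here: being an internet responder rather
than a telephone responder) given baseline covariates.  Matching is greedy
1:1 nearest-neighbour on the propensity score, without replacement and
without caliper, under exact-match constraints on a set of qualitative
variables (every pair agrees exactly on them).  Balance is diagnosed with
standardized mean differences (SMDs) per covariate term and for the
propensity distance itself, before and after matching, with the
pre-matching pooled SD held fixed as denominator so that post-matching SMDs
isolate mean movement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PropensityModel",
    "MatchedSample",
    "BalanceReport",
    "SeparationError",
    "build_design",
    "fit_propensity",
    "greedy_match",
    "standardized_mean_difference",
    "balance_improvement",
    "balance_report",
]


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE does not exist."""


class UndefinedSMDError(ValueError):
    """Zero reference SD: the standardized mean difference is undefined."""


@dataclass
class PropensityModel:
    """Fitted propensity model with per-subject scores."""

    coefficients: pd.Series
    linear_predictor: pd.Series
    propensity: pd.Series
    design: pd.DataFrame
    treated: pd.Series  # boolean, aligned with design
    binary_terms: tuple[str, ...] = ()


@dataclass
class MatchedSample:
    """Result of greedy 1:1 matching without replacement."""

    pairs: list[tuple]  # (treated_id, control_id)
    unmatched_treated: list
    unmatched_control: list
    distance: pd.Series  # propensity score per subject

    @property
    def treated_ids(self) -> list:
        return [t for t, _ in self.pairs]

    @property
    def control_ids(self) -> list:
        return [c for _, c in self.pairs]

    @property
    def matched_ids(self) -> list:
        return self.treated_ids + self.control_ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "treated_id": self.treated_ids,
                "control_id": self.control_ids,
                "p_treated": self.distance.loc[self.treated_ids].to_numpy(),
                "p_control": self.distance.loc[self.control_ids].to_numpy(),
            }
        )


@dataclass
class BalanceReport:
    smd_before: dict[str, float]
    smd_after: dict[str, float]
    global_before: float
    global_after: float
    balance_improvement_pct: float
    global_before_lp: float = field(default=float("nan"))
    global_after_lp: float = field(default=float("nan"))

    def to_frame(self) -> pd.DataFrame:
        terms = list(self.smd_before)
        return pd.DataFrame(
            {
                "term": terms,
                "smd_before": [self.smd_before[t] for t in terms],
                "smd_after": [self.smd_after[t] for t in terms],
            }
        )


def build_design(df: pd.DataFrame, covariates: list[str]) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Expand covariates into a numeric design matrix (no intercept).

    Numeric covariates enter linearly.  Categorical covariates are expanded
    to indicator terms with the most frequent level as the reference
    (dropped) level.  Returns the design and the names of the indicator
    (binary) terms.
    """
    cols: dict[str, np.ndarray] = {}
    binary: list[str] = []
    for cov in covariates:
        s = df[cov]
        if pd.api.types.is_numeric_dtype(s) and s.nunique() > 2:
            cols[cov] = s.to_numpy(dtype=float)
        else:
            levels = s.astype(str)
            ref = levels.value_counts().idxmax()
            for lev in sorted(levels.unique()):
                if lev == ref:
                    continue
                name = f"{cov}[{lev}]"
                cols[name] = (levels == lev).to_numpy(dtype=float)
                binary.append(name)
    design = pd.DataFrame(cols, index=df.index)
    return design, tuple(binary)


def fit_propensity(
    df: pd.DataFrame,
    covariates: list[str],
    treated: pd.Series | np.ndarray,
    maxiter: int = 100,
    tol: float = 1e-10,
) -> PropensityModel:
    """Fit the logistic propensity model by maximum likelihood (IRLS).

    ``treated`` is a boolean indicator aligned with ``df``.  Raises
    :class:`SeparationError` when the fit exhibits perfect separation
    (propensities indistinguishable from 0/1), advising covariate
    coarsening; raises ``RuntimeError`` on non-convergence.
    """
    treated = pd.Series(np.asarray(treated, dtype=bool), index=df.index)
    if treated.all() or (~treated).all():
        raise ValueError("both treated and control groups must be nonempty")
    design, binary = build_design(df, covariates)
    constant = [c for c in design.columns if design[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant covariate terms in pooled sample: {constant}")
    X = sm.add_constant(design.astype(float), prepend=True)
    model = sm.GLM(treated.astype(float), X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        # quasi-separation on rare levels is handled below by severity
        warnings.simplefilter("ignore", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = model.fit(maxiter=maxiter, tol=tol)
        except sm.tools.sm_exceptions.PerfectSeparationError as exc:
            raise SeparationError(
                "perfect separation in the propensity model; coarsen or drop "
                "the offending covariate levels"
            ) from exc
    if not res.converged:
        raise RuntimeError(
            f"propensity fit did not converge in {maxiter} IRLS iterations "
            f"(deviance {res.deviance:.6g})"
        )
    fitted = np.asarray(res.fittedvalues, dtype=float)
    eps = 1e-10
    at_bound = (fitted < eps) | (fitted > 1 - eps)
    if at_bound.mean() > 0.05:
        raise SeparationError(
            f"{int(at_bound.sum())} fitted propensities are numerically 0/1: "
            "(quasi-)separation; coarsen or drop the offending covariate levels"
        )
    if at_bound.any():
        warnings.warn(
            f"{int(at_bound.sum())} subject(s) with boundary propensities "
            "(quasi-separation on a rare covariate pattern); they will not "
            "find close matches",
            stacklevel=2,
        )
    lp = pd.Series(np.asarray(X @ res.params, dtype=float), index=df.index)
    return PropensityModel(
        coefficients=res.params,
        linear_predictor=lp,
        propensity=pd.Series(fitted, index=df.index),
        design=design,
        treated=treated,
        binary_terms=binary,
    )


def greedy_match(
    model: PropensityModel,
    exact: pd.DataFrame | None = None,
) -> MatchedSample:
    """Greedy 1:1 nearest-neighbour matching without replacement.

    Treated subjects are processed in decreasing propensity order (ties by
    smallest id); each receives the unused control with the closest
    propensity among controls identical on every ``exact`` column.  Ties in
    distance go to the smallest control id.  Treated subjects with no
    eligible control are recorded as unmatched with a warning.
    """
    prop = model.propensity
    treated_ids = sorted(
        prop.index[model.treated], key=lambda i: (-prop[i], _orderable(i))
    )
    control_ids = list(prop.index[~model.treated])

    def stratum(i):
        if exact is None:
            return ()
        return tuple(exact.loc[i])

    pools: dict[tuple, list] = {}
    for c in control_ids:
        pools.setdefault(stratum(c), []).append(c)

    pairs: list[tuple] = []
    unmatched: list = []
    for t in treated_ids:
        pool = pools.get(stratum(t), [])
        if not pool:
            unmatched.append(t)
            continue
        best = min(pool, key=lambda c: (abs(prop[t] - prop[c]), _orderable(c)))
        pool.remove(best)
        pairs.append((t, best))
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} treated subject(s) had no eligible control "
            "and were left unmatched",
            stacklevel=2,
        )
    used = {c for _, c in pairs}
    return MatchedSample(
        pairs=pairs,
        unmatched_treated=unmatched,
        unmatched_control=[c for c in control_ids if c not in used],
        distance=prop,
    )


def _orderable(i):
    # stable tie-break for mixed id types
    return str(i) if not isinstance(i, (int, np.integer, float)) else i


def standardized_mean_difference(
    values_t,
    values_c,
    sd_reference: float | None = None,
    binary: bool = False,
) -> float:
    """(mean_t - mean_c) / sd_reference.

    Without an explicit denominator, uses the pooled SD
    ``sqrt((s_t^2 + s_c^2)/2)`` (sample variances), or the pooled binomial
    SD ``sqrt((p_t(1-p_t) + p_c(1-p_c))/2)`` for indicator terms.
    """
    x = np.asarray(values_t, dtype=float)
    y = np.asarray(values_c, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    if sd_reference is None:
        if binary:
            p, q = x.mean(), y.mean()
            sd_reference = np.sqrt((p * (1 - p) + q * (1 - q)) / 2.0)
        else:
            sd_reference = np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2.0)
    if sd_reference <= 0 or np.isnan(sd_reference):
        raise UndefinedSMDError("reference SD is zero; SMD undefined")
    return (x.mean() - y.mean()) / sd_reference


def balance_improvement(global_before: float, global_after: float) -> float:
    """Percent reduction of the global distance SMD achieved by matching."""
    if global_before == 0:
        raise ZeroDivisionError("global SMD before matching is zero")
    return 100.0 * (abs(global_before) - abs(global_after)) / abs(global_before)


def _ref_sd(x: np.ndarray, y: np.ndarray, binary: bool) -> float:
    if binary:
        p, q = x.mean(), y.mean()
        return float(np.sqrt((p * (1 - p) + q * (1 - q)) / 2.0))
    return float(np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2.0))


def balance_report(model: PropensityModel, matched: MatchedSample) -> BalanceReport:
    """SMDs per model term and for the propensity distance, before/after.

    Denominators are fixed at their pre-matching values so that the after
    column reflects mean movement only.  The global distance is reported on
    the propensity scale (headline) and on the linear-predictor scale.
    """
    if not matched.pairs:
        raise ValueError("matched sample is empty")
    t_all = model.design.index[model.treated]
    c_all = model.design.index[~model.treated]
    t_m, c_m = matched.treated_ids, matched.control_ids

    smd_before: dict[str, float] = {}
    smd_after: dict[str, float] = {}
    terms = [("distance", model.propensity, False)] + [
        (name, model.design[name], name in model.binary_terms)
        for name in model.design.columns
    ]
    for name, series, is_bin in terms:
        xb = series.loc[t_all].to_numpy(dtype=float)
        yb = series.loc[c_all].to_numpy(dtype=float)
        sd = _ref_sd(xb, yb, is_bin)
        if sd == 0:
            smd_before[name] = smd_after[name] = float("nan")
            continue
        smd_before[name] = standardized_mean_difference(xb, yb, sd)
        smd_after[name] = standardized_mean_difference(
            series.loc[t_m].to_numpy(dtype=float),
            series.loc[c_m].to_numpy(dtype=float),
            sd,
        )
    lp = model.linear_predictor
    sd_lp = _ref_sd(lp.loc[t_all].to_numpy(), lp.loc[c_all].to_numpy(), False)
    return BalanceReport(
        smd_before=smd_before,
        smd_after=smd_after,
        global_before=smd_before["distance"],
        global_after=smd_after["distance"],
        balance_improvement_pct=balance_improvement(
            smd_before["distance"], smd_after["distance"]
        ),
        global_before_lp=standardized_mean_difference(
            lp.loc[t_all].to_numpy(), lp.loc[c_all].to_numpy(), sd_lp
        ),
        global_after_lp=standardized_mean_difference(
            lp.loc[t_m].to_numpy(), lp.loc[c_m].to_numpy(), sd_lp
        ),
    )
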