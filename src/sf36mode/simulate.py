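"""Synthetic two-arm survey cohorts with selection bias and a mode effect.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage is testable without any external data:

* a randomized two-arm cohort (``internet`` vs ``telephone``) with
  identically distributed baseline covariates in both arms;
* covariate-dependent nonresponse (selection bias): the probability of
  returning a questionnaire follows a logistic model in the covariates,
  with per-arm intercepts calibrated so each arm hits its configured
  marginal response rate in expectation;
* an interviewer effect: an additive per-scale shift ``delta_s`` applied to
  the latent 0-100 scale scores of the telephone arm before item
  generation, emulating the score inflation a human interviewer induces;
* item generation: each latent scale score (plus item-level Gaussian
  jitter) is mapped onto an item's calibrated answer positions by
  stochastic rounding between the two adjacent categories, which makes the
  reported scale score conditionally unbiased for the latent score - an
  injected shift therefore survives the scoring pipeline;
* item-level missingness at a configurable rate.

Latent scale scores share a person-level factor (``scale_correlation``) so
the 8 scales are positively correlated, as in real profile data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from . import matching
from .scoring import SCALE_ORDER, ScoringSpec, score_cohort

__all__ = [
    "SimulationConfig",
    "ARMS",
    "CATEGORICAL_COVARIATES",
    "NUMERIC_COVARIATES",
    "PROPENSITY_COVARIATES",
    "EXACT_MATCH_VARS",
    "simulate_cohort",
    "recovery_experiment",
]

ARMS = ("internet", "telephone")

#: Baseline covariates as recorded at enrollment.
CATEGORICAL_COVARIATES = (
    "sex",
    "hospitalization_type",
    "ward",
    "employment",
    "education",
    "relationship_status",
    "income",
    "insurance",
)
NUMERIC_COVARIATES = ("age", "length_of_stay")

#: Covariates entering the propensity model (the three exact-match
#: variables are also included as independent variables).
PROPENSITY_COVARIATES = [
    "age",
    "length_of_stay",
    "education",
    "employment",
    "income",
    "relationship_status",
    "insurance",
    "sex",
    "hospitalization_type",
    "ward",
]

#: Qualitative variables on which every matched pair must agree exactly.
EXACT_MATCH_VARS = ["sex", "hospitalization_type", "ward"]


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator; see ``data/table1_like.yaml``.

    ``response_coefficients`` and per-scale ``latent_loadings`` use keys
    that are either a numeric covariate name (per-unit log-odds / score
    points, covariate centered at its configured mean) or
    ``"covariate:level"`` for categorical indicator effects.
    """

    n_per_arm: int = 840
    covariates: dict[str, dict[str, float]] = field(default_factory=dict)
    numeric_covariates: dict[str, dict[str, float]] = field(default_factory=dict)
    response_targets: dict[str, float] = field(default_factory=dict)
    response_coefficients: dict[str, float] = field(default_factory=dict)
    latent_means: dict[str, float] = field(default_factory=dict)
    latent_sds: dict[str, float] = field(default_factory=dict)
    latent_loadings: dict[str, dict[str, float]] = field(default_factory=dict)
    interviewer_effect: dict[str, float] = field(default_factory=dict)
    missing_item_rate: float = 0.01
    item_jitter_sd: float = 8.0
    scale_correlation: float = 0.6

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ConfigError("n_per_arm must be >= 1")
        if not 0 <= self.missing_item_rate <= 1:
            raise ConfigError("missing_item_rate must be a probability")
        if not 0 <= self.scale_correlation < 1:
            raise ConfigError("scale_correlation must be in [0, 1)")
        for cov, tbl in self.covariates.items():
            tot = sum(tbl.values())
            if abs(tot - 1.0) > 1e-3:
                raise ConfigError(f"marginals for {cov} sum to {tot}, not 1")
            # normalise away rounding residue
            self.covariates[cov] = {k: v / tot for k, v in tbl.items()}
        for arm, r in self.response_targets.items():
            if not 0 < r < 1:
                raise ConfigError(f"response target for {arm} must be in (0,1)")
        for s in self.latent_means:
            if s not in SCALE_ORDER:
                raise ConfigError(f"unknown scale {s!r} in latent_means")
        for s, sd in self.latent_sds.items():
            if sd <= 0:
                raise ConfigError(f"latent SD for {s} must be positive")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationConfig":
        rm = raw.get("response_model", {})
        lm = raw.get("latent_model", {})
        return cls(
            n_per_arm=int(raw.get("n_per_arm", 840)),
            covariates={c: dict(t) for c, t in raw.get("covariates", {}).items()},
            numeric_covariates={
                c: dict(t) for c, t in raw.get("numeric_covariates", {}).items()
            },
            response_targets=dict(rm.get("target_rates", {})),
            response_coefficients=dict(rm.get("coefficients", {})),
            latent_means=dict(lm.get("means", {})),
            latent_sds=dict(lm.get("sds", {})),
            latent_loadings={s: dict(t) for s, t in lm.get("loadings", {}).items()},
            interviewer_effect=dict(raw.get("interviewer_effect", {})),
            missing_item_rate=float(raw.get("missing_item_rate", 0.01)),
            item_jitter_sd=float(raw.get("item_jitter_sd", 8.0)),
            scale_correlation=float(raw.get("scale_correlation", 0.6)),
        )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "SimulationConfig":
        ref = resources.files("sf36mode.data") / "table1_like.yaml"
        return cls.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


def _numeric_center(cfg: SimulationConfig, cov: str) -> float:
    p = cfg.numeric_covariates[cov]
    if "mean" in p:
        return float(p["mean"])
    # lognormal mean
    return float(np.exp(p["meanlog"] + p["sdlog"] ** 2 / 2.0))


def _effect_sum(cfg: SimulationConfig, df: pd.DataFrame, coefs: Mapping[str, float]) -> np.ndarray:
    """Linear combination of covariate effects for keys 'cov' or 'cov:level'."""
    s = np.zeros(len(df))
    for key, beta in coefs.items():
        if ":" in key:
            cov, level = key.split(":", 1)
            if cov not in df.columns:
                raise ConfigError(f"unknown covariate {cov!r} in effect key {key!r}")
            s = s + beta * (df[cov].astype(str) == level).to_numpy(dtype=float)
        else:
            if key not in df.columns:
                raise ConfigError(f"unknown covariate {key!r} in effects")
            s = s + beta * (df[key].to_numpy(dtype=float) - _numeric_center(cfg, key))
    return s


def _calibrated_response_prob(target: float, effects: np.ndarray) -> np.ndarray:
    """Per-subject response probabilities whose mean equals ``target``.

    Solves for the logistic intercept on the realized covariates, so the
    arm's expected marginal response rate matches the target exactly.
    """
    if np.ptp(effects) == 0:
        return np.full(len(effects), target)
    a = brentq(lambda a: expit(a + effects).mean() - target, -30.0, 30.0)
    return expit(a + effects)


def _item_positions(spec: ScoringSpec, item_id: int) -> tuple[np.ndarray, np.ndarray]:
    """Codes and their calibrated positions on [0,1], sorted by position."""
    table = spec.recode_tables[item_id]
    codes = np.array(sorted(table, key=lambda c: table[c]))
    vals = np.array([table[c] for c in codes], dtype=float)
    pos = (vals - vals.min()) / (vals.max() - vals.min())
    return codes, pos


def _stochastic_round(u: np.ndarray, pos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices into ``pos`` whose expected position equals ``u`` elementwise."""
    hi = np.searchsorted(pos, u)
    hi = np.clip(hi, 0, len(pos) - 1)
    lo = np.clip(hi - 1, 0, len(pos) - 1)
    width = pos[hi] - pos[lo]
    frac = np.divide(u - pos[lo], width, out=np.zeros_like(u), where=width > 0)
    take_hi = rng.random(len(u)) < frac
    return np.where(take_hi, hi, lo)


def simulate_cohort(
    cfg: SimulationConfig | None = None,
    seed: int | np.random.Generator = 0,
    spec: ScoringSpec | None = None,
) -> pd.DataFrame:
    """Draw one cohort: covariates, response status, latent scores, items.

    Returns one row per enrolled subject with columns ``id``, ``arm``,
    ``responder``, the baseline covariates, ``true_<scale>`` latent scores
    (interviewer shift included for the telephone arm) and
    ``item_1..item_36`` (NA for nonresponders and for blanked items).
    Fully reproducible from ``seed``.
    """
    cfg = cfg or SimulationConfig.default()
    spec = spec or ScoringSpec.default()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = cfg.n_per_arm
    total = 2 * n

    df = pd.DataFrame(
        {
            "id": np.arange(total),
            "arm": np.repeat(ARMS, n),
        }
    )
    for cov, tbl in cfg.covariates.items():
        levels = list(tbl)
        df[cov] = rng.choice(levels, p=[tbl[v] for v in levels], size=total)
    for cov, p in cfg.numeric_covariates.items():
        if "meanlog" in p:
            x = np.round(np.exp(rng.normal(p["meanlog"], p["sdlog"], size=total)))
        else:
            x = np.round(rng.normal(p["mean"], p["sd"], size=total))
        df[cov] = np.clip(x, p.get("min", -np.inf), p.get("max", np.inf))

    # --- nonresponse: covariate-dependent, per-arm calibrated intercepts ---
    effects = _effect_sum(cfg, df, cfg.response_coefficients)
    prob = np.empty(total)
    for arm in ARMS:
        m = (df["arm"] == arm).to_numpy()
        target = cfg.response_targets.get(arm, 0.5)
        prob[m] = _calibrated_response_prob(target, effects[m])
    df["responder"] = (rng.random(total) < prob).astype(int)

    # --- latent scale scores with a shared person factor ---
    rho = cfg.scale_correlation
    shared = rng.normal(size=total)
    telephone = (df["arm"] == "telephone").to_numpy(dtype=float)
    for s in SCALE_ORDER:
        mu = cfg.latent_means.get(s, 60.0)
        sd = cfg.latent_sds.get(s, 20.0)
        load = _effect_sum(cfg, df, cfg.latent_loadings.get(s, {}))
        noise = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.normal(size=total)
        latent = mu + load + sd * noise + cfg.interviewer_effect.get(s, 0.0) * telephone
        df[f"true_{s}"] = np.clip(latent, 0.0, 100.0)

    # --- item responses for responders ---
    resp = df["responder"].to_numpy(dtype=bool)
    n_resp = int(resp.sum())
    for s in SCALE_ORDER:
        latent = df.loc[resp, f"true_{s}"].to_numpy()
        for item_id in spec.scale_items[s]:
            codes, pos = _item_positions(spec, item_id)
            u = np.clip(
                (latent + rng.normal(0.0, cfg.item_jitter_sd, size=n_resp)) / 100.0,
                0.0,
                1.0,
            )
            col = np.full(len(df), np.nan)
            col[resp] = codes[_stochastic_round(u, pos, rng)]
            df[f"item_{item_id}"] = pd.array(col, dtype="Int64")
    for item_id in spec.excluded_items:
        codes = np.array(sorted(spec.recode_tables[item_id]))
        col = np.full(len(df), np.nan)
        col[resp] = rng.choice(codes, size=n_resp)
        df[f"item_{item_id}"] = pd.array(col, dtype="Int64")

    if cfg.missing_item_rate > 0 and n_resp:
        cols = [f"item_{i}" for i in range(1, 37)]
        blank = rng.random((n_resp, len(cols))) < cfg.missing_item_rate
        block = df.loc[resp, cols].to_numpy(dtype=object)
        block[blank] = pd.NA
        for j, c in enumerate(cols):
            vals = df[c].to_numpy(dtype=object)
            vals[resp] = block[:, j]
            df[c] = pd.array(vals, dtype="Int64")
    return df


def recovery_experiment(
    cfg: SimulationConfig | None = None,
    n_replicates: int = 10,
    seed: int = 0,
    spec: ScoringSpec | None = None,
    covariates: list[str] | None = None,
    exact_vars: list[str] | None = None,
) -> pd.DataFrame:
    """Repeated end-to-end recovery of the injected interviewer effect.

    Per replicate: simulate a cohort, score the responders, estimate the
    per-scale telephone-internet mean difference in the unmatched
    responders, then re-estimate it after propensity matching (internet
    responders matched 1:1 to telephone responders with exact constraints).
    Returns one row per (replicate, scale) with the true shift and both
    estimates - the raw material for bias/RMSE summaries of the method's
    central decomposition (mode effect vs selection bias).
    """
    cfg = cfg or SimulationConfig.default()
    spec = spec or ScoringSpec.default()
    covariates = covariates if covariates is not None else PROPENSITY_COVARIATES
    exact_vars = exact_vars if exact_vars is not None else EXACT_MATCH_VARS
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    rows = []
    for r, child in enumerate(children):
        cohort = simulate_cohort(cfg, np.random.default_rng(child), spec)
        responders = cohort[cohort["responder"] == 1].set_index("id")
        scored = score_cohort(responders, spec)
        treated = responders["arm"] == "internet"
        model = matching.fit_propensity(responders, covariates, treated)
        matched = matching.greedy_match(
            model, responders[exact_vars] if exact_vars else None
        )
        t_ids, c_ids = matched.treated_ids, matched.control_ids
        for s in SCALE_ORDER:
            col = scored[s]
            unmatched_est = (
                col[~treated].mean() - col[treated].mean()
            )  # telephone - internet
            matched_est = col.loc[c_ids].mean() - col.loc[t_ids].mean()
            rows.append(
                {
                    "replicate": r,
                    "scale": s,
                    "true_delta": cfg.interviewer_effect.get(s, 0.0),
                    "unmatched_estimate": float(unmatched_est),
                    "matched_estimate": float(matched_est),
                    "n_pairs": len(t_ids),
                }
            )
    return pd.DataFrame(rows)
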