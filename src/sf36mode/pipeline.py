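"""End-to-end pipeline: simulate/ingest -> score -> reliability -> match -> compare.

One entry point, :func:`run_pipeline`, reproduces the whole analysis from a
cohort CSV (or a fresh simulation): SF-36 scoring of responders,
internal-consistency checking, propensity matching of internet responders
to telephone responders with exact constraints, and the comparison tables
for both the unmatched and the matched responder samples.  All randomness
flows from the single configured seed; re-running with identical inputs
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .comparison import compare_groups, compare_proportions, format_p
from .matching import balance_report, fit_propensity, greedy_match
from .reliability import reliability_report
from .scoring import SCALE_ORDER, ScoringSpec, score_cohort
from .simulate import (
    EXACT_MATCH_VARS,
    PROPENSITY_COVARIATES,
    SimulationConfig,
    simulate_cohort,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "read_cohort"]

log = logging.getLogger("sf36mode")

#: CSV dialect: UTF-8, comma-separated, header row, blank or NA for missing.
_NA_VALUES = ["", "NA"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class PipelineConfig:
    """Paths and options for one pipeline run."""

    out_dir: Path = Path("sf36mode_out")
    cohort_csv: Path | None = None  # None -> simulate
    scoring_spec: Path | None = None  # None -> shipped default
    simulation_config: Path | None = None  # None -> shipped default
    seed: int = 0
    treated_arm: str = "internet"
    covariates: list[str] = field(default_factory=lambda: list(PROPENSITY_COVARIATES))
    exact_vars: list[str] = field(default_factory=lambda: list(EXACT_MATCH_VARS))
    bootstrap_reps: int = 10_000


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV (one row per participant, items as item_1..item_36)."""
    df = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False)
    for i in range(1, 37):
        col = f"item_{i}"
        if col in df.columns:
            df[col] = pd.array(pd.to_numeric(df[col], errors="raise"), dtype="Int64")
    return df


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kw):
            try:
                return fn(*args, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc

        return wrapped

    return deco


@_stage("simulate")
def _get_cohort(cfg: PipelineConfig) -> pd.DataFrame:
    if cfg.cohort_csv is not None:
        log.info("loading cohort from %s", cfg.cohort_csv)
        return read_cohort(cfg.cohort_csv)
    sim = (
        SimulationConfig.from_yaml(cfg.simulation_config)
        if cfg.simulation_config
        else SimulationConfig.default()
    )
    log.info("simulating cohort: n_per_arm=%d seed=%d", sim.n_per_arm, cfg.seed)
    return simulate_cohort(sim, seed=cfg.seed)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write the artifact files into ``cfg.out_dir``.

    Returns a summary dict (also written as ``run_log.json``) with response
    rates, matched-pair count, global balance figures and file paths.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = ScoringSpec.from_yaml(cfg.scoring_spec) if cfg.scoring_spec else ScoringSpec.default()

    cohort = _get_cohort(cfg)
    cohort.to_csv(out / "cohort.csv", index=False)

    # --- response rates -----------------------------------------------------
    arms = sorted(cohort["arm"].unique())
    if len(arms) != 2:
        raise PipelineError(f"[ingest] expected 2 arms, found {arms}")
    treated_arm = cfg.treated_arm
    control_arm = next(a for a in arms if a != treated_arm)
    n_t = int((cohort["arm"] == treated_arm).sum())
    n_c = int((cohort["arm"] == control_arm).sum())
    k_t = int(cohort.loc[cohort["arm"] == treated_arm, "responder"].sum())
    k_c = int(cohort.loc[cohort["arm"] == control_arm, "responder"].sum())
    rates = compare_proportions(k_t, n_t, k_c, n_c)
    log.info(
        "response: %s %d/%d (%.1f%%) vs %s %d/%d (%.1f%%), p=%s",
        treated_arm, k_t, n_t, 100 * rates.rate_1,
        control_arm, k_c, n_c, 100 * rates.rate_2, format_p(rates.p_value),
    )

    # --- scoring ------------------------------------------------------------
    responders = cohort[cohort["responder"] == 1].set_index("id")
    scored = _score_stage(responders, spec)
    scored.reset_index().to_csv(out / "scored.csv", index=False)
    n_valid = {s: int(scored[f"valid_{s}"].sum()) for s in SCALE_ORDER}
    log.info("scored %d responders; valid per scale: %s", len(scored), n_valid)

    # --- reliability --------------------------------------------------------
    rel = _reliability_stage(responders.reset_index(), spec)
    rel.to_csv(out / "reliability.csv", index=False)
    flagged = rel[~rel["acceptable"]]
    if len(flagged):
        log.warning("scales with alpha <= .7: %s",
                    flagged[["group", "scale", "alpha"]].to_dict("records"))

    # --- matching -----------------------------------------------------------
    treated = responders["arm"] == treated_arm
    model, matched, balance = _match_stage(responders, cfg, treated)
    matched.to_frame().to_csv(out / "pairs.csv", index=False)
    balance.to_frame().to_csv(out / "balance.csv", index=False)
    log.info(
        "matched %d pairs (%d treated unmatched); global SMD %0.4f -> %0.4f, "
        "balance improvement %.0f%%",
        len(matched.pairs), len(matched.unmatched_treated),
        balance.global_before, balance.global_after,
        balance.balance_improvement_pct,
    )

    # --- comparison ---------------------------------------------------------
    cmp_un = _compare_stage(
        scored[treated], scored[~treated], treated_arm, control_arm, cfg
    )
    cmp_un.to_csv(out / "comparison_unmatched.csv", index=False)
    cmp_m = _compare_stage(
        scored.loc[matched.treated_ids],
        scored.loc[matched.control_ids],
        treated_arm,
        control_arm,
        cfg,
    )
    cmp_m.to_csv(out / "comparison_matched.csv", index=False)
    log.info("comparison tables written (no multiple-testing adjustment applied)")

    summary = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "n_enrolled": {treated_arm: n_t, control_arm: n_c},
        "n_responders": {treated_arm: k_t, control_arm: k_c},
        "response_rate_pct": {
            treated_arm: 100 * rates.rate_1,
            control_arm: 100 * rates.rate_2,
        },
        "response_rate_p": rates.p_value,
        "n_pairs": len(matched.pairs),
        "n_treated_unmatched": len(matched.unmatched_treated),
        "global_smd_before": balance.global_before,
        "global_smd_after": balance.global_after,
        "balance_improvement_pct": balance.balance_improvement_pct,
        "artifacts": sorted(p.name for p in out.glob("*.csv")),
    }
    (out / "run_log.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


@_stage("score")
def _score_stage(responders, spec):
    return score_cohort(responders, spec)


@_stage("reliability")
def _reliability_stage(responders, spec):
    return reliability_report(responders, spec, group_col="arm")


@_stage("match")
def _match_stage(responders, cfg, treated):
    model = fit_propensity(responders, cfg.covariates, treated)
    matched = greedy_match(
        model, responders[cfg.exact_vars] if cfg.exact_vars else None
    )
    if not matched.pairs:
        raise ValueError("no pairs could be formed")
    return model, matched, balance_report(model, matched)


@_stage("compare")
def _compare_stage(scored_t, scored_c, label_t, label_c, cfg):
    return compare_groups(
        scored_t, scored_c, label_t, label_c, reps=cfg.bootstrap_reps, seed=cfg.seed
    )


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(
        {k: str(v) for k, v in vars(cfg).items()}, sort_keys=True
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
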