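"""SF-36 item-level scoring.

The SF-36 health survey asks 36 precoded questions.  Thirty-five of them are
grouped into 8 scales (physical functioning PF, role-physical RP, bodily
pain BP, general health GH, vitality VT, social functioning SF,
role-emotional RE, mental health MH); the remaining item (health transition)
enters no score.  Each answer code is first recoded to a calibrated item
value (reverse-coded and recalibrated items included), the calibrated values
of a scale are summed, and the raw sum is normalised to 0-100::

    score = 100 * (raw_sum - min_sum) / (max_sum - min_sum)

A scale is scorable only when at least half of its items are answered
(``n_answered >= ceil(k/2)``); missing items are then imputed with the
person-specific mean of the answered items of the same scale.  The two
norm-based component summaries are weighted sums of scale z-scores against
general-population norms, calibrated to mean 50 and SD 10::

    PCS/MCS = 50 + 10 * sum_s w_s * (scale_s - norm_mean_s) / norm_sd_s

All numeric tables (item-scale map, recode tables, ranges, norms, factor
weights) live in a :class:`ScoringSpec`, loadable from YAML; the shipped
default is the standard SF-36 v1 configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SCALE_ORDER",
    "ItemResponse",
    "InvalidResponseError",
    "ScoringSpec",
    "ScaleScore",
    "ScoreProfile",
    "recode_item",
    "score_scale",
    "score_components",
    "score_respondent",
    "score_cohort",
    "item_columns",
]

#: Canonical scale order used in reports.
SCALE_ORDER = ("PF", "RP", "BP", "GH", "VT", "SF", "RE", "MH")

#: Expected item counts per scale (structural invariant of the instrument).
_SCALE_SIZES = {"PF": 10, "RP": 4, "BP": 2, "GH": 5, "VT": 4, "SF": 2, "RE": 3, "MH": 5}


class InvalidResponseError(ValueError):
    """An answer code outside the admissible range for its item."""


class ConfigurationError(ValueError):
    """A scoring-spec table is malformed or an unknown scale was requested."""


class ItemResponse(NamedTuple):
    """One answer: item number (1-36) and the raw precoded choice, or None."""

    item_id: int
    raw_code: int | None


@dataclass(frozen=True)
class ScoringSpec:
    """Declarative scoring tables for one SF-36 configuration.

    Parameters
    ----------
    scale_items
        Scale name -> ordered item ids belonging to the scale.
    recode_tables
        Item id -> total map from admissible raw codes to calibrated values.
    scale_ranges
        Scale name -> (minimum, maximum) possible raw sums.
    summary_weights
        Component name ("PCS", "MCS") -> scale name -> factor coefficient.
    norm_means, norm_sds
        General-population norms used for the component z-scores.
    excluded_items
        Items that enter no score (the health-transition item by default).
    """

    scale_items: Mapping[str, tuple[int, ...]]
    recode_tables: Mapping[int, Mapping[int, float]]
    scale_ranges: Mapping[str, tuple[float, float]]
    summary_weights: Mapping[str, Mapping[str, float]]
    norm_means: Mapping[str, float]
    norm_sds: Mapping[str, float]
    excluded_items: tuple[int, ...] = field(default=(2,))

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        scales = dict(self.scale_items)
        if set(scales) != set(SCALE_ORDER):
            raise ConfigurationError(
                f"scales must be exactly {SCALE_ORDER}, got {sorted(scales)}"
            )
        used = [i for items in scales.values() for i in items]
        if len(used) != len(set(used)):
            raise ConfigurationError("an item appears in more than one scale")
        for s, k in _SCALE_SIZES.items():
            if len(scales[s]) != k:
                raise ConfigurationError(f"scale {s} must have {k} items, got {len(scales[s])}")
        all_items = set(used) | set(self.excluded_items)
        if all_items != set(range(1, 37)):
            raise ConfigurationError("scales plus excluded items must cover items 1..36")
        for i in used:
            if i not in self.recode_tables:
                raise ConfigurationError(f"item {i} has no recode table")
        for s, (lo, hi) in self.scale_ranges.items():
            if hi <= lo:
                raise ConfigurationError(f"degenerate score range for scale {s}")
        for s, sd in self.norm_sds.items():
            if sd <= 0:
                raise ConfigurationError(f"norm SD for scale {s} must be positive")

    def scale_of(self, item_id: int) -> str | None:
        for s, items in self.scale_items.items():
            if item_id in items:
                return s
        return None

    @classmethod
    def from_yaml(cls, path) -> "ScoringSpec":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ScoringSpec":
        return cls(
            scale_items={s: tuple(v) for s, v in raw["scales"].items()},
            recode_tables={
                int(i): {int(c): float(v) for c, v in tbl.items()}
                for i, tbl in raw["recode_tables"].items()
            },
            scale_ranges={s: (float(v[0]), float(v[1])) for s, v in raw["scale_ranges"].items()},
            summary_weights={
                comp: {s: float(w) for s, w in ws.items()}
                for comp, ws in raw["summary_weights"].items()
            },
            norm_means={s: float(v) for s, v in raw["norm_means"].items()},
            norm_sds={s: float(v) for s, v in raw["norm_sds"].items()},
            excluded_items=tuple(raw.get("excluded_items", (2,))),
        )

    @classmethod
    def default(cls) -> "ScoringSpec":
        """The shipped standard SF-36 v1 configuration."""
        ref = resources.files("sf36mode.data") / "sf36_v1_default.yaml"
        return cls.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))


class ScaleScore(NamedTuple):
    score: float  # 0-100, or NaN when the half-scale rule fails
    n_answered: int
    imputed: bool


@dataclass
class ScoreProfile:
    """Scored profile for one respondent.

    Scale scores are NaN when invalid (fewer than half the items answered);
    ``pcs``/``mcs`` are NaN whenever any scale score is invalid.
    """

    scale_scores: dict[str, float]
    pcs: float
    mcs: float
    n_items_answered: dict[str, int]
    imputed: dict[str, bool]

    def valid(self, scale: str) -> bool:
        return not math.isnan(self.scale_scores[scale])


def recode_item(resp: ItemResponse, spec: ScoringSpec) -> float | None:
    """Map a raw answer code to its calibrated item value.

    Missing answers (``raw_code is None``) propagate as ``None``.  A code
    outside the item's admissible range raises :class:`InvalidResponseError`.
    """
    table = spec.recode_tables.get(resp.item_id)
    if table is None:
        raise ConfigurationError(f"item {resp.item_id} has no recode table")
    if resp.raw_code is None:
        return None
    try:
        return table[resp.raw_code]
    except KeyError:
        raise InvalidResponseError(
            f"item {resp.item_id}: answer code {resp.raw_code} is not in the "
            f"admissible range {sorted(table)}"
        ) from None


def score_scale(
    items: Sequence[ItemResponse], scale: str, spec: ScoringSpec
) -> ScaleScore:
    """Score one scale for one respondent.

    Applies the half-scale validity rule, person-mean imputation of missing
    items, and the 0-100 range normalisation.
    """
    if scale not in spec.scale_items:
        raise ConfigurationError(f"unknown scale {scale!r}")
    wanted = spec.scale_items[scale]
    by_id = {r.item_id: r for r in items}
    values = []
    for item_id in wanted:
        resp = by_id.get(item_id, ItemResponse(item_id, None))
        values.append(recode_item(resp, spec))
    answered = [v for v in values if v is not None]
    k = len(wanted)
    n_answered = len(answered)
    if n_answered < math.ceil(k / 2):
        return ScaleScore(float("nan"), n_answered, False)
    person_mean = sum(answered) / n_answered
    raw_sum = sum(v if v is not None else person_mean for v in values)
    lo, hi = spec.scale_ranges[scale]
    return ScaleScore(100.0 * (raw_sum - lo) / (hi - lo), n_answered, n_answered < k)


def score_components(
    scale_scores: Mapping[str, float], spec: ScoringSpec
) -> tuple[float, float]:
    """Norm-based component summaries (PCS, MCS) from 8 valid scale scores.

    Returns (NaN, NaN) if any scale score is missing or NaN.
    """
    out = []
    for comp in ("PCS", "MCS"):
        acc = 0.0
        for s in SCALE_ORDER:
            val = scale_scores.get(s, float("nan"))
            if math.isnan(val):
                return float("nan"), float("nan")
            z = (val - spec.norm_means[s]) / spec.norm_sds[s]
            acc += spec.summary_weights[comp].get(s, 0.0) * z
        out.append(50.0 + 10.0 * acc)
    return out[0], out[1]


def score_respondent(
    responses: Sequence[ItemResponse] | Mapping[int, int | None],
    spec: ScoringSpec | None = None,
) -> ScoreProfile:
    """Score all 8 scales and both component summaries for one respondent."""
    spec = spec or ScoringSpec.default()
    if isinstance(responses, Mapping):
        responses = [ItemResponse(i, c) for i, c in responses.items()]
    scale_scores: dict[str, float] = {}
    n_ans: dict[str, int] = {}
    imputed: dict[str, bool] = {}
    for s in SCALE_ORDER:
        res = score_scale(responses, s, spec)
        scale_scores[s] = res.score
        n_ans[s] = res.n_answered
        imputed[s] = res.imputed
    pcs, mcs = score_components(scale_scores, spec)
    return ScoreProfile(scale_scores, pcs, mcs, n_ans, imputed)


def item_columns(n: int = 36) -> list[str]:
    """Column names ``item_1..item_36`` used in cohort CSVs."""
    return [f"item_{i}" for i in range(1, n + 1)]


def score_cohort(df: pd.DataFrame, spec: ScoringSpec | None = None) -> pd.DataFrame:
    """Vectorised scoring of a cohort table.

    ``df`` needs columns ``item_1``..``item_36`` holding integer codes or
    NA.  Returns a frame indexed like ``df`` with the 8 scale columns,
    ``PCS``/``MCS``, and per-scale ``n_answered_*`` / ``valid_*`` columns.
    Inadmissible codes raise :class:`InvalidResponseError`.

    Person-mean imputation makes the imputed raw sum equal
    ``k * mean(answered values)``, which is what is computed here.
    """
    spec = spec or ScoringSpec.default()
    out = pd.DataFrame(index=df.index)
    calibrated: dict[int, np.ndarray] = {}
    for s in SCALE_ORDER:
        for item_id in spec.scale_items[s]:
            col = pd.to_numeric(df[f"item_{item_id}"], errors="coerce")
            table = spec.recode_tables[item_id]
            bad = col.notna() & ~col.isin(list(table))
            if bad.any():
                idx = df.index[bad][0]
                raise InvalidResponseError(
                    f"item {item_id}: answer code {col[idx]!r} (row {idx!r}) is "
                    f"not in the admissible range {sorted(table)}"
                )
            calibrated[item_id] = col.map(table).to_numpy(dtype=float)
    for s in SCALE_ORDER:
        vals = np.column_stack([calibrated[i] for i in spec.scale_items[s]])
        k = vals.shape[1]
        n_answered = np.sum(~np.isnan(vals), axis=1)
        person_mean = np.divide(
            np.nansum(vals, axis=1),
            n_answered,
            out=np.full(len(vals), np.nan),
            where=n_answered > 0,
        )
        raw_sum = k * person_mean
        lo, hi = spec.scale_ranges[s]
        score = 100.0 * (raw_sum - lo) / (hi - lo)
        valid = n_answered >= np.ceil(k / 2)
        out[s] = np.where(valid, score, np.nan)
        out[f"n_answered_{s}"] = n_answered
        out[f"valid_{s}"] = valid
    z = {
        s: (out[s].to_numpy() - spec.norm_means[s]) / spec.norm_sds[s]
        for s in SCALE_ORDER
    }
    for comp in ("PCS", "MCS"):
        acc = np.zeros(len(out))
        for s in SCALE_ORDER:
            acc = acc + spec.summary_weights[comp].get(s, 0.0) * z[s]
        out[comp] = 50.0 + 10.0 * acc  # NaN whenever any scale is NaN
    return out
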