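"""Unit and property tests for SF-36 item recoding and scale scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sf36mode.scoring import (
    SCALE_ORDER,
    ConfigurationError,
    InvalidResponseError,
    ItemResponse,
    ScoringSpec,
    recode_item,
    score_cohort,
    score_components,
    score_respondent,
    score_scale,
)
from .conftest import random_questionnaires


def best_answers(spec):
    return {i: max(t, key=t.get) for i, t in spec.recode_tables.items()}


def worst_answers(spec):
    return {i: min(t, key=t.get) for i, t in spec.recode_tables.items()}


class TestRecodeItem:
    def test_identity_item_passes_code_through(self, spec):
        # a physical-functioning item uses identity calibration on codes 1..3
        assert recode_item(ItemResponse(3, 2), spec) == 2

    def test_missing_propagates(self, spec):
        assert recode_item(ItemResponse(7, None), spec) is None

    def test_general_health_recalibration_table(self, spec):
        # the current-health rating uses the standard nonlinear recalibration
        assert recode_item(ItemResponse(1, 2), spec) == spec.recode_tables[1][2]
        assert recode_item(ItemResponse(1, 2), spec) == pytest.approx(4.4)

    def test_reverse_coded_item(self, spec):
        # social-functioning interference item: best health = code 1
        assert recode_item(ItemResponse(20, 1), spec) == 5

    def test_out_of_range_code_names_item_and_code(self, spec):
        with pytest.raises(InvalidResponseError, match=r"item 3.*code 9"):
            recode_item(ItemResponse(3, 9), spec)


class TestScoreScale:
    @pytest.mark.parametrize("scale", SCALE_ORDER)
    def test_bounds_by_construction(self, spec, scale):
        items_best = [ItemResponse(i, best_answers(spec)[i]) for i in spec.scale_items[scale]]
        items_worst = [ItemResponse(i, worst_answers(spec)[i]) for i in spec.scale_items[scale]]
        assert score_scale(items_best, scale, spec).score == pytest.approx(100.0)
        assert score_scale(items_worst, scale, spec).score == pytest.approx(0.0)

    @pytest.mark.parametrize("scale", SCALE_ORDER)
    def test_half_scale_boundary(self, spec, scale):
        """Exactly ceil(k/2) answered items is valid; one fewer is invalid."""
        item_ids = spec.scale_items[scale]
        k = len(item_ids)
        need = math.ceil(k / 2)
        best = best_answers(spec)

        def with_n_answered(n):
            return [
                ItemResponse(i, best[i] if j < n else None)
                for j, i in enumerate(item_ids)
            ]

        ok = score_scale(with_n_answered(need), scale, spec)
        assert not math.isnan(ok.score)
        assert ok.n_answered == need
        assert ok.imputed == (need < k)
        bad = score_scale(with_n_answered(need - 1), scale, spec)
        assert math.isnan(bad.score)

    def test_person_mean_imputation_identity(self, spec):
        """2 answered + 2 missing scores like all 4 at (v1, v2, m, m)."""
        ids = spec.scale_items["VT"]  # 4 items, codes 1..6
        partial = [ItemResponse(ids[0], 2), ItemResponse(ids[1], 5),
                   ItemResponse(ids[2], None), ItemResponse(ids[3], None)]
        v1 = recode_item(ItemResponse(ids[0], 2), spec)
        v2 = recode_item(ItemResponse(ids[1], 5), spec)
        m = (v1 + v2) / 2
        lo, hi = spec.scale_ranges["VT"]
        expected = 100 * (v1 + v2 + 2 * m - lo) / (hi - lo)
        res = score_scale(partial, "VT", spec)
        assert res.score == pytest.approx(expected)
        assert res.imputed

    def test_unknown_scale_is_configuration_error(self, spec):
        with pytest.raises(ConfigurationError):
            score_scale([], "XX", spec)


class TestScoreComponents:
    def test_norm_mean_profile_gives_50_50(self, spec):
        pcs, mcs = score_components(dict(spec.norm_means), spec)
        assert pcs == pytest.approx(50.0)
        assert mcs == pytest.approx(50.0)

    def test_zero_weights_give_50_50(self, spec):
        degenerate = ScoringSpec(
            scale_items=spec.scale_items,
            recode_tables=spec.recode_tables,
            scale_ranges=spec.scale_ranges,
            summary_weights={"PCS": {}, "MCS": {}},
            norm_means=spec.norm_means,
            norm_sds=spec.norm_sds,
            excluded_items=spec.excluded_items,
        )
        scores = {s: 30.0 + 5 * i for i, s in enumerate(SCALE_ORDER)}
        assert score_components(scores, degenerate) == pytest.approx((50.0, 50.0))

    def test_single_weight_one_sd_above_mean(self, spec):
        """One scale 1 norm-SD up with a single weight w gives 50 + 10w."""
        w = 0.37
        single = ScoringSpec(
            scale_items=spec.scale_items,
            recode_tables=spec.recode_tables,
            scale_ranges=spec.scale_ranges,
            summary_weights={"PCS": {"GH": w}, "MCS": {}},
            norm_means=spec.norm_means,
            norm_sds=spec.norm_sds,
            excluded_items=spec.excluded_items,
        )
        scores = dict(spec.norm_means)
        scores["GH"] = spec.norm_means["GH"] + spec.norm_sds["GH"]
        pcs, mcs = score_components(scores, single)
        assert pcs == pytest.approx(50 + 10 * w)
        assert mcs == pytest.approx(50.0)

    def test_invalid_scale_invalidates_both(self, spec):
        scores = dict(spec.norm_means)
        scores["MH"] = float("nan")
        pcs, mcs = score_components(scores, spec)
        assert math.isnan(pcs) and math.isnan(mcs)

    @pytest.mark.parametrize("scale", SCALE_ORDER)
    def test_affine_in_each_scale(self, spec, scale):
        """PCS is affine in each scale score, slope 10 * w / norm_sd."""
        base = dict(spec.norm_means)
        hi = dict(base, **{scale: base[scale] + 7.0})
        p0, _ = score_components(base, spec)
        p1, _ = score_components(hi, spec)
        slope = 10 * spec.summary_weights["PCS"][scale] / spec.norm_sds[scale]
        assert (p1 - p0) / 7.0 == pytest.approx(slope, abs=1e-10)


class TestScoreRespondent:
    def test_best_health_is_all_100(self, spec):
        prof = score_respondent(best_answers(spec), spec)
        assert all(v == pytest.approx(100.0) for v in prof.scale_scores.values())

    def test_fully_missing_is_all_invalid(self, spec):
        prof = score_respondent({i: None for i in range(1, 37)}, spec)
        assert all(math.isnan(v) for v in prof.scale_scores.values())
        assert math.isnan(prof.pcs) and math.isnan(prof.mcs)

    def test_hand_scored_fixture(self, spec):
        """A partially answered questionnaire against a by-hand calculation.

        PF: items 3..12 all 'limited a little' (code 2) -> raw 20 -> 50.
        RP: codes (1,1,2,2) -> raw 6 -> 50.
        BP: item 21 code 3 (-> 4.2), item 22 code 2 (-> 4.75) -> raw 8.95
            -> 100*(8.95-2)/10 = 69.5.
        GH: item 1 code 2 (-> 4.4), items 33..36 codes (2,2,2,2) ->
            values (2, 4, 2, 4) -> raw 16.4 -> 100*(16.4-5)/20 = 57.
        VT: codes (3,3,3,missing) -> values (4,4,3), person mean 11/3 ->
            raw 11 + 11/3 = 44/3 -> 100*(44/3-4)/20 = 160/3 = 53.333...
        SF: item 20 code 2 (-> 4), item 32 code 2 (-> 2) -> raw 6 -> 50.
        RE: codes (2,2,1) -> raw 5 -> 66.666...
        MH: codes (5,5,2,5,2) -> values (5,5,5,5,5) -> raw 25 -> 80.
        """
        answers = {i: 2 for i in range(3, 13)}
        answers.update({13: 1, 14: 1, 15: 2, 16: 2})
        answers.update({21: 3, 22: 2})
        answers.update({1: 2, 33: 2, 34: 2, 35: 2, 36: 2})
        answers.update({23: 3, 27: 3, 29: 3, 31: None})
        answers.update({20: 2, 32: 2})
        answers.update({17: 2, 18: 2, 19: 1})
        answers.update({24: 5, 25: 5, 26: 2, 28: 5, 30: 2})
        answers[2] = 3
        prof = score_respondent(answers, spec)
        expected = {
            "PF": 50.0, "RP": 50.0, "BP": 69.5, "GH": 57.0,
            "VT": 160 / 3, "SF": 50.0, "RE": 200 / 3, "MH": 80.0,
        }
        for s, v in expected.items():
            assert prof.scale_scores[s] == pytest.approx(v), s
        assert prof.imputed["VT"] and not prof.imputed["MH"]
        # components by hand from the z-score formula
        for comp, got in (("PCS", prof.pcs), ("MCS", prof.mcs)):
            want = 50 + 10 * sum(
                spec.summary_weights[comp][s]
                * (expected[s] - spec.norm_means[s]) / spec.norm_sds[s]
                for s in SCALE_ORDER
            )
            assert got == pytest.approx(want)


@st.composite
def questionnaires(draw):
    spec = ScoringSpec.default()
    answers = {}
    for item_id, table in spec.recode_tables.items():
        codes = sorted(table)
        answers[item_id] = draw(st.one_of(st.none(), st.sampled_from(codes)))
    return answers


class TestProperties:
    @given(questionnaires())
    def test_valid_scores_within_bounds(self, answers):
        prof = score_respondent(answers)
        for v in prof.scale_scores.values():
            assert math.isnan(v) or 0.0 <= v <= 100.0

    @given(questionnaires(), st.data())
    def test_improving_one_item_never_decreases_scale(self, answers, data):
        spec = ScoringSpec.default()
        answered = [i for i, c in answers.items() if c is not None and spec.scale_of(i)]
        if not answered:
            return
        item = data.draw(st.sampled_from(answered))
        table = spec.recode_tables[item]
        better = [c for c in table if table[c] > table[answers[item]]]
        if not better:
            return
        scale = spec.scale_of(item)
        before = score_respondent(answers, spec).scale_scores[scale]
        improved = {**answers, item: data.draw(st.sampled_from(better))}
        after = score_respondent(improved, spec).scale_scores[scale]
        if math.isnan(before):
            # too few answers: the scale stays invalid either way
            assert math.isnan(after)
        else:
            assert after >= before - 1e-12

    @given(questionnaires(), st.data())
    def test_imputation_identity(self, answers, data):
        """Setting an answered item to the person-mean then blanking it
        leaves the scale score unchanged."""
        spec = ScoringSpec.default()
        prof = score_respondent(answers, spec)
        candidates = [
            s for s in SCALE_ORDER
            if prof.n_items_answered[s] > math.ceil(len(spec.scale_items[s]) / 2)
        ]
        if not candidates:
            return
        scale = data.draw(st.sampled_from(candidates))
        items = spec.scale_items[scale]
        answered = [i for i in items if answers.get(i) is not None]
        drop = data.draw(st.sampled_from(answered))
        others = [recode_item(ItemResponse(i, answers[i]), spec)
                  for i in answered if i != drop]
        mean_others = sum(others) / len(others)
        # direct raw-sum computation with the dropped item at the person mean
        lo, hi = spec.scale_ranges[scale]
        expected = 100 * (sum(others) + (len(items) - len(others)) * mean_others - lo) / (hi - lo)
        blanked = {**answers, drop: None}
        got = score_respondent(blanked, spec).scale_scores[scale]
        assert got == pytest.approx(expected)


def test_vectorised_cohort_scoring_matches_per_respondent(spec):
    rng = np.random.default_rng(5)
    df = random_questionnaires(rng, 80, spec)
    table = score_cohort(df, spec)
    for idx in df.index[:25]:
        answers = {
            i: (None if pd.isna(df.loc[idx, f"item_{i}"]) else int(df.loc[idx, f"item_{i}"]))
            for i in range(1, 37)
        }
        prof = score_respondent(answers, spec)
        for s in SCALE_ORDER:
            a, b = table.loc[idx, s], prof.scale_scores[s]
            assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)
            assert table.loc[idx, f"n_answered_{s}"] == prof.n_items_answered[s]
        for comp, v in (("PCS", prof.pcs), ("MCS", prof.mcs)):
            a = table.loc[idx, comp]
            assert (math.isnan(a) and math.isnan(v)) or a == pytest.approx(v)


def test_cohort_scoring_rejects_inadmissible_codes(spec):
    df = pd.DataFrame({f"item_{i}": pd.array([1], dtype="Int64") for i in range(1, 37)})
    df.loc[0, "item_5"] = 7
    with pytest.raises(InvalidResponseError, match="item 5"):
        score_cohort(df, spec)


def test_spec_structure_is_validated(spec):
    bad_scales = {s: list(v) for s, v in spec.scale_items.items()}
    bad_scales["PF"] = bad_scales["PF"][:-1]  # 9 items
    with pytest.raises(ConfigurationError):
        ScoringSpec(
            scale_items={s: tuple(v) for s, v in bad_scales.items()},
            recode_tables=spec.recode_tables,
            scale_ranges=spec.scale_ranges,
            summary_weights=spec.summary_weights,
            norm_means=spec.norm_means,
            norm_sds=spec.norm_sds,
        )
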