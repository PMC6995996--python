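"""Scoring unit and property tests against the hand-entered chart oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ewscompare.scoring import (
    AggregateScore,
    ValidationError,
    VitalSignSet,
    complete_mask,
    gcs_to_avpu,
    is_complete,
    score_frame,
    score_news,
    score_news2,
)
from ewscompare.tables import component_weight, load_news2_tables, load_news_tables

from ._oracle import (
    oracle_avpu,
    oracle_hr,
    oracle_news,
    oracle_news2_scale2,
    oracle_rr,
    oracle_sbp,
    oracle_spo2_scale1,
    oracle_spo2_scale2,
    oracle_temp,
)

NEWS = load_news_tables()
NEWS2 = load_news2_tables()


def obs(**over) -> VitalSignSet:
    base = dict(
        admission_id="x",
        heart_rate=70,
        systolic_bp=120,
        respiratory_rate=16,
        temperature=37.0,
        spo2=98,
        on_oxygen=False,
        consciousness="A",
    )
    base.update(over)
    return VitalSignSet(**base)


class TestGcsToAvpu:
    def test_endpoints(self):
        assert gcs_to_avpu(15) == "A"
        assert gcs_to_avpu(3) == "U"
        assert gcs_to_avpu(10) == "V"

    def test_exhaustive_and_monotone(self):
        expected = {15: "A", **{g: "V" for g in range(9, 15)},
                    **{g: "P" for g in range(4, 9)}, 3: "U"}
        order = {"A": 0, "V": 1, "P": 2, "U": 3}
        depths = []
        for g in range(15, 2, -1):
            cat = gcs_to_avpu(g)
            assert cat == expected[g]
            depths.append(order[cat])
        # deeper impairment never reverses as GCS falls
        assert depths == sorted(depths)

    @pytest.mark.parametrize("bad", [2, 16, 0, -1, "A", None])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError):
            gcs_to_avpu(bad)


class TestComponentWeights:
    @pytest.mark.parametrize(
        "param,value,expected",
        [("respiratory_rate", 16, 0), ("respiratory_rate", 25, 3)],
    )
    def test_chart_bands(self, param, value, expected):
        assert component_weight(param, value, NEWS.tables[param]) == expected

    def test_normal_saturation_on_air_scores_zero(self):
        assert NEWS.spo2_table(1, False).weight(100) == 0

    def test_exhaustive_per_parameter_grids(self):
        """Every integer value over the physiological range matches the oracle."""
        for v in range(0, 81):
            assert NEWS.tables["respiratory_rate"].weight(v) == oracle_rr(v)
        for v in range(0, 251):
            assert NEWS.tables["heart_rate"].weight(v) == oracle_hr(v)
        for v in range(0, 301):
            assert NEWS.tables["systolic_bp"].weight(v) == oracle_sbp(v)
        for d in range(300, 431):  # 30.0-43.0 by 0.1
            assert NEWS.tables["temperature"].weight(d / 10) == oracle_temp(d / 10)
        for v in range(50, 101):
            assert NEWS.spo2_table(1, False).weight(v) == oracle_spo2_scale1(v)
            assert NEWS2.spo2_table(1, True).weight(v) == oracle_spo2_scale1(v)
            for oxy in (False, True):
                assert NEWS2.spo2_table(2, oxy).weight(v) == oracle_spo2_scale2(v, oxy)

    def test_unimodal_weights_around_zero_band(self):
        """Weights never decrease moving away from the zero band."""
        for table in [*NEWS.tables.values(), NEWS.spo2_table(1, False)]:
            ws = [w for (_, _, w) in table.bins]
            zeros = [i for i, w in enumerate(ws) if w == 0]
            assert len(zeros) == 1
            z = zeros[0]
            left, right = ws[: z + 1], ws[z:]
            assert left == sorted(left, reverse=True)
            assert right == sorted(right)

    def test_rounding_half_up_at_recording_precision(self):
        # 20.4 rounds to 20 (weight 0); 20.5 rounds to 21 (weight 2)
        assert NEWS.tables["respiratory_rate"].weight(20.4) == 0
        assert NEWS.tables["respiratory_rate"].weight(20.5) == 2
        # temperature at 0.1 degC: 38.04 -> 38.0 (0), 38.05 -> 38.1 (1)
        assert NEWS.tables["temperature"].weight(38.04) == 0
        assert NEWS.tables["temperature"].weight(38.05) == 1

    def test_extreme_values_fall_into_extreme_bins(self):
        assert NEWS.tables["respiratory_rate"].weight(200) == 3
        assert NEWS.tables["heart_rate"].weight(0) == 3


class TestCompleteness:
    def test_complete(self, normal_vitals):
        assert is_complete(VitalSignSet("x", **normal_vitals))

    @pytest.mark.parametrize(
        "missing",
        ["heart_rate", "systolic_bp", "respiratory_rate", "temperature",
         "spo2", "on_oxygen", "consciousness"],
    )
    def test_each_missing_field_breaks_completeness(self, normal_vitals, missing):
        normal_vitals[missing] = None
        o = VitalSignSet("x", **normal_vitals)
        assert not is_complete(o)
        with pytest.raises(ValidationError):
            score_news(o)


class TestAggregateScores:
    def test_all_normal_scores_zero(self):
        assert score_news(obs()).value == 0

    def test_low_saturation_on_air(self):
        assert score_news(obs(spo2=90)).value == 3

    def test_flat_oxygen_weight(self):
        assert score_news(obs(spo2=98, on_oxygen=True)).value == 2

    def test_scale2_zero_band_covers_88_to_92(self):
        assert score_news2(obs(spo2=90), use_scale2=True).value == 0

    def test_scale2_high_saturation_on_oxygen(self):
        s = score_news2(obs(spo2=97, on_oxygen=True), use_scale2=True)
        assert s.value == 5
        assert s.components["spo2"] == 3
        assert s.components["supplemental_oxygen"] == 2

    def test_scale1_reproduces_news(self):
        assert score_news2(obs(spo2=90), use_scale2=False).value == 3

    def test_components_sum_to_value_and_max_bound(self):
        worst = obs(heart_rate=200, systolic_bp=60, respiratory_rate=40,
                    temperature=34.0, spo2=70, on_oxygen=True, consciousness="U")
        s = score_news(worst)
        assert s.value == sum(s.components.values()) == 20

    def test_component_sum_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            AggregateScore(5, "NEWS", {"a": 1})

    def test_gcs_input_converted_before_scoring(self):
        assert score_news(obs(consciousness=10)).value == 3  # GCS 10 -> V


VITALS_STRATEGY = st.fixed_dictionaries(
    {
        "heart_rate": st.integers(0, 250),
        "systolic_bp": st.integers(0, 300),
        "respiratory_rate": st.integers(0, 80),
        "temperature": st.integers(300, 430).map(lambda d: d / 10),
        "spo2": st.integers(50, 100),
        "on_oxygen": st.booleans(),
        "consciousness": st.sampled_from("AVPU"),
    }
)


class TestScoringProperties:
    @settings(max_examples=300, deadline=None)
    @given(VITALS_STRATEGY)
    def test_matches_oracle_and_scale_relations(self, v):
        o = obs(**v)
        news = score_news(o).value
        s1 = score_news2(o, use_scale2=False).value
        s2 = score_news2(o, use_scale2=True).value
        assert news == oracle_news(
            v["respiratory_rate"], v["temperature"], v["systolic_bp"],
            v["heart_rate"], v["spo2"], v["on_oxygen"], v["consciousness"],
        )
        assert s1 == news
        assert s2 == oracle_news2_scale2(
            v["respiratory_rate"], v["temperature"], v["systolic_bp"],
            v["heart_rate"], v["spo2"], v["on_oxygen"], v["consciousness"],
        )
        if not v["on_oxygen"]:
            assert s2 <= news

    @settings(max_examples=100, deadline=None)
    @given(VITALS_STRATEGY, st.randoms(use_true_random=False))
    def test_component_sum_order_invariant(self, v, rnd):
        comps = list(score_news(obs(**v)).components.items())
        rnd.shuffle(comps)
        assert sum(w for _, w in comps) == score_news(obs(**v)).value


class TestScoreFrame:
    def test_vectorised_agrees_with_scalar(self):
        rows = []
        cases = list(
            itertools.product(
                [8, 16, 25], [35.0, 37.0, 39.5], [85, 120, 225],
                [40, 70, 120], [85, 91, 94, 97], [0, 1], ["A", "P"],
            )
        )
        for hr_i, case in enumerate(cases):
            rr, t, sbp, hr, spo2, oxy, avpu = case
            rows.append(
                {
                    "admission_id": str(hr_i), "observed_at": "2016-01-01",
                    "heart_rate": hr, "systolic_bp": sbp, "respiratory_rate": rr,
                    "temperature": t, "spo2": spo2, "on_oxygen": oxy,
                    "avpu": avpu, "gcs": np.nan,
                }
            )
        df = pd.DataFrame(rows)
        news = score_frame(df, "news")
        news2_s2 = score_frame(df, "news2", scale2=True)
        for i, case in enumerate(cases):
            rr, t, sbp, hr, spo2, oxy, avpu = case
            o = obs(heart_rate=hr, systolic_bp=sbp, respiratory_rate=rr,
                    temperature=t, spo2=spo2, on_oxygen=bool(oxy),
                    consciousness=avpu)
            assert news[i] == score_news(o).value
            assert news2_s2[i] == score_news2(o, use_scale2=True).value

    def test_incomplete_rows_rejected_and_maskable(self):
        df = pd.DataFrame(
            [
                {"admission_id": "a", "observed_at": "2016-01-01", "heart_rate": 70,
                 "systolic_bp": 120, "respiratory_rate": 16, "temperature": 37.0,
                 "spo2": 98, "on_oxygen": 0, "avpu": "A", "gcs": np.nan},
                {"admission_id": "a", "observed_at": "2016-01-01", "heart_rate": 70,
                 "systolic_bp": 120, "respiratory_rate": 16, "temperature": np.nan,
                 "spo2": 98, "on_oxygen": 0, "avpu": "A", "gcs": np.nan},
            ]
        )
        assert complete_mask(df).tolist() == [True, False]
        with pytest.raises(ValidationError):
            score_frame(df, "news")
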