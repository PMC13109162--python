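"""Observation-set scoring against the published band cells, temperature
site correction, and trigger-rule semantics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ewsval.scoring import (ScoreResult, TriggerRule, adjust_temperature,
                            evaluate_trigger, score_frame, score_observation,
                            trigger_alerts, validate_observations)
from ewsval.tables import ValidationError


class TestTemperatureCorrection:
    @pytest.mark.parametrize("raw,site,expected", [
        (36.8, "forehead", 37.0),
        (36.8, "tympanic", 36.8),
        (35.0, "forehead", 35.2),
        (38.0, "axilla", 38.0),
        (37.1, "temporal", 37.1),
    ])
    def test_correction(self, raw, site, expected):
        assert adjust_temperature(raw, site) == pytest.approx(expected)

    def test_unknown_site_rejected(self):
        with pytest.raises(ValidationError, match="armpit"):
            adjust_temperature(36.8, "armpit")

    def test_missing_site_is_identity(self):
        assert adjust_temperature(36.8, None) == 36.8


# published band cells: (table fixture name, parameter, value, subscore)
BAND_CELLS = [
    ("gews", "pain", 7, 3),
    ("gews", "pain", 0, 0),
    ("gews", "spo2", 85, 3),
    ("gews", "spo2", 95, 0),
    ("gews", "o2_flow", 3, 2),
    ("gews", "o2_flow", 0, 0),
    ("gews", "consciousness", "agitated", 3),
    ("gews", "consciousness", "alert", 0),
    ("gews", "resp_rate", 25, 2),
    ("gews", "hr", 100, 2),
    ("gews", "temp", 37.8, 2),
    ("news", "resp_rate", 24, 2),
    ("news", "spo2", 94, 1),
    ("news", "o2_flow", 2, 2),
    ("news", "temp", 38.5, 1),
    ("news", "sbp", 100, 2),
    ("news", "hr", 95, 1),
    ("news", "consciousness", "alert", 0),
    ("news", "consciousness", "voice", 3),
    ("news", "consciousness", "agitated", 0),
]


@pytest.mark.parametrize("tname,param,value,expected", BAND_CELLS)
def test_published_band_cells(tname, param, value, expected, news, gews):
    table = news if tname == "news" else gews
    assert table.score_value(param, value) == expected


def test_gews_zero_band_observation_scores_zero(gews):
    obs = dict(resp_rate=16, spo2=95, o2_flow=0, temp=36.8,
               temp_site="tympanic", sbp=130, hr=70,
               consciousness="alert", pain=0)
    r = score_observation(obs, gews)
    assert r.total == 0 and r.max_single == 0
    assert set(r.provenance.values()) == {"measured"}


def test_news_zero_band_observation_scores_zero(news):
    obs = dict(resp_rate=16, spo2=98, o2_flow=0, temp=36.8,
               temp_site="tympanic", sbp=130, hr=70, consciousness="alert")
    assert score_observation(obs, news).total == 0


def test_news_composite_hand_scored_case(news):
    """RR 22, SpO2 94, on oxygen, T 38.5, SBP 100, HR 95, alert:
    subscores 2+1+2+1+2+1+0 sum to 9."""
    obs = dict(resp_rate=22, spo2=94, o2_flow=2, temp=38.5,
               temp_site="tympanic", sbp=100, hr=95, consciousness="alert")
    r = score_observation(obs, news)
    assert r.subscores == {"resp_rate": 2, "spo2": 1, "o2_flow": 2,
                           "temp": 1, "sbp": 2, "hr": 1, "consciousness": 0}
    assert r.total == 9


def test_missing_parameter_scores_zero_with_provenance(gews):
    r = score_observation({"consciousness": "alert"}, gews)
    assert r.total == 0
    assert r.provenance["resp_rate"] == "imputed_zero"
    assert r.provenance["consciousness"] == "measured"


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    rr=st.one_of(st.none(), st.integers(0, 60)),
    spo2=st.one_of(st.none(), st.integers(50, 100)),
    o2=st.one_of(st.none(), st.integers(0, 15)),
    temp=st.one_of(st.none(), st.floats(30.0, 43.0).map(lambda x: round(x, 1))),
    sbp=st.one_of(st.none(), st.integers(40, 260)),
    hr=st.one_of(st.none(), st.integers(20, 220)),
    cons=st.one_of(st.none(), st.sampled_from(
        ["alert", "voice", "pain", "unresponsive", "agitated"])),
    pain=st.one_of(st.none(), st.integers(0, 10)),
)
def test_total_is_sum_of_subscores(rr, spo2, o2, temp, sbp, hr, cons, pain):
    from ewsval import load_band_table

    obs = dict(resp_rate=rr, spo2=spo2, o2_flow=o2, temp=temp,
               temp_site="tympanic", sbp=sbp, hr=hr, consciousness=cons,
               pain=pain)
    for table in (load_band_table("news"), load_band_table("gews")):
        r = score_observation(obs, table)
        assert r.total == sum(r.subscores.values())
        assert r.max_single == max(r.subscores.values())
        assert 0 <= r.total <= table.max_total


def test_score_frame_matches_scalar_scoring(gews, rng):
    n = 100
    df = pd.DataFrame({
        "patient_id": ["p"] * n,
        "timestamp": pd.date_range("2022-09-01", periods=n, freq="h"),
        "resp_rate": rng.integers(5, 40, n).astype(float),
        "spo2": rng.integers(80, 100, n).astype(float),
        "o2_flow": rng.integers(0, 6, n).astype(float),
        "temp": np.round(rng.uniform(34, 40, n), 1),
        "temp_site": rng.choice(["tympanic", "forehead"], n),
        "sbp": rng.integers(80, 230, n).astype(float),
        "hr": rng.integers(40, 140, n).astype(float),
        "consciousness": rng.choice(["alert", "voice", "agitated"], n),
        "pain": rng.integers(0, 10, n).astype(float),
    })
    df.loc[::7, "resp_rate"] = np.nan
    frame = score_frame(df, gews)
    for i in range(n):
        row = df.iloc[i].to_dict()
        r = score_observation(row, gews)
        for p in gews.parameters:
            got = frame.iloc[i][f"{p}_score"]
            if np.isnan(row.get(p) if not isinstance(row.get(p), str) else 0.0):
                assert np.isnan(got)
            else:
                assert got == r.subscores[p]


class TestTriggerRules:
    @pytest.mark.parametrize("total,mx,rule,expected", [
        (4, 2, TriggerRule("GEWS>=5+S3", "gews", 5, True), False),
        (3, 3, TriggerRule("GEWS>=5+S3", "gews", 5, True), True),
        (3, 3, TriggerRule("GEWS>=5", "gews", 5, False), False),
        (4, 2, TriggerRule("GEWS>=4+S3", "gews", 4, True), True),
        (5, 2, TriggerRule("GEWS>=5", "gews", 5, False), True),
    ])
    def test_threshold_and_s3_clause(self, total, mx, rule, expected):
        assert evaluate_trigger((total, mx), rule) is expected

    def test_threshold_below_one_rejected(self):
        with pytest.raises(ValueError):
            TriggerRule("bad", "news", 0, False)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(subs=st.lists(st.integers(0, 3), min_size=4, max_size=8),
           bump=st.integers(0, 7), thr=st.integers(1, 10), s3=st.booleans())
    def test_raising_a_subscore_never_cancels_an_alert(self, subs, bump, thr, s3):
        rule = TriggerRule("r", "gews", thr, s3)
        before = evaluate_trigger((sum(subs), max(subs)), rule)
        i = bump % len(subs)
        raised = list(subs)
        raised[i] = 3
        after = evaluate_trigger((sum(raised), max(raised)), rule)
        assert after or not before

    def test_vectorised_matches_scalar(self, rng):
        total = rng.integers(0, 15, 500)
        mx = rng.integers(0, 4, 500)
        for rule in (TriggerRule("a", "gews", 5, True),
                     TriggerRule("b", "gews", 5, False)):
            vec = trigger_alerts(total, mx, rule)
            assert all(evaluate_trigger((t, m), rule) == v
                       for t, m, v in zip(total, mx, vec))


def test_validate_observations_rejects_bad_ranges():
    base = dict(patient_id=["p"], timestamp=["2022-09-01"],
                resp_rate=[16.0], spo2=[95.0], o2_flow=[0.0], temp=[36.8],
                temp_site=["tympanic"], sbp=[130.0], hr=[70.0],
                consciousness=["alert"], pain=[0.0])
    validate_observations(pd.DataFrame(base))
    bad = dict(base, spo2=[104.0])
    with pytest.raises(ValidationError):
        validate_observations(pd.DataFrame(bad))
    bad = dict(base, pain=[11.0])
    with pytest.raises(ValidationError):
        validate_observations(pd.DataFrame(bad))
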