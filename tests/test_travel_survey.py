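"""Filtering, summarising and mode-share arithmetic on travel surveys."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ithim_pa as ip
from ithim_pa.travel_survey import (
    DEFAULT_AGE_BANDS,
    MODES,
    SEXES,
    TravelRecord,
    format_band,
    parse_band,
)

from conftest import sex_level_summary


def rec(pid="p", sex="male", age=30, community=50_000, trips=(), weight=1.0):
    return TravelRecord(pid, sex, age, community, tuple(trips), weight)


class TestFilterRecords:
    def test_short_trip_dropped_person_kept(self):
        r = rec(trips=[("walk", 2.0)])
        out = ip.filter_records([r], 3, 10_000, 16)
        assert len(out) == 1 and out[0].trips == ()

    def test_empty_input(self):
        assert ip.filter_records([], 3, 10_000, 16) == []

    def test_community_and_age_exclusions_drop_whole_records(self):
        records = [
            rec("small", community=9_999, trips=[("walk", 10)]),
            rec("young", age=15, trips=[("walk", 10)]),
            rec("ok", trips=[("walk", 10)]),
        ]
        out = ip.filter_records(records, 3, 10_000, 16)
        assert [r.person_id for r in out] == ["ok"]

    def test_matches_brute_force_on_synthetic_survey(self):
        records = ip.generate_travel_survey(ip.setting_profile("ew", 1_000, seed=3))
        out = ip.filter_records(records, 3, 10_000, 16)
        expected = []
        for r in records:  # independent application of the three rules
            if r.community_size < 10_000:
                continue
            if r.age < 16:
                continue
            trips = tuple(t for t in r.trips if t[1] >= 3)
            expected.append((r.person_id, trips))
        assert [(r.person_id, r.trips) for r in out] == expected

    def test_idempotent(self):
        records = ip.generate_travel_survey(ip.setting_profile("nl", 500, seed=1))
        once = ip.filter_records(records)
        twice = ip.filter_records(once)
        assert once == twice

    def test_negative_duration_rejected_naming_record(self):
        with pytest.raises(ValueError, match="bad-person"):
            rec("bad-person", trips=[("walk", -1.0)])


class TestSummarizeTravel:
    def test_nontravellers_stay_in_denominator(self):
        records = [
            rec("a", trips=[("walk", 20.0)]),
            rec("b", trips=[]),
        ]
        s = ip.summarize_travel(records)
        assert s.mean_minutes("male", (30, 45), "walk") == pytest.approx(10.0)

    def test_weighted_mean(self):
        records = [
            rec("a", trips=[("walk", 20.0)], weight=1.0),
            rec("b", trips=[], weight=3.0),
        ]
        s = ip.summarize_travel(records)
        assert s.mean_minutes("male", (30, 45), "walk") == pytest.approx(5.0)

    def test_permutation_invariant_and_matches_naive_loop(self):
        records = ip.generate_travel_survey(ip.setting_profile("ch", 2_000, seed=5))
        records = ip.filter_records(records)
        s1 = ip.summarize_travel(records)
        rng = np.random.default_rng(0)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        s2 = ip.summarize_travel(shuffled)
        for key, v in s1.entries.items():
            assert s2.entries[key] == pytest.approx(v, abs=1e-9)
        # naive per-person accumulation
        for sex in SEXES:
            for band in DEFAULT_AGE_BANDS:
                persons = [
                    r for r in records
                    if r.sex == sex and band[0] <= r.age < band[1]
                ]
                if not persons:
                    continue
                for mode in MODES:
                    naive = sum(
                        r.survey_weight * sum(d for m, d in r.trips if m == mode)
                        for r in persons
                    ) / sum(r.survey_weight for r in persons)
                    assert s1.entries[(sex, band, mode)] == pytest.approx(naive, abs=1e-9)

    def test_empty_stratum_is_missing_not_zero(self, caplog):
        records = [rec("a", age=20, trips=[("walk", 10.0)])]
        with caplog.at_level("WARNING"):
            s = ip.summarize_travel(records)
        assert np.isnan(s.mean_minutes("female", (80, 120), "walk"))
        assert "empty stratum" in caplog.text

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            ip.summarize_travel([], age_bands=[(15, 40), (30, 60)])


class TestModeShares:
    @pytest.mark.parametrize(
        "setting,sex,mode,expected_pct",
        [
            ("ch", "male", "walk", 25.4),
            ("ch", "female", "walk", 36.1),
            ("nl", "male", "cycle", 16.6),
            ("ca", "female", "car", 77.2),
        ],
    )
    def test_published_sex_level_shares(self, setting, sex, mode, expected_pct):
        shares = ip.mode_shares(sex_level_summary(setting), group_by_sex_only=True)
        assert round(100 * shares[(sex, mode)], 1) == expected_pct

    def test_shares_sum_to_one(self, summaries):
        for summary in summaries.values():
            shares = ip.mode_shares(summary)
            for sex in SEXES:
                for band in summary.age_bands:
                    total = sum(shares[(sex, band, m)] for m in MODES)
                    assert total == pytest.approx(1.0, abs=1e-12)

    def test_single_mode_stratum(self):
        records = [rec("a", trips=[("walk", 30.0)])]
        s = ip.summarize_travel(records, age_bands=[(15, 120)])
        shares = ip.mode_shares(s, group_by_sex_only=True)
        assert shares[("male", "walk")] == pytest.approx(1.0)

    def test_zero_total_raises_naming_stratum(self):
        records = [rec("a", age=30, trips=[])]
        s = ip.summarize_travel(records, age_bands=[(15, 120)])
        with pytest.raises(ValueError, match="male"):
            ip.mode_shares(s, group_by_sex_only=True)


@given(
    durations=st.lists(
        st.floats(min_value=0.1, max_value=200, allow_nan=False), max_size=8
    ),
    threshold=st.floats(min_value=0, max_value=10),
)
@settings(deadline=None, max_examples=50, derandomize=True)
def test_filter_idempotence_property(durations, threshold):
    r = rec(trips=[("walk", d) for d in durations])
    once = ip.filter_records([r], threshold, 0, 0)
    assert ip.filter_records(once, threshold, 0, 0) == once


def test_band_label_round_trip():
    for band in DEFAULT_AGE_BANDS:
        assert parse_band(format_band(band)) == band
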