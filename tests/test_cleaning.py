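import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ctdroc.cleaning import (apply_consort, net_spt, recode_challenge,
                             select_biomarker, summarize, truncate_sige)


class TestTruncateSige:
    @pytest.mark.parametrize("raw,expected", [
        (150.0, 101.0),   # above the lab reporting cap
        (100.0, 100.0),   # boundary not exceeded
        (4.39, 4.39),
        (0.0, 0.0),
    ])
    def test_cap(self, raw, expected):
        assert truncate_sige(raw) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            truncate_sige(-0.1)

    @given(st.floats(min_value=0, max_value=1e4, allow_nan=False))
    def test_never_exceeds_cap(self, v):
        assert 0 <= truncate_sige(v) <= 101.0


class TestNetSpt:
    @pytest.mark.parametrize("raw,saline,expected", [
        (10.0, 2.0, 8.0),
        (2.0, 3.0, 0.0),   # floored at zero
        (7.0, 0.0, 7.0),
    ])
    def test_subtraction(self, raw, saline, expected):
        assert net_spt(raw, saline) == expected

    def test_missing_saline_is_zero(self):
        assert net_spt(5.0, None) == 5.0
        assert net_spt(5.0, float("nan")) == 5.0

    @given(st.floats(0, 50, allow_nan=False), st.floats(0, 10, allow_nan=False))
    def test_net_wheal_non_negative(self, raw, saline):
        assert net_spt(raw, saline) >= 0.0


class TestSelectBiomarker:
    def _m(self, pairs):
        return pd.DataFrame(pairs, columns=["value", "date"])

    def test_stale_measurement_excluded(self):
        m = self._m([(8.0, "2014-06-01")])
        assert select_biomarker(m, pd.Timestamp("2015-07-15")) is None

    def test_post_challenge_excluded(self):
        m = self._m([(8.0, "2015-01-02")])
        assert select_biomarker(m, pd.Timestamp("2015-01-01")) is None

    def test_most_recent_wins(self):
        m = self._m([(12.0, "2014-07-01"), (8.0, "2014-11-01")])
        assert select_biomarker(m, pd.Timestamp("2015-01-01")) == 8.0

    def test_boundary_day_inclusive(self):
        m = self._m([(6.0, "2014-01-01")])
        assert select_biomarker(m, pd.Timestamp("2015-01-01")) == 6.0  # 365 days

    def test_same_day_kept(self):
        m = self._m([(6.0, "2015-01-01")])
        assert select_biomarker(m, pd.Timestamp("2015-01-01")) == 6.0


class TestRecode:
    @pytest.mark.parametrize("outcome,ctd,expected", [
        ("positive", 77.0, (1, 77.0)),
        ("positive", 501.0, (0, 500.0)),  # recoded negative
        ("positive", 500.0, (0, 500.0)),
        ("negative", 500.0, (0, 500.0)),
        ("negative", 377.0, None),        # inconsistent, excluded
    ])
    def test_mapping(self, outcome, ctd, expected):
        assert recode_challenge(outcome, ctd) == expected

    def test_negative_ctd_rejected(self):
        with pytest.raises(ValueError):
            recode_challenge("positive", -1.0)


class TestConsort:
    def test_toy_cascade(self, toy_consort):
        challenges, biomarkers, participants = toy_consort
        records, flog = apply_consort(challenges, biomarkers, participants)
        assert len(records) == 3
        by_rule = {r: e for r, _, e, _ in flog.steps}
        assert by_rule["placebo_challenges_excluded"] == 1
        assert by_rule["other_allergen_excluded"] == 1
        assert by_rule["negative_ctd_lt_500_excluded"] == 1
        flog.validate()

    def test_biomarkers_attached_and_derived(self, toy_consort):
        challenges, biomarkers, participants = toy_consort
        records, _ = apply_consort(challenges, biomarkers, participants)
        r = records[(records.participant_id == "P1") & (records.food == "peanut")].iloc[0]
        assert r["spt_net_mm"] == 8.0          # 10 - 2 saline
        assert r["sige_kul"] == 101.0          # truncated from 150
        assert r["sige_ratio"] == pytest.approx(101.0 / 500.0)
        # zero total IgE -> ratio undefined rather than infinite
        p3 = records[records.participant_id == "P3"]
        assert p3["sige_ratio"].isna().all()

    def test_demographic_recoding(self, toy_consort):
        challenges, biomarkers, participants = toy_consort
        records, _ = apply_consort(challenges, biomarkers, participants)
        p2 = records[records.participant_id == "P2"].iloc[0]
        assert p2["race"] == "other"           # native_hawaiian pooled
        assert np.isnan(p2["hispanic"])        # unknown ethnicity -> missing
        assert p2["mono_allergic"] == 1

    def test_missing_markers_retained(self, toy_consort):
        challenges, biomarkers, participants = toy_consort
        records, _ = apply_consort(challenges, pd.DataFrame(
            columns=["participant_id", "food", "kind", "value", "date"]
        ), participants)
        assert len(records) == 3
        assert records["spt_net_mm"].isna().all()

    def test_duplicate_rows_rejected(self, toy_consort):
        challenges, biomarkers, participants = toy_consort
        dup = pd.concat([challenges, challenges.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            apply_consort(dup, biomarkers, participants)

    def test_empty_input(self, toy_consort):
        challenges, biomarkers, participants = toy_consort
        records, flog = apply_consort(challenges.iloc[0:0], biomarkers, participants)
        assert records.empty
        flog.validate()

    def test_idempotent_on_clean_records(self, toy_consort):
        """Re-running the cascade on retained challenges excludes nothing."""
        challenges, biomarkers, participants = toy_consort
        records, _ = apply_consort(challenges, biomarkers, participants)
        again = records[["participant_id", "food", "date", "dose_mg"]].copy()
        again["outcome"] = np.where(records["event"] == 1, "positive", "negative")
        again = again.rename(columns={"dose_mg": "ctd_mg"})
        again["schedule_id"] = "generic"
        rec2, flog2 = apply_consort(again, biomarkers, participants)
        assert len(rec2) == len(records)
        assert all(e == 0 for _, _, e, _ in flog2.steps)
        pd.testing.assert_frame_equal(
            rec2[["participant_id", "food", "event", "dose_mg"]],
            records[["participant_id", "food", "event", "dose_mg"]],
        )


class TestAnalysisRecordInvariants:
    def test_cohort_invariants(self, records):
        ev0 = records[records.event == 0]
        ev1 = records[records.event == 1]
        assert (ev0["dose_mg"] == 500.0).all()
        assert ((ev1["dose_mg"] >= 0) & (ev1["dose_mg"] < 500)).all()
        assert (records["sige_kul"].dropna() <= 101.0).all()
        assert (records["spt_net_mm"].dropna() >= 0).all()
        ratio = records["sige_ratio"].dropna()
        assert ((ratio >= 0) & (ratio <= 1)).all()

    @given(st.lists(
        st.tuples(
            st.sampled_from(["positive", "negative"]),
            st.floats(0, 600, allow_nan=False),
        ),
        min_size=1, max_size=30,
    ))
    def test_recode_invariants_random(self, rows):
        for outcome, ctd in rows:
            res = recode_challenge(outcome, ctd)
            if res is None:
                assert outcome == "negative" and ctd < 500
            else:
                event, dose = res
                if event == 1:
                    assert 0 <= dose < 500
                else:
                    assert dose == 500.0


class TestSummarize:
    def test_counts_and_formatting(self, toy_consort):
        challenges, biomarkers, participants = toy_consort
        records, _ = apply_consort(challenges, biomarkers, participants)
        s = summarize(records).set_index("food")
        assert s.loc["peanut", "positive_ofcs"] == "1/1 (100)"
        assert s.loc["milk", "positive_ofcs"] == "0/1 (0)"
        assert s.loc["total", "n_total"] == 3

    def test_single_negative_is_zero_percent(self):
        rec = pd.DataFrame({
            "food": ["milk"], "event": [0], "participant_id": ["P1"],
            "spt_net_mm": [np.nan], "sige_kul": [np.nan], "sige_ratio": [np.nan],
        })
        s = summarize(rec)
        assert s.iloc[0]["positive_ofcs"] == "0/1 (0)"
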