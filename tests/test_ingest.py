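"""Dedup, drug-name normalization, inclusion filters, time to onset."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tnfvigil as tv
from tnfvigil.ingest import HEALTH_PROFESSIONALS, SynonymDictionary

from conftest import make_reports


@pytest.fixture(scope="module")
def syn():
    return SynonymDictionary.default()


class TestDeduplicate:
    def test_higher_version_wins(self):
        df = make_reports(
            [
                {"case_id": "A", "version": 1, "weight_kg": 60.0},
                {"case_id": "A", "version": 2, "weight_kg": 61.0},
            ]
        )
        out = tv.deduplicate(df)
        assert len(out) == 1
        assert out.loc[0, "version"] == 2
        assert out.loc[0, "weight_kg"] == 61.0

    def test_identity_on_distinct_ids(self):
        df = make_reports([{"case_id": str(i)} for i in range(10)])
        pd.testing.assert_frame_equal(tv.deduplicate(df), df)

    def test_tie_broken_by_last_occurrence(self):
        df = make_reports(
            [
                {"case_id": "A", "version": 2, "weight_kg": 60.0},
                {"case_id": "A", "version": 2, "weight_kg": 99.0},
            ]
        )
        out = tv.deduplicate(df)
        assert out.loc[0, "weight_kg"] == 99.0

    def test_output_order_by_first_appearance(self):
        df = make_reports(
            [
                {"case_id": "B", "version": 1},
                {"case_id": "A", "version": 1},
                {"case_id": "B", "version": 2},
            ]
        )
        assert list(tv.deduplicate(df)["case_id"]) == ["B", "A"]

    def test_count_matches_distinct_key_oracle(self, small_reports, small_raw):
        # independent oracle: distinct case count straight off the raw table
        assembled = tv.assemble_reports(small_raw)
        assert len(tv.deduplicate(assembled)) == assembled["case_id"].nunique()

    def test_idempotent(self, small_reports):
        once = tv.deduplicate(small_reports)
        pd.testing.assert_frame_equal(tv.deduplicate(once), once)


class TestNormalizeDrug:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("HUMIRA", "adalimumab"),
            ("adalimumab", "adalimumab"),
            (" Enbrel  ", "etanercept"),
            ("Remicade", "infliximab"),
            ("definitely-not-a-drug", None),
        ],
    )
    def test_lookup(self, syn, raw, expected):
        assert tv.normalize_drug(raw, syn) == expected

    def test_mapping_is_function_and_canonicals_self_map(self, syn):
        for canon in set(syn.mapping.values()):
            assert syn.mapping[canon] == canon

    def test_conflicting_mapping_rejected(self):
        with pytest.raises(ValueError):
            SynonymDictionary({"humira": "adalimumab", "HUMIRA ": "etanercept"})


class TestInclusionFilters:
    def test_multi_indication_excluded(self):
        df = make_reports(
            [{"indications": ("psoriasis", "rheumatoid arthritis")}, {}]
        )
        res = tv.apply_inclusion_filters(df)
        assert len(res.retained) == 1
        assert res.log.removed["indication_not_ra_only"] == 1

    def test_consumer_reporter_excluded(self):
        df = make_reports([{"reporter": "consumer"}, {"reporter": "pharmacist"}])
        res = tv.apply_inclusion_filters(df)
        assert len(res.retained) == 1
        assert res.log.removed["reporter_not_health_professional"] == 1

    def test_toy_batch_against_per_report_oracle(self):
        rows = [{} for _ in range(6)]
        rows += [
            {"ps_drug": "methotrexate"},
            {"indications": ("psoriasis",)},
            {"reporter": "consumer"},
            {"reporter": "lawyer"},
        ]
        df = make_reports(rows)
        res = tv.apply_inclusion_filters(df)
        assert len(res.retained) == 6
        assert sum(res.log.removed.values()) == 4

        def keep(row):
            return (
                row["ps_drug"] in tv.synthetic.STUDY_DRUGS
                and row["indications"] == ("rheumatoid arthritis",)
                and row["reporter"] in HEALTH_PROFESSIONALS
            )

        oracle = df.apply(keep, axis=1)
        assert set(res.retained["case_id"]) == set(df.loc[oracle, "case_id"])

    def test_conservation_and_monotonicity(self, small_filtered, small_reports):
        log = small_filtered.log
        assert log.retained_count + sum(log.removed.values()) == log.input_count
        # dropping a criterion never shrinks the retained set
        relaxed = tv.apply_inclusion_filters(
            small_reports, tv.InclusionConfig(health_professional_only=False)
        )
        assert len(relaxed.retained) >= len(small_filtered.retained)

    def test_background_pool_fails_only_drug_criterion(self, small_filtered):
        bg = small_filtered.background
        assert (~bg["ps_drug"].isin(tv.synthetic.STUDY_DRUGS)).all()
        assert bg["indications"].map(lambda t: t == ("rheumatoid arthritis",)).all()
        assert bg["reporter"].isin(HEALTH_PROFESSIONALS).all()

    def test_empty_result_warns_not_raises(self):
        df = make_reports([{"ps_drug": "methotrexate"}])
        with pytest.warns(UserWarning):
            res = tv.apply_inclusion_filters(df)
        assert len(res.retained) == 0


class TestTimeToOnset:
    def test_basic_difference(self):
        df = make_reports(
            [{"therapy_start": "2020-01-01", "event_date": "2020-01-31"}]
        )
        assert df.loc[0, "tto_days"] == 30
        assert bool(df.loc[0, "tto_valid"])

    def test_beyond_720_days_flagged_excluded(self):
        df = make_reports(
            [{"therapy_start": "2020-01-01", "event_date": "2022-06-01"}]
        )
        assert df.loc[0, "tto_days"] == 882
        assert not bool(df.loc[0, "tto_valid"])

    def test_missing_propagates(self):
        df = make_reports([{"event_date": "2020-05-01"}])
        assert np.isnan(df.loc[0, "tto_days"])
        assert not bool(df.loc[0, "tto_valid"])

    def test_negative_gap_invalid(self):
        df = make_reports(
            [{"therapy_start": "2020-06-01", "event_date": "2020-01-01"}]
        )
        assert df.loc[0, "tto_days"] < 0
        assert not bool(df.loc[0, "tto_valid"])


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(0, 5), st.integers(1, 4)), min_size=1, max_size=30
    )
)
def test_dedup_property_one_row_per_case_max_version(pairs):
    df = make_reports(
        [{"case_id": f"c{cid}", "version": v} for cid, v in pairs]
    )
    out = tv.deduplicate(df)
    assert out["case_id"].is_unique
    expected_max = df.groupby("case_id")["version"].max()
    got = out.set_index("case_id")["version"]
    assert (got == expected_max.loc[got.index]).all()
    pd.testing.assert_frame_equal(tv.deduplicate(out), out)
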