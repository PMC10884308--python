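"""Ingest, anomaly filtering, relative times and min-max normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import skatesense as sk
from skatesense.errors import DataError, SchemaError
from skatesense.preprocess import records_from_csv_text

CSV_HEADER = "skater_id,distance,race_date,t_abs,altitude,ice_temp,race_index,anomaly_flag\n"


def make_csv(rows):
    return CSV_HEADER + "\n".join(rows) + ("\n" if rows else "")


class TestLoadRecords:
    def test_parses_typed_fields_with_unicode_minus_and_compact_date(self):
        df = records_from_csv_text(make_csv(["GAO,500,20220212,34.32,49,−7,3,false"]))
        row = df.iloc[0]
        assert row["t_abs"] == 34.32
        assert row["altitude"] == 49
        assert row["ice_temp"] == -7
        assert row["race_index"] == 3
        assert row["season_label"] == "2021-2022"  # February -> season started previous July

    def test_iso_dates_and_season_cutover_at_july(self):
        df = records_from_csv_text(make_csv([
            "A,500,2021-06-30,35.0,49,-7,1,false",
            "A,500,2021-07-01,35.0,49,-7,1,false",
        ]))
        assert list(df["season_label"]) == ["2020-2021", "2021-2022"]

    def test_missing_required_column_names_the_column(self):
        with pytest.raises(SchemaError, match="ice_temp"):
            records_from_csv_text("skater_id,distance,race_date,t_abs,altitude\n")

    def test_unparseable_value_reports_line_number(self):
        with pytest.raises(SchemaError, match="line 3"):
            records_from_csv_text(make_csv([
                "A,500,2021-01-01,35.0,49,-7,1,false",
                "A,500,2021-01-02,oops,49,-7,2,false",
            ]))

    def test_header_only_gives_empty_collection(self):
        df = records_from_csv_text(make_csv([]))
        assert len(df) == 0

    def test_duplicated_rows_are_kept(self):
        df = records_from_csv_text(make_csv([
            "A,500,2021-01-01,35.0,49,-7,1,false",
            "A,500,2021-01-01,35.0,49,-7,1,false",
        ]))
        assert len(df) == 2

    def test_race_index_recomputed_per_skater_season(self):
        csv = (
            "skater_id,distance,race_date,t_abs,altitude,ice_temp\n"
            "A,500,2021-11-02,35.0,49,-7\n"
            "A,1000,2021-11-01,70.0,49,-7\n"
            "A,500,2022-10-01,35.0,49,-7\n"
        )
        df = records_from_csv_text(csv)
        # sorted by date; counts across distances, restarting each season
        assert list(df["race_index"]) == [1.0, 2.0, 1.0]

    def test_rows_missing_factors_are_dropped(self):
        csv = CSV_HEADER + "A,500,2021-01-01,35.0,,-7,1,false\nA,500,2021-01-02,35.0,49,-7,2,false\n"
        df = records_from_csv_text(csv)
        assert len(df) == 1


class TestFilterAnomalies:
    @pytest.mark.parametrize("n_flagged", [0, 2, 10])
    def test_removes_exactly_the_flagged_rows(self, records, n_flagged):
        df = records.head(10).copy()
        df.loc[df.index[:n_flagged], "anomaly_flag"] = True
        out = sk.filter_anomalies(df)
        assert len(out) == 10 - n_flagged
        assert not out["anomaly_flag"].any()

    def test_idempotent(self, records):
        df = sk.inject_anomalies(records, 0.2, seed=4)
        once = sk.filter_anomalies(df)
        twice = sk.filter_anomalies(once)
        pd.testing.assert_frame_equal(once, twice)


class TestRelativeTimes:
    def test_single_race_season_gives_exactly_one(self):
        df = records_from_csv_text(make_csv(["A,500,2021-01-01,70.0,49,-7,1,false"]))
        out = sk.compute_relative_times(df)
        assert out["t_rel"].iloc[0] == 1.0

    def test_two_race_season_hand_arithmetic(self):
        df = records_from_csv_text(make_csv([
            "A,500,2021-01-01,60.0,49,-7,1,false",
            "A,500,2021-01-08,62.0,49,-7,2,false",
        ]))
        out = sk.compute_relative_times(df)
        np.testing.assert_allclose(out["t_rel"], [60 / 61, 62 / 61], rtol=1e-12)

    def test_season_means_are_one_on_every_dataset(self, records):
        out = sk.compute_relative_times(records)
        means = out.groupby(["skater_id", "season_label", "distance"])["t_rel"].mean()
        np.testing.assert_allclose(means, 1.0, atol=1e-12)


class TestMinMaxScale:
    @pytest.mark.parametrize("x,lo,hi,expected", [(0, 0, 10, 0.0), (10, 0, 10, 1.0), (5, 0, 10, 0.5)])
    def test_examples(self, x, lo, hi, expected):
        assert sk.minmax_scale(x, lo, hi) == expected

    @settings(derandomize=True, max_examples=50)
    @given(
        x=st.floats(-1e6, 1e6),
        lo=st.floats(-1e3, 1e3),
        width=st.floats(1e-3, 1e6),
    )
    def test_roundtrip_is_identity(self, x, lo, width):
        hi = lo + width
        back = sk.minmax_inverse(sk.minmax_scale(x, lo, hi), lo, hi)
        assert back == pytest.approx(x, abs=1e-6 * max(1.0, abs(x)))

    def test_degenerate_range_is_an_error(self):
        with pytest.raises(DataError):
            sk.minmax_scale(1.0, 5.0, 5.0)
        with pytest.raises(DataError, match="altitude"):
            sk.NormalizationSpec({"altitude": (3.0, 3.0)})


class TestDatasetStatistics:
    def test_singleton_means(self):
        df = sk.compute_relative_times(records_from_csv_text(
            make_csv(["A,500,2021-01-01,70.0,49,-7,3,false"])))
        stats = sk.dataset_statistics(df)
        assert stats["t_ave"] == 70.0
        assert stats["t_con"] == -7.0
        assert stats["r_con"] == 3.0

    def test_two_record_temperature_mean(self):
        df = sk.compute_relative_times(records_from_csv_text(make_csv([
            "A,500,2021-01-01,70.0,49,-6,1,false",
            "A,500,2021-01-08,70.0,49,-8,2,false",
        ])))
        assert sk.dataset_statistics(df)["t_con"] == -7.0

    def test_altitude_range_fixed_regardless_of_observations(self, records):
        stats = sk.dataset_statistics(sk.compute_relative_times(records))
        assert stats["ranges"]["altitude"] == (0.0, 1500.0)
        assert stats["ranges"]["race_index"][0] == 1.0

    def test_empty_dataset_is_an_error(self, records):
        with pytest.raises(DataError):
            sk.dataset_statistics(records.iloc[0:0])

    def test_ranges_bracket_observations(self, skater_dataset):
        recs = skater_dataset.records
        lo, hi = skater_dataset.ranges["ice_temp"]
        assert lo <= recs["ice_temp"].min() and recs["ice_temp"].max() <= hi


class TestBuildDatasets:
    def test_min_records_threshold_skips_small_groups(self, records):
        small = records.head(12)  # below the default minimum of 13
        assert sk.build_datasets(small) == []
        assert len(sk.build_datasets(small, min_records=5)) == 1

    def test_record_count_matches_rows_minus_flagged(self, records):
        df = sk.inject_anomalies(records, 0.1, seed=2)
        ds = sk.build_datasets(df)[0]
        assert ds.a == len(records) - int(df["anomaly_flag"].sum())
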