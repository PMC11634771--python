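"""Census ingest, lumping, seasons, profile grouping and filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foramshift.census import (add_seasons, assign_season, filter_records,
                               group_profiles, lump_taxa, read_census,
                               read_taxonomy, species_columns, write_census)
from foramshift.errors import SchemaError

from conftest import make_census

HEADER = ("subsample_id,sample_id,latitude,longitude,date,depth_upper,depth_lower,"
          "device,size_lower,size_upper,volume_filtered,count_kind")


def write_csv(tmp_path, body, name="census.csv"):
    path = tmp_path / name
    path.write_text(body)
    return path


class TestReadCensus:
    def test_identity_ingest_preserves_counts(self, tmp_path):
        body = f"{HEADER},A,B\n" \
               "s1,p1,40,-30,2000-07-15,0,50,net,100,,25,raw_count,3,0\n" \
               "s2,p1,40,-30,2000-07-15,50,100,net,100,,25,raw_count,5,2\n" \
               "s3,p2,-10,5,1995-01-02,0,100,cpr,150,300,10,concentration,0.5,0\n"
        res = read_census(write_csv(tmp_path, body))
        assert len(res.records) == 3 and res.n_rejected == 0
        assert res.records["A"].tolist() == [3, 5, 0.5]
        assert species_columns(res.records) == ["A", "B"]

    def test_inverted_depth_interval_is_rejected_with_diagnostic(self, tmp_path):
        body = f"{HEADER},A\n" \
               "s1,p1,40,-30,2000-07-15,50,20,net,100,,25,raw_count,3\n"
        res = read_census(write_csv(tmp_path, body))
        assert len(res.records) == 0 and res.n_rejected == 1
        assert "depth_upper" in res.rejected["field"].tolist()
        assert "depth_upper < depth_lower" in res.rejected["message"].iloc[0]

    def test_blank_size_upper_means_open_fraction(self, tmp_path):
        body = f"{HEADER},A\n" \
               "s1,p1,40,-30,2000-07-15,0,50,net,100,,25,raw_count,3\n"
        res = read_census(write_csv(tmp_path, body))
        assert np.isnan(res.records["size_upper"].iloc[0])

    def test_missing_mandatory_column_raises_schema_error(self, tmp_path):
        path = write_csv(tmp_path, "subsample_id,latitude\ns1,40\n")
        with pytest.raises(SchemaError):
            read_census(path)

    def test_schema_mapping_renames_columns(self, tmp_path):
        body = HEADER.replace("latitude", "Lat") + ",A\n" \
            + "s1,p1,40,-30,2000-07-15,0,50,net,100,,25,raw_count,3\n"
        res = read_census(write_csv(tmp_path, body), schema={"Lat": "latitude"})
        assert res.records["latitude"].iloc[0] == 40

    def test_round_trip_is_lossless(self, tmp_path, census_two_stations):
        path = tmp_path / "out.csv"
        write_census(census_two_stations, path)
        back = read_census(path).records
        pd.testing.assert_frame_equal(
            back, census_two_stations.reset_index(drop=True), check_dtype=False)


class TestLumpTaxa:
    taxonomy = pd.DataFrame({
        "species_name": ["A1", "A2", "ruber_pink", "ruber_white"],
        "lumped_name": ["A", "A", "ruber_pink", "ruber_white"],
    })

    def test_lumped_counts_sum(self):
        df = make_census([{"A1": 3.0, "A2": 5.0}])
        out = lump_taxa(df, self.taxonomy)
        assert out["A"].iloc[0] == 8 and "A1" not in out.columns

    def test_identity_map_is_noop(self):
        df = make_census([{"ruber_pink": 2.0, "ruber_white": 7.0}])
        out = lump_taxa(df, self.taxonomy)
        assert out["ruber_pink"].iloc[0] == 2 and out["ruber_white"].iloc[0] == 7

    def test_pink_type_stays_separate_from_white(self):
        # the taxonomy deliberately keeps the pink type apart
        df = make_census([{"ruber_pink": 1.0, "ruber_white": 1.0, "A1": 1.0}])
        out = lump_taxa(df, self.taxonomy)
        assert {"ruber_pink", "ruber_white", "A"} <= set(out.columns)

    def test_total_count_conserved(self):
        df = make_census([{"A1": 3.0, "A2": 5.0, "X": 2.0}, {"A1": 0.0, "A2": 1.0, "X": 0.0}])
        out = lump_taxa(df, self.taxonomy)
        before = df[["A1", "A2", "X"]].sum(axis=1)
        after = out[species_columns(out)].sum(axis=1)
        assert np.allclose(before, after)

    def test_non_idempotent_taxonomy_rejected(self, tmp_path):
        bad = tmp_path / "tax.csv"
        bad.write_text("species_name,lumped_name\nA,B\nB,C\n")
        with pytest.raises(SchemaError):
            read_taxonomy(bad)


class TestSeasons:
    @pytest.mark.parametrize("lat,date,expected", [
        (40, "2000-07-15", "summer"),
        (-40, "2000-07-15", "winter"),
        (0, "2000-12-01", "winter"),  # the equator uses the northern convention
        (40, "2000-09-01", "autumn"),
        (-40, "2000-09-01", "spring"),
        (75, "2000-03-31", "spring"),
    ])
    def test_hemisphere_aware_seasons(self, lat, date, expected):
        assert assign_season(lat, date) == expected

    @given(lat=st.floats(-90, 90), month=st.integers(1, 12), day=st.integers(1, 28))
    @settings(max_examples=60, deadline=None)
    def test_every_date_maps_to_exactly_one_season(self, lat, month, day):
        season = assign_season(lat, f"2010-{month:02d}-{day:02d}")
        assert season in {"winter", "spring", "summer", "autumn"}


class TestGroupProfiles:
    def test_co_located_subsamples_form_one_profile(self, census_two_stations):
        out = group_profiles(census_two_stations)
        st0 = out[out["sample_id"] == "st0"]
        assert st0["profile_id"].nunique() == 1 and len(st0) == 4
        assert out["profile_id"].nunique() == 3  # two stations + the CPR record

    def test_distant_stations_stay_separate(self):
        df = make_census([{"latitude": 40.0, "A": 1.0}, {"latitude": 45.0, "A": 1.0}])
        assert group_profiles(df, location_tolerance=0.1)["profile_id"].nunique() == 2

    def test_overlapping_depths_flag_profile_invalid(self):
        df = make_census([
            {"depth_upper": 0, "depth_lower": 50, "A": 1.0},
            {"depth_upper": 30, "depth_lower": 80, "A": 1.0},
        ])
        out = group_profiles(df)
        assert not out["profile_valid"].any()

    def test_members_ordered_by_depth(self, census_two_stations):
        out = group_profiles(census_two_stations)
        for _, prof in out.groupby("profile_id"):
            assert prof["depth_upper"].is_monotonic_increasing


class TestFilterRecords:
    def test_no_predicates_is_identity(self, census_two_stations):
        res = filter_records(census_two_stations)
        assert len(res.records) == len(census_two_stations)

    def test_depth_window_is_half_open(self):
        df = make_census([
            {"depth_upper": 0, "depth_lower": 100, "A": 1.0},
            {"depth_upper": 200, "depth_lower": 300, "A": 1.0},
        ])
        res = filter_records(df, depth_range=(0, 200))
        assert len(res.records) == 1 and res.removed["depth_range"] == 1

    def test_band_and_season_conjunction_matches_hand_enumeration(self):
        df = make_census([
            {"latitude": 35.0, "date": "2000-07-01", "A": 1.0},   # in band, summer -> kept
            {"latitude": 35.0, "date": "2000-01-01", "A": 1.0},   # winter -> out
            {"latitude": 55.0, "date": "2000-07-01", "A": 1.0},   # out of band
            {"latitude": 50.0, "date": "2000-07-01", "A": 1.0},   # 50 excluded: half-open
            {"latitude": 30.0, "date": "2000-08-31", "A": 1.0},   # boundary lat included
        ])
        res = filter_records(df, lat_band=(30, 50), seasons={"summer"})
        assert sorted(res.records["latitude"]) == [30.0, 35.0]

    def test_output_subset_and_idempotent(self, census_two_stations):
        kwargs = dict(depth_range=(0, 150), devices={"net"})
        once = filter_records(census_two_stations, **kwargs).records
        twice = filter_records(once, **kwargs).records
        assert set(once["subsample_id"]) <= set(census_two_stations["subsample_id"])
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_result_is_returned_not_raised(self, census_two_stations):
        res = filter_records(census_two_stations, devices={"trap"})
        assert res.records.empty

    def test_min_profile_size(self, census_two_stations):
        grouped = group_profiles(add_seasons(census_two_stations))
        res = filter_records(grouped, min_profile_size=4)
        assert set(res.records["sample_id"]) == {"st0", "st1"}
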