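"""Decadal series, trend tests, sections, thermal responses, clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA

from foramshift.errors import InsufficientDataError, ParameterError
from foramshift.trends import (DecadalSeries, assemblage_clustering,
                               decadal_series, latitudinal_section, minmax,
                               response_matrix, thermal_response, trend_test,
                               ThermalResponse)

from conftest import make_census


def records_with_decades(decade_means, species="A", lat=15.0):
    rows = []
    for decade, mean in decade_means.items():
        for k in range(4):
            rows.append({"latitude": lat, "date": f"{decade + 2}-06-15",
                         species: float(mean)})
    return make_census(rows)


class TestDecadalSeries:
    def test_scaled_by_maximum_decade(self):
        df = records_with_decades({1950: 10.0, 1980: 5.0, 2010: 0.0})
        s = decadal_series(df, "A", band=(0.0, 30.0))
        assert np.allclose(s.mean_norm, [1.0, 0.5, 0.0])
        assert list(s.decades) == [1950, 1980, 2010]

    def test_empty_decades_absent_not_zero(self):
        df = records_with_decades({1950: 4.0, 2010: 2.0})
        s = decadal_series(df, "A", band=(0.0, 30.0))
        assert list(s.decades) == [1950, 2010]

    def test_constant_series_flagged_degenerate(self):
        df = records_with_decades({1950: 3.0, 1980: 3.0, 2010: 3.0})
        s = decadal_series(df, "A", band=(0.0, 30.0))
        assert s.degenerate and np.all(np.isnan(s.mean_norm))

    def test_single_decade_insufficient(self):
        df = records_with_decades({1980: 3.0})
        with pytest.raises(InsufficientDataError):
            decadal_series(df, "A", band=(0.0, 30.0))


class TestTrendTest:
    def make_series(self, values, start=1950):
        decades = start + 10 * np.arange(len(values))
        v = np.asarray(values, dtype=float)
        return DecadalSeries("A", (0.0, 30.0), decades, v / v.max(),
                             np.full(len(v), 5), np.zeros(len(v)))

    def test_perfectly_linear_decline(self):
        res = trend_test(self.make_series([1.0, 0.75, 0.5, 0.25, 0.0 + 1e-9]))
        assert res.slope_per_decade == pytest.approx(-0.25, abs=1e-6)
        assert res.percent_change == pytest.approx(100.0, abs=1e-4)
        assert res.p_value < 1e-8
        assert res.classification == "significant_decrease"

    def test_analytic_slope_to_machine_precision(self):
        res = trend_test(self.make_series([1.0, 0.9, 0.8, 0.7]))
        assert res.slope_per_decade == pytest.approx(-0.1, abs=1e-12)

    def test_reversed_series_negates_slope_and_direction(self):
        fwd = trend_test(self.make_series([1.0, 0.8, 0.6, 0.4]))
        rev = trend_test(self.make_series([0.4, 0.6, 0.8, 1.0]))
        assert rev.slope_per_decade == pytest.approx(-fwd.slope_per_decade)
        assert fwd.classification == "significant_decrease"
        assert rev.classification == "significant_increase"
        assert rev.percent_change == pytest.approx(-150.0)  # 0.4 -> 1.0 growth

    def test_degenerate_series_rejected(self):
        s = self.make_series([1.0, 1.0, 1.0])
        s.degenerate = True
        with pytest.raises(InsufficientDataError):
            trend_test(s)


class TestLatitudinalSection:
    def test_single_record_single_bin(self):
        df = make_census([{"latitude": 42.0, "depth_upper": 0, "depth_lower": 50,
                           "date": "1995-06-15", "A": 3.0}])
        out = latitudinal_section(df, "A")
        assert len(out) == 1
        assert out.iloc[0]["lat_bin_lo"] == 40.0 and out.iloc[0]["depth_section"] == "shallow"

    def test_depth_split_assigns_sections(self):
        df = make_census([
            {"latitude": 42.0, "depth_upper": 0, "depth_lower": 50,
             "date": "1995-06-15", "A": 3.0},
            {"latitude": 42.0, "depth_upper": 150, "depth_lower": 200,
             "date": "1995-06-15", "A": 5.0},
        ])
        out = latitudinal_section(df, "A").set_index("depth_section")
        assert out.loc["shallow", "mean"] == 3.0 and out.loc["deep", "mean"] == 5.0

    def test_hand_averaged_fixture(self):
        df = make_census([
            {"latitude": 31.0, "depth_upper": 0, "depth_lower": 40, "date": "1990-07-01", "A": 2.0},
            {"latitude": 35.0, "depth_upper": 0, "depth_lower": 40, "date": "1991-07-01", "A": 4.0},
            {"latitude": 38.0, "depth_upper": 0, "depth_lower": 40, "date": "1992-07-01", "A": 6.0},
            {"latitude": 45.0, "depth_upper": 0, "depth_lower": 40, "date": "1990-07-01", "A": 10.0},
            {"latitude": 33.0, "depth_upper": 150, "depth_lower": 250, "date": "1990-07-01", "A": 1.0},
            {"latitude": 33.0, "depth_upper": 250, "depth_lower": 350, "date": "1990-07-01", "A": 3.0},
        ])
        out = latitudinal_section(df, "A").set_index(["lat_bin_lo", "depth_section"])
        assert out.loc[(30.0, "shallow"), "mean"] == pytest.approx(4.0)  # (2+4+6)/3
        assert out.loc[(40.0, "shallow"), "mean"] == pytest.approx(10.0)
        assert out.loc[(30.0, "deep"), "mean"] == pytest.approx(2.0)  # (1+3)/2


class TestThermalResponse:
    def attached(self, temps, concs, species="A"):
        df = make_census([
            {"latitude": 10.0, "depth_upper": 0, "depth_lower": 50,
             "date": "2000-06-15", species: float(c)} for c in concs])
        df["temperature"] = temps
        return df

    def test_peak_bin_is_one_and_min_zero(self):
        df = self.attached([10.2, 15.5, 20.1], [1.0, 9.0, 2.0])
        resp = thermal_response(df, "A")
        assert resp.normalized.max() == 1.0 and resp.normalized.min() == 0.0
        assert resp.bin_centres[np.argmax(resp.normalized)] == 15.5

    def test_single_populated_bin_is_one(self):
        df = self.attached([12.3], [4.0])
        resp = thermal_response(df, "A")
        assert resp.normalized.tolist() == [1.0]

    def test_scale_invariance(self):
        df1 = self.attached([10.2, 15.5, 20.1], [1.0, 9.0, 2.0])
        df7 = self.attached([10.2, 15.5, 20.1], [7.0, 63.0, 14.0])
        r1 = thermal_response(df1, "A")
        r7 = thermal_response(df7, "A")
        assert np.allclose(r1.normalized, r7.normalized)

    def test_requires_temperature_column(self):
        df = make_census([{"A": 1.0}])
        with pytest.raises(ParameterError):
            thermal_response(df, "A")

    def test_minmax_constant_maps_to_nan(self):
        assert np.all(np.isnan(minmax([2.0, 2.0])))


class TestAssemblageClustering:
    def gaussian_matrix(self, optima, rng, sd=2.0):
        bins = np.arange(0.5, 30.5)
        rows = {}
        for i, opt in enumerate(optima):
            resp = np.exp(-((bins - opt) ** 2) / (2 * sd ** 2))
            resp = resp + rng.normal(0, 0.02, len(bins))
            rows[f"sp{i}"] = minmax(resp)
        return pd.DataFrame(rows).T.set_axis(bins, axis=1)

    def test_duplicate_rows_share_a_cluster(self, rng):
        mat = self.gaussian_matrix([10, 25, 25], rng)
        mat.loc["sp2"] = mat.loc["sp1"]  # exact duplicate
        labels, _ = assemblage_clustering(mat, k=2)
        assert labels["sp1"] == labels["sp2"] != labels["sp0"]

    def test_recovers_two_separated_thermal_guilds(self, rng):
        optima = [10, 10.5, 11, 25, 25.5, 26]
        mat = self.gaussian_matrix(optima, rng)
        labels, explained = assemblage_clustering(mat, k=2)
        cold = {labels[f"sp{i}"] for i in range(3)}
        warm = {labels[f"sp{i}"] for i in range(3, 6)}
        assert len(cold) == len(warm) == 1 and cold != warm

    def test_variance_explained_ordered_and_bounded(self, rng):
        mat = self.gaussian_matrix([8, 14, 20, 26], rng)
        _, explained = assemblage_clustering(mat, k=2)
        assert explained[0] >= explained[1] >= 0
        assert explained.sum() <= 1.0 + 1e-9

    def test_pcoa_scores_match_pca_oracle(self, rng):
        # with Euclidean distances PCoA reproduces PCA scores up to sign
        mat = pd.DataFrame(rng.normal(size=(12, 9)),
                           index=[f"sp{i}" for i in range(12)])
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.ordination import pcoa
        from scipy.spatial.distance import pdist
        dm = DistanceMatrix(pdist(mat.to_numpy()), ids=list(mat.index))
        scores = pcoa(dm, number_of_dimensions=2).samples.to_numpy()
        oracle = PCA(n_components=2).fit_transform(mat.to_numpy())
        for k in range(2):
            assert (np.allclose(scores[:, k], oracle[:, k], atol=1e-6)
                    or np.allclose(scores[:, k], -oracle[:, k], atol=1e-6))

    def test_k_larger_than_species_rejected(self, rng):
        mat = self.gaussian_matrix([10, 20, 30], rng)
        with pytest.raises(ParameterError):
            assemblage_clustering(mat, k=5)

    def test_response_matrix_aligns_bins_with_zero_fill(self):
        r1 = ThermalResponse("a", np.array([10.5, 11.5]), np.array([1.0, 0.5]))
        r2 = ThermalResponse("b", np.array([11.5, 12.5]), np.array([0.2, 1.0]))
        mat = response_matrix([r1, r2])
        assert mat.loc["a", 12.5] == 0.0 and mat.loc["b", 10.5] == 0.0
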