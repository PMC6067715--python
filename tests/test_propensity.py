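"""Propensity, speed and e-bike table estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cycleshift.errors import ValidationError
from cycleshift.propensity import (EbikeTables, assign_band,
                                   build_ebike_tables, estimate_propensity,
                                   estimate_speeds, make_bands)

from conftest import make_survey


def lookup_cell(table, age_band, gender, band_idx):
    t = table.table
    row = t[(t["age_band"] == age_band) & (t["gender"] == gender)
            & (t["band_idx"] == band_idx)]
    return float(row["p_cycle"].iloc[0])


class TestBands:
    def test_bands_are_contiguous_and_cover(self):
        bands = make_bands()
        assert bands[0].lower == 0.0 and np.isinf(bands[-1].upper)
        for a, b in zip(bands, bands[1:]):
            assert a.upper == b.lower

    @given(st.floats(min_value=1e-6, max_value=1e4,
                     allow_nan=False, allow_infinity=False))
    @settings(deadline=None, derandomize=True)
    def test_every_distance_falls_in_its_assigned_band(self, d):
        bands = make_bands()
        assert d in bands[assign_band([d], bands)[0]]

    def test_bad_edges_rejected(self):
        with pytest.raises(ValidationError):
            make_bands([0.0, 2.0, 1.0, np.inf])
        with pytest.raises(ValidationError):
            make_bands([1.0, 2.0, np.inf])


class TestEstimatePropensity:
    def test_all_trips_cycled_gives_one(self):
        trips = [(f"t{i}", "p1", "cycle", 0.5, 5.0) for i in range(5)]
        survey = make_survey([("p1", 30, "male")], trips)
        table = estimate_propensity(survey, min_support=1)
        assert lookup_cell(table, "18-39", "male", 0) == 1.0

    def test_three_of_ten_gives_point_three(self):
        trips = [(f"t{i}", "p1", "cycle" if i < 3 else "walk", 0.5, 8.0)
                 for i in range(10)]
        survey = make_survey([("p1", 30, "male")], trips)
        table = estimate_propensity(survey, min_support=1)
        assert lookup_cell(table, "18-39", "male", 0) == pytest.approx(0.3)

    def test_weighted_ratio(self):
        # weight-2 person cycles in band [0,1); two weight-1 cyclists
        # contribute non-cycled trips there -> p = 2 / (2+1+1) = 0.5
        survey = make_survey(
            [("pa", 30, "male", 2.0), ("pb", 30, "male", 1.0),
             ("pc", 30, "male", 1.0)],
            [("t1", "pa", "cycle", 0.5, 5.0),
             ("t2", "pb", "walk", 0.5, 10.0), ("t3", "pb", "cycle", 4.0, 20.0),
             ("t4", "pc", "walk", 0.5, 10.0), ("t5", "pc", "cycle", 4.0, 20.0)])
        table = estimate_propensity(survey, min_support=1)
        assert lookup_cell(table, "18-39", "male", 0) == pytest.approx(0.5)

    def test_no_cyclists_raises(self):
        survey = make_survey([("p1", 30, "male")],
                             [("t1", "p1", "walk", 0.5, 10.0)])
        with pytest.raises(ValidationError, match="no current cyclists"):
            estimate_propensity(survey)

    def test_low_support_cell_falls_back_to_pooled(self, base_survey):
        strict = estimate_propensity(base_survey, min_support=10**9)
        pooled_by_band = (strict.table.groupby("band_idx")["p_cycle"].nunique())
        # with an impossible support requirement every cell is pooled
        assert (pooled_by_band == 1).all()

    def test_pooling_identity(self, base_survey):
        """Support-weighted stratum propensities reproduce the pooled
        estimate exactly (ratio-of-sums identity, unit weights)."""
        own = estimate_propensity(base_survey, min_support=1)
        pooled = estimate_propensity(base_survey, min_support=10**9)
        for band_idx in own.table["band_idx"].unique():
            sub = own.table[own.table["band_idx"] == band_idx]
            sub = sub[sub["n_trips"] > 0]
            if not len(sub):
                continue
            weighted = np.average(sub["p_cycle"], weights=sub["n_trips"])
            expected = pooled.table.loc[
                pooled.table["band_idx"] == band_idx, "p_cycle"].iloc[0]
            assert weighted == pytest.approx(expected, abs=1e-12)

    def test_every_cell_present(self, base_survey):
        table = estimate_propensity(base_survey)
        assert len(table.table) == 6 * len(table.bands)
        assert table.table["p_cycle"].between(0, 1).all()


class TestEstimateSpeeds:
    def test_single_trip_speed(self):
        survey = make_survey([("p1", 30, "male")],
                             [("t1", "p1", "cycle", 3.0, 20.0)])
        speeds = estimate_speeds(survey)
        row = speeds.table.query("age_band == '18-39' and gender == 'male'")
        assert row["speed_mph"].iloc[0] == pytest.approx(9.0)

    def test_ratio_of_sums_not_mean_of_ratios(self):
        survey = make_survey([("p1", 30, "male")],
                             [("t1", "p1", "cycle", 2.0, 10.0),
                              ("t2", "p1", "cycle", 2.0, 30.0)])
        speeds = estimate_speeds(survey)
        row = speeds.table.query("age_band == '18-39' and gender == 'male'")
        assert row["speed_mph"].iloc[0] == pytest.approx(6.0)  # 4 mi / (40/60) h

    def test_stratum_without_cycle_trips_uses_pooled(self):
        survey = make_survey([("p1", 30, "male")],
                             [("t1", "p1", "cycle", 3.0, 20.0)])
        speeds = estimate_speeds(survey)
        row = speeds.table.query("age_band == '60-79' and gender == 'female'")
        assert row["speed_mph"].iloc[0] == pytest.approx(9.0)

    def test_speed_invariant_under_trip_splitting(self):
        whole = make_survey([("p1", 30, "male")],
                            [("t1", "p1", "cycle", 6.0, 40.0)])
        split = make_survey([("p1", 30, "male")],
                            [("t1", "p1", "cycle", 2.5, 15.0),
                             ("t2", "p1", "cycle", 3.5, 25.0)])
        s1 = estimate_speeds(whole).table["speed_mph"]
        s2 = estimate_speeds(split).table["speed_mph"]
        np.testing.assert_allclose(s1, s2)

    def test_ebike_speed_comes_from_config(self):
        survey = make_survey([("p1", 30, "male")],
                             [("t1", "p1", "cycle", 3.0, 20.0)])
        speeds = estimate_speeds(survey, ebike_speed_mph=14.0)
        assert speeds.ebike_speed_mph == 14.0
        out = speeds.lookup(["18-39"], ["male"], ["ebike"])
        assert out[0] == 14.0


class TestEbikeTables:
    def test_choice_probability_from_survey(self):
        # band [2,3): 4 e-bike vs 6 pedal-cycle trips -> 0.4
        trips = ([(f"e{i}", "p1", "ebike", 2.5, 15.0) for i in range(4)]
                 + [(f"c{i}", "p1", "cycle", 2.5, 15.0) for i in range(6)])
        survey = make_survey([("p1", 30, "male")], trips)
        tables = build_ebike_tables(survey)
        assert tables.choice_prob[2] == pytest.approx(0.4)
        assert tables.propensity[2] == pytest.approx(1.0)

    def test_supplied_table_returned_after_validation(self):
        bands = make_bands()
        supplied = EbikeTables(bands=bands,
                               choice_prob=np.full(len(bands), 0.5),
                               propensity=np.linspace(0.8, 0.1, len(bands)))
        assert build_ebike_tables(supplied) is supplied

    def test_probability_above_one_rejected(self):
        bands = make_bands()
        with pytest.raises(ValidationError):
            EbikeTables(bands=bands, choice_prob=np.full(len(bands), 1.2),
                        propensity=np.full(len(bands), 0.5))

    def test_survey_without_ebike_trips_errors(self):
        survey = make_survey([("p1", 30, "male")],
                             [("t1", "p1", "cycle", 2.0, 12.0)])
        with pytest.raises(ValidationError, match="supply"):
            build_ebike_tables(survey)

    def test_open_ended_band_carries_last_value(self):
        bands = make_bands([0.0, 5.0, np.inf])
        t = EbikeTables(bands=bands, choice_prob=[0.2, 0.9],
                        propensity=[0.7, 0.3])
        choice, prop = t.lookup([5])  # clamped to last band
        assert choice[0] == 0.9 and prop[0] == 0.3
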