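import numpy as np
import pandas as pd
import pytest

from phenoplate import plate_io


def _series(well="A1", pid="p1", n=3):
    return plate_io.WellTimeSeries(pid, well, np.arange(n) * 10.0, 0.1 + 0.01 * np.arange(n))


class TestWellTimeSeries:
    def test_well_normalized_to_upper_case(self):
        s = plate_io.WellTimeSeries("p1", "b7", [0.0, 10.0], [0.1, 0.2])
        assert s.well == "B7"

    @pytest.mark.parametrize("well", ["I1", "A13", "A0", "99", "AA1"])
    def test_invalid_coordinates_rejected(self, well):
        with pytest.raises(plate_io.PlateValidationError):
            plate_io.WellTimeSeries("p1", well, [0.0, 10.0], [0.1, 0.2])

    def test_non_increasing_times_rejected(self):
        with pytest.raises(plate_io.PlateValidationError):
            plate_io.WellTimeSeries("p1", "A1", [0.0, 10.0, 10.0], [0.1, 0.2, 0.3])


class TestReadPlateTimeseries:
    def test_long_dialect(self, tmp_path):
        df = pd.DataFrame(
            {
                "plate_id": ["p1"] * 6,
                "well": ["A1", "A1", "A1", "A2", "A2", "A2"],
                "time_min": [0, 10, 20, 0, 10, 20],
                "od_raw": [0.1, 0.2, 0.3, 0.15, 0.25, 0.35],
            }
        )
        path = tmp_path / "ts.csv"
        df.to_csv(path, index=False)
        series = plate_io.read_plate_timeseries(path)
        assert len(series) == 2
        assert all(len(s.times) == 3 for s in series)

    def test_wide_dialect(self, tmp_path):
        df = pd.DataFrame(
            {"time_min": [0, 10], "A1": [0.1, 0.2], "A2": [0.1, 0.3], "A3": [0.1, 0.4]}
        )
        path = tmp_path / "wide.csv"
        df.to_csv(path, index=False)
        series = plate_io.read_plate_timeseries(path, dialect="wide")
        assert sorted(s.well for s in series) == ["A1", "A2", "A3"]

    def test_round_trip_preserves_values(self, tmp_path):
        original = [_series("A1"), _series("B3", n=5)]
        path = tmp_path / "rt.csv"
        plate_io.write_plate_timeseries(original, path)
        back = plate_io.read_plate_timeseries(path)
        assert len(back) == 2
        for a, b in zip(sorted(original, key=lambda s: s.well), back):
            np.testing.assert_allclose(b.times, a.times)
            np.testing.assert_allclose(b.od_raw, a.od_raw)

    def test_shuffled_rows_parse_identically(self, tmp_path):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "plate_id": ["p1"] * 8,
                "well": ["A1", "A2"] * 4,
                "time_min": [0, 0, 10, 10, 20, 20, 30, 30],
                "od_raw": np.round(rng.uniform(0.1, 0.5, 8), 4),
            }
        )
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        df.to_csv(p1, index=False)
        df.sample(frac=1, random_state=1).to_csv(p2, index=False)
        s1 = plate_io.read_plate_timeseries(p1)
        s2 = plate_io.read_plate_timeseries(p2)
        for a, b in zip(s1, s2):
            assert a.well == b.well
            np.testing.assert_array_equal(a.od_raw, b.od_raw)

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"plate_id": ["p1"], "well": ["A1"], "time_min": [0]}).to_csv(path, index=False)
        with pytest.raises(plate_io.PlateFormatError, match="od_raw"):
            plate_io.read_plate_timeseries(path)

    def test_non_numeric_od_reports_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame(
            {"plate_id": ["p1", "p1"], "well": ["A1", "A1"], "time_min": [0, 10], "od_raw": [0.1, "oops"]}
        ).to_csv(path, index=False)
        with pytest.raises(plate_io.PlateFormatError, match="row index 1"):
            plate_io.read_plate_timeseries(path)

    def test_duplicate_time_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        pd.DataFrame(
            {"plate_id": ["p1"] * 3, "well": ["A1"] * 3, "time_min": [0, 10, 10], "od_raw": [0.1, 0.2, 0.3]}
        ).to_csv(path, index=False)
        with pytest.raises(plate_io.PlateValidationError, match="duplicate"):
            plate_io.read_plate_timeseries(path)


def _map_frame(n_samples=93, n_blanks=3):
    wells = [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]
    rows = []
    for i, w in enumerate(wells[: n_samples + n_blanks]):
        blank = i >= n_samples
        rows.append(
            {
                "well": w,
                "genotype": "" if blank else f"g{i % 4}",
                "vector": "" if blank else "v",
                "treatment": "" if blank else "drug",
                "concentration": 0.0,
                "conc_unit": "mM",
                "replicate": 1 + i % 3,
                "role": "blank" if blank else "sample",
                "is_reference_condition": 0,
                "is_empty_vector": 0,
            }
        )
    return pd.DataFrame(rows)


class TestPlateMap:
    def test_full_plate_counts(self, tmp_path):
        path = tmp_path / "map.csv"
        _map_frame().to_csv(path, index=False)
        pm = plate_io.read_plate_map(path)
        assert len(pm.samples()) == 93
        assert len(pm.blanks()) == 3

    def test_blank_without_genotype_accepted(self, tmp_path):
        path = tmp_path / "map.csv"
        _map_frame(n_samples=2, n_blanks=1).to_csv(path, index=False)
        pm = plate_io.read_plate_map(path)
        assert len(pm.blanks()) == 1

    def test_sample_without_genotype_rejected(self, tmp_path):
        df = _map_frame(n_samples=2, n_blanks=1)
        df.loc[0, "genotype"] = ""
        path = tmp_path / "map.csv"
        df.to_csv(path, index=False)
        with pytest.raises(plate_io.PlateValidationError, match="genotype"):
            plate_io.read_plate_map(path)

    def test_no_blanks_warns_not_fatal(self, tmp_path):
        path = tmp_path / "map.csv"
        _map_frame(n_samples=3, n_blanks=0).to_csv(path, index=False)
        pm = plate_io.read_plate_map(path)
        assert any("blank" in w for w in pm.warnings)

    def test_conflicting_reference_concentrations_rejected(self, tmp_path):
        df = _map_frame(n_samples=4, n_blanks=1)
        df.loc[:3, "genotype"] = "g0"
        df.loc[:3, "treatment"] = "drug"
        df.loc[0, "is_reference_condition"] = 1
        df.loc[1, "is_reference_condition"] = 1
        df.loc[1, "concentration"] = 2.0
        path = tmp_path / "map.csv"
        df.to_csv(path, index=False)
        with pytest.raises(plate_io.PlateValidationError, match="reference"):
            plate_io.read_plate_map(path)


class TestResults:
    def test_write_one_row(self, tmp_path):
        table = plate_io.ResultTable(
            [plate_io.ResultRow("g1", "drug", 0.5, 1, 100.0, 0.01, 2.5, 900.0, 1234.5, 0.8, 0.9, "")]
        )
        path = tmp_path / "res.csv"
        plate_io.write_results(table, path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 2
        assert lines[0].split(",") == plate_io.RESULT_COLUMNS

    def test_missing_value_empty_field_with_flag(self, tmp_path):
        row = plate_io.ResultRow("g1", "drug", 0.5, 1, flags="no_reference_auc")
        path = tmp_path / "res.csv"
        plate_io.write_results(plate_io.ResultTable([row]), path)
        df = plate_io.read_results(path)
        assert np.isnan(df["delta_auc_vs_control"].iloc[0])
        assert df["flags"].iloc[0] == "no_reference_auc"

    def test_round_trip_within_serialization_precision(self, tmp_path):
        row = plate_io.ResultRow("g1", "drug", 0.5, 2, 123.456789, 0.0123456789, 2.5, 900.0, 999.999, 1.0, 1.0, "")
        path = tmp_path / "res.csv"
        plate_io.write_results(plate_io.ResultTable([row]), path)
        df = plate_io.read_results(path)
        assert df["lag_lambda"].iloc[0] == pytest.approx(123.456789, rel=1e-5)
        assert df["mu_max"].iloc[0] == pytest.approx(0.0123456789, rel=1e-5)
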