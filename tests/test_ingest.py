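"""Packet-log parsing, the missing-sample formula, imputation, outliers."""

import numpy as np
import pandas as pd
import pytest

from sordkit import (
    DataQualityError,
    FormatError,
    OrderingError,
    detect_missing,
    fill_boundary,
    impute_gaps,
    inject_packet_loss,
    read_packet_log,
    remove_outliers,
    simulate_session,
    write_packet_log,
)
from sordkit.ingest import OutlierPolicy
from sordkit.stream import CHANNEL_COLUMNS, LabeledStream
from tests.conftest import short_script


def make_stream(timestamps, accel_x=None, rate=25.0):
    n = len(timestamps)
    data = {"timestamp": np.asarray(timestamps, dtype=float)}
    for c in CHANNEL_COLUMNS:
        data[c] = np.zeros(n)
    if accel_x is not None:
        data["accel_x"] = np.asarray(accel_x, dtype=float)
    return LabeledStream(pd.DataFrame(data), sampling_rate=rate)


class TestReadPacketLog:
    def test_round_trip(self, mini_stream, tmp_path):
        path = tmp_path / "raw.csv"
        write_packet_log(mini_stream, path)
        stream, skipped = read_packet_log(path)
        assert skipped == 0
        assert len(stream) == len(mini_stream)
        np.testing.assert_array_equal(stream.timestamps, mini_stream.timestamps)
        np.testing.assert_allclose(
            stream.channels(), mini_stream.channels(), rtol=0, atol=5e-7
        )

    def test_three_row_fixture(self, tmp_path):
        path = tmp_path / "raw.csv"
        write_packet_log(make_stream([0.0, 0.04, 0.08], accel_x=[1, 2, 3]), path)
        stream, skipped = read_packet_log(path)
        assert len(stream) == 3 and skipped == 0
        np.testing.assert_allclose(stream.data["accel_x"], [1, 2, 3])

    def test_header_order_independence(self, tmp_path):
        path = tmp_path / "raw.csv"
        write_packet_log(make_stream([0.0, 0.04], accel_x=[5, 6]), path)
        df = pd.read_csv(path, dtype=str)
        shuffled = tmp_path / "shuffled.csv"
        df[list(df.columns[::-1])].to_csv(shuffled, index=False)
        a, _ = read_packet_log(path)
        b, _ = read_packet_log(shuffled)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_malformed_row_skipped_and_counted(self, tmp_path):
        path = tmp_path / "raw.csv"
        write_packet_log(make_stream([0.0, 0.04, 0.08]), path)
        lines = path.read_text().splitlines()
        lines[2] = lines[2].replace("0.0", "not-a-number", 1)
        path.write_text("\n".join(lines))
        stream, skipped = read_packet_log(path)
        assert skipped == 1
        assert len(stream) == 2

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "raw.csv"
        write_packet_log(make_stream([0.0, 0.04]), path)
        df = pd.read_csv(path).drop(columns=["gyroY"])
        df.to_csv(path, index=False)
        with pytest.raises(FormatError, match="gyroY"):
            read_packet_log(path)

    def test_non_monotone_timestamps_name_the_row(self, tmp_path):
        path = tmp_path / "raw.csv"
        write_packet_log(make_stream([0.0, 0.04, 0.08]), path)
        df = pd.read_csv(path, dtype=str)
        df.loc[2, "time"] = df.loc[0, "time"]  # clock goes backwards
        df.to_csv(path, index=False)
        with pytest.raises(OrderingError, match="row 2"):
            read_packet_log(path)


class TestDetectMissing:
    def test_nominal_spacing_has_no_gaps(self):
        report = detect_missing(make_stream([0.00, 0.04, 0.08]), 25.0)
        assert report.total_missing == 0
        assert report.gaps == ()

    @pytest.mark.parametrize("k", range(1, 11))
    def test_gap_of_k_samples_counts_k(self, k):
        # ΔT = (k+1)/25 → missing = ΔT·25 − 1 = k
        report = detect_missing(make_stream([0.0, (k + 1) / 25.0]), 25.0)
        assert report.total_missing == k
        assert report.gaps[0][2] == k

    def test_printed_formula_examples(self):
        assert detect_missing(make_stream([0.0, 0.08]), 25.0).total_missing == 1
        assert detect_missing(make_stream([0.0, 0.20]), 25.0).total_missing == 4

    def test_jitter_under_half_period_absorbed_by_rounding(self):
        report = detect_missing(make_stream([0.0, 0.04 + 0.015]), 25.0)
        assert report.total_missing == 0

    def test_negative_delta_is_ordering_error(self):
        # construction rejects decreasing timestamps outright ...
        with pytest.raises(ValueError, match="strictly increasing"):
            make_stream([0.04, 0.0])
        # ... and detect_missing guards against post-construction mutation too
        stream = make_stream([0.0, 0.04, 0.08])
        stream.data.loc[1, "timestamp"] = 0.10
        with pytest.raises(OrderingError):
            detect_missing(stream)


class TestImputeGaps:
    def test_no_gaps_is_identity(self):
        s = make_stream([0.0, 0.04, 0.08])
        assert impute_gaps(s, detect_missing(s)) is s

    def test_single_gap_neighbor_average(self):
        s = make_stream([0.0, 0.08], accel_x=[10.0, 20.0])
        out = impute_gaps(s, detect_missing(s))
        np.testing.assert_allclose(out.data["accel_x"], [10.0, 15.0, 20.0])
        np.testing.assert_array_equal(out.timestamps, [0.0, 0.04, 0.08])

    def test_multi_sample_gap_is_constant_fill_not_interpolation(self):
        s = make_stream([0.0, 0.16], accel_x=[10.0, 20.0])
        out = impute_gaps(s, detect_missing(s))
        # the literal before/after-average rule: every slot gets the same value
        np.testing.assert_allclose(out.data["accel_x"], [10.0, 15.0, 15.0, 15.0, 20.0])

    def test_linear_fill_available_behind_flag(self):
        s = make_stream([0.0, 0.16], accel_x=[10.0, 20.0])
        out = impute_gaps(s, detect_missing(s), linear=True)
        np.testing.assert_allclose(out.data["accel_x"], [10.0, 12.5, 15.0, 17.5, 20.0])

    def test_repair_is_idempotent(self, mini_stream):
        lossy = inject_packet_loss(mini_stream, 0.15, seed=3)
        fixed = impute_gaps(lossy)
        assert detect_missing(fixed).total_missing == 0
        assert fixed.is_regular()
        assert len(fixed) == len(mini_stream)

    def test_surviving_samples_bitwise_unchanged(self, mini_stream):
        lossy = inject_packet_loss(mini_stream, 0.15, seed=3)
        fixed = impute_gaps(lossy)
        merged = lossy.data.merge(fixed.data, on="timestamp", suffixes=("", "_f"))
        assert len(merged) == len(lossy)
        for c in CHANNEL_COLUMNS:
            assert (merged[c].to_numpy() == merged[f"{c}_f"].to_numpy()).all()

    def test_round_trip_recovers_timestamps_and_rmse_shrinks_with_loss(self):
        script = short_script(("walking", "treadmill-4kmh", 60.0))
        s = simulate_session(script, seed=8)

        def rmse_at(rate):
            fixed = impute_gaps(inject_packet_loss(s, rate, seed=13))
            assert np.array_equal(fixed.timestamps, s.timestamps)
            return float(np.sqrt(np.mean((fixed.channels() - s.channels()) ** 2)))

        assert rmse_at(0.02) < rmse_at(0.1) < rmse_at(0.3)

    def test_boundary_fill_uses_nearest_neighbor(self):
        s = make_stream([0.08, 0.12], accel_x=[7.0, 8.0])
        out = fill_boundary(s, expected_start=0.0, expected_end=0.20)
        np.testing.assert_array_equal(out.timestamps, [0.0, 0.04, 0.08, 0.12, 0.16, 0.20])
        np.testing.assert_allclose(out.data["accel_x"], [7, 7, 7, 8, 8, 8])


class TestRemoveOutliers:
    def test_clean_stream_zero_removals(self, mini_stream):
        out, log = remove_outliers(mini_stream)
        assert log.count == 0
        assert out.data.equals(mini_stream.data)

    def test_physically_impossible_sample_refilled(self):
        s = make_stream([0.0, 0.04, 0.08], accel_x=[1.0, 50.0, 2.0])
        out, log = remove_outliers(s)
        assert log.count == 1
        assert log.removed_indices == (1,)
        assert out.data.loc[1, "accel_x"] == pytest.approx(1.5)
        assert len(out) == 3

    def test_gyro_bound_configurable(self):
        s = make_stream([0.0, 0.04, 0.08])
        s.data["gyro_z"] = [0.0, 500.0, 0.0]
        _, log_default = remove_outliers(s)
        assert log_default.count == 0
        _, log_strict = remove_outliers(s, OutlierPolicy(max_gyro_dps=300.0))
        assert log_strict.count == 1

    def test_all_violating_stream_rejected(self):
        s = make_stream([0.0, 0.04], accel_x=[99.0, 99.0])
        with pytest.raises(DataQualityError):
            remove_outliers(s)
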