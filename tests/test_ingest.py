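"""Ingestion chain: R-R conversion, resampling, filtering, alignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hragree import cohort as ch
from hragree import ingest
from hragree.series import RRStream, UniformHRSeries


def uniform(hr, cadence=1.0, start=0.0, mask=None):
    return UniformHRSeries("s", cadence, start, np.asarray(hr, float), mask)


class TestRRToBpm:
    @pytest.mark.parametrize(
        "rr,expected", [(1000.0, 60.0), (600.0, 100.0), (857.0, 60000.0 / 857.0)]
    )
    def test_definitional_conversion(self, rr, expected):
        stream = RRStream("s", np.array([1.0]), np.array([rr]))
        _, bpm = ingest.rr_to_bpm(stream)
        assert bpm[0] == pytest.approx(expected, abs=1e-4)

    def test_non_positive_interval_names_row(self):
        with pytest.raises(ValueError, match="row 1"):
            RRStream("s", np.array([1.0, 2.0]), np.array([800.0, -5.0]))


class TestResampleUniform:
    def test_linear_midpoint(self):
        s = ingest.resample_uniform(np.array([0.0, 10.0]), np.array([60.0, 80.0]))
        assert s.hr[5] == pytest.approx(70.0)
        assert s.start_offset_s == 0.0

    def test_constant_input_constant_output(self):
        t = np.array([0.3, 2.1, 5.9, 9.4])
        s = ingest.resample_uniform(t, np.full(4, 82.0))
        assert np.allclose(s.hr, 82.0)

    def test_no_extrapolation_beyond_span(self):
        s = ingest.resample_uniform(np.array([1.4, 9.3]), np.array([60.0, 80.0]))
        assert s.start_offset_s == 2.0
        assert s.times_s[-1] == 9.0

    def test_values_bracketed_by_neighbours(self, rng):
        # oracle: two-point interpolation bounds every grid value
        t = np.sort(rng.uniform(0, 100, 100))
        v = rng.uniform(50, 150, 100)
        s = ingest.resample_uniform(t, v)
        for ti, vi in zip(s.times_s, s.hr):
            left = np.searchsorted(t, ti, side="right") - 1
            right = min(left + 1, len(t) - 1)
            lo, hi = sorted((v[left], v[right]))
            assert lo - 1e-9 <= vi <= hi + 1e-9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="2 points"):
            ingest.resample_uniform(np.array([1.0]), np.array([60.0]))


class TestLowpassFilter:
    def test_dc_gain_unity(self):
        s = uniform(np.full(600, 100.0))
        out = ingest.lowpass_filter(s)
        assert np.abs(out.hr - 100.0).max() < 1e-6

    def test_stopband_attenuation_at_quarter_hz(self):
        # analytic 5th-order Butterworth: |H(0.25)| = 1/sqrt(1+(0.25/0.1)^10),
        # squared for the two-pass application -> ~1e-4; assert the >20x bound
        t = np.arange(600.0)
        s = uniform(100.0 + 10.0 * np.sin(2 * np.pi * 0.25 * t))
        out = ingest.lowpass_filter(s)
        interior = out.hr[60:-60]
        assert np.abs(interior - 100.0).max() < 10.0 / 20.0

    def test_passband_preserved_at_hundredth_hz(self):
        t = np.arange(1200.0)
        s = uniform(100.0 + 10.0 * np.sin(2 * np.pi * 0.01 * t))
        out = ingest.lowpass_filter(s)
        interior = np.abs(out.hr[100:-100] - 100.0)
        assert interior.max() == pytest.approx(10.0, rel=0.05)

    def test_mean_preserved_for_bandlimited_input(self):
        t = np.arange(1200.0)
        s = uniform(110.0 + 5.0 * np.sin(2 * np.pi * 0.03 * t))
        out = ingest.lowpass_filter(s)
        assert abs(out.hr[100:-100].mean() - s.hr[100:-100].mean()) < 0.1

    def test_short_series_instructs_exclusion(self):
        with pytest.raises(ValueError, match="exclude"):
            ingest.lowpass_filter(uniform(np.full(10, 100.0)))

    def test_wrong_cadence_rejected(self):
        with pytest.raises(ValueError, match="1-s cadence"):
            ingest.lowpass_filter(uniform(np.full(100, 100.0), cadence=10.0))


class TestDownsampleMean:
    def test_constant_minute(self):
        out = ingest.downsample_mean(uniform(np.full(60, 120.0)), 60.0)
        assert out.hr == pytest.approx([120.0])

    def test_two_slot_mean(self):
        out = ingest.downsample_mean(uniform([60.0, 120.0], cadence=30.0), 60.0)
        assert out.hr == pytest.approx([90.0])

    def test_matches_bruteforce_bins(self, rng):
        v = rng.uniform(60, 160, 600)
        out = ingest.downsample_mean(uniform(v), 10.0)
        expected = v.reshape(60, 10).mean(axis=1)
        assert np.allclose(out.hr, expected)

    def test_mean_of_means_equals_overall_mean(self, rng):
        v = rng.uniform(60, 160, 600)
        out = ingest.downsample_mean(uniform(v), 10.0)
        assert out.hr.mean() == pytest.approx(v.mean())

    def test_sparse_bin_marked_missing(self):
        v = np.full(60, 100.0)
        mask = np.ones(60, bool)
        mask[:30] = False  # first 10-s bins below the coverage threshold
        out = ingest.downsample_mean(uniform(v, mask=mask), 10.0)
        assert not out.mask[:3].any()
        assert out.mask[3:].all()

    def test_non_divisible_cadence_rejected(self):
        with pytest.raises(ValueError, match="integer multiple"):
            ingest.downsample_mean(uniform(np.full(100, 100.0), cadence=7.0), 60.0)


class TestPairing:
    def test_interval_intersection(self):
        test = uniform(np.full(60, 100.0), cadence=60.0, start=0.0)
        ref = uniform(np.full(60, 100.0), cadence=60.0, start=120.0)
        idx, t, r = ingest.pair_minutes(test, ref)
        assert idx[0] == 2 and idx[-1] == 59 and len(idx) == 58

    def test_symmetry_of_alignment(self, rng):
        m1 = rng.random(50) > 0.2
        m2 = rng.random(50) > 0.2
        a = uniform(rng.uniform(60, 150, 50), cadence=60.0, mask=m1)
        b = uniform(rng.uniform(60, 150, 50), cadence=60.0, start=300.0, mask=m2)
        idx_ab, _, _ = ingest.pair_minutes(a, b)
        idx_ba, _, _ = ingest.pair_minutes(b, a)
        assert np.array_equal(idx_ab, idx_ba)

    def test_short_reference_session_excluded(self, tiny_dataset, tmp_path):
        root, participants, manifest = tiny_dataset
        row = manifest.iloc[[0]].copy()
        ref = pd.read_csv(root / row.iloc[0].reference_file)
        short = ref.iloc[:900]  # ~15 minutes of beats
        short_path = tmp_path / "short_ref.csv"
        short.to_csv(short_path, index=False)
        (tmp_path / "streams").mkdir()
        import shutil

        shutil.copy(root / row.iloc[0].test_file, tmp_path / row.iloc[0].test_file)
        row.loc[row.index[0], "reference_file"] = "short_ref.csv"
        sessions, excl = ingest.align_sessions(row, participants, tmp_path)
        assert not sessions
        assert len(excl) == 1 and "too_few_paired_minutes" in excl[0].reason

    def test_zero_overlap_distinct_reason(self, tiny_dataset, tmp_path):
        root, participants, manifest = tiny_dataset
        row = manifest.iloc[[0]].copy()
        test_df = pd.read_csv(root / row.iloc[0].test_file)
        shifted = test_df.copy()
        shifted["timestamp_iso8601"] = (
            pd.to_datetime(shifted["timestamp_iso8601"]) + pd.Timedelta(hours=3)
        ).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
        (tmp_path / "streams").mkdir()
        import shutil

        shutil.copy(
            root / row.iloc[0].reference_file, tmp_path / row.iloc[0].reference_file
        )
        shifted.to_csv(tmp_path / row.iloc[0].test_file, index=False)
        sessions, excl = ingest.align_sessions(row, participants, tmp_path)
        assert not sessions
        assert excl[0].reason == "no_overlapping_minutes"

    def test_missing_file_logged_not_fatal(self, tiny_dataset, tmp_path):
        _, participants, manifest = tiny_dataset
        sessions, excl = ingest.align_sessions(
            manifest.iloc[[0]], participants, tmp_path
        )
        assert not sessions
        assert excl[0].reason.startswith("missing_file")

    def test_headerless_dialect_tolerated(self, tiny_dataset, tmp_path):
        root, _, manifest = tiny_dataset
        src = pd.read_csv(root / manifest.iloc[0].test_file)
        bare = tmp_path / "noheader.csv"
        src.to_csv(bare, index=False, header=False)
        start = pd.Timestamp(manifest.iloc[0].start_iso8601)
        series = ingest.read_test_minutes(bare, start)
        assert series.mask.sum() == len(src)


class TestEndToEnd:
    def test_zero_noise_identity_sessions_agree(self):
        prof = ch.ParticipantProfile("P01", 60, 60.0, 1)
        traj = ch.simulate_true_hr(prof, ch.default_protocol(), 1, noise_sd=0.0)
        err = ch.error_preset("identity-clean")
        stream = ch.emit_reference_rr(traj, err, 2)
        stream.session_id = "s"
        test = ch.emit_test_minutes(traj, err, 3)
        ref_minutes = ingest.reference_to_minutes(stream)
        idx, t, r = ingest.pair_minutes(test, ref_minutes)
        interior = (idx >= 1) & (idx <= idx.max() - 1)
        assert np.abs(t[interior] - r[interior]).max() < 0.5

    def test_validity_gate_drops_corrupt_minutes(self):
        s = uniform([80.0, 300.0, 5.0, 90.0], cadence=60.0)
        out = ingest.validity_gate(s)
        assert list(out.mask) == [True, False, False, True]
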