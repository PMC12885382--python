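"""Feature-extraction tests: filtering, Welch PSDs, bands, matrices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepprint.containers import (
    CHANNELS_1020,
    DataError,
    PSDSegment,
    SleepRecording,
)
from sleepprint.features import (
    Epoch,
    bandpass_and_epoch,
    bandpass_filter,
    build_matrices,
    define_bands,
    psd_auc,
    relative_bandpower,
    welch_psd,
    zscore_features,
)

FS = 250.0
WELCH_FREQS = np.fft.rfftfreq(1024, 1 / FS)


def _recording(data):
    return SleepRecording(
        subject_id="R1",
        sampling_rate=FS,
        channels=tuple(CHANNELS_1020),
        data=data,
        stage_annotation=[(0.0, 300.0, "N1"), (300.0, 600.0, "N2")],
    )


def _epoch(data, label="N2a", stage="N2"):
    return Epoch(subject_id="R1", segment_label=label, stage=stage, data=data, sampling_rate=FS)


def _segment(psd, freqs=WELCH_FREQS, label="N2a"):
    return PSDSegment(subject_id="R1", segment_label=label, stage="N2", freqs=freqs, psd=psd)


class TestBandDefinition:
    def test_matches_published_band_table(self):
        bands = define_bands()
        assert bands.n_bands == 13
        assert (bands.edges[0], bands.edges[1]) == (1.0, 3.0)
        assert (bands.edges[-2], bands.edges[-1]) == (38.2, 42.6)
        np.testing.assert_allclose(np.diff(bands.widths), 0.2, atol=1e-12)
        assert bands.total_width == pytest.approx(41.6)


class TestBandpassAndEpoch:
    def test_six_canonical_epochs(self):
        rng = np.random.default_rng(0)
        rec = _recording(rng.standard_normal((19, 225000)))
        epochs = bandpass_and_epoch(rec)
        assert [e.segment_label for e in epochs] == ["N1a", "N1b", "N2a", "N2b", "N2c", "N2d"]
        assert sum(e.stage == "N1" for e in epochs) == 2
        assert sum(e.stage == "N2" for e in epochs) == 4
        assert all(e.data.shape == (19, 15000) for e in epochs)

    def test_zero_signal_stays_zero(self):
        out = bandpass_filter(np.zeros((2, 30000)), FS)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_slow_drift_attenuated_20db(self):
        t = np.arange(225000) / FS
        drift = np.sin(2 * np.pi * 0.1 * t)[None, :]
        passband = np.sin(2 * np.pi * 10.0 * t)[None, :]
        mid = slice(30000, 195000)  # avoid filter edges
        drift_gain = np.std(bandpass_filter(drift, FS)[0, mid]) / np.std(drift[0, mid])
        pass_gain = np.std(bandpass_filter(passband, FS)[0, mid]) / np.std(passband[0, mid])
        assert 20 * np.log10(pass_gain / drift_gain) >= 20.0

    def test_short_recording_rejected(self):
        rec = _recording(np.zeros((19, 1000)))
        with pytest.raises(DataError, match="R1"):
            bandpass_and_epoch(rec)


class TestWelchPsd:
    def test_sinusoid_total_power_parseval(self):
        t = np.arange(15000) / FS
        x = np.sin(2 * np.pi * 10.0 * t)[None, :]
        seg = welch_psd(_epoch(x))
        total = np.trapezoid(seg.psd[0], seg.freqs)
        assert total == pytest.approx(0.5, rel=0.05)

    def test_white_noise_halves_agree(self):
        rng = np.random.default_rng(1)
        a = welch_psd(_epoch(rng.standard_normal((4, 15000))))
        b = welch_psd(_epoch(rng.standard_normal((4, 15000))))
        keep = (a.freqs >= 1) & (a.freqs <= 42.6)
        pa, pb = a.psd[:, keep].mean(axis=0), b.psd[:, keep].mean(axis=0)
        rel_mad = np.mean(np.abs(pa - pb)) / np.mean(pa)
        assert rel_mad < 0.20

    def test_zero_signal_zero_psd(self):
        seg = welch_psd(_epoch(np.zeros((3, 15000))))
        np.testing.assert_array_equal(seg.psd, 0.0)

    def test_wrong_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="sampling rate"):
            welch_psd(Epoch("R1", "N2a", "N2", np.zeros((1, 15000)), 200.0))


class TestRelativeBandpower:
    def test_flat_spectrum_gives_width_shares(self):
        seg = _segment(np.ones((19, WELCH_FREQS.size)))
        rel = relative_bandpower(seg).reshape(19, 13)
        bands = define_bands()
        np.testing.assert_allclose(
            rel, np.tile(bands.widths / bands.total_width, (19, 1)), atol=1e-12
        )
        assert rel[0, 0] == pytest.approx(2.0 / 41.6, abs=1e-12)

    def test_power_concentrated_in_one_band(self):
        psd = np.zeros((1, WELCH_FREQS.size))
        psd[0, (WELCH_FREQS > 13.2) & (WELCH_FREQS < 15.8)] = 4.0
        rel = relative_bandpower(_segment(psd)).reshape(1, 13)
        assert rel[0, 5] == pytest.approx(1.0)
        assert np.all(rel[0, np.arange(13) != 5] < 1e-12)

    def test_matches_piecewise_linear_integration_oracle(self, rng):
        """Trapezoid band powers equal an independent segment-by-segment
        analytic integration of the piecewise-linear PSD."""
        psd = rng.random((2, WELCH_FREQS.size)) + 0.1
        psd[:, WELCH_FREQS > 50] = 0.0
        rel = relative_bandpower(_segment(psd)).reshape(2, 13)
        bands = define_bands()
        f = WELCH_FREQS
        for c in range(2):
            oracle = np.zeros(13)
            for b in range(13):
                lo, hi = bands.edges[b], bands.edges[b + 1]
                for i in range(f.size - 1):
                    a_, b_ = max(f[i], lo), min(f[i + 1], hi)
                    if a_ >= b_:
                        continue
                    ya = np.interp(a_, f, psd[c])
                    yb = np.interp(b_, f, psd[c])
                    oracle[b] += 0.5 * (ya + yb) * (b_ - a_)
            np.testing.assert_allclose(rel[c], oracle / oracle.sum(), atol=1e-9)

    def test_dead_channel_raises(self):
        psd = np.ones((2, WELCH_FREQS.size))
        psd[1] = 0.0
        with pytest.raises(DataError, match=r"channel\(s\) \[1\]"):
            relative_bandpower(_segment(psd))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_channel_shares_always_sum_to_one(self, seed):
        psd = np.random.default_rng(seed).random((19, WELCH_FREQS.size)) + 1e-6
        rel = relative_bandpower(_segment(psd))
        assert rel.size == 247
        np.testing.assert_allclose(rel.reshape(19, 13).sum(axis=1), 1.0, atol=1e-9)


class TestPsdAuc:
    def test_zero_and_flat(self):
        assert psd_auc(_segment(np.zeros((2, WELCH_FREQS.size)))) == 0.0
        assert psd_auc(_segment(np.full((2, WELCH_FREQS.size), 3.0))) == pytest.approx(
            3.0 * 41.6, rel=1e-9
        )

    def test_matches_quadrature_oracle(self, rng):
        psd = rng.random((3, WELCH_FREQS.size))
        val = psd_auc(_segment(psd))
        mean = psd.mean(axis=0)
        f = WELCH_FREQS
        oracle = 0.0
        for i in range(f.size - 1):
            a_, b_ = max(f[i], 1.0), min(f[i + 1], 42.6)
            if a_ >= b_:
                continue
            oracle += 0.5 * (np.interp(a_, f, mean) + np.interp(b_, f, mean)) * (b_ - a_)
        assert val == pytest.approx(oracle, abs=1e-9)


class TestBuildMatrices:
    def _segments(self, n_subjects, labels):
        rng = np.random.default_rng(5)
        segs = []
        for i in range(n_subjects):
            for lab in labels:
                segs.append(
                    PSDSegment(
                        subject_id=f"S{i}",
                        segment_label=lab,
                        stage="N2",
                        freqs=WELCH_FREQS,
                        psd=rng.random((19, WELCH_FREQS.size)) + 0.01,
                    )
                )
        return segs

    def test_shapes_and_one_hot(self):
        fm, design = build_matrices(self._segments(3, ["N2a", "N2b"]), ["N2a", "N2b"])
        assert fm.values.shape == (6, 247)
        assert design.values.shape == (6, 3)
        design.validate()

    def test_single_subject_design_is_ones_column(self):
        _, design = build_matrices(self._segments(1, ["N2a", "N2b"]), ["N2a", "N2b"])
        np.testing.assert_array_equal(design.values, np.ones((2, 1)))

    def test_duplicate_segment_rejected(self):
        segs = self._segments(1, ["N2a"]) * 2
        with pytest.raises(DataError, match="duplicate"):
            build_matrices(segs, ["N2a"])

    def test_missing_segment_lists_subject(self):
        segs = self._segments(2, ["N2a", "N2b"])[:-1]
        with pytest.raises(DataError, match="S1"):
            build_matrices(segs, ["N2a", "N2b"])


class TestZscore:
    def test_train_columns_standardized(self, rng):
        from sleepprint.containers import FeatureMatrix
        import pandas as pd

        fm = FeatureMatrix(
            values=rng.random((50, 10)) * 3 + 1,
            row_meta=pd.DataFrame({"subject_id": ["s"] * 50, "segment_label": "a", "stage": "N2"}),
            feature_names=[f"f{i}" for i in range(10)],
        )
        std = zscore_features(fm)
        assert np.abs(std.values.mean(axis=0)).max() < 1e-10
        np.testing.assert_allclose(std.values.std(axis=0), 1.0, atol=1e-10)
        # applying to the train matrix itself reproduces the same output
        std2, applied = zscore_features(fm, fm)
        np.testing.assert_array_equal(std.values, applied.values)

    def test_heldout_rows_near_zero_mean(self, rng):
        from sleepprint.containers import FeatureMatrix
        import pandas as pd

        def make(n, seed):
            r = np.random.default_rng(seed)
            return FeatureMatrix(
                values=r.normal(2.0, 1.5, size=(n, 5)),
                row_meta=pd.DataFrame(
                    {"subject_id": ["s"] * n, "segment_label": "a", "stage": "N2"}
                ),
                feature_names=[f"f{i}" for i in range(5)],
            )

        _, applied = zscore_features(make(1000, 1), make(1000, 2))
        assert np.abs(applied.values.mean(axis=0)).max() < 0.15

    def test_zero_variance_column_warns(self):
        from sleepprint.containers import FeatureMatrix
        import pandas as pd

        fm = FeatureMatrix(
            values=np.column_stack([np.ones(10), np.arange(10.0)]),
            row_meta=pd.DataFrame({"subject_id": ["s"] * 10, "segment_label": "a", "stage": "N2"}),
            feature_names=["const", "ramp"],
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            std = zscore_features(fm)
        assert np.all(np.isfinite(std.values))
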