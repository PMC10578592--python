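"""Referencing, epoching, rejection rules, downsampling."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from painhfa.io import ChannelMeta, Recording
from painhfa.preprocess import (
    EpochSet,
    common_median_reference,
    detect_artifacts,
    downsample,
    extract_epochs,
    mad_outlier_flag,
)


def _rec(samples, fs=1000.0):
    chans = [ChannelMeta(name=f"ch{i}", atlas_label="Amyg_L_1_1")
             for i in range(samples.shape[0])]
    return Recording(samples=samples, fs=fs, channels=chans, patient_id="P00")


def _epochs(data, fs=1000.0, t_start_ms=-1000.0, **kw):
    data = np.asarray(data, dtype=float)
    return EpochSet(data=data, fs=fs, event="hand_on", t_start_ms=t_start_ms,
                    trial_ids=np.arange(data.shape[0]), **kw)


class TestCommonMedianReference:
    def test_three_channel_example(self):
        rec = _rec(np.array([[1.0], [2.0], [3.0]]))
        out = common_median_reference(rec)
        np.testing.assert_allclose(out.samples[:, 0], [-1.0, 0.0, 1.0])

    def test_identical_channels_become_zero(self):
        rec = _rec(np.ones((4, 20)) * 7.5)
        out = common_median_reference(rec)
        np.testing.assert_allclose(out.samples, 0.0)

    def test_per_sample_median_zero_for_odd_channel_count(self):
        rng = np.random.default_rng(0)
        rec = _rec(rng.normal(0, 50, (5, 1000)))
        out = common_median_reference(rec)
        np.testing.assert_allclose(np.median(out.samples, axis=0), 0.0,
                                   atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        rec = _rec(rng.normal(0, 50, (6, 500)))
        once = common_median_reference(rec)
        twice = common_median_reference(once)
        np.testing.assert_allclose(twice.samples, once.samples, atol=1e-9)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            common_median_reference(_rec(np.zeros((1, 10))))


def _trials(events, fs=1000.0):
    return pd.DataFrame(
        dict(patient_id="P00", trial_id=np.arange(len(events)),
             temperature=45.0, hand_on=events,
             hand_off=np.asarray(events) + int(10 * fs),
             binary_response=0, vas=0)
    )


class TestExtractEpochs:
    def test_shape_bookkeeping(self):
        rng = np.random.default_rng(0)
        rec = _rec(rng.normal(0, 10, (3, 400_000)))
        events = 5000 + np.arange(20) * 15000
        ep = extract_epochs(rec, _trials(events), span=(-3000, 1000))
        assert ep.data.shape == (20, 3, 4000)
        assert ep.t_axis[0] == -3000.0

    def test_out_of_bounds_trial_dropped(self):
        rec = _rec(np.zeros((2, 10_000)))
        ep = extract_epochs(rec, _trials([500, 5000]), span=(-3000, 1000))
        assert ep.n_trials == 1
        assert ep.dropped_trials == [0]

    def test_epoch_equals_recording_slice(self):
        rng = np.random.default_rng(2)
        rec = _rec(rng.normal(0, 10, (2, 20_000)))
        ep = extract_epochs(rec, _trials([8000]), span=(-1000, 1000))
        np.testing.assert_array_equal(ep.data[0], rec.samples[:, 7000:9000])


class TestDetectArtifacts:
    def test_flat_epoch_flagged_as_variance(self):
        rng = np.random.default_rng(0)
        data = rng.normal(0, 20, (3, 1, 2000))
        data[1] = 0.0
        out = detect_artifacts(_epochs(data))
        assert out.reject_mask[1, 0]
        assert "variance" in out.reasons_for(1, 0)
        assert not out.reject_mask[0, 0] and not out.reject_mask[2, 0]

    def test_saturation_value_flagged(self):
        rng = np.random.default_rng(1)
        data = rng.normal(0, 20, (2, 1, 2000))
        data[0, 0, 137] = 6553.0
        out = detect_artifacts(_epochs(data))
        assert "saturation" in out.reasons_for(0, 0)
        assert not out.reject_mask[1, 0]

    def test_transient_slope_flagged(self):
        """400 uV one-sample step at 1 kHz is a 400 uV/ms slope; the
        oracle is max(abs(diff)) * fs / 1000."""
        rng = np.random.default_rng(2)
        data = rng.normal(0, 20, (2, 1, 2000))
        data[0, 0, 1000:] += 400.0
        oracle = np.abs(np.diff(data[0, 0])).max() * 1000.0 / 1000.0
        assert oracle > 300.0
        out = detect_artifacts(_epochs(data))
        assert "transient" in out.reasons_for(0, 0)
        assert not out.reject_mask[1, 0]

    def test_line_noise_psd_flagged(self):
        rng = np.random.default_rng(3)
        t = np.arange(4000) / 1000.0
        data = rng.normal(0, 20, (2, 1, 4000))
        data[0, 0] += 40.0 * np.sin(2 * np.pi * 60.0 * t)
        # oracle: Welch with 1 s Hann segments at 60 Hz
        f, p = signal.welch(data[0, 0], fs=1000.0, window="hann",
                            nperseg=1000, noverlap=500)
        assert p[np.argmin(np.abs(f - 60))] > 100.0
        out = detect_artifacts(_epochs(data))
        assert "line_noise" in out.reasons_for(0, 0)
        assert not out.reject_mask[1, 0]

    def test_runs_only_on_raw_epochs(self):
        data = np.random.default_rng(0).normal(0, 20, (2, 1, 1000))
        ep = _epochs(data)
        with pytest.raises(ValueError):
            detect_artifacts(downsample(ep, 500.0))
        ep2 = _epochs(data, referenced=True)
        with pytest.raises(ValueError, match="reference"):
            detect_artifacts(ep2)
        ep3 = _epochs(np.abs(data), units="envelope")
        with pytest.raises(ValueError, match="uV"):
            detect_artifacts(ep3)


class TestMadOutlier:
    def test_spike_epoch_flagged_by_peak_oracle(self):
        """Brute-force oracle: peak deviations per epoch; only the epoch
        carrying the spike exceeds median + 3 scaled MADs."""
        rng = np.random.default_rng(0)
        data = rng.standard_normal((30, 1, 500))
        data[7, 0, 250] = 50.0
        out = mad_outlier_flag(_epochs(data))
        center = np.median(data[:, 0, :])
        peaks = np.abs(data[:, 0, :] - center).max(axis=-1)
        med = np.median(peaks)
        mad = np.median(np.abs(peaks - med))
        oracle = peaks > med + 3 * 1.4826 * mad
        assert oracle[7]
        np.testing.assert_array_equal(out.reject_mask[:, 0], oracle)
        assert "mad_outlier" in out.reasons_for(7, 0)

    def test_identical_epochs_not_flagged(self):
        data = np.tile(np.sin(np.arange(500) / 20.0), (10, 1, 1))
        out = mad_outlier_flag(_epochs(data))
        assert not out.reject_mask.any()

    def test_k_infinite_flags_nothing(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((20, 2, 300))
        data[3, 0, 10] = 1e6
        out = mad_outlier_flag(_epochs(data), k=np.inf)
        assert not out.reject_mask.any()

    def test_reference_population_excludes_rejected_epochs(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((20, 1, 300))
        data[0] = 0.0  # flat, rejected before the MAD stage
        data[5, 0, 100] = 40.0
        ep = detect_artifacts(_epochs(data))
        out = mad_outlier_flag(ep)
        assert "variance" in out.reasons_for(0, 0)
        assert "mad_outlier" in out.reasons_for(5, 0)


class TestDownsample:
    def test_sample_count_halves(self):
        data = np.random.default_rng(0).normal(0, 10, (5, 2, 4000))
        out = downsample(_epochs(data), 500.0)
        assert out.data.shape[-1] == 2000
        assert out.fs == 500.0
        assert out.downsampled

    def test_dc_preserved(self):
        out = downsample(_epochs(np.full((1, 1, 4000), 3.25)), 500.0)
        np.testing.assert_allclose(out.data[0, 0, 50:-50], 3.25, rtol=1e-6)

    def test_40hz_sine_amplitude_error_below_one_percent(self):
        t = np.arange(8000) / 1000.0
        x = np.sin(2 * np.pi * 40.0 * t)[None, None, :]
        out = downsample(_epochs(x), 500.0)
        td = np.arange(out.data.shape[-1]) / 500.0
        # fit amplitude on the interior against the analytic sine
        design = np.column_stack([np.sin(2 * np.pi * 40 * td),
                                  np.cos(2 * np.pi * 40 * td)])
        interior = slice(200, -200)
        coef, *_ = np.linalg.lstsq(design[interior],
                                   out.data[0, 0, interior], rcond=None)
        amp = np.hypot(*coef)
        assert abs(amp - 1.0) < 0.01

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError):
            downsample(_epochs(np.zeros((1, 1, 100))), 300.0)
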