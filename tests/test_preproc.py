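import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from infodyn.errors import DegenerateSignalError, FormatError, ParameterError
from infodyn.preproc import (
    Recording,
    act,
    band_power,
    butter_bandpass,
    load_recording,
    reject_by_amplitude,
    reject_by_delta,
    relative_delta_power,
    resample,
    segment_epochs,
    write_recording,
    znormalize,
)

from conftest import ar1


@pytest.fixture
def recording(rng):
    return Recording(
        data={"V1": rng.normal(size=(3, 500)), "PFC": rng.normal(size=(3, 500))},
        fs=1000.0,
        condition="iso0.0",
        session_id="s1",
        ground_truth={"coupling_gain": 0.1},
    )


class TestRecordingContainer:
    def test_roundtrip_hdf5(self, recording, tmp_path):
        path = tmp_path / "rec.h5"
        write_recording(recording, path)
        back = load_recording(path)
        for site in recording.sites:
            np.testing.assert_array_equal(back.channel(site), recording.channel(site))
        assert back.fs == recording.fs
        assert back.condition == "iso0.0"
        assert back.ground_truth == {"coupling_gain": 0.1}

    def test_roundtrip_text_dialect(self, recording, tmp_path):
        path = tmp_path / "rec_dir"
        write_recording(recording, path)
        back = load_recording(path)
        for site in recording.sites:
            np.testing.assert_allclose(
                back.channel(site), recording.channel(site), rtol=0, atol=0
            )
        assert back.session_id == "s1"

    def test_missing_fs_is_format_error(self, recording, tmp_path):
        import json

        path = tmp_path / "rec_dir"
        write_recording(recording, path)
        meta = json.loads((path / "recording.json").read_text())
        del meta["fs"]
        (path / "recording.json").write_text(json.dumps(meta))
        with pytest.raises(FormatError):
            load_recording(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FormatError):
            load_recording(tmp_path / "nope.h5")

    def test_ragged_channels_rejected(self, rng):
        with pytest.raises(FormatError):
            Recording(
                data={"a": rng.normal(size=(2, 10)), "b": rng.normal(size=(3, 10))},
                fs=1000.0,
            )

    def test_epoch_count(self, recording):
        assert recording.n_epochs == 3


class TestSegmentEpochs:
    def test_two_epochs_with_remainder_dropped(self, rng):
        out = segment_epochs(rng.normal(size=10_000), fs=1000.0, epoch_len_s=4.81)
        assert out.shape == (2, 4810)

    def test_exactly_one_epoch(self, rng):
        assert segment_epochs(rng.normal(size=4810), 1000.0).shape == (1, 4810)

    def test_too_short(self, rng):
        with pytest.raises(ParameterError):
            segment_epochs(rng.normal(size=4809), 1000.0)


class TestZnormalize:
    def test_basic(self):
        out = znormalize(np.array([1.0, 2.0, 3.0]))
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std() == pytest.approx(1.0)

    def test_constant_raises(self):
        with pytest.raises(DegenerateSignalError):
            znormalize(np.full(10, 3.0))

    def test_idempotent(self, rng):
        x = rng.normal(2.0, 5.0, size=(2, 100))
        once = znormalize(x)
        np.testing.assert_allclose(znormalize(once), once, atol=1e-12)


class TestDeltaRejection:
    def test_pure_2hz_rejected(self):
        t = np.arange(4810) / 1000.0
        qc = reject_by_delta(np.sin(2 * np.pi * 2.0 * t), fs=1000.0)[0]
        assert qc.relative_delta > 0.9
        assert qc.rejected and qc.reason == "delta_power"

    def test_pure_20hz_kept(self):
        t = np.arange(4810) / 1000.0
        qc = reject_by_delta(np.sin(2 * np.pi * 20.0 * t), fs=1000.0)[0]
        assert qc.relative_delta < 0.1
        assert not qc.rejected

    def test_threshold_is_strict(self, rng):
        # "more than 30%": a fraction exactly at the threshold is kept
        epoch = ar1(rng, 0.9, 4810)
        frac = relative_delta_power(epoch, 1000.0)
        qc = reject_by_delta(epoch, 1000.0, threshold=frac)[0]
        assert not qc.rejected

    def test_qc_does_not_modify_data(self, rng):
        epochs = rng.normal(size=(3, 1000))
        before = epochs.copy()
        reject_by_delta(epochs, 1000.0)
        reject_by_amplitude(epochs)
        np.testing.assert_array_equal(epochs, before)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=15, deadline=None)
    def test_fraction_in_unit_interval(self, seed):
        epoch = np.random.default_rng(seed).normal(size=1000)
        assert 0.0 <= relative_delta_power(epoch, 1000.0) <= 1.0

    def test_amplitude_artifact_flagged(self, rng):
        epochs = rng.normal(size=(4, 1000))
        epochs[2, 500] += 100.0
        qc = reject_by_amplitude(epochs)
        assert [q.rejected for q in qc] == [False, False, True, False]
        assert qc[2].reason == "artifact"


class TestBandPower:
    def test_alpha_sine(self):
        t = np.arange(4810) / 1000.0
        x = np.sin(2 * np.pi * 10.0 * t)
        alpha = band_power(x, 1000.0, (8, 12))
        for band in [(0.5, 4), (4, 8), (12, 30), (30, 40)]:
            assert alpha > 50 * band_power(x, 1000.0, band)

    def test_white_noise_flat_spectrum(self):
        # for white noise, band power is proportional to bandwidth
        x = np.random.default_rng(8).normal(size=8000)
        p1 = band_power(x, 1000.0, (100, 150))
        p2 = band_power(x, 1000.0, (200, 300))
        assert p2 / p1 == pytest.approx(2.0, rel=0.15)

    def test_zero_signal(self):
        assert band_power(np.zeros(1000), 1000.0, (8, 12)) == 0.0

    def test_band_outside_nyquist(self, rng):
        with pytest.raises(ParameterError):
            band_power(rng.normal(size=100), 100.0, (40, 60))

    def test_band_sum_below_total(self, rng):
        x = rng.normal(size=4810)
        total = band_power(x, 1000.0, (0.5, 499.0))
        parts = sum(
            band_power(x, 1000.0, b)
            for b in [(0.5, 4), (4, 8), (8, 12), (12, 30), (30, 40)]
        )
        assert parts <= total * 1.001


class TestAct:
    def test_white_noise_lag_one(self, rng):
        assert act(rng.normal(size=4810)) == 1

    @pytest.mark.parametrize("phi", [0.5, 0.7, 0.9])
    def test_ar1_closed_form(self, phi):
        rng = np.random.default_rng(int(phi * 100))
        expected = int(np.ceil(-1.0 / np.log(phi)))
        assert abs(act(ar1(rng, phi, 4810)) - expected) <= 1

    def test_constant_raises(self):
        with pytest.raises(DegenerateSignalError):
            act(np.ones(100))

    def test_always_finds_a_lag(self, rng):
        # mean-removed biased autocorrelations sum to -1/2, so a lag below
        # 1/e always exists for any non-constant epoch
        for _ in range(10):
            lag = act(rng.normal(size=200).cumsum())
            assert lag >= 1


class TestButterBandpass:
    def test_dc_offset_removed(self):
        # 0.1 Hz high-pass edge: the 7.0 offset decays over a few seconds
        x = np.full(30_000, 7.0)
        out = butter_bandpass(x, 1000.0, 0.1, 300.0)
        assert abs(out[-1000:].mean()) < 0.05

    def test_stopband_attenuation(self):
        t = np.arange(5000) / 1000.0
        x = np.sin(2 * np.pi * 50.0 * t)
        out = butter_bandpass(x, 1000.0, 12.0, 30.0)
        assert np.abs(out[2000:]).max() < 0.05

    def test_passband_matches_frequency_response(self):
        # measured steady-state gain must match the analytic response
        fs, f0 = 1000.0, 20.0
        t = np.arange(20_000) / fs
        x = np.sin(2 * np.pi * f0 * t)
        out = butter_bandpass(x, fs, 12.0, 30.0)
        measured = np.abs(out[10_000:]).max()
        sos = sps.butter(4, [12.0, 30.0], btype="bandpass", fs=fs, output="sos")
        _, h = sps.sosfreqz(sos, worN=[f0], fs=fs)
        assert measured == pytest.approx(np.abs(h[0]), rel=0.02)

    def test_invalid_band(self, rng):
        with pytest.raises(ParameterError):
            butter_bandpass(rng.normal(size=100), 1000.0, 30.0, 12.0)


def test_resample_halves_length(rng):
    x = rng.normal(size=1000)
    assert resample(x, 1000.0, 500.0).size == 500
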