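"""Filter-chain behavior, EDF round-trip epoching and averaging."""

import numpy as np
import pandas as pd
import pytest

from ssmvep.io_edf import assemble_continuous, read_edf, write_session_edf
from ssmvep.preprocess import (FILTER_PRESETS, FilterSpec, apply_filter_chain,
                               average_trials, epoch_trials)
from ssmvep.synth_eeg import (ResponseModel, SessionLayout, TrialTensor,
                              generate_session)

FS = 1200.0


def _tone(freq, seconds=5.0, fs=FS):
    t = np.arange(int(seconds * fs)) / fs
    return np.sin(2 * np.pi * freq * t)[None, :]


class TestFilterChain:
    def test_zero_in_zero_out(self):
        out = apply_filter_chain(np.zeros((3, 6000)), "acq", fs=FS)
        np.testing.assert_array_equal(out, 0.0)

    def test_notch_kills_50hz(self):
        x = _tone(50.0)
        y = apply_filter_chain(x, "acq", fs=FS)
        assert np.sqrt(np.mean(y**2)) <= 0.1 * np.sqrt(np.mean(x**2))

    def test_passband_preserves_10hz(self):
        x = _tone(10.0)
        spec = (FilterSpec("bandpass", 8, (2.0, 100.0)),)
        y = apply_filter_chain(x, spec, fs=FS)
        # compare RMS away from filtfilt edge transients
        sl = slice(600, -600)
        assert np.sqrt(np.mean(y[:, sl]**2)) == pytest.approx(
            np.sqrt(np.mean(x[:, sl]**2)), rel=0.05)

    def test_linearity(self, rng):
        a = rng.standard_normal((2, 4800))
        b = rng.standard_normal((2, 4800))
        fa = apply_filter_chain(a, "avg_1_30", fs=FS)
        fb = apply_filter_chain(b, "avg_1_30", fs=FS)
        fab = apply_filter_chain(a + b, "avg_1_30", fs=FS)
        np.testing.assert_allclose(fab, fa + fb, atol=1e-8)

    def test_band_edge_beyond_nyquist_rejected(self):
        spec = (FilterSpec("bandpass", 4, (2.0, 700.0)),)
        with pytest.raises(ValueError):
            apply_filter_chain(np.zeros((1, 6000)), spec, fs=FS)

    def test_presets_exist(self):
        assert set(FILTER_PRESETS) == {"acq", "avg_1_30", "fft_2_40"}


@pytest.fixture(scope="module")
def written_session(tmp_path_factory):
    layout = SessionLayout(n_subjects=1, trials_per_run=2,
                           brightness_levels=("medium",))
    sess = generate_session(layout, ResponseModel(), 5, paradigms=("bimodal",))
    out = tmp_path_factory.mktemp("edf")
    edf, csv = write_session_edf(sess, layout, out)
    return layout, sess, edf, csv


class TestEpoching:
    def test_edf_round_trip_recovers_trials(self, written_session):
        layout, sess, edf, csv = written_session
        data, fs, names = read_edf(edf)
        assert fs == 1200.0
        assert names == list(layout.channels)
        events = pd.read_csv(csv)
        rt = epoch_trials(data, events, fs, layout.trial_seconds,
                          channels=layout.channels)
        assert rt.data.shape == sess.data.shape
        # identical up to the 16-bit quantization of the physical range
        quantum = 1000.0 / 65535
        assert np.abs(rt.data - sess.data).max() <= quantum
        pd.testing.assert_frame_equal(rt.labels, sess.labels,
                                      check_dtype=False)

    def test_epoch_covers_trial_window_only(self):
        fs = 100.0
        cont = np.zeros((1, 1000))
        cont[0, 300:800] = 7.0  # 5 s of signal at fs=100 starting at t=3 s
        events = pd.DataFrame({"onset_sample": [300], "label": ["x"]})
        tt = epoch_trials(cont, events, fs, trial_seconds=5.0, channels=("Oz",))
        assert tt.data.shape == (1, 1, 500)
        np.testing.assert_array_equal(tt.data[0, 0], 7.0)

    def test_incomplete_epoch_dropped_with_warning(self, caplog):
        fs = 100.0
        cont = np.zeros((1, 600))
        events = pd.DataFrame({"onset_sample": [0, 550], "label": ["a", "b"]})
        with caplog.at_level("WARNING"):
            tt = epoch_trials(cont, events, fs, trial_seconds=5.0, channels=("Oz",))
        assert tt.n_trials == 1
        assert "dropping epoch" in caplog.text

    def test_overlapping_events_rejected(self):
        events = pd.DataFrame({"onset_sample": [0, 100]})
        with pytest.raises(ValueError, match="overlap"):
            epoch_trials(np.zeros((1, 2000)), events, 100.0, trial_seconds=5.0)


class TestAveraging:
    def _tensor(self, data):
        labels = pd.DataFrame({"frequency_hz": [3.0] * len(data)})
        return TrialTensor(np.asarray(data, dtype=float), labels, FS,
                           channels=("Oz",))

    def test_single_trial_identity(self, rng):
        x = rng.standard_normal((1, 1, 100))
        np.testing.assert_array_equal(average_trials(self._tensor(x)), x[0])

    def test_opposite_trials_cancel(self, rng):
        x = rng.standard_normal((1, 100))
        avg = average_trials(self._tensor(np.stack([x, -x])))
        np.testing.assert_allclose(avg, 0.0, atol=1e-12)

    def test_noise_rms_shrinks_as_sqrt_n(self, rng):
        n = 100
        trials = rng.standard_normal((n, 1, 2000))
        avg = average_trials(self._tensor(trials))
        single_rms = np.sqrt(np.mean(trials**2))
        assert np.sqrt(np.mean(avg**2)) == pytest.approx(single_rms / 10, rel=0.2)

    def test_empty_group_rejected(self):
        tensor = self._tensor(np.zeros((0, 1, 10)))
        with pytest.raises(ValueError):
            average_trials(tensor)

    def test_grouped_averaging(self, bimodal_session):
        groups = average_trials(bimodal_session, by="frequency_hz")
        assert set(groups) == {3.0, 3.5, 4.0, 4.5}
        manual = bimodal_session.data[
            (bimodal_session.labels.frequency_hz == 3.0).to_numpy()].mean(axis=0)
        np.testing.assert_allclose(groups[3.0], manual)


class TestContinuousAssembly:
    def test_event_spacing_matches_protocol(self):
        layout = SessionLayout(n_subjects=1, trials_per_run=3,
                               brightness_levels=("medium",))
        sess = generate_session(layout, ResponseModel(), 1,
                                paradigms=("bimodal",))
        cont, events = assemble_continuous(sess, layout)
        # cue (1 s) + trial (5 s) + gray (1 s) = 7 s per trial
        step = int(7 * layout.sampling_rate_hz)
        assert np.all(np.diff(events.onset_sample) == step)
        assert cont.shape[1] == step * sess.n_trials
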