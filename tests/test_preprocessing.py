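"""Filtering, epoching, artifact handling and normalization."""

import numpy as np
import pytest
import scipy.signal

from sincdecode.data import (IMAGINATION, IMAGINE_ONSET, VISUAL,
                             VISUAL_ONSET, Event, RawRecording, TrialSet,
                             default_channel_labels)
from sincdecode.preprocessing import (EOGRemover, PreprocessConfig, bandpass,
                                      downsample, epoch_imagination,
                                      epoch_visual, preprocess_session,
                                      reference_and_zscore,
                                      reject_artifact_trials)
from sincdecode.synthetic import SyntheticConfig, generate_session


def _sine_recording(freq, rate=500.0, dur=10.0, n_channels=4, task=VISUAL):
    t = np.arange(int(dur * rate)) / rate
    data = np.tile(np.sin(2 * np.pi * freq * t), (n_channels, 1))
    return RawRecording(data=data, rate_hz=rate,
                        channel_labels=default_channel_labels(n_channels),
                        events=[], subject_id=0, task=task)


class TestBandpass:
    def test_midband_sinusoid_amplitude_preserved(self):
        rec = bandpass(_sine_recording(25.0))
        mid = rec.data[0, 1000:4000]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.10)

    def test_slow_drift_strongly_attenuated(self):
        rec = bandpass(_sine_recording(0.1))
        assert np.abs(rec.data[0]).max() < 0.10

    def test_zero_input_gives_zero_output(self):
        rec = _sine_recording(10.0)
        rec.data[:] = 0.0
        assert np.all(bandpass(rec).data == 0.0)

    def test_cutoffs_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(_sine_recording(10.0, rate=80.0), low=1.0, high=50.0)


def _event_recording(onsets_labels, kind, task, rate=500.0, dur=60.0,
                     n_channels=3):
    rng = np.random.default_rng(0)
    data = rng.normal(size=(n_channels, int(dur * rate)))
    events = [Event(s, l, kind) for s, l in onsets_labels]
    return RawRecording(data=data, rate_hz=rate,
                        channel_labels=default_channel_labels(n_channels),
                        events=events, subject_id=0, task=task)


class TestEpoching:
    def test_one_epoch_per_visual_event_with_labels_in_order(self):
        onsets = [(i * 300, i % 3) for i in range(20)]
        rec = _event_recording(onsets, VISUAL_ONSET, VISUAL)
        trials = epoch_visual(rec)
        assert len(trials) == 20
        assert trials.n_samples == 250
        np.testing.assert_array_equal(trials.labels,
                                      [l for _, l in onsets])

    def test_event_too_close_to_end_is_dropped(self):
        rate, dur = 500.0, 10.0
        onsets = [(100, 0), (int(dur * rate) - 10, 1)]
        rec = _event_recording(onsets, VISUAL_ONSET, VISUAL, rate, dur)
        trials = epoch_visual(rec)
        assert len(trials) == 1
        assert trials.labels.tolist() == [0]

    def test_full_imagination_block_yields_twenty_segments(self):
        rec = _event_recording([(100, 2)], IMAGINE_ONSET, IMAGINATION,
                               rate=500.0, dur=12.0)
        trials = epoch_imagination(rec)
        assert len(trials) == 20
        assert set(trials.labels) == {2}

    def test_short_imagination_span_yields_floor_count(self):
        # 9.7 s of signal after the cue → 19 whole 500 ms segments
        rate = 500.0
        n = int(9.7 * rate) + 50
        rec = _event_recording([(50, 1)], IMAGINE_ONSET, IMAGINATION,
                               rate=rate, dur=n / rate)
        trials = epoch_imagination(rec)
        assert len(trials) == 19

    def test_epoching_requires_matching_task(self, visual_recording):
        with pytest.raises(ValueError):
            epoch_imagination(visual_recording)


class TestArtifactRejection:
    @pytest.fixture()
    def trials(self):
        rng = np.random.default_rng(1)
        return TrialSet(epochs=rng.normal(size=(10, 3, 50)),
                        labels=np.arange(10) % 2,
                        task=np.array([VISUAL] * 10),
                        subject=np.zeros(10), rate_hz=100.0)

    def test_infinite_threshold_is_identity(self, trials):
        kept, rejected = reject_artifact_trials(trials, np.inf)
        assert len(kept) == len(trials)
        assert len(rejected) == 0

    def test_injected_spike_is_the_only_rejection(self, trials):
        base = np.ptp(trials.epochs)
        trials.epochs[4, 1, 25] += 10 * base
        kept, rejected = reject_artifact_trials(trials, 5 * base)
        assert rejected.tolist() == [4]
        assert len(kept) == 9

    def test_empty_input_passes_through(self, trials):
        empty = trials.select(np.array([], dtype=int))
        kept, rejected = reject_artifact_trials(empty, 100.0)
        assert len(kept) == 0 and len(rejected) == 0

    def test_rejecting_everything_is_an_error(self, trials):
        with pytest.raises(ValueError, match="all trials"):
            reject_artifact_trials(trials, 1e-12)


@pytest.fixture(scope="module")
def noisy_session():
    cfg = SyntheticConfig(n_subjects=1, n_classes=3,
                          visual_trials_per_class=8, n_channels=8,
                          native_rate_hz=500.0, snr_db=0.0,
                          eog_rate=20.0, seed=11)
    return generate_session(cfg, 0, VISUAL)


class TestEOGRemoval:
    def test_frontal_low_frequency_power_halved(self, noisy_session):
        rec = bandpass(noisy_session)
        cleaned = EOGRemover(n_components=8, corr_threshold=0.6,
                             seed=0).fit(rec).clean_recording(rec)

        def low_power(x):
            f, p = scipy.signal.periodogram(x, fs=rec.rate_hz)
            return p[(f > 0) & (f <= 4.0)].sum()

        before = low_power(rec.data[0]) + low_power(rec.data[1])
        after = low_power(cleaned.data[0]) + low_power(cleaned.data[1])
        assert after < 0.5 * before

    def test_clean_session_keeps_class_band_power(self):
        band = (10.0, 14.0)
        cfg = SyntheticConfig(n_subjects=1, n_classes=2,
                              visual_trials_per_class=10, n_channels=8,
                              native_rate_hz=500.0, snr_db=6.0,
                              class_bands=[band, band], eog_rate=0.0,
                              seed=13)
        rec = bandpass(generate_session(cfg, 0, VISUAL))
        remover = EOGRemover(n_components=8, corr_threshold=0.9,
                             seed=0).fit(rec)
        cleaned = remover.clean_recording(rec)
        assert remover.n_removed <= 1

        def band_power(x):
            f, p = scipy.signal.periodogram(x, fs=rec.rate_hz, axis=1)
            return p[:, (f >= band[0]) & (f <= band[1])].sum()

        assert band_power(cleaned.data) == \
            pytest.approx(band_power(rec.data), rel=0.10)

    def test_unreachable_threshold_removes_nothing(self, noisy_session):
        rec = bandpass(noisy_session)
        remover = EOGRemover(n_components=8, corr_threshold=1.0,
                             seed=0).fit(rec)
        assert remover.n_removed == 0
        np.testing.assert_allclose(remover.clean_recording(rec).data,
                                   rec.data, atol=1e-9)

    def test_missing_reference_channel_is_an_error(self, noisy_session):
        with pytest.raises(ValueError, match="not present"):
            EOGRemover().fit(noisy_session, eog_channels=("Fp1", "Nope"))


class TestDownsample:
    def test_half_second_epoch_becomes_125_samples(self):
        rec = _sine_recording(10.0, rate=2000.0, dur=4.0)
        rec.events.append(Event(1000, 0, VISUAL_ONSET))
        down = downsample(rec, 250.0)
        assert down.rate_hz == 250.0
        assert down.events[0].sample == 125
        trials = epoch_visual(down)
        assert trials.n_samples == 125

    def test_passband_sinusoid_survives(self):
        rec = _sine_recording(40.0, rate=2000.0, dur=4.0)
        down = downsample(rec, 250.0)
        mid = down.data[0, 200:800]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.10)

    def test_identity_at_native_rate(self):
        rec = _sine_recording(10.0, rate=500.0)
        down = downsample(rec, 500.0)
        np.testing.assert_array_equal(down.data, rec.data)

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError, match="integer multiple"):
            downsample(_sine_recording(10.0, rate=500.0), 300.0)


class TestReferenceAndZscore:
    def test_channel_means_zero_and_sds_one(self):
        rng = np.random.default_rng(2)
        trials = TrialSet(epochs=rng.normal(size=(5, 4, 60)),
                          labels=np.zeros(5), task=np.array([VISUAL] * 5),
                          subject=np.zeros(5), rate_hz=120.0)
        out = reference_and_zscore(trials)
        np.testing.assert_allclose(out.epochs.mean(axis=2), 0.0, atol=1e-6)
        np.testing.assert_allclose(out.epochs.std(axis=2), 1.0, atol=1e-6)

    def test_average_reference_zeroes_channel_sums_before_zscore(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 6, 40))
        referenced = x - x.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(referenced.sum(axis=1), 0.0, atol=1e-10)

    def test_constant_channel_is_an_error_naming_the_culprit(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(3, 4, 30))
        # equal to the mean of the other channels → flat after referencing
        x[2, 1, :] = x[2, [0, 2, 3], :].mean(axis=0)
        trials = TrialSet(epochs=x, labels=np.zeros(3),
                          task=np.array([VISUAL] * 3), subject=np.zeros(3),
                          rate_hz=100.0,
                          channel_labels=default_channel_labels(4))
        with pytest.raises(ValueError, match="trial 2"):
            reference_and_zscore(trials)


class TestFullPipeline:
    def test_counts_and_shape_conserved(self, visual_trials, tiny_config):
        expected = (tiny_config.n_classes
                    * tiny_config.visual_trials_per_class)
        assert len(visual_trials) == expected
        assert visual_trials.n_channels == tiny_config.n_channels
        assert visual_trials.n_samples == 125
        assert visual_trials.rate_hz == 250.0

    def test_rerun_is_bit_identical(self, visual_recording):
        cfg = PreprocessConfig(ica_components=6, seed=0)
        a, _ = preprocess_session(visual_recording, cfg)
        b, _ = preprocess_session(visual_recording, cfg)
        np.testing.assert_array_equal(a.epochs, b.epochs)

    def test_imagination_pipeline_counts(self, imagination_recording,
                                         tiny_config):
        trials, report = preprocess_session(
            imagination_recording, PreprocessConfig(ica_enabled=False))
        segments = int(tiny_config.imagine_block_s * 2)
        assert len(trials) == tiny_config.n_classes * segments \
            - report["n_rejected"]
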