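"""Raw EEG → model-ready trials.

Pipeline order: band-pass (1–50 Hz, zero-phase) → epoching → amplitude-based
trial rejection → ICA-based ocular artifact removal → downsampling to 250 Hz
→ average reference → per-channel z-scoring.  The ICA decomposition is fit
on the continuous band-passed recording (more samples, standard practice)
and applied to the surviving epochs.

Amplitude rejection is the automated surrogate for manual inspection of
movement artifacts: any trial whose peak-to-peak amplitude on any channel
exceeds a threshold (default 300 µV) is dropped and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.signal
from sklearn.decomposition import FastICA

from .data import (IMAGINATION, IMAGINE_ONSET, VISUAL, VISUAL_ONSET,
                   RawRecording, TrialSet)

logger = logging.getLogger(__name__)

__all__ = ["bandpass", "epoch_visual", "epoch_imagination",
           "reject_artifact_trials", "EOGRemover", "remove_eog_ica",
           "downsample", "downsample_trials", "reference_and_zscore",
           "PreprocessConfig", "preprocess_session"]


def bandpass(recording: RawRecording, low: float = 1.0,
             high: float = 50.0, order: int = 4) -> RawRecording:
    """Zero-phase Butterworth band-pass (forward-backward filtering)."""
    nyq = recording.rate_hz / 2.0
    if not 0.0 < low < high < nyq:
        raise ValueError(f"cutoffs ({low}, {high}) invalid for "
                         f"Nyquist {nyq} Hz")
    sos = scipy.signal.butter(order, [low, high], btype="bandpass",
                              fs=recording.rate_hz, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, recording.data, axis=1)
    return recording.copy_with(filtered.astype(recording.data.dtype))


def _epoch(recording: RawRecording, kind: str, epoch_ms: float,
           segments_per_event, max_span_s: float | None) -> TrialSet:
    seg_len = int(round(epoch_ms / 1000.0 * recording.rate_hz))
    epochs, labels = [], []
    events = [e for e in recording.events if e.kind == kind]
    n = recording.n_samples
    for i, ev in enumerate(events):
        limit = events[i + 1].sample if i + 1 < len(events) else n
        span = limit - ev.sample
        if max_span_s is not None:
            span = min(span, int(round(max_span_s * recording.rate_hz)))
        n_seg = span // seg_len
        if segments_per_event is not None:
            n_seg = min(n_seg, segments_per_event)
        if n_seg == 0:
            logger.warning("event at sample %d too close to recording end; "
                           "epoch dropped", ev.sample)
            continue
        if segments_per_event is not None and n_seg < segments_per_event:
            logger.warning("event at sample %d: only %d of %d segments fit",
                           ev.sample, n_seg, segments_per_event)
        for s in range(n_seg):
            start = ev.sample + s * seg_len
            epochs.append(recording.data[:, start:start + seg_len])
            labels.append(ev.label)
    n_trials = len(epochs)
    shape = (n_trials, recording.n_channels, seg_len)
    arr = np.stack(epochs) if n_trials else np.empty(shape)
    return TrialSet(
        epochs=arr,
        labels=np.array(labels, dtype=np.int64),
        task=np.array([recording.task] * n_trials),
        subject=np.full(n_trials, recording.subject_id, dtype=np.int64),
        rate_hz=recording.rate_hz,
        channel_labels=list(recording.channel_labels),
    )


def epoch_visual(recording: RawRecording,
                 epoch_ms: float = 500.0) -> TrialSet:
    """One epoch per stimulus event, spanning [onset, onset + 500 ms)."""
    if recording.task != VISUAL:
        raise ValueError(f"expected a visual recording, got {recording.task}")
    return _epoch(recording, VISUAL_ONSET, epoch_ms,
                  segments_per_event=1, max_span_s=None)


def epoch_imagination(recording: RawRecording, epoch_ms: float = 500.0,
                      block_s: float = 10.0) -> TrialSet:
    """Split each imagination period into non-overlapping 500 ms segments.

    A full 10 s period yields 20 segments, all inheriting the cue's class
    label; shorter spans yield as many whole segments as fit (logged).
    """
    if recording.task != IMAGINATION:
        raise ValueError(f"expected an imagination recording, "
                         f"got {recording.task}")
    per_event = int(block_s * 1000.0 // epoch_ms)
    return _epoch(recording, IMAGINE_ONSET, epoch_ms,
                  segments_per_event=per_event, max_span_s=block_s)


def reject_artifact_trials(trials: TrialSet, peak_to_peak_uv: float = 300.0
                           ) -> tuple[TrialSet, np.ndarray]:
    """Drop trials whose peak-to-peak amplitude exceeds the threshold.

    Returns the surviving trials and the rejected trial indices.
    """
    if peak_to_peak_uv <= 0:
        raise ValueError("threshold must be positive")
    if len(trials) == 0:
        return trials, np.array([], dtype=np.int64)
    ptp = trials.epochs.max(axis=2) - trials.epochs.min(axis=2)
    bad = np.flatnonzero(ptp.max(axis=1) > peak_to_peak_uv)
    if len(bad) == len(trials):
        raise ValueError("all trials exceeded the rejection threshold")
    if len(bad):
        logger.info("rejected %d trials (indices %s)", len(bad), bad.tolist())
    keep = np.setdiff1d(np.arange(len(trials)), bad)
    return trials.select(keep), bad


class EOGRemover:
    """ICA-based ocular artifact removal.

    Fit on a continuous recording; independent components whose absolute
    Pearson correlation with either frontal reference channel (Fp1/Fp2 by
    default) exceeds ``corr_threshold`` are subtracted on reconstruction.
    The fitted removal is a linear map, so it applies equally to the
    continuous data and to epochs.
    """

    def __init__(self, n_components: int | None = None,
                 corr_threshold: float = 0.6, seed: int = 0):
        if not 0.0 < corr_threshold <= 1.0:
            raise ValueError("corr_threshold must be in (0, 1]")
        self.n_components = n_components
        self.corr_threshold = corr_threshold
        self.seed = seed
        self.removal_matrix: np.ndarray | None = None
        self.mean_: np.ndarray | None = None
        self.n_removed: int = 0

    def fit(self, recording: RawRecording,
            eog_channels: tuple[str, str] = ("Fp1", "Fp2")) -> "EOGRemover":
        for ch in eog_channels:
            if ch not in recording.channel_labels:
                raise ValueError(f"EOG reference channel {ch!r} not present")
        X = recording.data.astype(np.float64).T  # samples × channels
        k = self.n_components or min(recording.n_channels, 20)
        ica = FastICA(n_components=k, random_state=self.seed,
                      whiten="unit-variance", max_iter=500, tol=1e-3)
        try:
            S = ica.fit_transform(X)  # samples × k
        except Exception as exc:  # rank-deficient or non-convergent input
            raise RuntimeError(f"ICA decomposition failed: {exc}") from exc
        refs = np.stack([
            recording.data[recording.channel_labels.index(ch)]
            for ch in eog_channels])
        corr = np.corrcoef(np.vstack([S.T, refs]))[:k, k:]
        bad = np.flatnonzero(np.abs(corr).max(axis=1) > self.corr_threshold)
        self.n_removed = len(bad)
        logger.info("removing %d of %d ICA components", len(bad), k)
        W = ica.components_          # k × channels (applied after centering)
        A = ica.mixing_              # channels × k
        self.mean_ = ica.mean_
        if len(bad):
            self.removal_matrix = A[:, bad] @ W[bad, :]
        else:
            self.removal_matrix = np.zeros(
                (recording.n_channels, recording.n_channels))
        return self

    def clean_array(self, x: np.ndarray) -> np.ndarray:
        """Remove the flagged components from (…, channels, samples) data."""
        if self.removal_matrix is None:
            raise RuntimeError("fit the remover first")
        centered = x - self.mean_[..., :, None]
        return x - np.einsum("cd,...dt->...ct", self.removal_matrix, centered)

    def clean_recording(self, recording: RawRecording) -> RawRecording:
        return recording.copy_with(
            self.clean_array(recording.data.astype(np.float64)))

    def clean_trials(self, trials: TrialSet) -> TrialSet:
        out = trials.select(np.arange(len(trials)))
        out.epochs = self.clean_array(trials.epochs)
        return out


def remove_eog_ica(recording: RawRecording,
                   eog_channels: tuple[str, str] = ("Fp1", "Fp2"),
                   corr_threshold: float = 0.6,
                   n_components: int | None = None,
                   seed: int = 0) -> RawRecording:
    """One-shot continuous cleaning (fit + reconstruct)."""
    remover = EOGRemover(n_components=n_components,
                         corr_threshold=corr_threshold, seed=seed)
    remover.fit(recording, eog_channels)
    return remover.clean_recording(recording)


def _decimate(data: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return np.array(data, dtype=np.float64)
    return scipy.signal.decimate(data.astype(np.float64), factor,
                                 axis=-1, zero_phase=True)


def downsample(recording: RawRecording,
               target_hz: float = 250.0) -> RawRecording:
    """Anti-alias filter and decimate to ``target_hz`` (integer ratio)."""
    ratio = recording.rate_hz / target_hz
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(f"rate {recording.rate_hz} is not an integer "
                         f"multiple of {target_hz}")
    data = _decimate(recording.data, factor)
    from .data import Event
    events = [Event(e.sample // factor, e.label, e.kind)
              for e in recording.events]
    return recording.copy_with(data, rate_hz=target_hz, events=events)


def downsample_trials(trials: TrialSet, target_hz: float = 250.0) -> TrialSet:
    ratio = trials.rate_hz / target_hz
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(f"rate {trials.rate_hz} is not an integer "
                         f"multiple of {target_hz}")
    out = trials.select(np.arange(len(trials)))
    out.epochs = _decimate(trials.epochs, factor)
    out.rate_hz = target_hz
    return out


def reference_and_zscore(trials: TrialSet) -> TrialSet:
    """Average-reference each time point, then z-score each channel.

    The cross-channel mean is removed at every sample (average reference);
    each channel is then standardized over time within the trial.  A
    zero-variance channel is a hard error naming the trial and channel.
    """
    x = trials.epochs - trials.epochs.mean(axis=1, keepdims=True)
    sd = x.std(axis=2, keepdims=True)
    # degenerate = variance at (or within float residue of) zero
    scale = np.sqrt((x ** 2).mean(axis=(1, 2), keepdims=True))
    zero = np.argwhere(sd[:, :, 0] <= 1e-10 * scale[:, :, 0])
    if len(zero):
        t, c = zero[0]
        name = (trials.channel_labels[c] if trials.channel_labels
                else str(c))
        raise ValueError(f"zero-variance channel {name} in trial {t}")
    out = trials.select(np.arange(len(trials)))
    out.epochs = (x - x.mean(axis=2, keepdims=True)) / sd
    return out


@dataclass
class PreprocessConfig:
    band_low_hz: float = 1.0
    band_high_hz: float = 50.0
    epoch_ms: float = 500.0
    imagine_block_s: float = 10.0
    reject_ptp_uv: float = 300.0
    ica_enabled: bool = True
    ica_components: int | None = None
    ica_corr_threshold: float = 0.6
    target_rate_hz: float = 250.0
    seed: int = 0


def preprocess_session(recording: RawRecording,
                       config: PreprocessConfig = PreprocessConfig()
                       ) -> tuple[TrialSet, dict]:
    """Full pipeline for one recording; returns trials and a report."""
    rec = bandpass(recording, config.band_low_hz, config.band_high_hz)
    remover = None
    if config.ica_enabled:
        remover = EOGRemover(n_components=config.ica_components,
                             corr_threshold=config.ica_corr_threshold,
                             seed=config.seed).fit(rec)
    if rec.task == VISUAL:
        trials = epoch_visual(rec, config.epoch_ms)
    else:
        trials = epoch_imagination(rec, config.epoch_ms,
                                   config.imagine_block_s)
    n_epoched = len(trials)
    trials, rejected = reject_artifact_trials(trials, config.reject_ptp_uv)
    if remover is not None:
        trials = remover.clean_trials(trials)
    trials = downsample_trials(trials, config.target_rate_hz)
    trials = reference_and_zscore(trials)
    report = {
        "task": recording.task,
        "subject_id": recording.subject_id,
        "n_events": len(recording.events),
        "n_epoched": n_epoched,
        "n_rejected": int(len(rejected)),
        "rejected_indices": rejected.tolist(),
        "n_ica_components_removed": remover.n_removed if remover else 0,
        "n_trials": len(trials),
        "rate_hz": trials.rate_hz,
        "n_samples": trials.n_samples,
    }
    return trials, report
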