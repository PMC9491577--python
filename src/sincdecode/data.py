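"""Core data containers and the HDF5 trial store.

Two containers travel through the pipeline: :class:`RawRecording`, a
continuous multichannel EEG session with stimulus events, and
:class:`TrialSet`, the epoched (trials × channels × samples) tensor with
per-trial class labels, task tags and subject ids.  Both round-trip through
HDF5; EDF recordings are imported through MNE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

VISUAL = "visual"
IMAGINATION = "imagination"
TASKS = (VISUAL, IMAGINATION)

VISUAL_ONSET = "visual_onset"
IMAGINE_ONSET = "imagine_onset"

# Anterior-to-posterior ordering of the 10-10 names we use for the first
# electrodes; everything beyond gets a generic E## label.  Only Fp1/Fp2 are
# load-bearing (EOG proxies); the rest make topography exports readable.
_TEN_TEN = [
    "Fp1", "Fp2", "Fpz", "AF3", "AF4", "AF7", "AF8", "AFz",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2",
]


def default_channel_labels(n_channels: int) -> list[str]:
    """Channel names: 10-10 labels first (front to back), then E61, E62, …"""
    labels = list(_TEN_TEN[:n_channels])
    labels += [f"E{i + 1}" for i in range(len(labels), n_channels)]
    return labels


@dataclass
class Event:
    sample: int
    label: int
    kind: str


@dataclass
class RawRecording:
    """Continuous EEG: (channels × samples) in µV plus stimulus events."""

    data: np.ndarray
    rate_hz: float
    channel_labels: list[str]
    events: list[Event]
    subject_id: int
    task: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be channels × samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.data.shape[0]} channels")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")
        samples = [e.sample for e in self.events]
        if any(b <= a for a, b in zip(samples, samples[1:])):
            raise ValueError("event samples must be strictly increasing")
        if samples and (samples[0] < 0 or samples[-1] >= self.data.shape[1]):
            raise ValueError("event sample index outside recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def copy_with(self, data: np.ndarray, rate_hz: float | None = None,
                  events: list[Event] | None = None) -> "RawRecording":
        return RawRecording(
            data=data,
            rate_hz=self.rate_hz if rate_hz is None else rate_hz,
            channel_labels=list(self.channel_labels),
            events=list(self.events) if events is None else events,
            subject_id=self.subject_id,
            task=self.task,
        )

    # -- persistence ----------------------------------------------------------

    def save_h5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data.astype(np.float32))
            ev = np.array([(e.sample, e.label, e.kind == IMAGINE_ONSET)
                           for e in self.events], dtype=np.int64).reshape(-1, 3)
            f.create_dataset("events", data=ev)
            f.attrs["rate_hz"] = self.rate_hz
            f.attrs["subject_id"] = self.subject_id
            f.attrs["task"] = self.task
            f.attrs["channel_labels"] = np.array(self.channel_labels, dtype="S")

    @classmethod
    def load_h5(cls, path: str | Path) -> "RawRecording":
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            ev = f["events"][()]
            events = [Event(int(s), int(l),
                            IMAGINE_ONSET if k else VISUAL_ONSET)
                      for s, l, k in ev]
            return cls(
                data=data,
                rate_hz=float(f.attrs["rate_hz"]),
                channel_labels=[s.decode() for s in f.attrs["channel_labels"]],
                events=events,
                subject_id=int(f.attrs["subject_id"]),
                task=str(f.attrs["task"]),
            )


def read_edf(path: str | Path, task: str, subject_id: int = 0,
             event_kind: str = VISUAL_ONSET) -> RawRecording:
    """Import an EDF recording (annotations become events) via MNE."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns volts
    events = []
    for onset, _dur, desc in zip(raw.annotations.onset,
                                 raw.annotations.duration,
                                 raw.annotations.description):
        try:
            label = int(str(desc))
        except ValueError:
            continue
        events.append(Event(int(round(onset * raw.info["sfreq"])), label,
                            event_kind))
    return RawRecording(data=data, rate_hz=float(raw.info["sfreq"]),
                        channel_labels=list(raw.ch_names), events=events,
                        subject_id=subject_id, task=task)


@dataclass
class TrialSet:
    """Epoched EEG: (trials × channels × samples) with per-trial metadata."""

    epochs: np.ndarray
    labels: np.ndarray
    task: np.ndarray
    subject: np.ndarray
    rate_hz: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs)  # dtype preserved; model code
        # upcasts to float64 where the numerics need it
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.task = np.asarray(self.task)
        self.subject = np.asarray(self.subject, dtype=np.int64)
        n = self.epochs.shape[0]
        for name, arr in (("labels", self.labels), ("task", self.task),
                          ("subject", self.subject)):
            if len(arr) != n:
                raise ValueError(f"{name} has {len(arr)} entries for {n} trials")

    def __len__(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    def select(self, idx) -> "TrialSet":
        idx = np.asarray(idx)
        return TrialSet(self.epochs[idx], self.labels[idx], self.task[idx],
                        self.subject[idx], self.rate_hz,
                        list(self.channel_labels))

    def select_task(self, task: str) -> "TrialSet":
        return self.select(np.flatnonzero(self.task == task))

    @staticmethod
    def concatenate(sets: list["TrialSet"]) -> "TrialSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        rates = {s.rate_hz for s in sets}
        if len(rates) != 1:
            raise ValueError(f"mixed sampling rates: {rates}")
        return TrialSet(
            np.concatenate([s.epochs for s in sets]),
            np.concatenate([s.labels for s in sets]),
            np.concatenate([s.task for s in sets]),
            np.concatenate([s.subject for s in sets]),
            sets[0].rate_hz,
            list(sets[0].channel_labels),
        )

    def save_h5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("epochs", data=self.epochs.astype(np.float32))
            f.create_dataset("labels", data=self.labels)
            f.create_dataset("task", data=self.task.astype("S"))
            f.create_dataset("subject", data=self.subject)
            f.attrs["rate_hz"] = self.rate_hz
            f.attrs["channel_labels"] = np.array(self.channel_labels, dtype="S")

    @classmethod
    def load_h5(cls, path: str | Path) -> "TrialSet":
        with h5py.File(path, "r") as f:
            return cls(
                epochs=f["epochs"][()],
                labels=f["labels"][()],
                task=np.array([s.decode() for s in f["task"][()]]),
                subject=f["subject"][()],
                rate_hz=float(f.attrs["rate_hz"]),
                channel_labels=[s.decode()
                                for s in f.attrs["channel_labels"]],
            )
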