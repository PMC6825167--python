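"""Epoched multichannel EEG container and its on-disk form.

One :class:`EpochArray` holds a single subject's epoched data as
channels x time x trials, with the time axis in milliseconds relative to
stimulus (CS) onset.  Serialization is a ``.npy`` array per subject plus
a JSON sidecar carrying the axes and labels; the round trip is lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

EPOCH_START_MS = -600.0
EPOCH_END_MS = 2000.0  # exclusive


def epoch_times(srate: float) -> np.ndarray:
    """Epoch time axis in ms: −600 … 2000 (exclusive), step 1000/srate."""
    step = 1000.0 / srate
    return np.arange(EPOCH_START_MS, EPOCH_END_MS - 0.5 * step, step)


@dataclass
class EpochArray:
    """Single-subject epoched EEG.

    Attributes
    ----------
    data
        ``(n_channels, n_times, n_trials)`` signal in nominal µV.
    srate
        Sampling rate in Hz.
    times
        Time axis in ms relative to CS onset.
    ch_names
        Channel labels, aligned with the first axis.
    trial_labels
        CS type per trial (e.g. ``"CS+E"``), aligned with the last axis.
    subject_id
        Identifier carried through the pipeline.
    """

    data: np.ndarray = field(repr=False)
    srate: float
    times: np.ndarray = field(repr=False)
    ch_names: tuple[str, ...]
    trial_labels: tuple[str, ...]
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.ch_names = tuple(self.ch_names)
        self.trial_labels = tuple(self.trial_labels)
        n_ch, n_t, n_tr = self.data.shape
        if len(self.ch_names) != n_ch:
            raise ValueError("ch_names length does not match data")
        if len(self.times) != n_t:
            raise ValueError("times length does not match data")
        if len(self.trial_labels) != n_tr:
            raise ValueError("trial_labels length does not match trial count")
        step = 1000.0 / self.srate
        if not np.allclose(np.diff(self.times), step, atol=1e-9):
            raise ValueError("times must be uniformly sampled at 1000/srate ms")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def time_indices(self, window_ms: tuple[float, float]) -> np.ndarray:
        """Indices of samples inside ``window_ms`` (inclusive endpoints)."""
        lo, hi = window_ms
        idx = np.where((self.times >= lo - 1e-9) & (self.times <= hi + 1e-9))[0]
        if idx.size == 0:
            raise ValueError(f"window {window_ms} ms selects no samples")
        return idx

    def pick(self, channels) -> "EpochArray":
        """Subset of channels, order as given."""
        missing = [ch for ch in channels if ch not in self.ch_names]
        if missing:
            raise ValueError(f"channels not in epochs: {missing}")
        idx = [self.ch_names.index(ch) for ch in channels]
        return EpochArray(
            self.data[idx], self.srate, self.times, tuple(channels),
            self.trial_labels, self.subject_id,
        )

    def select_trials(self, mask) -> "EpochArray":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.where(mask)[0]
        else:
            idx = mask
        labels = tuple(self.trial_labels[i] for i in idx)
        return EpochArray(
            self.data[:, :, idx], self.srate, self.times, self.ch_names,
            labels, self.subject_id,
        )

    def save(self, directory) -> None:
        """Write ``<subject_id>.npy`` plus ``<subject_id>.json`` sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / f"{self.subject_id}.npy", self.data)
        sidecar = {
            "subject_id": self.subject_id,
            "srate": self.srate,
            "times_ms": self.times.tolist(),
            "ch_names": list(self.ch_names),
            "trial_labels": list(self.trial_labels),
        }
        with open(directory / f"{self.subject_id}.json", "w") as fh:
            json.dump(sidecar, fh, sort_keys=True)


def load_epochs(directory, subject_id: str) -> EpochArray:
    directory = Path(directory)
    npy = directory / f"{subject_id}.npy"
    sidecar_path = directory / f"{subject_id}.json"
    if not npy.exists() or not sidecar_path.exists():
        raise FileNotFoundError(f"no epochs for {subject_id!r} in {directory}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    return EpochArray(
        np.load(npy), meta["srate"], np.array(meta["times_ms"]),
        tuple(meta["ch_names"]), tuple(meta["trial_labels"]),
        meta["subject_id"],
    )


def load_cohort(directory) -> list[EpochArray]:
    """Load every subject (``*.npy`` + sidecar) found in a directory."""
    directory = Path(directory)
    subjects = sorted(p.stem for p in directory.glob("*.npy"))
    if not subjects:
        raise FileNotFoundError(f"no epoch files found in {directory}")
    return [load_epochs(directory, s) for s in subjects]
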