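"""Recordings on disk: EDF signals + CSV seizure-onset annotations.

A :class:`Recording` holds a continuous multichannel scalp EEG in microvolts
together with seizure onset times in seconds from recording start.  Signals
travel as EDF (European Data Format); annotations as a small CSV with columns
``onset_s`` and optional free-text ``classification``.

Reading goes through :mod:`mne`.  Writing uses a minimal EDF encoder (16-bit,
one-second data records) sufficient for round-tripping synthetic recordings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import ELECTRODES, is_standard_label, canonical_label

#: Minimum spacing between consecutive seizures (hours) for a recording to be
#: usable for training/testing — mirrors the patient-selection criterion.
MIN_SEIZURE_SPACING_H = 4.5


class InvalidRecordingError(ValueError):
    pass


class InsufficientSeizuresError(ValueError):
    pass


@dataclass
class Recording:
    """Continuous multichannel EEG with seizure-onset annotations.

    Parameters
    ----------
    channels
        Ordered 10-20 electrode labels, one per signal row.
    fs
        Sampling rate in Hz.
    samples
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    onsets
        Seizure onset times in seconds from recording start, strictly
        increasing.
    """

    channels: list[str]
    fs: float
    samples: np.ndarray
    onsets: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channels):
            raise InvalidRecordingError(
                "samples must be (n_channels, n_samples) matching channels"
            )
        if self.fs <= 0:
            raise InvalidRecordingError("fs must be positive")
        if self.onsets.size and np.any(np.diff(self.onsets) <= 0):
            raise InvalidRecordingError("onsets must be strictly increasing")
        if self.onsets.size and (
            self.onsets[0] < 0 or self.onsets[-1] > self.duration
        ):
            raise InvalidRecordingError("onsets must lie inside the recording")

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.shape[1] / self.fs


# ---------------------------------------------------------------------------
# annotations

def read_annotations(path) -> np.ndarray:
    """Read onset times (seconds) from an annotation CSV, sorted check."""
    df = pd.read_csv(path)
    if "onset_s" not in df.columns:
        raise InvalidRecordingError("annotation CSV needs an onset_s column")
    onsets = df["onset_s"].to_numpy(dtype=float)
    if onsets.size and np.any(np.diff(onsets) <= 0):
        raise InvalidRecordingError("annotation onsets are not sorted")
    return onsets


def write_annotations(onsets, path, classification=None) -> None:
    onsets = np.asarray(onsets, dtype=float)
    df = pd.DataFrame({"onset_s": onsets})
    df["classification"] = classification if classification is not None else ""
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# EDF

def write_recording(rec: Recording, edf_path, annotation_path=None) -> None:
    """Write a Recording as 16-bit EDF (1-s data records) + annotation CSV.

    The physical range is fixed at +/-2000 uV (digital +/-32767), a
    quantisation step of ~0.06 uV.  The recording is truncated to a whole
    number of one-second records.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise InvalidRecordingError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = len(rec.channels)
    n_rec = rec.samples.shape[1] // fs
    phys_min, phys_max = -2000.0, 2000.0
    dig_min, dig_max = -32768, 32767

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    header = b"".join([
        pad("0", 8),
        pad("X X X X", 80),
        pad("Startdate X X X X", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 * (n_ch + 1)), 8),
        pad("", 44),
        pad(str(n_rec), 8),
        pad("1", 8),
        pad(str(n_ch), 4),
    ])
    labels = [f"EEG {c}" for c in rec.channels]
    sig = b"".join([
        b"".join(pad(lb, 16) for lb in labels),
        b"".join(pad("", 80) for _ in labels),
        b"".join(pad("uV", 8) for _ in labels),
        b"".join(pad(f"{phys_min:g}", 8) for _ in labels),
        b"".join(pad(f"{phys_max:g}", 8) for _ in labels),
        b"".join(pad(str(dig_min), 8) for _ in labels),
        b"".join(pad(str(dig_max), 8) for _ in labels),
        b"".join(pad("", 80) for _ in labels),
        b"".join(pad(str(fs), 8) for _ in labels),
        b"".join(pad("", 32) for _ in labels),
    ])

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    x = np.clip(rec.samples[:, : n_rec * fs], phys_min, phys_max)
    dig = np.round((x - phys_min) * scale + dig_min).astype("<i2")
    # records are interleaved: all of channel 1's samples for record r, then
    # channel 2's, ...
    blocks = dig.reshape(n_ch, n_rec, fs).transpose(1, 0, 2)
    with open(edf_path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        fh.write(blocks.tobytes())

    if annotation_path is not None:
        write_annotations(rec.onsets, annotation_path)


def read_recording(edf_path, annotation_path=None) -> Recording:
    """Read an EDF recording (+ optional annotation CSV) into a Recording.

    Channels whose labels are not in the 19-electrode 10-20 set are dropped
    with a warning.  Onsets beyond the recording duration raise an error.
    """
    import mne

    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    keep, labels = [], []
    for i, name in enumerate(raw.ch_names):
        lbl = name.removeprefix("EEG ").strip()
        if is_standard_label(lbl):
            keep.append(i)
            labels.append(canonical_label(lbl))
        else:
            warnings.warn(f"dropping non-10-20 channel {name!r}")
    if not keep:
        raise InvalidRecordingError("no 10-20 channels found in EDF")
    data = raw.get_data(picks=keep) * 1e6  # mne returns volts
    onsets = (
        read_annotations(annotation_path)
        if annotation_path is not None
        else np.empty(0)
    )
    duration = data.shape[1] / raw.info["sfreq"]
    if onsets.size and onsets[-1] > duration:
        raise InvalidRecordingError(
            f"onset {onsets[-1]} s beyond recording duration {duration} s"
        )
    return Recording(
        channels=labels,
        fs=float(raw.info["sfreq"]),
        samples=data.astype(np.float32),
        onsets=onsets,
    )


# ---------------------------------------------------------------------------
# training-segment selection

def select_training_segments(
    recording: Recording, n_train_seizures: int = 3, hours_before: float = 4.0
):
    """Pick the training segments: the last ``hours_before`` hours before each
    of the first ``n_train_seizures`` chronological seizures.

    Returns a list of ``(start_s, end_s, onset_s)`` tuples with
    ``end_s == onset_s``; the remaining data (everything, no segments removed)
    is left for testing.  Requires at least one extra seizure for testing.
    """
    onsets = recording.onsets
    if onsets.size < n_train_seizures + 1:
        raise InsufficientSeizuresError(
            f"need >= {n_train_seizures + 1} seizures, got {onsets.size}"
        )
    segments = []
    for onset in onsets[:n_train_seizures]:
        start = onset - hours_before * 3600.0
        if start < 0:
            warnings.warn(
                f"segment before onset at {onset} s truncated to recording start"
            )
            start = 0.0
        segments.append((start, float(onset), float(onset)))
    return segments
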