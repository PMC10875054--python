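"""Readers and writers for EEG recordings, hypnograms, and event-label files.

The shared data model lives here: :class:`EEGRecording` (channels x samples,
microvolts), :class:`Hypnogram` (30-s epoch stage codes), and
:class:`LabeledEvent` (a half-open sample interval on one channel with an
SO / non-SO / unlabeled tag).

Two recording dialects are supported: a FieldTrip-style preprocessed ``.mat``
container (``trial`` matrix, ``label`` cell array, ``fsample`` scalar) and a
plain HDF5 array-plus-attributes layout used for fixtures and synthetic data.
Sample indexing is 0-based and intervals are half-open ``[start, end)``, so a
duration is always ``(end - start) / sampling_rate``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import h5py
import numpy as np
import pandas as pd
import scipy.io as sio

from .exceptions import FormatError, ValidationError

#: Closed set of hypnogram stage codes.
STAGE_CODES = ("Wa", "N1", "N2", "N3", "N4", "REM", "artifact")

#: Admissible event labels.
EVENT_LABELS = ("SO", "nonSO", "unlabeled")


@dataclass
class EEGRecording:
    """Multichannel EEG time series in microvolts.

    Parameters
    ----------
    channel_names
        One name per channel, unique.
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    sampling_rate
        Sampling rate in Hz, strictly positive.
    reference_label
        Optional recording reference (e.g. ``"nose"``); informational only.
    """

    channel_names: list[str]
    data: np.ndarray
    sampling_rate: float
    reference_label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError(
                f"data must be 2-D (channels x samples), got shape {self.data.shape}"
            )
        if len(self.channel_names) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if not np.isfinite(self.sampling_rate) or self.sampling_rate <= 0:
            raise ValidationError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        """Return the sample vector of a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None
        return self.data[idx]


@dataclass
class Hypnogram:
    """Sequence of sleep-stage codes on fixed-length epochs."""

    epoch_stages: list[str]
    epoch_length_s: float = 30.0

    def __post_init__(self) -> None:
        if self.epoch_length_s <= 0:
            raise ValidationError("epoch_length_s must be > 0")
        for i, code in enumerate(self.epoch_stages):
            if code not in STAGE_CODES:
                raise ValidationError(f"unknown stage code {code!r} at epoch {i}")

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_stages)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_length_s

    def stage_at_sample(self, sample: int, fs: float) -> str:
        """Stage code of the epoch containing ``sample`` at rate ``fs``."""
        epoch = int(sample / (self.epoch_length_s * fs))
        if not 0 <= epoch < self.n_epochs:
            raise ValidationError(
                f"sample {sample} falls outside the hypnogram span "
                f"({self.n_epochs} epochs of {self.epoch_length_s} s)"
            )
        return self.epoch_stages[epoch]


@dataclass
class LabeledEvent:
    """A labeled event: half-open sample interval on one channel."""

    channel: str
    start_sample: int
    end_sample: int
    label: str = "unlabeled"
    rater_id: str | None = None

    def __post_init__(self) -> None:
        self.start_sample = int(self.start_sample)
        self.end_sample = int(self.end_sample)
        if self.start_sample < 0:
            raise ValidationError(f"start_sample must be >= 0, got {self.start_sample}")
        if self.end_sample <= self.start_sample:
            raise ValidationError(
                f"end_sample ({self.end_sample}) must exceed start_sample "
                f"({self.start_sample})"
            )
        if self.label not in EVENT_LABELS:
            raise ValidationError(f"unknown event label {self.label!r}")

    def duration_s(self, fs: float) -> float:
        return (self.end_sample - self.start_sample) / fs

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

RecordingFormat = Literal["fieldtrip_mat", "array_hdf5"]


def write_recording(
    recording: EEGRecording, path: str | Path, format_hint: RecordingFormat = "array_hdf5"
) -> None:
    """Write a recording in one of the supported dialects."""
    path = Path(path)
    if format_hint == "fieldtrip_mat":
        payload = {
            "data": {
                "trial": recording.data,
                "label": np.array(recording.channel_names, dtype=object).reshape(-1, 1),
                "fsample": float(recording.sampling_rate),
                "time": np.arange(recording.n_samples) / recording.sampling_rate,
            }
        }
        sio.savemat(path, payload)
    elif format_hint == "array_hdf5":
        with h5py.File(path, "w") as f:
            dset = f.create_dataset("data", data=recording.data)
            dset.attrs["unit"] = "uV"
            f.attrs["sampling_rate"] = float(recording.sampling_rate)
            f.attrs["channel_names"] = [str(c) for c in recording.channel_names]
            if recording.reference_label is not None:
                f.attrs["reference"] = recording.reference_label
    else:
        raise FormatError(f"unknown recording format {format_hint!r}")


def _unwrap_mat(value):
    """Collapse the nested object arrays scipy.io.loadmat produces."""
    while isinstance(value, np.ndarray) and value.dtype == object and value.size == 1:
        value = value.reshape(-1)[0]
    return value


def _read_fieldtrip_mat(path: Path) -> EEGRecording:
    try:
        mat = sio.loadmat(path, squeeze_me=False, struct_as_record=True)
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise FormatError(f"unreadable .mat file {path}: {exc}") from exc
    structs = {k: v for k, v in mat.items() if not k.startswith("__")}
    if not structs:
        raise FormatError(f"{path}: no data struct found")
    struct = _unwrap_mat(next(iter(structs.values())))
    if not isinstance(struct, np.void) and not (
        isinstance(struct, np.ndarray) and struct.dtype.names
    ):
        raise FormatError(f"{path}: top-level variable is not a struct")
    names = struct.dtype.names or ()
    if "fsample" not in names:
        raise FormatError(f"{path}: missing sampling rate field 'fsample'")
    if "trial" not in names:
        raise FormatError(f"{path}: missing field 'trial'")
    fsample = float(np.asarray(_unwrap_mat(struct["fsample"])).reshape(-1)[0])
    trial = _unwrap_mat(struct["trial"])
    if isinstance(trial, np.ndarray) and trial.dtype == object:
        # cell array of trials; single continuous trial expected
        trials = [np.asarray(_unwrap_mat(t), dtype=np.float64) for t in trial.reshape(-1)]
        if len(trials) != 1:
            trial = np.concatenate(trials, axis=1)
        else:
            trial = trials[0]
    trial = np.asarray(trial, dtype=np.float64)
    if trial.ndim != 2:
        raise FormatError(f"{path}: field 'trial' is not a channels x samples matrix")
    if "label" in names:
        label_arr = _unwrap_mat(struct["label"])
        labels = [
            str(np.asarray(_unwrap_mat(v)).reshape(-1)[0]).strip()
            for v in np.asarray(label_arr).reshape(-1)
        ]
    else:
        labels = [f"ch{i}" for i in range(trial.shape[0])]
    if len(labels) != trial.shape[0]:
        raise FormatError(
            f"{path}: {len(labels)} labels for {trial.shape[0]} channel rows"
        )
    return EEGRecording(channel_names=labels, data=trial, sampling_rate=fsample)


def _read_array_hdf5(path: Path) -> EEGRecording:
    try:
        with h5py.File(path, "r") as f:
            if "data" not in f:
                raise FormatError(f"{path}: missing 'data' dataset")
            if "sampling_rate" not in f.attrs:
                raise FormatError(f"{path}: missing 'sampling_rate' attribute")
            data = np.asarray(f["data"], dtype=np.float64)
            fs = float(f.attrs["sampling_rate"])
            if "channel_names" in f.attrs:
                names = [str(c) for c in f.attrs["channel_names"]]
            else:
                names = [f"ch{i}" for i in range(data.shape[0])]
            ref = str(f.attrs["reference"]) if "reference" in f.attrs else None
    except OSError as exc:
        raise FormatError(f"unreadable HDF5 file {path}: {exc}") from exc
    return EEGRecording(channel_names=names, data=data, sampling_rate=fs,
                        reference_label=ref)


def read_recording(
    path: str | Path, format_hint: RecordingFormat | None = None
) -> EEGRecording:
    """Read a recording, inferring the dialect from the suffix if not given.

    Raises
    ------
    FormatError
        If the file cannot be parsed, names the offending field.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format_hint is None:
        format_hint = "fieldtrip_mat" if path.suffix == ".mat" else "array_hdf5"
    if format_hint == "fieldtrip_mat":
        return _read_fieldtrip_mat(path)
    if format_hint == "array_hdf5":
        return _read_array_hdf5(path)
    raise FormatError(f"unknown recording format {format_hint!r}")


# ---------------------------------------------------------------------------
# Hypnogram I/O
# ---------------------------------------------------------------------------


def read_hypnogram(path: str | Path, epoch_length_s: float = 30.0) -> Hypnogram:
    """Read a plain-text hypnogram, one stage code per line."""
    stages: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        code = line.strip()
        if not code or code.startswith("#"):
            continue
        if code not in STAGE_CODES:
            raise FormatError(f"{path}:{lineno}: unknown stage code {code!r}")
        stages.append(code)
    return Hypnogram(epoch_stages=stages, epoch_length_s=epoch_length_s)


def write_hypnogram(hypnogram: Hypnogram, path: str | Path) -> None:
    Path(path).write_text("".join(s + "\n" for s in hypnogram.epoch_stages))


# ---------------------------------------------------------------------------
# Event I/O — TSV with a JSON metadata sidecar
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = ["channel", "start_sample", "end_sample", "label", "rater_id"]


def write_events(
    events: Sequence[LabeledEvent],
    path: str | Path,
    metadata: dict | None = None,
) -> None:
    """Write events as a TSV (one event per row) plus a ``.json`` sidecar."""
    path = Path(path)
    rows = [
        {
            "channel": e.channel,
            "start_sample": e.start_sample,
            "end_sample": e.end_sample,
            "label": e.label,
            "rater_id": e.rater_id if e.rater_id is not None else "",
        }
        for e in events
    ]
    frame = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)
    if metadata is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(metadata, indent=2, sort_keys=True) + "\n"
        )


def read_events(path: str | Path) -> list[LabeledEvent]:
    """Read an event TSV written by :func:`write_events`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    frame = pd.read_csv(path, sep="\t", dtype={"channel": str}, keep_default_na=False)
    missing = [c for c in _EVENT_COLUMNS[:4] if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    events = []
    for row in frame.itertuples(index=False):
        rater = getattr(row, "rater_id", "")
        events.append(
            LabeledEvent(
                channel=str(row.channel),
                start_sample=int(row.start_sample),
                end_sample=int(row.end_sample),
                label=str(row.label),
                rater_id=str(rater) if str(rater) else None,
            )
        )
    return events


def read_event_metadata(path: str | Path) -> dict | None:
    sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
    if sidecar.exists():
        return json.loads(sidecar.read_text())
    return None
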