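"""Reading multichannel EEG recordings and seizure annotations.

Two on-disk dialects are supported and mapped onto the common
:class:`EEGRecord` container:

* EDF (European Data Format, 16-bit), the format of scalp-EEG corpora
  such as CHB-MIT; read through :mod:`mne`. Channel selection is by
  name, since montage labels vary between recordings.
* A plain CSV matrix (one row per channel, the first field of each row
  being the channel name), the way intracranial recordings are often
  delivered as bare numeric matrices. Channel selection is by row index.

Seizure annotations live in a plain-text sidecar, one
``onset_s<TAB>offset_s`` pair per line, in seconds from record start.
Intervals are half-open ``[onset, offset)`` so the boundary sample is
never labeled twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import AnnotationError, DataError, FormatError, MissingChannelError

__all__ = [
    "SeizureInterval",
    "EEGRecord",
    "read_edf",
    "read_csv_matrix",
    "read_annotations",
]


@dataclass(frozen=True)
class SeizureInterval:
    """One annotated seizure, ``[onset_s, offset_s)`` seconds from record start."""

    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not (0 <= self.onset_s < self.offset_s):
            raise AnnotationError(
                f"invalid seizure interval ({self.onset_s}, {self.offset_s}): "
                "need 0 <= onset < offset"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class EEGRecord:
    """A multichannel recording: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    fs: float
    channel_names: list[str]
    patient_id: str = ""
    annotations: list[SeizureInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise DataError(f"data must be 2-D (channels x samples), got {self.data.ndim}-D")
        if not np.all(np.isfinite(self.data)):
            raise DataError("record contains non-finite samples")
        if self.fs <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.data.shape[0]:
            raise DataError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )
        _validate_intervals(self.annotations, self.duration_s)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs


def _validate_intervals(intervals: Sequence[SeizureInterval], duration_s: float) -> None:
    prev_offset = 0.0
    for iv in intervals:
        if iv.onset_s < prev_offset:
            raise AnnotationError(
                f"seizure intervals overlap or are unsorted near onset {iv.onset_s}"
            )
        if iv.offset_s > duration_s + 1e-9:
            raise AnnotationError(
                f"seizure interval ({iv.onset_s}, {iv.offset_s}) exceeds record "
                f"duration {duration_s:.3f} s"
            )
        prev_offset = iv.offset_s


def read_edf(path: str | Path, channel_subset: Sequence[str] | None = None) -> EEGRecord:
    """Read an EDF file into an :class:`EEGRecord` (annotations empty).

    Parameters
    ----------
    path
        EDF file path.
    channel_subset
        Optional channel names to keep, returned in the requested order.
        A name absent from the file raises :class:`MissingChannelError`.
    """
    import mne  # deferred: mne import is slow and only needed for EDF

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted exceptions on bad headers
        raise FormatError(f"cannot read EDF file {path}: {exc}") from exc

    names = list(raw.ch_names)
    data_uv = raw.get_data(units="uV")
    if channel_subset is not None:
        missing = [c for c in channel_subset if c not in names]
        if missing:
            raise MissingChannelError(
                f"channels {missing} not found in {path.name}; available: {names}"
            )
        idx = [names.index(c) for c in channel_subset]
        data_uv = data_uv[idx]
        names = list(channel_subset)

    return EEGRecord(
        data=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_names=names,
        patient_id=path.stem,
    )


def read_csv_matrix(path: str | Path, fs: float, patient_id: str | None = None) -> EEGRecord:
    """Read a CSV channel-by-sample matrix (row header = channel name)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, header=None, index_col=0, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"cannot parse CSV matrix {path}: {exc}") from exc
    data = frame.to_numpy(dtype=np.float64)
    if data.size == 0:
        raise FormatError(f"empty CSV matrix {path}")
    if not np.all(np.isfinite(data)):
        # pandas pads short rows with NaN, so raggedness surfaces here
        raise FormatError(f"ragged or non-numeric CSV matrix {path}")
    return EEGRecord(
        data=data,
        fs=float(fs),
        channel_names=[str(c) for c in frame.index],
        patient_id=patient_id if patient_id is not None else path.stem,
    )


def read_annotations(path: str | Path, record_duration_s: float) -> list[SeizureInterval]:
    """Parse a seizure-annotation sidecar and validate against the record.

    Empty files (seizure-free records) yield an empty list. Lines must
    hold two whitespace-separated numbers; intervals are returned sorted
    and must not overlap or exceed ``record_duration_s``.
    """
    path = Path(path)
    intervals: list[SeizureInterval] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise AnnotationError(f"{path.name}:{lineno}: expected 'onset<TAB>offset', got {line!r}")
        try:
            onset, offset = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise AnnotationError(f"{path.name}:{lineno}: non-numeric annotation {line!r}") from exc
        intervals.append(SeizureInterval(onset, offset))
    intervals.sort(key=lambda iv: iv.onset_s)
    _validate_intervals(intervals, record_duration_s)
    return intervals
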