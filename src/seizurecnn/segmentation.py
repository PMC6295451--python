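"""Per-second state labeling and 1-s epoch extraction.

Each whole second of a recording is assigned exactly one label:

* ``ictal`` — the second overlaps an annotated seizure interval;
* ``preictal`` — within ``preictal_len_s`` seconds immediately before a
  seizure onset (truncated at record start or a preceding seizure's
  offset);
* ``excluded`` — within ``interictal_margin_s`` of any seizure but
  neither ictal nor preictal, removed so that "interictal" epochs are
  guaranteed to be far from seizure activity;
* ``interictal`` — everything else.

Non-excluded seconds become labeled epochs of ``fs`` samples. The
preictal window length and the interictal distance criterion are not
universal constants — they are parameters with conservative clinical
defaults (30 min preictal, 60 min margin); synthetic experiments use
much shorter values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eeg_io import EEGRecord
from .exceptions import ConfigurationError, DataError

__all__ = [
    "LABELS",
    "CLASS_ORDER",
    "StateTimeline",
    "Epoch",
    "build_timeline",
    "extract_epochs",
    "balance_classes",
]

CLASS_ORDER = ("interictal", "preictal", "ictal")
LABELS = CLASS_ORDER + ("excluded",)

DEFAULT_PREICTAL_LEN_S = 1800.0
DEFAULT_INTERICTAL_MARGIN_S = 3600.0


@dataclass
class StateTimeline:
    """One label per whole second of a record."""

    labels: np.ndarray  # array of str, length = floor(duration_s)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)

    def __len__(self) -> int:
        return len(self.labels)

    def count(self, label: str) -> int:
        return int(np.sum(self.labels == label))


@dataclass
class Epoch:
    """One labeled 1-s channels x samples grid."""

    data: np.ndarray
    label: str
    patient_id: str = ""
    t_start: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.label not in CLASS_ORDER:
            raise DataError(f"epoch label must be one of {CLASS_ORDER}, got {self.label!r}")


def build_timeline(
    record: EEGRecord,
    preictal_len_s: float = DEFAULT_PREICTAL_LEN_S,
    interictal_margin_s: float = DEFAULT_INTERICTAL_MARGIN_S,
) -> StateTimeline:
    """Label every whole second of ``record`` from its seizure annotations."""
    if preictal_len_s <= 0:
        raise ConfigurationError("preictal_len_s must be > 0")
    if interictal_margin_s < preictal_len_s:
        raise ConfigurationError("interictal_margin_s must be >= preictal_len_s")

    n = int(np.floor(record.duration_s))
    labels = np.array(["interictal"] * n, dtype=object)
    seconds = np.arange(n)

    # ictal: any overlap between [s, s+1) and [onset, offset)
    for iv in record.annotations:
        ictal = (seconds < iv.offset_s) & (seconds + 1 > iv.onset_s)
        labels[ictal] = "ictal"

    # preictal window before each onset, not overwriting ictal seconds
    for iv in record.annotations:
        pre = (seconds + 1 > iv.onset_s - preictal_len_s) & (seconds < iv.onset_s)
        labels[pre & (labels != "ictal")] = "preictal"

    # margin around every seizure: remaining interictal seconds too close
    for iv in record.annotations:
        near = (seconds + 1 > iv.onset_s - interictal_margin_s) & (
            seconds < iv.offset_s + interictal_margin_s
        )
        labels[near & (labels == "interictal")] = "excluded"

    return StateTimeline(labels)


def extract_epochs(
    record: EEGRecord, timeline: StateTimeline, stride_s: float = 1.0
) -> list[Epoch]:
    """Cut labeled 1-s epochs from a record.

    With the default stride of 1 s windows are non-overlapping and
    aligned to whole seconds, so no epoch spans a state boundary. A
    fractional stride produces overlapping windows; a window is kept
    only if every second it touches carries the same non-excluded label.
    A trailing partial second is dropped.
    """
    if stride_s <= 0:
        raise ConfigurationError("stride_s must be > 0")
    n = len(timeline)
    if n > int(np.floor(record.duration_s)):
        raise DataError("timeline longer than record")
    L = int(round(record.fs))
    epochs: list[Epoch] = []
    t = 0.0
    while t + 1.0 <= n + 1e-9:
        first = int(np.floor(t + 1e-9))
        last = int(np.ceil(t + 1.0 - 1e-9)) - 1
        covered = set(timeline.labels[first : last + 1])
        if len(covered) == 1 and "excluded" not in covered:
            start = int(round(t * record.fs))
            epochs.append(
                Epoch(
                    data=record.data[:, start : start + L],
                    label=covered.pop(),
                    patient_id=record.patient_id,
                    t_start=t,
                )
            )
        t += stride_s
    return epochs


def balance_classes(epochs: list[Epoch], seed: int = 0) -> list[Epoch]:
    """Undersample the majority classes to the minority count.

    Selection is a seeded draw without replacement; the temporal order
    of the surviving epochs is preserved.
    """
    labels = np.array([e.label for e in epochs], dtype=object)
    present = [c for c in CLASS_ORDER if np.any(labels == c)]
    if not present:
        return []
    counts = {c: int(np.sum(labels == c)) for c in present}
    target = min(counts.values())
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for c in present:
        idx = np.flatnonzero(labels == c)
        chosen = rng.choice(idx, size=target, replace=False)
        keep.extend(int(i) for i in chosen)
    keep.sort()
    return [epochs[i] for i in keep]
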