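"""HDF5 containers for labeled epoch sets (time or frequency domain)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .exceptions import FormatError
from .segmentation import Epoch
from .spectral import SpectralEpoch

__all__ = ["save_epochs", "load_epochs"]


def save_epochs(
    path: str | Path,
    epochs: Sequence[Epoch | SpectralEpoch],
    domain: str,
    fs: float,
    patient_id: str = "",
) -> None:
    """Write an epoch set to one HDF5 file (datasets: data, labels, t_start)."""
    if domain not in ("time", "frequency"):
        raise FormatError(f"domain must be 'time' or 'frequency', got {domain!r}")
    if not epochs:
        raise FormatError("refusing to write an empty epoch set")
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=np.stack([e.data for e in epochs]))
        fh.create_dataset(
            "labels",
            data=np.array([e.label for e in epochs], dtype=h5py.string_dtype()),
        )
        fh.create_dataset("t_start", data=np.array([e.t_start for e in epochs]))
        fh.attrs["domain"] = domain
        fh.attrs["fs"] = fs
        fh.attrs["patient_id"] = patient_id


def load_epochs(path: str | Path) -> tuple[list[Epoch | SpectralEpoch], dict]:
    """Read an epoch set; returns (epochs, meta) with meta['domain'] etc."""
    with h5py.File(path, "r") as fh:
        for key in ("data", "labels", "t_start"):
            if key not in fh:
                raise FormatError(f"epoch container {path} lacks dataset {key!r}")
        data = fh["data"][()]
        labels = [s.decode() if isinstance(s, bytes) else str(s) for s in fh["labels"][()]]
        t_start = fh["t_start"][()]
        meta = {
            "domain": str(fh.attrs.get("domain", "time")),
            "fs": float(fh.attrs.get("fs", 0.0)),
            "patient_id": str(fh.attrs.get("patient_id", "")),
        }
    cls = SpectralEpoch if meta["domain"] == "frequency" else Epoch
    epochs = [
        cls(data=d, label=lab, patient_id=meta["patient_id"], t_start=float(t))
        for d, lab, t in zip(data, labels, t_start)
    ]
    return epochs, meta
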