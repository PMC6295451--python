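"""One-sided FFT amplitude spectra of 1-s epochs.

Each channel of an epoch of length ``L`` maps to ``B = L//2 + 1``
amplitude bins (bin spacing ``fs/L`` Hz), scaled so that a bin-aligned
sinusoid of amplitude ``A`` is recovered as exactly ``A``:

    amp[k] = (2/L) * |X[k]|   for 0 < k < L/2
    amp[k] = (1/L) * |X[k]|   for k = 0 and k = L/2

where ``X`` is the DFT of the raw, unwindowed samples. No taper is
applied and the DC bin is kept; the classifier is free to ignore it.
The channels x bins grid has the same layout as a time-domain epoch, so
the same 2-D convolutional network consumes both domains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DataError
from .segmentation import CLASS_ORDER, Epoch

__all__ = ["SpectralEpoch", "to_spectrum", "batch_transform"]


@dataclass
class SpectralEpoch:
    """One labeled channels x frequency-bins amplitude grid."""

    data: np.ndarray
    label: str
    patient_id: str = ""
    t_start: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.label not in CLASS_ORDER:
            raise DataError(f"label must be one of {CLASS_ORDER}, got {self.label!r}")
        if np.any(self.data < 0):
            raise DataError("amplitude spectrum contains negative values")


def amplitude_spectrum(data: np.ndarray) -> np.ndarray:
    """One-sided amplitude spectrum of each row of ``data`` (channels x L)."""
    data = np.asarray(data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise DataError("cannot transform non-finite samples")
    L = data.shape[-1]
    amp = (2.0 / L) * np.abs(np.fft.rfft(data, axis=-1))
    amp[..., 0] /= 2.0
    if L % 2 == 0:
        amp[..., -1] /= 2.0
    return amp


def to_spectrum(epoch: Epoch) -> SpectralEpoch:
    """FFT amplitude spectrum of one epoch; label and metadata carried through."""
    return SpectralEpoch(
        data=amplitude_spectrum(epoch.data),
        label=epoch.label,
        patient_id=epoch.patient_id,
        t_start=epoch.t_start,
    )


def batch_transform(epochs: list[Epoch]) -> list[SpectralEpoch]:
    """Elementwise :func:`to_spectrum`, order preserved."""
    return [to_spectrum(e) for e in epochs]
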