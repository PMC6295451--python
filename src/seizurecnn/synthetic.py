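"""Seeded synthetic EEG with distinct interictal / preictal / ictal spectra.

Real seizure corpora are either access-restricted (intracranial
monitoring data) or very large (scalp-EEG archives), so the pipeline is
exercised on simulated 256-Hz multichannel recordings instead. Each
brain state is a sum of sinusoids plus white Gaussian noise:

    x_c(t) = sum_b A_b * sin(2*pi*f_b*t + phi_cb) + N(0, noise_sd^2)

with the phase ``phi_cb`` fixed per channel and per timeline segment.
The default state parameters give each state a clearly distinct
amplitude-spectrum signature: a strong low-frequency rhythm for ictal
(high-amplitude rhythmic discharge), a mid-band shift for preictal, and
an alpha-dominated background for interictal.

With ``phase_randomize=True`` every segment draws fresh per-channel
phases, so time-domain waveforms of the same state are unalignable
across segments while their amplitude spectra are unchanged — the
controlled condition under which frequency-domain inputs should beat
time-domain inputs for classification.

Limitations (deliberate): noise is white rather than 1/f, there are no
artifacts (eye blinks, EMG) and no spatial topography — all channels
share the same oscillation amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .eeg_io import EEGRecord, SeizureInterval
from .exceptions import ConfigurationError, FormatError

__all__ = [
    "StateSpec",
    "SyntheticConfig",
    "STATES",
    "default_state_specs",
    "generate_record",
    "write_fixture",
]

STATES = ("interictal", "preictal", "ictal")


@dataclass
class StateSpec:
    """Oscillation mixture and noise level for one brain state.

    ``oscillations`` is a list of ``(frequency_hz, amplitude_uv)`` pairs;
    ``noise_sd`` is the white-noise standard deviation in microvolts.
    """

    name: str
    oscillations: list[tuple[float, float]]
    noise_sd: float = 5.0

    def validate(self, fs: float) -> None:
        if self.name not in STATES:
            raise ConfigurationError(f"unknown state {self.name!r}; expected one of {STATES}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"{self.name}: noise_sd must be >= 0")
        for f, a in self.oscillations:
            if not (0 < f < fs / 2):
                raise ConfigurationError(
                    f"{self.name}: frequency {f} Hz outside (0, {fs / 2}) Hz"
                )
            if a < 0:
                raise ConfigurationError(f"{self.name}: amplitude {a} must be >= 0")


def default_state_specs(noise_sd: float = 5.0) -> dict[str, StateSpec]:
    """Default per-state spectral signatures (frequency Hz, amplitude uV)."""
    return {
        "interictal": StateSpec("interictal", [(10.0, 10.0), (20.0, 3.0)], noise_sd),
        "preictal": StateSpec("preictal", [(10.0, 5.0), (15.0, 6.0), (20.0, 8.0)], noise_sd),
        "ictal": StateSpec("ictal", [(4.0, 40.0), (8.0, 15.0)], noise_sd),
    }


@dataclass
class SyntheticConfig:
    """Full description of one simulated recording.

    ``timeline`` is an ordered list of ``(state, duration_s)`` segments.
    Identical config + seed produces bit-identical output.
    """

    timeline: list[tuple[str, float]]
    n_channels: int = 6
    fs: float = 256.0
    state_specs: dict[str, StateSpec] = field(default_factory=default_state_specs)
    seed: int = 0
    phase_randomize: bool = False
    patient_id: str = "synthetic"

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ConfigurationError("n_channels must be >= 1")
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if not self.timeline:
            raise ConfigurationError("timeline is empty")
        for state, dur in self.timeline:
            if state not in self.state_specs:
                raise ConfigurationError(f"timeline state {state!r} has no StateSpec")
            if dur <= 0:
                raise ConfigurationError(f"timeline duration {dur} must be > 0")
        for spec in self.state_specs.values():
            spec.validate(self.fs)


def generate_record(config: SyntheticConfig) -> EEGRecord:
    """Synthesize an annotated multichannel recording from a config.

    Annotations contain exactly the ictal segments of the timeline.
    Time runs continuously across segments; each segment contributes
    ``round(duration * fs)`` samples.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs, n_ch = config.fs, config.n_channels

    chunks: list[np.ndarray] = []
    annotations: list[SeizureInterval] = []
    t_offset = 0.0
    sample_offset = 0
    for state, dur in config.timeline:
        spec = config.state_specs[state]
        n = int(round(dur * fs))
        t = (sample_offset + np.arange(n)) / fs
        osc = spec.oscillations
        if config.phase_randomize:
            phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_ch, len(osc)))
        else:
            phases = np.zeros((n_ch, len(osc)))
        seg = np.zeros((n_ch, n))
        for b, (f, a) in enumerate(osc):
            seg += a * np.sin(2.0 * np.pi * f * t[None, :] + phases[:, b][:, None])
        if spec.noise_sd > 0:
            seg += rng.normal(0.0, spec.noise_sd, size=(n_ch, n))
        chunks.append(seg)
        if state == "ictal":
            annotations.append(SeizureInterval(t_offset, t_offset + dur))
        t_offset += dur
        sample_offset += n

    return EEGRecord(
        data=np.concatenate(chunks, axis=1),
        fs=fs,
        channel_names=[f"C{i + 1}" for i in range(n_ch)],
        patient_id=config.patient_id,
        annotations=annotations,
    )


def write_fixture(record: EEGRecord, path: str | Path, format: str = "csv") -> tuple[Path, Path]:
    """Write a record plus its annotation sidecar to disk.

    ``format`` is ``"csv"`` (lossless text matrix) or ``"edf"`` (16-bit
    EDF, quantization error bounded by physical range / 2^16). Returns
    ``(data_path, annotation_path)``; the sidecar shares the stem with
    extension ``.ann``.
    """
    path = Path(path)
    if format == "csv":
        _write_csv(record, path)
    elif format == "edf":
        _write_edf(record, path)
    else:
        raise ConfigurationError(f"unknown fixture format {format!r}; use 'csv' or 'edf'")
    ann_path = path.with_suffix(".ann")
    with open(ann_path, "w") as fh:
        for iv in record.annotations:
            fh.write(f"{iv.onset_s:g}\t{iv.offset_s:g}\n")
    return path, ann_path


def _write_csv(record: EEGRecord, path: Path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(record.channel_names, record.data):
            fh.write(name + "," + ",".join(repr(float(v)) for v in row) + "\n")


def _fit_field(value: float, width: int = 8) -> str:
    """Format a number into an EDF ASCII field, shrinking precision to fit."""
    for prec in range(6, -1, -1):
        s = f"{value:.{prec}f}"
        if len(s) <= width:
            return s
    raise FormatError(f"cannot encode {value} in {width} ASCII characters")


def _write_edf(record: EEGRecord, path: Path) -> None:
    """Minimal EDF writer: 16-bit samples, one 1-s data record per second.

    The physical min/max are written as 8-character ASCII fields and the
    parsed-back values are used for quantization, so the round-trip error
    is bounded by (physical range)/2^16 regardless of header rounding.
    """
    fs = record.fs
    spr = int(round(fs))  # samples per 1-s data record
    if abs(fs - spr) > 1e-9:
        raise FormatError(f"EDF writer requires an integer sampling rate, got {fs}")
    n_records = record.n_samples // spr
    if n_records * spr != record.n_samples:
        raise FormatError(
            f"EDF writer requires a whole number of seconds, got {record.n_samples} "
            f"samples at {fs} Hz"
        )
    n_sig = record.n_channels

    pmins, pmaxs, scaled = [], [], []
    for row in record.data:
        lo, hi = float(row.min()), float(row.max())
        if hi - lo < 1e-6:  # degenerate (constant) channel: widen the range
            lo, hi = lo - 1.0, hi + 1.0
        lo_s, hi_s = _fit_field(lo), _fit_field(hi)
        lo_v, hi_v = float(lo_s), float(hi_s)
        # header rounding may shrink the range; nudge outward one ULP of the field
        while lo_v > row.min():
            lo_s = _fit_field(lo_v - max(abs(lo_v) * 1e-5, 1e-4))
            lo_v = float(lo_s)
        while hi_v < row.max():
            hi_s = _fit_field(hi_v + max(abs(hi_v) * 1e-5, 1e-4))
            hi_v = float(hi_s)
        pmins.append(lo_s)
        pmaxs.append(hi_s)
        gain = (hi_v - lo_v) / 65535.0
        dig = np.round((row - lo_v) / gain) - 32768
        scaled.append(np.clip(dig, -32768, 32767).astype("<i2"))

    def f(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise FormatError(f"EDF header field {text!r} exceeds {width} bytes")
        return b.ljust(width)

    header = b"".join(
        [
            f("0", 8),
            f(record.patient_id[:80] or "X", 80),
            f("Startdate 01-JAN-2000", 80),
            f("01.01.00", 8),
            f("00.00.00", 8),
            f(str(256 * (n_sig + 1)), 8),
            f("", 44),
            f(str(n_records), 8),
            f("1", 8),
            f(str(n_sig), 4),
        ]
    )
    sig_fields = [
        (16, [name[:16] for name in record.channel_names]),
        (80, [""] * n_sig),  # transducer
        (8, ["uV"] * n_sig),
        (8, pmins),
        (8, pmaxs),
        (8, ["-32768"] * n_sig),
        (8, ["32767"] * n_sig),
        (80, [""] * n_sig),  # prefiltering
        (8, [str(spr)] * n_sig),
        (32, [""] * n_sig),  # reserved
    ]
    header += b"".join(f(v, w) for w, values in sig_fields for v in values)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for ch in range(n_sig):
                fh.write(scaled[ch][r * spr : (r + 1) * spr].tobytes())

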