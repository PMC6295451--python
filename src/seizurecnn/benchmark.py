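"""Reference synthetic experiment: the task x domain matrix at desk scale.

The benchmark recording alternates interictal (8 s), preictal (4 s) and
ictal (4 s) segments for a configurable number of cycles at 256 Hz over
6 channels, with per-segment random phases. With a 4-s preictal window
and a 4-s interictal margin the second-level labels reproduce the
generator's states exactly, yielding (after balancing) 4*cycles epochs
per class. The default 50 cycles give 200 epochs per class — enough to
train the CNN while keeping a full cross-validated matrix to a few
minutes on one CPU.

``compare_domains`` evaluates one task in both signal domains on the
*same* fold partition, so the frequency-vs-time accuracy difference is
a paired comparison on identical test epochs.

The CNN optimization budget used here (40 SGD epochs, batch 32,
learning rate 0.05) is reduced relative to the library defaults to keep
the benchmark fast; the architecture is unchanged.
"""

from __future__ import annotations

import numpy as np

from . import evaluation, segmentation, spectral, synthetic
from .cnn import CNNConfig

__all__ = ["BENCHMARK_CNN", "benchmark_epochs", "compare_domains", "run_matrix"]

BENCHMARK_CNN = dict(max_epochs=40, batch_size=32, learning_rate=0.05)


def benchmark_epochs(
    seed: int, cycles: int = 50, phase_randomize: bool = True
) -> tuple[list, list]:
    """Balanced (time_epochs, spectral_epochs) for one benchmark recording."""
    timeline = [("interictal", 8.0), ("preictal", 4.0), ("ictal", 4.0)] * cycles
    cfg = synthetic.SyntheticConfig(
        timeline=timeline, seed=seed, phase_randomize=phase_randomize
    )
    record = synthetic.generate_record(cfg)
    tl = segmentation.build_timeline(record, preictal_len_s=4, interictal_margin_s=4)
    epochs = segmentation.balance_classes(
        segmentation.extract_epochs(record, tl), seed=seed
    )
    return epochs, spectral.batch_transform(epochs)


def _cnn_config(shape: tuple[int, int], n_classes: int, seed: int) -> CNNConfig:
    return CNNConfig(input_shape=shape, n_classes=n_classes, seed=seed, **BENCHMARK_CNN)


def compare_domains(
    epochs: list, spectra: list, task: str, seed: int
) -> dict[str, evaluation.MetricsReport]:
    """6-fold CV of one task in both domains on a shared fold partition."""
    _, y = evaluation.task_arrays(epochs, task)
    folds = evaluation.make_folds(len(y), 6, y, seed=seed)
    n_classes = len(evaluation.TASKS[task])
    out = {}
    for domain, eps in (("time", epochs), ("frequency", spectra)):
        x, _ = evaluation.task_arrays(eps, task)
        out[domain] = evaluation.cross_validate(
            eps, task, domain,
            cnn_config=_cnn_config(x.shape[1:], n_classes, seed),
            seed=seed, folds=folds,
        )
    return out


def run_matrix(
    seed: int, cycles: int = 50, tasks: tuple[str, ...] = tuple(evaluation.TASKS)
) -> dict[str, dict[str, evaluation.MetricsReport]]:
    """The full task x domain matrix on one benchmark recording."""
    epochs, spectra = benchmark_epochs(seed, cycles=cycles)
    return {task: compare_domains(epochs, spectra, task, seed) for task in tasks}
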