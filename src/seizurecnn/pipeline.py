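"""End-to-end experiment orchestration.

One experiment runs the full chain — load or simulate a recording,
label seconds, cut 1-s epochs, optionally balance classes, transform to
the frequency domain where requested — and cross-validates the CNN on
every requested task x domain cell of the experiment matrix:

    {interictal-vs-preictal, interictal-vs-ictal, three-class}
        x {time, frequency}

Within one run the time- and frequency-domain evaluations of a task
share the same fold partition, so their accuracies are a paired
comparison on identical test epochs. Evaluation is per recording (per
patient); there is no cross-patient pooling.

Every run writes its metrics (CSV and JSON), one final model and loss
trace per cell (trained on the full epoch set, separate from the CV
models), and the resolved configuration for provenance.
"""

from __future__ import annotations

import csv
import json
import logging
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cnn, evaluation, segmentation, spectral, storage, synthetic
from .eeg_io import EEGRecord, read_annotations, read_csv_matrix, read_edf
from .exceptions import ConfigurationError, SeizureCNNError

__all__ = ["ExperimentConfig", "run_experiment", "load_config"]

log = logging.getLogger("seizurecnn")


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment run."""

    # input: either paths to a recording + annotations, or a synthetic config
    data_path: str | None = None
    data_format: str = "edf"  # 'edf' or 'csv'
    annotations_path: str | None = None
    fs: float = 256.0  # used by the CSV reader only
    channels: list[str] | None = None  # EDF channel subset, by name
    synthetic: dict | None = None  # SyntheticConfig fields

    preictal_len_s: float = segmentation.DEFAULT_PREICTAL_LEN_S
    interictal_margin_s: float = segmentation.DEFAULT_INTERICTAL_MARGIN_S
    stride_s: float = 1.0
    balance: bool = True

    cnn: dict = field(default_factory=dict)  # CNNConfig overrides
    k: int = 6
    seed: int = 0
    tasks: list[str] = field(default_factory=lambda: list(evaluation.TASKS))
    domains: list[str] = field(default_factory=lambda: ["time", "frequency"])

    output_dir: str = "results"
    save_epoch_sets: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.tasks or not self.domains:
            raise ConfigurationError("tasks and domains must be non-empty")
        for t in self.tasks:
            if t not in evaluation.TASKS:
                raise ConfigurationError(f"unknown task {t!r}")
        for d in self.domains:
            if d not in ("time", "frequency"):
                raise ConfigurationError(f"unknown domain {d!r}")
        if self.synthetic is None and self.data_path is None:
            raise ConfigurationError("config needs either data_path or a synthetic section")


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an :class:`ExperimentConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return ExperimentConfig(**raw)
    except TypeError as exc:
        raise ConfigurationError(f"bad experiment config {path}: {exc}") from exc


@contextmanager
def _stage(name: str, context: str = ""):
    """Attach the failing pipeline stage to any package error."""
    try:
        yield
    except SeizureCNNError as exc:
        raise type(exc)(f"[stage: {name}{' ' + context if context else ''}] {exc}") from exc
    except OSError as exc:
        raise SeizureCNNError(f"[stage: {name}{' ' + context if context else ''}] {exc}") from exc


def _load_record(config: ExperimentConfig) -> EEGRecord:
    if config.synthetic is not None:
        with _stage("simulate"):
            syn = _synthetic_config(config)
            return synthetic.generate_record(syn)
    with _stage("read", config.data_path or ""):
        if config.data_format == "edf":
            record = read_edf(config.data_path, channel_subset=config.channels)
        elif config.data_format == "csv":
            record = read_csv_matrix(config.data_path, fs=config.fs)
        else:
            raise ConfigurationError(f"unknown data_format {config.data_format!r}")
    with _stage("annotations", config.annotations_path or "(missing)"):
        if config.annotations_path is None:
            raise ConfigurationError("annotations_path is required for on-disk recordings")
        record.annotations = read_annotations(config.annotations_path, record.duration_s)
    return record


def _synthetic_config(config: ExperimentConfig) -> synthetic.SyntheticConfig:
    raw = dict(config.synthetic or {})
    specs = raw.pop("state_specs", None)
    timeline = [(str(s), float(d)) for s, d in raw.pop("timeline")]
    syn = synthetic.SyntheticConfig(timeline=timeline, **raw)
    if specs is not None:
        syn.state_specs = {
            name: synthetic.StateSpec(
                name,
                [(float(f), float(a)) for f, a in sp["oscillations"]],
                float(sp.get("noise_sd", 5.0)),
            )
            for name, sp in specs.items()
        }
    if "seed" not in raw:
        syn.seed = config.seed
    return syn


def run_experiment(config: ExperimentConfig) -> dict[str, evaluation.MetricsReport]:
    """Execute the full pipeline; returns reports keyed by ``task|domain``.

    Side effects: writes ``metrics.csv``, ``metrics.json``, one model
    checkpoint + loss-trace CSV per task x domain, and the resolved
    config, all under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, config.log_level)
    log.info("resolved config: %s", asdict(config))
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh)

    record = _load_record(config)
    log.info(
        "record %s: %d channels, %.1f s at %g Hz, %d seizures",
        record.patient_id, record.n_channels, record.duration_s, record.fs,
        len(record.annotations),
    )

    with _stage("timeline"):
        timeline = segmentation.build_timeline(
            record, config.preictal_len_s, config.interictal_margin_s
        )
    with _stage("epochs"):
        epochs = segmentation.extract_epochs(record, timeline, config.stride_s)
        if config.balance:
            epochs = segmentation.balance_classes(epochs, seed=config.seed)
    counts = {c: sum(e.label == c for e in epochs) for c in segmentation.CLASS_ORDER}
    log.info("epoch counts after %sbalancing: %s", "" if config.balance else "no ", counts)

    domain_epochs: dict[str, list] = {}
    if "time" in config.domains:
        domain_epochs["time"] = epochs
    if "frequency" in config.domains:
        with _stage("fft"):
            domain_epochs["frequency"] = spectral.batch_transform(epochs)
    if config.save_epoch_sets:
        for dom, eps in domain_epochs.items():
            storage.save_epochs(out / f"epochs_{dom}.h5", eps, dom, record.fs, record.patient_id)

    reports: dict[str, evaluation.MetricsReport] = {}
    for task in config.tasks:
        # one fold partition per task, shared by every domain (paired comparison)
        _, y = evaluation.task_arrays(epochs, task)
        folds = evaluation.make_folds(len(y), config.k, y, seed=config.seed)
        for dom in config.domains:
            with _stage("cross-validate", f"{task}/{dom}"):
                x, y_dom = evaluation.task_arrays(domain_epochs[dom], task)
                cfg = _cnn_config(config, x.shape[1:], len(evaluation.TASKS[task]))
                report = evaluation.cross_validate(
                    domain_epochs[dom], task, dom, cnn_config=cfg,
                    k=config.k, seed=config.seed, folds=folds,
                )
                reports[f"{task}|{dom}"] = report
                log.info("%s / %s: mean acc %.3f", task, dom, report.mean_acc)
            with _stage("final-model", f"{task}/{dom}"):
                model, trace = cnn.train(x, y_dom, cfg)
                tag = f"{task.replace('-', '_')}__{dom}"
                cnn.save_model(model, out / f"model_{tag}.h5")
                _write_trace(out / f"trace_{tag}.csv", trace)

    _write_metrics(out, reports)
    return reports


def _cnn_config(config: ExperimentConfig, input_shape, n_classes: int) -> cnn.CNNConfig:
    return cnn.CNNConfig(
        input_shape=tuple(int(v) for v in input_shape),
        n_classes=n_classes,
        seed=config.seed,
        **config.cnn,
    )


def _write_trace(path: Path, trace: cnn.TrainTrace) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "mse"])
        for i, v in enumerate(trace.mse):
            writer.writerow([i, f"{v:.10g}"])


def _write_metrics(out: Path, reports: dict[str, evaluation.MetricsReport]) -> None:
    with open(out / "metrics.json", "w") as fh:
        json.dump({key: r.to_dict() for key, r in reports.items()}, fh, indent=2)
    with open(out / "metrics.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["task", "domain", "fold", "acc", "sen", "spe", "n_test"])
        for key, r in reports.items():
            for i, f in enumerate(r.folds):
                writer.writerow([r.task, r.domain, i, _fmt(f.acc), _fmt(f.sen), _fmt(f.spe), f.n_test])
            writer.writerow([r.task, r.domain, "mean", _fmt(r.mean_acc), _fmt(r.mean_sen), _fmt(r.mean_spe), ""])


def _fmt(v: float | None) -> str:
    return "" if v is None else f"{v:.4f}"


def _setup_logging(out: Path, level: str) -> None:
    log.setLevel(getattr(logging, level.upper(), logging.INFO))
    have = {type(h) for h in log.handlers}
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    if logging.StreamHandler not in have:
        sh = logging.StreamHandler()
        sh.setFormatter(fmt)
        log.addHandler(sh)
    for h in [h for h in log.handlers if isinstance(h, logging.FileHandler)]:
        log.removeHandler(h)
        h.close()
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(fmt)
    log.addHandler(fh)
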