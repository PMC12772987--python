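"""Readers, writers and run persistence.

EDF is the interchange format for real recordings (one channel, default
label "Flow"). Reading goes through :mod:`mne`; writing uses a minimal
16-bit EDF writer implemented here, round-trip-checked against the mne
reader. Annotations travel as plain CSV with the header
``onset_sec,duration_sec,kind``, and all tabular outputs are CSV so that
downstream tooling is language-agnostic.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .ahi import CorrectionModel
from .cnn import CNNRegressor, ModelConfig
from .simulate import ANNOTATION_KINDS, AirflowRecord, EventAnnotation
from .training import TrainConfig, TrainedModel

__all__ = [
    "write_edf",
    "read_edf_airflow",
    "write_flow_text",
    "read_flow_text",
    "write_annotations",
    "read_annotations",
    "RunConfig",
    "save_run",
    "load_run",
    "CHECKPOINT_VERSION",
]

CHECKPOINT_VERSION = 1


# ---------------------------------------------------------------------------
# EDF


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r}")
    return b.ljust(width)


def write_edf(path, record: AirflowRecord, channel_name: str = "Flow") -> None:
    """Write one airflow channel as a standard 16-bit EDF file.

    The physical range spans the signal with 6% headroom (rounded so the
    8-character header field is exact), so the round-trip error is bounded
    by (phys_max - phys_min) / (dig_max - dig_min). Requires an integer
    sampling rate (one-second data records).
    """
    fs = record.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    x = np.asarray(record.samples, dtype=float)
    n_rec = int(np.ceil(x.size / spr))
    pad_n = n_rec * spr - x.size
    if pad_n:
        x = np.pad(x, (0, pad_n), mode="edge")

    amax = float(np.max(np.abs(x))) or 1.0
    # physical range rounded so its <=8-char decimal header string is exact
    pmax = float(f"{1.06 * amax:.5g}")
    pmin = -pmax
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((x - pmin) * scale + dmin).astype("<i2")

    header = b"".join(
        [
            _pad("0", 8),
            _pad(f"X X X {record.subject_id or 'X'}", 80),
            _pad("Startdate X X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 + 256), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad("1", 4),
        ]
    )
    sig = b"".join(
        [
            _pad(channel_name, 16),
            _pad("thermistor", 80),
            _pad("", 8),  # unitless flow
            _pad(f"{pmin:.5g}", 8),
            _pad(f"{pmax:.5g}", 8),
            _pad(str(dmin), 8),
            _pad(str(dmax), 8),
            _pad("", 80),
            _pad(str(spr), 8),
            _pad("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        fh.write(digital.tobytes())


def read_edf_airflow(path, channel_name: str = "Flow") -> AirflowRecord:
    """Read one airflow channel from an EDF file via mne.

    Annotations are loaded from a sidecar CSV (same stem, ``.annotations.csv``
    suffix) when present, otherwise left empty; sleep time then defaults to
    the recording duration minus annotated wake.
    """
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channel_name not in raw.ch_names:
        raise ValueError(
            f"channel {channel_name!r} not found; available channels: {raw.ch_names}"
        )
    data = raw.get_data(picks=[channel_name])[0]
    fs = float(raw.info["sfreq"])
    duration = data.size / fs

    sidecar = path.with_suffix(".annotations.csv")
    annotations = read_annotations(sidecar) if sidecar.exists() else []
    wake = sum(a.duration for a in annotations if a.kind == "wake")
    sleep_time = duration - wake
    n_events = sum(1 for a in annotations if a.kind in ("apnea", "hypopnea"))
    true_ahi = 3600.0 * n_events / sleep_time if sleep_time > 0 else 0.0
    return AirflowRecord(
        subject_id=path.stem,
        samples=data,
        fs=fs,
        duration=duration,
        sleep_time=sleep_time,
        annotations=annotations,
        true_ahi=true_ahi,
    )


# ---------------------------------------------------------------------------
# plain-text formats


def write_flow_text(path, record: AirflowRecord) -> None:
    """Two-column text format: time_s, flow."""
    t = np.arange(record.samples.size) / record.fs
    np.savetxt(
        path,
        np.column_stack([t, record.samples]),
        fmt="%.6f",
        header="time_s flow",
        comments="# ",
    )


def read_flow_text(path, fs: float | None = None) -> tuple[np.ndarray, float]:
    """Read the two-column format back; sampling rate inferred from the time
    column unless given."""
    arr = np.loadtxt(path)
    t, x = arr[:, 0], arr[:, 1]
    if fs is None:
        dt = np.median(np.diff(t))
        fs = 1.0 / dt
    return x, float(fs)


def write_annotations(path, annotations: Sequence[EventAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write("onset_sec,duration_sec,kind\n")
        for a in annotations:
            fh.write(f"{float(a.onset)!r},{float(a.duration)!r},{a.kind}\n")


def read_annotations(path) -> list[EventAnnotation]:
    """Parse an annotation CSV; malformed rows raise with their line number."""
    out: list[EventAnnotation] = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header.replace(" ", "") != "onset_sec,duration_sec,kind":
            raise ValueError(
                f"{path}: expected header 'onset_sec,duration_sec,kind', got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            try:
                onset, duration = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric onset/duration") from exc
            kind = parts[2].strip()
            if kind not in ANNOTATION_KINDS:
                raise ValueError(
                    f"{path}:{lineno}: unknown kind {kind!r}; "
                    f"expected one of {ANNOTATION_KINDS}"
                )
            out.append(EventAnnotation(onset, duration, kind))
    return out


# ---------------------------------------------------------------------------
# run configuration + checkpointing


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of a pipeline run."""

    input_dir: str = "."
    output_dir: str = "out"
    checkpoint_dir: str = "checkpoint"
    segment_minutes: int = 10
    preset: str = "desk"  # "desk" or "full"
    seed: int = 0
    explain_method: str = "both"  # gradcam | shap | both
    shap_background_size: int = 50

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def save_run(
    checkpoint_dir,
    trained: TrainedModel,
    correction: CorrectionModel | None = None,
    run_config: RunConfig | None = None,
) -> None:
    """Persist weights, configs, history and correction to a directory."""
    d = Path(checkpoint_dir)
    d.mkdir(parents=True, exist_ok=True)
    np.savez(d / "weights.npz", **trained.model.state_dict())
    meta = {
        "version": CHECKPOINT_VERSION,
        "model_config": dataclasses.asdict(trained.config),
        "train_config": dataclasses.asdict(trained.train_config),
        "best_epoch": trained.best_epoch,
    }
    (d / "config.json").write_text(json.dumps(meta, indent=2))
    (d / "history.json").write_text(json.dumps(trained.history, indent=2))
    if correction is not None:
        (d / "correction.json").write_text(json.dumps(dataclasses.asdict(correction)))
    if run_config is not None:
        run_config.to_yaml(d / "run.yaml")


def load_run(checkpoint_dir):
    """Load a saved run; returns (TrainedModel, CorrectionModel|None,
    RunConfig|None). Reloaded models predict identically to the originals."""
    d = Path(checkpoint_dir)
    cfg_path = d / "config.json"
    if not cfg_path.exists():
        raise FileNotFoundError(f"no checkpoint at {d} (missing config.json)")
    meta = json.loads(cfg_path.read_text())
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(
            f"checkpoint version {meta.get('version')} does not match "
            f"supported version {CHECKPOINT_VERSION}"
        )
    mc = ModelConfig(**meta["model_config"])
    tc = TrainConfig(**meta["train_config"])
    model = CNNRegressor(mc, seed=tc.seed)
    with np.load(d / "weights.npz") as npz:
        model.load_state_dict({k: npz[k] for k in npz.files})
    history = json.loads((d / "history.json").read_text())
    trained = TrainedModel(model=model, train_config=tc, history=history,
                           best_epoch=meta["best_epoch"])
    correction = None
    if (d / "correction.json").exists():
        correction = CorrectionModel(**json.loads((d / "correction.json").read_text()))
    run_config = None
    if (d / "run.yaml").exists():
        run_config = RunConfig.from_yaml(d / "run.yaml")
    return trained, correction, run_config
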