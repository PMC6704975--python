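"""Readers and writers for recordings, models, segmentations and tables.

Two recording formats are supported: EDF (read through MNE, written by the
package's minimal EDF writer) and a plain delimited channels x samples
matrix with a JSON sidecar carrying the sampling rate and channel labels.
Readers validate rather than silently coerce: inconsistent shapes, missing
sidecars or non-positive sampling rates raise with file context.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from ._edf import write_edf
from .cluster import MetaCriterionReport, MicrostateModel
from .recording import EEGRecording
from .segment import Segmentation
from .synth import GroundTruth

__all__ = [
    "read_eeg",
    "write_eeg",
    "read_clinical",
    "write_model",
    "read_model",
    "write_segmentation",
    "read_segmentation",
    "write_metrics",
    "write_report",
    "write_ground_truth",
]

logger = logging.getLogger(__name__)

#: Channel labels excluded when reading EDF: annotation/trigger channels are
#: not scalp potentials.
_NON_EEG_PATTERN = re.compile(r"annotation|status|trigger|marker", re.IGNORECASE)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_eeg(path: str | Path, fmt: str | None = None) -> EEGRecording:
    """Read a recording from EDF or a delimited matrix with JSON sidecar.

    The format is inferred from the extension (``.edf`` vs ``.tsv``/
    ``.csv``/``.txt``) unless given explicitly.  Non-EEG annotation
    channels in EDF files are excluded from the data matrix and logged.
    """
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "matrix":
        return _read_matrix(path)
    raise ValueError(f"unknown format {fmt!r}; expected 'edf' or 'matrix'")


def _read_edf(path: Path) -> EEGRecording:
    import mne  # deferred: mne import is slow

    raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR", stim_channel=None)
    keep = [i for i, ch in enumerate(raw.ch_names) if not _NON_EEG_PATTERN.search(ch)]
    dropped = [ch for ch in raw.ch_names if _NON_EEG_PATTERN.search(ch)]
    if dropped:
        logger.info("%s: excluded non-EEG channels %s", path.name, dropped)
    if len(keep) < 2:
        raise ValueError(f"{path}: fewer than 2 EEG channels after exclusion")
    data = raw.get_data()[keep] * 1e6  # MNE loads EEG in volts; restore uV
    return EEGRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=[raw.ch_names[i] for i in keep],
    )


def _read_matrix(path: Path) -> EEGRecording:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"{path}: missing sidecar header {sidecar.name}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    for key in ("fs", "channel_labels"):
        if key not in meta:
            raise ValueError(f"{sidecar}: sidecar lacks required field {key!r}")
    if not meta["fs"] > 0:
        raise ValueError(f"{sidecar}: fs must be positive, got {meta['fs']}")
    delim = "," if path.suffix.lower() == ".csv" else None
    try:
        data = np.loadtxt(path, delimiter=delim, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: malformed matrix ({exc})") from exc
    if data.shape[0] != len(meta["channel_labels"]):
        raise ValueError(
            f"{path}: {data.shape[0]} rows but {len(meta['channel_labels'])} "
            f"channel labels in sidecar"
        )
    return EEGRecording(
        data=data,
        fs=float(meta["fs"]),
        channel_labels=list(meta["channel_labels"]),
        subject=meta.get("subject"),
        group=meta.get("group"),
    )


def write_eeg(rec: EEGRecording, path: str | Path, fmt: str | None = None) -> Path:
    """Write a recording as EDF or delimited matrix (+ JSON sidecar)."""
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if fmt == "edf":
        write_edf(path, rec.data, rec.fs, rec.channel_labels)
    elif fmt == "matrix":
        delim = "," if path.suffix.lower() == ".csv" else "\t"
        np.savetxt(path, rec.data, fmt="%.6f", delimiter=delim)
        meta = {
            "fs": rec.fs,
            "channel_labels": rec.channel_labels,
            "subject": rec.subject,
            "group": rec.group,
        }
        with open(_sidecar_path(path), "w") as fh:
            json.dump(meta, fh, indent=1)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read and validate a clinical covariate CSV."""
    from .stats import validate_clinical

    df = pd.read_csv(path)
    return validate_clinical(df)


def write_model(model: MicrostateModel, path: str | Path) -> Path:
    """Model maps as a channels x K delimited table with class-label header."""
    path = Path(path)
    df = pd.DataFrame(model.maps.T, columns=model.class_labels)
    if model.channel_labels:
        df.insert(0, "channel", model.channel_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.8f")
    return path


def read_model(path: str | Path) -> MicrostateModel:
    df = pd.read_csv(path, sep="\t")
    channel_labels: list[str] = []
    if "channel" in df.columns:
        channel_labels = df.pop("channel").astype(str).tolist()
    maps = df.to_numpy(float).T
    K = maps.shape[0]
    return MicrostateModel(
        maps=maps,
        gev_total=np.nan,
        gev_per_class=np.full(K, np.nan),
        channel_labels=channel_labels,
        class_labels=list(df.columns),
    )


def write_segmentation(seg: Segmentation, path: str | Path) -> Path:
    """Two-column (sample index, class label) delimited file."""
    path = Path(path)
    arr = np.column_stack([np.arange(seg.n_samples), seg.labels])
    np.savetxt(path, arr, fmt="%d", delimiter="\t", header="sample\tclass", comments="")
    return path


def read_segmentation(path: str | Path, fs: float, n_classes: int) -> Segmentation:
    arr = np.loadtxt(path, delimiter="\t", skiprows=1, dtype=int, ndmin=2)
    return Segmentation(labels=arr[:, 1], fs=fs, n_classes=n_classes)


def write_metrics(metrics: pd.DataFrame, path: str | Path) -> Path:
    """Tidy metrics CSV (subject, group, class, duration_ms, ...)."""
    path = Path(path)
    metrics.to_csv(path, index=False, float_format="%.8g")
    return path


def write_report(report: MetaCriterionReport, path: str | Path) -> Path:
    """Meta-criterion score table as CSV (rows = K, columns = criteria)."""
    path = Path(path)
    report.to_frame().to_csv(path, index=False, float_format="%.6g")
    return path


def write_ground_truth(gt: GroundTruth, label_path: str | Path, metrics_path: str | Path) -> None:
    """Ground-truth sidecar: one label per line, plus per-class metric CSV."""
    np.savetxt(label_path, gt.labels, fmt="%d")
    gt.to_frame().to_csv(metrics_path, index=False, float_format="%.8g")
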