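"""Recording containers and plain-text I/O.

A recording on disk is a numeric channels x samples matrix (whitespace-
separated text) plus a JSON sidecar ``<stem>.json`` holding ``sfreq``,
``channel_labels``, ``condition`` and ``participant``. A study manifest is a
CSV with columns ``participant, condition, path``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RawRecording",
    "read_recording",
    "write_recording",
    "read_manifest",
    "write_manifest",
]


@dataclass(frozen=True)
class RawRecording:
    """Continuous multichannel recording in microvolts."""

    data: np.ndarray  # (channels, samples), µV
    sfreq: float
    channel_labels: tuple[str, ...]
    condition: str = ""
    participant: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValueError("data must be 2-D (channels, samples)")
        if len(self.channel_labels) != data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {data.shape[0]} channels"
            )
        if not np.isfinite(data).all():
            raise ValueError("data contains non-finite values")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    def with_data(self, data: np.ndarray, sfreq: float | None = None) -> "RawRecording":
        return replace(self, data=data, sfreq=self.sfreq if sfreq is None else sfreq)


def write_recording(rec: RawRecording, path: str | Path, fmt: str = "%.6f") -> Path:
    """Write ``rec`` as a text matrix plus JSON sidecar; returns the data path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        np.savetxt(path, rec.data, fmt=fmt)
    except OSError as exc:
        raise OSError(f"failed writing recording to {path}: {exc}") from exc
    sidecar = {
        "sfreq": rec.sfreq,
        "channel_labels": list(rec.channel_labels),
        "condition": rec.condition,
        "participant": rec.participant,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording(path: str | Path) -> RawRecording:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    data = np.loadtxt(path, ndmin=2)
    return RawRecording(
        data=data,
        sfreq=float(meta["sfreq"]),
        channel_labels=tuple(meta["channel_labels"]),
        condition=meta.get("condition", ""),
        participant=str(meta.get("participant", "")),
    )


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["participant", "condition", "path"]).to_csv(
        path, index=False
    )
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant": str})
    missing = {"participant", "condition", "path"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns {sorted(missing)}")
    return df
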