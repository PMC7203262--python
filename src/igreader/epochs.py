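"""Epoched EEG container and its on-disk format.

An :class:`EpochArray` holds word-locked epochs as an
``(n_epochs, n_channels, n_samples)`` array in microvolts with a time axis
in milliseconds relative to word onset, per-epoch metadata (subject, block,
word, covariates) and a ``qc`` record (rejection mask, bad channels,
threshold).  On disk it is a raw little-endian float32 array next to a JSON
sidecar carrying shape, sampling rate, channel names and metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class EpochArray:
    data: np.ndarray  # (n_epochs, n_channels, n_samples), microvolts
    times: np.ndarray  # milliseconds relative to word onset
    sfreq: float
    channel_names: list[str]
    metadata: pd.DataFrame
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, samples)")
        n_epochs, n_channels, n_samples = self.data.shape
        if len(self.channel_names) != n_channels:
            raise ValueError("channel_names length does not match data")
        if len(self.times) != n_samples:
            raise ValueError("time axis length does not match data")
        if len(self.metadata) != n_epochs:
            raise ValueError("metadata rows do not match epoch count")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def ch_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def time_mask(self, lo_ms: float, hi_ms: float) -> np.ndarray:
        """Boolean sample mask for the closed interval [lo_ms, hi_ms]."""
        return (self.times >= lo_ms) & (self.times <= hi_ms)

    def copy(self) -> "EpochArray":
        return EpochArray(
            self.data.copy(), self.times.copy(), self.sfreq,
            list(self.channel_names), self.metadata.copy(),
            json.loads(json.dumps(self.qc)),
        )

    def retained(self) -> "EpochArray":
        """Subset to epochs not flagged in the qc rejection mask."""
        mask = np.asarray(self.qc.get("rejected", np.zeros(self.n_epochs, bool)), bool)
        keep = ~mask
        return EpochArray(
            self.data[keep], self.times.copy(), self.sfreq,
            list(self.channel_names),
            self.metadata.loc[keep].reset_index(drop=True),
            {k: v for k, v in self.qc.items() if k != "rejected"},
        )

    # -- disk format -------------------------------------------------------
    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.f32`` (raw little-endian float32) + ``<prefix>.json``."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.data.astype("<f4").tofile(prefix.with_suffix(".f32"))
        sidecar = {
            "shape": list(self.data.shape),
            "sfreq": self.sfreq,
            "channels": self.channel_names,
            "tmin_ms": float(self.times[0]),
            "tmax_ms": float(self.times[0]) + len(self.times) * 1000.0 / self.sfreq,
            "metadata": self.metadata.to_dict(orient="records"),
            "qc": _jsonable(self.qc),
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True))

    @classmethod
    def load(cls, prefix: str | Path) -> "EpochArray":
        prefix = Path(prefix)
        sidecar = json.loads(prefix.with_suffix(".json").read_text())
        shape = tuple(sidecar["shape"])
        data = np.fromfile(prefix.with_suffix(".f32"), dtype="<f4").reshape(shape)
        sfreq = float(sidecar["sfreq"])
        times = sidecar["tmin_ms"] + np.arange(shape[2]) * 1000.0 / sfreq
        return cls(
            data.astype(np.float64), times, sfreq, list(sidecar["channels"]),
            pd.DataFrame(sidecar["metadata"]), dict(sidecar.get("qc", {})),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def default_times(sfreq: float = 250.0, tmin_ms: float = -200.0, tmax_ms: float = 1000.0) -> np.ndarray:
    """Epoch time axis covering [tmin, tmax) at 1/sfreq spacing, in ms."""
    step = 1000.0 / sfreq
    n = int(round((tmax_ms - tmin_ms) / step))
    return tmin_ms + np.arange(n) * step
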