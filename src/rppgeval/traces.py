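"""In-memory containers for video-derived (rPPG) and contact-PPG traces.

An :class:`RGBTrace` holds the per-frame ROI-mean intensities of the three
color channels at the camera frame rate; a :class:`ContactTrace` holds the
pulse-oximeter waveform, nominally at 60 Hz. Both are uniformly sampled and
carry their sampling rate and start time, which is what the windowing stage
aligns on.

CSV layout (one file pair per subject-activity video):

* rPPG: columns ``t_s,R,G,B``
* cPPG: columns ``t_s,ppg``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

CHANNELS = ("red", "green", "blue")

#: Column names used in the CSV trace exports.
RPPG_COLUMNS = ("t_s", "R", "G", "B")
CPPG_COLUMNS = ("t_s", "ppg")


@dataclass
class RGBTrace:
    """Uniformly sampled mean-intensity traces for the R, G, B channels."""

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    fs: float
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        self.blue = np.asarray(self.blue, dtype=float)
        if not (len(self.red) == len(self.green) == len(self.blue)):
            raise DataError("RGB channels must have equal length")
        if self.fs <= 0:
            raise DataError("sampling rate must be positive")
        for name in CHANNELS:
            if not np.all(np.isfinite(self.channel(name))):
                raise DataError(f"non-finite samples in {name} channel")

    @property
    def n(self) -> int:
        return len(self.green)

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise DataError(f"unknown channel {name!r}; expected one of {CHANNELS}")
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.time(), "R": self.red,
                             "G": self.green, "B": self.blue})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "RGBTrace":
        df = _read_trace_csv(path, RPPG_COLUMNS)
        fs, t0 = _infer_rate(df["t_s"].to_numpy(), path)
        return cls(red=df["R"].to_numpy(), green=df["G"].to_numpy(),
                   blue=df["B"].to_numpy(), fs=fs, t0=t0)


@dataclass
class ContactTrace:
    """Uniformly sampled contact-PPG waveform (arbitrary units)."""

    samples: np.ndarray
    fs: float = 60.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise DataError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("non-finite samples in contact trace")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.time(), "ppg": self.samples})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ContactTrace":
        df = _read_trace_csv(path, CPPG_COLUMNS)
        fs, t0 = _infer_rate(df["t_s"].to_numpy(), path)
        return cls(samples=df["ppg"].to_numpy(), fs=fs, t0=t0)


@dataclass
class WindowPair:
    """One aligned 10-s (rPPG channel, cPPG) segment pair after preprocessing."""

    x: np.ndarray            # rPPG channel segment
    y: np.ndarray            # cPPG segment
    fs_common: float
    window_index: int
    channel: str
    subject: str = ""
    activity: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) != len(self.y):
            raise DataError("window pair segments must have equal length")

    @property
    def duration_s(self) -> float:
        return len(self.x) / self.fs_common


def _read_trace_csv(path: str | Path, columns: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"trace file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataError(f"malformed CSV {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    bad = df[list(columns)].isna().any(axis=1)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
        raise DataError(f"{path}: missing values at rows {rows}")
    return df


def _infer_rate(t: np.ndarray, path: str | Path) -> tuple[float, float]:
    """Infer (fs, t0) from a timestamp column, requiring uniform sampling."""
    if len(t) < 2:
        raise DataError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0) or np.max(np.abs(dt - dt.mean())) > 0.01 * dt.mean():
        raise DataError(f"{path}: timestamps are not uniformly increasing")
    return 1.0 / dt.mean(), float(t[0])
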