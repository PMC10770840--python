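"""Preprocessing chain turning raw traces into aligned 10-s window pairs.

The chain, applied in this fixed order to both the rPPG channels and the
contact PPG:

1. robust normalization, ``(x - median) / IQR`` — outlier-insensitive scale
2. resampling to a common rate (default 60 Hz, linear interpolation)
3. detrending (smoothness-priors high-pass by default)
4. zero-phase 6th-order Butterworth band-pass, 0.65-4 Hz
5. segmentation into non-overlapping 10-s windows (60 s per video)

Normalization precedes windowing, i.e. it is per-video by default; the
scope is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.signal import butter, sosfiltfilt

from .errors import ConfigError, DataError, FlatSignalError
from .traces import CHANNELS, ContactTrace, RGBTrace, WindowPair

#: Band-pass edges in Hz: 0.65 Hz (39 BPM) to 4 Hz (240 BPM).
BAND_HZ = (0.65, 4.0)
BUTTER_ORDER = 6

WINDOW_S = 10.0
TOTAL_S = 60.0


@dataclass
class PreprocessConfig:
    """Options of the preprocessing chain (defaults match the standard run)."""

    common_fs: float = 60.0                # target rate; cPPG default rate
    detrend_method: str = "smoothness_priors"   # or "linear"
    detrend_lambda: float = 1000.0
    band_hz: tuple = BAND_HZ
    butter_order: int = BUTTER_ORDER
    window_s: float = WINDOW_S
    total_s: float = TOTAL_S
    normalize_scope: str = "per_video"     # or "per_window"

    def __post_init__(self) -> None:
        if self.common_fs <= 0:
            raise ConfigError("common_fs must be positive")
        if self.detrend_method not in ("smoothness_priors", "linear"):
            raise ConfigError(f"unknown detrend method {self.detrend_method!r}")
        if self.normalize_scope not in ("per_video", "per_window"):
            raise ConfigError(f"unknown normalize scope {self.normalize_scope!r}")
        if self.window_s <= 0 or self.total_s < self.window_s:
            raise ConfigError("need total_s >= window_s > 0")


def robust_normalize(signal: np.ndarray) -> np.ndarray:
    """Center by the median and scale by the interquartile range.

    Raises :class:`FlatSignalError` when the IQR is zero (the window carries
    no usable variation).
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 4:
        raise DataError("robust normalization needs at least 4 samples")
    med = np.median(x)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        raise FlatSignalError()
    return (x - med) / iqr


def resample_to(signal: np.ndarray, fs_in: float, fs_out: float,
                t0: float = 0.0) -> np.ndarray:
    """Uniformly resample by linear interpolation on the time grid.

    The output grid starts at ``t0`` and covers the input duration; the
    duration is preserved to within one sample period.
    """
    if fs_in <= 0 or fs_out <= 0:
        raise ConfigError("sampling rates must be positive")
    x = np.asarray(signal, dtype=float)
    if fs_in == fs_out:
        return x.copy()
    n_in = x.size
    t_in = t0 + np.arange(n_in) / fs_in
    # keep the duration: the output may overrun the last input sample by
    # less than one input period; that tail is linearly extrapolated from
    # the final segment so degree-1 signals stay exact
    n_out = int(round(n_in * fs_out / fs_in))
    t_out = t0 + np.arange(n_out) / fs_out
    y = np.interp(t_out, t_in, x)
    tail = t_out > t_in[-1]
    if tail.any() and n_in >= 2:
        slope = (x[-1] - x[-2]) * fs_in
        y[tail] = x[-1] + slope * (t_out[tail] - t_in[-1])
    return y


def _smoothness_priors_trend(x: np.ndarray, lam: float) -> np.ndarray:
    """Low-pass trend: argmin_z ||x - z||^2 + lam^2 ||D2 z||^2 (sparse solve)."""
    n = x.size
    d2 = sp.diags_array([1.0, -2.0, 1.0], offsets=[0, 1, 2], shape=(n - 2, n),
                        format="csc")
    a = sp.eye_array(n, format="csc") + (lam ** 2) * (d2.T @ d2)
    return sp.linalg.spsolve(a, x)


def detrend(signal: np.ndarray, fs: float, method: str = "smoothness_priors",
            lam: float = 1000.0) -> np.ndarray:
    """Remove the slow baseline component; output is zero-mean.

    The smoothness-priors method fits a regularized low-pass trend and
    subtracts it; polynomial trends up to degree one are in its null space,
    so a pure ramp maps to (numerically) zero. ``lam`` sets the corner
    frequency on the sampling grid: at 60 Hz, lam=1000 places the high-pass
    corner near 0.3 Hz, below the cardiac band.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 10:
        raise DataError("detrend needs at least 10 samples")
    if method == "linear":
        t = np.arange(x.size)
        coef = np.polyfit(t, x, 1)
        resid = x - np.polyval(coef, t)
    elif method == "smoothness_priors":
        resid = x - _smoothness_priors_trend(x, lam)
    else:
        raise ConfigError(f"unknown detrend method {method!r}")
    return resid - resid.mean()


def bandpass(signal: np.ndarray, fs: float, band_hz: tuple = BAND_HZ,
             order: int = BUTTER_ORDER) -> np.ndarray:
    """Zero-phase Butterworth band-pass (0.65-4 Hz, order 6).

    Designed in second-order sections and applied forward-backward, so the
    phase response is identically zero and waveform morphology is
    preserved for the DTW / correlation comparison.
    """
    if fs <= 2 * band_hz[1]:
        raise ConfigError(f"fs={fs} too low for band edge {band_hz[1]} Hz")
    x = np.asarray(signal, dtype=float)
    sos = butter(order, band_hz, btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def segment_windows(rppg: RGBTrace, cppg: ContactTrace,
                    win_s: float = WINDOW_S, total_s: float = TOTAL_S,
                    subject: str = "", activity: str = "") -> list[WindowPair]:
    """Cut both traces into aligned non-overlapping windows per channel.

    Both traces must share one sampling rate (the common rate produced by
    resampling) and are aligned on the timestamp grid starting at t0.
    Exactly ``total_s / win_s`` pairs per channel are produced; trailing
    samples beyond ``total_s`` are dropped.
    """
    if abs(rppg.fs - cppg.fs) > 1e-9:
        raise DataError("segment_windows requires a common sampling rate")
    if abs(rppg.t0 - cppg.t0) > 1e-9:
        raise DataError("traces must share a start time")
    fs = rppg.fs
    usable_s = min(rppg.duration_s, cppg.duration_s, total_s)
    n_windows = int(usable_s // win_s)
    if n_windows < 1:
        raise DataError(
            f"traces too short: {usable_s:.1f} s available, window is {win_s} s")
    wlen = int(round(win_s * fs))
    pairs = []
    for channel in CHANNELS:
        x_full = rppg.channel(channel)
        y_full = cppg.samples
        for w in range(n_windows):
            sl = slice(w * wlen, (w + 1) * wlen)
            pairs.append(WindowPair(x=x_full[sl], y=y_full[sl], fs_common=fs,
                                    window_index=w, channel=channel,
                                    subject=subject, activity=activity))
    return pairs


def preprocess_pair(rppg: RGBTrace, cppg: ContactTrace,
                    config: PreprocessConfig | None = None,
                    subject: str = "", activity: str = "",
                    channels: tuple = CHANNELS) -> list[WindowPair]:
    """Full chain: normalize -> resample -> detrend -> bandpass -> window.

    ``channels`` selects which rPPG channels to process (all three by
    default). Raises :class:`FlatSignalError` (carrying the channel
    identity) if a processed channel has zero IQR under per-video
    normalization.
    """
    cfg = config or PreprocessConfig()
    fs_c = cfg.common_fs

    def _prep(x: np.ndarray, fs_in: float, label: str) -> np.ndarray:
        try:
            if cfg.normalize_scope == "per_video":
                x = robust_normalize(x)
        except FlatSignalError:
            raise FlatSignalError(channel=label, subject=subject,
                                  activity=activity) from None
        x = resample_to(x, fs_in, fs_c)
        x = detrend(x, fs_c, method=cfg.detrend_method, lam=cfg.detrend_lambda)
        return bandpass(x, fs_c, band_hz=cfg.band_hz, order=cfg.butter_order)

    chans = {name: _prep(rppg.channel(name), rppg.fs, name) for name in channels}
    y = _prep(cppg.samples, cppg.fs, "cppg")
    n = min(min(len(v) for v in chans.values()), len(y))
    # unprocessed channels are filled with the cPPG as a placeholder and
    # filtered out of the returned pairs below
    full = {name: chans.get(name, y)[:n] for name in CHANNELS}
    rppg_p = RGBTrace(red=full["red"], green=full["green"],
                      blue=full["blue"], fs=fs_c, t0=0.0)
    cppg_p = ContactTrace(samples=y[:n], fs=fs_c, t0=0.0)
    pairs = [p for p in segment_windows(rppg_p, cppg_p, win_s=cfg.window_s,
                                        total_s=cfg.total_s, subject=subject,
                                        activity=activity)
             if p.channel in chans]
    if cfg.normalize_scope == "per_window":
        out = []
        for p in pairs:
            try:
                p.x = robust_normalize(p.x)
                p.y = robust_normalize(p.y)
            except FlatSignalError:
                raise FlatSignalError(channel=p.channel, window=p.window_index,
                                      subject=subject, activity=activity) from None
            out.append(p)
        pairs = out
    return pairs
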