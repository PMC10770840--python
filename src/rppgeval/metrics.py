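"""Per-window comparison metrics between an rPPG channel and the contact PPG.

Four metrics are computed on each aligned 10-s window pair:

* DTW — minimum cumulative |a_i - b_j| over monotone warp paths, tolerant
  of residual temporal misalignment between camera and oximeter;
* Pearson's r — linear association between the two waveforms;
* RMSE — root-mean-square residual between the (normalized) waveforms;
* |dBPM| — absolute error of the heart rate estimated from the rPPG window
  (Welch periodogram peak, restricted to 39-240 BPM) against the reference
  heart rate.

Per-video results are the unweighted mean over the valid windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import welch

from .errors import DataError, ZeroVarianceError
from .traces import WindowPair

#: Heart-rate search band: 0.65-4.0 Hz, i.e. 39-240 beats/min.
HR_BAND_HZ = (0.65, 4.0)
BPM_RANGE = (39.0, 240.0)

#: Welch settings: Hann taper, 5-s segments with 50% overlap, FFT
#: zero-padded to 4096 points (~0.88 BPM grid spacing at 60 Hz).
WELCH_SEGMENT_S = 5.0
WELCH_NFFT = 4096

METRIC_NAMES = ("dtw", "r", "rmse", "delta_bpm")


# ---------------------------------------------------------------------------
# DTW

try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not args else args[0]


@_njit(cache=False)
def _dtw_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n, m = len(a), len(b)
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            c = abs(a[i - 1] - b[j - 1])
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = c + best
    return acc


@dataclass
class WarpPath:
    """An optimal DTW alignment: index pairs from (0, 0) to (n-1, m-1)."""

    pairs: list            # [(i_k, j_k)], monotone, steps in {(1,0),(0,1),(1,1)}
    distance: float


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Dynamic-time-warping dissimilarity with |a_i - b_j| local cost.

    Unconstrained symmetric steps, no band, no path-length normalization.
    Symmetric, non-negative, and zero for identical series.
    """
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise DataError("DTW requires non-empty series")
    return float(_dtw_matrix(a, b)[a.size, b.size])


def dtw_path(a: np.ndarray, b: np.ndarray) -> WarpPath:
    """DTW distance together with one optimal warp path (backtracked)."""
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise DataError("DTW requires non-empty series")
    acc = _dtw_matrix(a, b)
    i, j = a.size, b.size
    pairs = [(i - 1, j - 1)]
    while (i, j) != (1, 1):
        steps = [(i - 1, j - 1), (i - 1, j), (i, j - 1)]
        i, j = min(steps, key=lambda ij: acc[ij])
        pairs.append((i - 1, j - 1))
    pairs.reverse()
    return WarpPath(pairs=pairs, distance=float(acc[a.size, b.size]))


# ---------------------------------------------------------------------------
# Closed-form metrics

def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient between equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DataError("pearson_r requires equal lengths")
    if x.size < 2:
        raise DataError("pearson_r requires at least 2 points")
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if den == 0:
        raise ZeroVarianceError("correlation undefined for zero-variance input")
    return float(np.clip((xc * yc).sum() / den, -1.0, 1.0))


def rmse(x: np.ndarray, y: np.ndarray) -> float:
    """Root-mean-square error between equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DataError("rmse requires equal lengths")
    if x.size == 0:
        raise DataError("rmse requires at least 1 point")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def abs_bpm_diff(est_bpm: float, ref_bpm: float) -> float:
    """Absolute heart-rate error in beats/min."""
    if not (np.isfinite(est_bpm) and np.isfinite(ref_bpm)):
        raise DataError("BPM values must be finite")
    return abs(float(est_bpm) - float(ref_bpm))


# ---------------------------------------------------------------------------
# Spectral heart rate

@dataclass
class SpectralEstimate:
    """Welch power spectral density with the in-band peak location."""

    freqs: np.ndarray
    psd: np.ndarray
    peak_hz: float = field(init=False)
    est_bpm: float = field(init=False)

    def __post_init__(self) -> None:
        band = (self.freqs >= HR_BAND_HZ[0]) & (self.freqs <= HR_BAND_HZ[1])
        if not band.any():
            raise DataError("spectrum has no bins in the heart-rate band")
        p = self.psd[band]
        if np.all(p <= 0):
            raise DataError("no in-band spectral power")
        f = self.freqs[band]
        # argmax returns the first maximum: ties resolve to the lowest frequency
        self.peak_hz = float(f[np.argmax(p)])
        self.est_bpm = 60.0 * self.peak_hz


def welch_spectrum(x: np.ndarray, fs: float,
                   segment_s: float = WELCH_SEGMENT_S,
                   nfft: int = WELCH_NFFT) -> SpectralEstimate:
    """Welch PSD: Hann-tapered overlapping segments, zero-padded FFT."""
    x = np.asarray(x, dtype=float)
    nperseg = int(round(segment_s * fs))
    if x.size < nperseg:
        raise DataError(
            f"window of {x.size} samples shorter than one Welch segment ({nperseg})")
    freqs, psd = welch(x, fs=fs, window="hann", nperseg=nperseg,
                       noverlap=nperseg // 2, nfft=max(nfft, nperseg))
    return SpectralEstimate(freqs=freqs, psd=psd)


def spectral_hr(est: SpectralEstimate) -> float:
    """Heart rate in beats/min from the highest in-band spectral peak."""
    return est.est_bpm


def estimate_hr(x: np.ndarray, fs: float) -> float:
    """Convenience: Welch spectrum then in-band peak, in beats/min."""
    return spectral_hr(welch_spectrum(x, fs))


# ---------------------------------------------------------------------------
# Window evaluation and per-video aggregation

@dataclass
class MetricRecord:
    """All four metrics for one window of one channel."""

    subject: str
    activity: str
    channel: str
    window_index: int
    dtw: float = np.nan
    r: float = np.nan
    rmse: float = np.nan
    est_bpm: float = np.nan
    delta_bpm: float = np.nan


def evaluate_window(pair: WindowPair, ref_hr_bpm: float | None = None,
                    metrics: tuple = METRIC_NAMES) -> MetricRecord:
    """Compute the requested metrics for one preprocessed window pair.

    The reference heart rate is the ground-truth value when provided,
    otherwise it is estimated from the contact-PPG segment. A flat rPPG
    segment raises :class:`ZeroVarianceError`; callers exclude and log it.
    """
    if np.ptp(pair.x) == 0:
        raise ZeroVarianceError(
            f"flat rPPG window (subject={pair.subject}, channel={pair.channel}, "
            f"window={pair.window_index})")
    rec = MetricRecord(subject=pair.subject, activity=pair.activity,
                       channel=pair.channel, window_index=pair.window_index)
    if "dtw" in metrics:
        rec.dtw = dtw_distance(pair.x, pair.y)
    if "r" in metrics:
        rec.r = pearson_r(pair.x, pair.y)
    if "rmse" in metrics:
        rec.rmse = rmse(pair.x, pair.y)
    if "delta_bpm" in metrics:
        rec.est_bpm = estimate_hr(pair.x, pair.fs_common)
        ref = ref_hr_bpm if ref_hr_bpm is not None else estimate_hr(pair.y, pair.fs_common)
        rec.delta_bpm = abs_bpm_diff(rec.est_bpm, ref)
    return rec


def average_video(records: list[MetricRecord]) -> dict:
    """Unweighted mean of each metric over the valid windows of one video."""
    if not records:
        raise DataError("no valid windows to average")
    first = records[0]
    out = {"subject": first.subject, "activity": first.activity,
           "channel": first.channel, "n_windows": len(records)}
    for name in METRIC_NAMES + ("est_bpm",):
        vals = np.array([getattr(r, name) for r in records], dtype=float)
        out[name] = float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else np.nan
    return out
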