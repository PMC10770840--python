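"""Independent brute-force oracles used by the test suite.

These are deliberately naive (enumeration, double loops, plain
periodograms) and share no code with the implementation they check.
"""

from __future__ import annotations

import numpy as np


def dtw_bruteforce(a, b) -> float:
    """Exhaustive minimum over all admissible warp paths.

    Recursively enumerates every monotone path from (0, 0) to (n-1, m-1)
    with steps {(1,0), (0,1), (1,1)} and |a_i - b_j| local cost. Exponential;
    only usable for lengths <= ~8.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)

    def rec(i: int, j: int) -> float:
        cost = abs(a[i] - b[j])
        if i == n - 1 and j == m - 1:
            return cost
        nxt = []
        if i + 1 < n:
            nxt.append(rec(i + 1, j))
        if j + 1 < m:
            nxt.append(rec(i, j + 1))
        if i + 1 < n and j + 1 < m:
            nxt.append(rec(i + 1, j + 1))
        return cost + min(nxt)

    return rec(0, 0)


def roi_mean_bruteforce(frames, mask) -> np.ndarray:
    """Per-frame per-channel ROI mean via explicit python loops."""
    frames = np.asarray(frames, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n, h, w, _ = frames.shape
    out = np.zeros((n, 3))
    for f in range(n):
        for c in range(3):
            total, count = 0.0, 0
            for i in range(h):
                for j in range(w):
                    if mask[i, j]:
                        total += frames[f, i, j, c]
                        count += 1
            out[f, c] = total / count
    return out


def dominant_frequency(x, fs) -> float:
    """Plain rectangular-window periodogram peak (zero-padded), in Hz."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    nfft = max(4096, len(x))
    spec = np.abs(np.fft.rfft(x, n=nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return float(freqs[np.argmax(spec)])
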