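"""Loop-based reference implementations used as independent oracles.

Everything here is deliberately written as explicit Python loops over pixels
and frames, independent of the vectorised/scipy paths in the package.
"""

from __future__ import annotations

import math

import numpy as np


def gaussian_weights_1d(kernel: int, sigma: float) -> np.ndarray:
    r = (kernel - 1) // 2
    w = np.array([math.exp(-(d * d) / (2.0 * sigma * sigma)) for d in range(-r, r + 1)])
    return w / w.sum()


def spatial_smooth(frames: np.ndarray, kernel: int = 3, sigma: float = 1.0) -> np.ndarray:
    """Per-frame 2-D Gaussian convolution with nearest-edge replication."""
    r = (kernel - 1) // 2
    w1 = gaussian_weights_1d(kernel, sigma)
    w2 = np.outer(w1, w1)
    T, H, W = frames.shape
    out = np.zeros_like(frames)
    for t in range(T):
        for i in range(H):
            for j in range(W):
                acc = 0.0
                for di in range(-r, r + 1):
                    for dj in range(-r, r + 1):
                        ii = min(max(i + di, 0), H - 1)
                        jj = min(max(j + dj, 0), W - 1)
                        acc += w2[di + r, dj + r] * frames[t, ii, jj]
                out[t, i, j] = acc
    return out


def temporal_smooth(frames: np.ndarray, kernel: int = 3, sigma: float = 1.0) -> np.ndarray:
    """Per-pixel 1-D Gaussian convolution along time, nearest replication."""
    r = (kernel - 1) // 2
    w = gaussian_weights_1d(kernel, sigma)
    T, H, W = frames.shape
    out = np.zeros_like(frames)
    for t in range(T):
        for i in range(H):
            for j in range(W):
                acc = 0.0
                for dt in range(-r, r + 1):
                    tt = min(max(t + dt, 0), T - 1)
                    acc += w[dt + r] * frames[tt, i, j]
                out[t, i, j] = acc
    return out


def mean_sd_maps(frames: np.ndarray, first: int, last: int):
    """Two-pass per-pixel mean and sample SD over frames [first, last)."""
    T, H, W = frames.shape
    n = last - first
    mean = np.zeros((H, W))
    sd = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            s = 0.0
            for t in range(first, last):
                s += frames[t, i, j]
            m = s / n
            ss = 0.0
            for t in range(first, last):
                ss += (frames[t, i, j] - m) ** 2
            mean[i, j] = m
            sd[i, j] = math.sqrt(ss / (n - 1))
    return mean, sd


def delta_i_over_i(frames: np.ndarray, mean_map: np.ndarray) -> np.ndarray:
    T, H, W = frames.shape
    out = np.zeros_like(frames)
    for t in range(T):
        for i in range(H):
            for j in range(W):
                out[t, i, j] = 100.0 * (frames[t, i, j] - mean_map[i, j]) / mean_map[i, j]
    return out


def count_at_least(frame: np.ndarray, threshold: float) -> int:
    n = 0
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            if frame[i, j] >= threshold:
                n += 1
    return n


def disc_pixel_count(height: int, width: int, center, radius: float) -> int:
    """Brute-force count of pixels within Euclidean radius of a site."""
    n = 0
    for i in range(height):
        for j in range(width):
            if math.dist((i, j), center) <= radius:
                n += 1
    return n


def signal_fraction_threshold(image: np.ndarray, fraction: float):
    """Exhaustive scan over sorted distinct values for the elimination cut."""
    flat = sorted(image.ravel().tolist())
    total = sum(flat)
    target = fraction * total
    if fraction == 0.0:
        return 0.0, 0.0
    candidates = sorted(set(flat))
    best = None
    for v in candidates:
        eliminated = sum(x for x in flat if x < v)
        if eliminated >= target:
            best = (v, eliminated / total)
            break
    if best is None:
        eliminated = sum(x for x in flat if x < candidates[-1])
        best = (candidates[-1], eliminated / total)
    return best


def roi_mean(image: np.ndarray, mask: np.ndarray) -> float:
    s, n = 0.0, 0
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            if mask[i, j]:
                s += image[i, j]
                n += 1
    return s / n
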