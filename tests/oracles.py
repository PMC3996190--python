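"""Independent oracles used only by the test suite.

These deliberately use different algorithms from the implementation they
check: a box-counting fractal-dimension estimator (vs Higuchi), an exact
circulant-embedding fractional-Gaussian-noise sampler (for FD = 2 - H
benchmarks), and plain-loop recomputations of vectorized operations.
"""

from __future__ import annotations

import numpy as np


def box_counting_fd(series: np.ndarray, n_scales: int = 6) -> float:
    """Box-counting dimension of the graph of a 1-D series.

    The series is rescaled to the unit square; at each scale the number of
    grid boxes touched by the linearly interpolated graph is counted, and the
    dimension is the slope of log N against log(1/box size).
    """
    y = np.asarray(series, dtype=float)
    n = y.size
    y = (y - y.min()) / max(np.ptp(y), 1e-12)
    x = np.linspace(0.0, 1.0, n)
    sizes = 2 ** np.arange(2, 2 + n_scales)
    counts = []
    for m in sizes:
        boxes = set()
        # walk each segment, marking boxes crossed (dense subsampling)
        for i in range(n - 1):
            ts = np.linspace(0, 1, 8)
            xs = x[i] + ts * (x[i + 1] - x[i])
            ys = y[i] + ts * (y[i + 1] - y[i])
            cols = np.minimum((xs * m).astype(int), m - 1)
            rows = np.minimum((ys * m).astype(int), m - 1)
            boxes.update(zip(cols.tolist(), rows.tolist()))
        counts.append(len(boxes))
    slope = np.polyfit(np.log(sizes), np.log(counts), 1)[0]
    return float(slope)


def fractional_gaussian_noise(
    hurst: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Exact fGn sample via circulant embedding (Davies-Harte).

    Cumulative sums of the returned increments form fractional Brownian
    motion with the given Hurst exponent.
    """
    k = np.arange(n)
    gamma = 0.5 * (
        np.abs(k - 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k + 1) ** (2 * hurst)
    )
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    eig = np.fft.fft(row).real
    if eig.min() < -1e-8:
        raise ValueError("circulant embedding not nonnegative definite")
    eig = np.clip(eig, 0.0, None)
    m = row.size
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    w = np.fft.fft(np.sqrt(eig / (2.0 * m)) * z)
    return w.real[:n] * np.sqrt(2.0)


def fbm_profile(hurst: float, n: int, seed: int) -> np.ndarray:
    """Fractional Brownian motion path of length n."""
    rng = np.random.default_rng(seed)
    return np.cumsum(fractional_gaussian_noise(hurst, n, rng))
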