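"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's own code paths (no FFTs, no
vectorized lag tricks) so that agreement is evidence of correctness rather
than shared bugs.
"""

from __future__ import annotations

import numpy as np
import pytest


def brute_force_msd(traj):
    """Ensemble-of-time-averages MSD by explicit double loops.

    Mirrors the contract of :func:`condkit.compute_msd` (unweighted mean of
    per-trajectory time averages, lags up to 25% of trajectory length) on
    small inputs.
    """
    per_track = []
    for pid in sorted(traj.data["particle_id"].unique()):
        grp = traj.data[traj.data["particle_id"] == pid].sort_values("frame")
        x = grp["x_um"].to_numpy()
        y = grp["y_um"].to_numpy()
        n = len(x)
        max_lag = int(np.floor(0.25 * n))
        vals = []
        for k in range(1, max_lag + 1):
            acc = 0.0
            for i in range(n - k):
                acc += (x[i + k] - x[i]) ** 2 + (y[i + k] - y[i]) ** 2
            vals.append(acc / (n - k))
        per_track.append(vals)
    longest = max(len(v) for v in per_track)
    msd = np.zeros(longest)
    counts = np.zeros(longest)
    for vals in per_track:
        for k, v in enumerate(vals):
            msd[k] += v
            counts[k] += 1
    msd /= counts
    return traj.dt * np.arange(1, longest + 1), msd, counts.astype(int)


def direct_sum_autocorrelation(image, mask):
    """Masked spatial autocovariance by direct summation over all lags.

    Returns the full correlation map normalized to 1 at zero lag, matching
    the layout of ``SACResult.corr_map`` (centre at index (H-1, W-1)).
    """
    image = np.asarray(image, dtype=float)
    m = np.asarray(mask, dtype=float)
    h, w = image.shape
    mu = (image * m).sum() / m.sum()
    a = (image - mu) * m
    cov = np.full((2 * h - 1, 2 * w - 1), np.nan)
    for du in range(-(h - 1), h):
        for dv in range(-(w - 1), w):
            r0, r1 = max(0, du), min(h, h + du)
            c0, c1 = max(0, dv), min(w, w + dv)
            a1 = a[r0:r1, c0:c1]
            a2 = a[r0 - du : r1 - du, c0 - dv : c1 - dv]
            m1 = m[r0:r1, c0:c1]
            m2 = m[r0 - du : r1 - du, c0 - dv : c1 - dv]
            pairs = (m1 * m2).sum()
            if pairs > 0.5:
                cov[h - 1 + du, w - 1 + dv] = (a1 * a2).sum() / pairs
    return cov / cov[h - 1, w - 1]


@pytest.fixture
def gaussian_blob():
    """Factory: a single Gaussian cluster on zero background, in um."""

    def make(sigma_um, pixel_size=0.2196, n=96, amplitude=100.0, noise_sd=0.0, seed=0):
        y, x = np.mgrid[0:n, 0:n] * pixel_size
        c = (n - 1) / 2 * pixel_size
        img = amplitude * np.exp(-((x - c) ** 2 + (y - c) ** 2) / (2.0 * sigma_um**2))
        if noise_sd > 0:
            img = img + np.random.default_rng(seed).normal(0, noise_sd, img.shape)
        return img

    return make
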