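"""Particle localization, trajectory linking, drift correction and MSD profiles.

Video particle tracking (VPT) nanorheology infers the material state of a
medium from the thermal motion of embedded tracer beads.  This module covers
the image-to-MSD half of that workflow:

* :func:`detect_particles` — sub-pixel localization of bright spots,
* :func:`link_trajectories` — frame-to-frame assignment into tracks,
* :func:`correct_drift` — removal of common-mode (stage/flow) motion,
* :func:`compute_msd` — time- and ensemble-averaged mean squared displacement.

All positions are carried in micrometres and times in seconds; pixel units
never cross the module boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment


class InvalidParameterError(ValueError):
    """A parameter violates an operation's stated preconditions."""


class EmptyProfileError(RuntimeError):
    """No trajectory was long enough to contribute to an MSD profile."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

TRAJECTORY_COLUMNS = ["particle_id", "frame", "t_s", "x_um", "y_um"]


@dataclass
class TrajectorySet:
    """Per-particle 2D positions over frames, in physical units.

    ``data`` is a DataFrame with columns ``particle_id, frame, t_s, x_um,
    y_um``; within a particle the frame indices strictly increase.  ``dt`` is
    the acquisition interval in seconds, ``pixel_size`` (optional) records
    provenance.
    """

    data: pd.DataFrame
    dt: float
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        missing = [c for c in TRAJECTORY_COLUMNS if c not in self.data.columns]
        if missing:
            raise InvalidParameterError(f"trajectory table missing columns {missing}")
        if not np.isfinite(self.data[["x_um", "y_um"]].to_numpy()).all():
            raise InvalidParameterError("non-finite coordinates in trajectory table")
        for pid, grp in self.data.groupby("particle_id"):
            frames = grp["frame"].to_numpy()
            if np.any(np.diff(frames) <= 0):
                raise InvalidParameterError(
                    f"frame indices not strictly increasing for particle {pid}"
                )

    @property
    def n_particles(self) -> int:
        return self.data["particle_id"].nunique()

    def positions(self, particle_id) -> np.ndarray:
        grp = self.data[self.data["particle_id"] == particle_id]
        return grp[["x_um", "y_um"]].to_numpy()

    def iter_tracks(self):
        for pid, grp in self.data.groupby("particle_id", sort=True):
            yield pid, grp.sort_values("frame")


@dataclass
class MSDProfile:
    """Lag times vs mean squared displacement with per-lag support counts."""

    lags: np.ndarray  # s, sorted ascending
    msd: np.ndarray  # um^2
    n_obs: np.ndarray  # contributing trajectories (or displacement pairs)
    averaging_mode: str = "ensemble_of_time_averages"

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_obs = np.asarray(self.n_obs, dtype=int)
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise InvalidParameterError("lags must be positive and strictly increasing")
        if np.any(self.msd < 0):
            raise InvalidParameterError("msd values must be non-negative")

    def with_floor_subtracted(self, floor_um2: float) -> "MSDProfile":
        """Return a copy with a static-localization-error floor removed.

        The floor (``4*sigma_loc^2`` for 2D tracking) adds a constant offset
        to every lag; subtracting it restores the power-law shape of the
        underlying motion.  Values are clipped at a small positive number so
        log-log fits remain defined.
        """
        corrected = np.clip(self.msd - floor_um2, 1e-12, None)
        return MSDProfile(self.lags.copy(), corrected, self.n_obs.copy(), self.averaging_mode)


# ---------------------------------------------------------------------------
# localization
# ---------------------------------------------------------------------------

def detect_particles(
    frame: np.ndarray,
    pixel_size: float,
    expected_diameter: float,
    min_intensity: float = 0.0,
) -> pd.DataFrame:
    """Localize bright spots in a single frame to sub-pixel precision.

    Candidate maxima above ``min_intensity`` are refined by an
    intensity-weighted centroid within a window of ``expected_diameter``;
    duplicates closer than half the expected diameter are merged keeping the
    brighter one.

    Returns a DataFrame with columns ``x_um, y_um, mass`` (possibly empty).
    """
    from skimage.feature import peak_local_max

    frame = np.asarray(frame, dtype=float)
    diam_px = expected_diameter / pixel_size
    if diam_px < 2:
        raise InvalidParameterError("expected_diameter must be at least 2 pixels")
    half = max(int(round(diam_px / 2)), 1)

    coords = peak_local_max(
        frame, min_distance=max(half, 1), threshold_abs=min_intensity, exclude_border=False
    )
    records = []
    for r, c in coords:
        r0, r1 = max(r - half, 0), min(r + half + 1, frame.shape[0])
        c0, c1 = max(c - half, 0), min(c + half + 1, frame.shape[1])
        win = frame[r0:r1, c0:c1]
        base = win.min()
        w = win - base  # offset so the centroid is not dragged by background
        total = w.sum()
        if total <= 0:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        r_cm = (w * rr).sum() / total
        c_cm = (w * cc).sum() / total
        records.append((c_cm * pixel_size, r_cm * pixel_size, win.sum()))

    if not records:
        return pd.DataFrame(columns=["x_um", "y_um", "mass"])

    df = pd.DataFrame(records, columns=["x_um", "y_um", "mass"])
    df = df.sort_values("mass", ascending=False).reset_index(drop=True)
    keep: list[int] = []
    min_sep = expected_diameter / 2
    for i in range(len(df)):
        xi, yi = df.loc[i, "x_um"], df.loc[i, "y_um"]
        if all(
            np.hypot(xi - df.loc[j, "x_um"], yi - df.loc[j, "y_um"]) >= min_sep for j in keep
        ):
            keep.append(i)
    return df.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def link_trajectories(
    localizations: list[pd.DataFrame],
    max_disp: float,
    memory: int = 0,
    dt: float = 1.0,
    pixel_size: float | None = None,
) -> tuple[TrajectorySet, dict]:
    """Link per-frame localizations into trajectories.

    Assignment between active tracks and new detections minimizes total
    squared displacement (Hungarian algorithm) among candidates within
    ``max_disp``; tracks missing for up to ``memory`` frames stay eligible.
    Unmatched detections start new particle ids.

    Returns the linked :class:`TrajectorySet` and a linking report dict.
    """
    if max_disp <= 0:
        raise InvalidParameterError("max_disp must be positive")

    BIG = 1e12
    next_id = 0
    # active track state: id -> (x, y, last_frame)
    active: dict[int, tuple[float, float, int]] = {}
    rows: list[tuple[int, int, float, float, float]] = []
    n_broken = 0

    for f, locs in enumerate(localizations):
        pts = (
            locs[["x_um", "y_um"]].to_numpy()
            if locs is not None and len(locs)
            else np.empty((0, 2))
        )
        ids = list(active.keys())
        assigned_det: set[int] = set()
        if ids and len(pts):
            prev = np.array([[active[i][0], active[i][1]] for i in ids])
            d2 = ((prev[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
            cost = np.where(d2 <= max_disp**2, d2, BIG)
            ri, ci = linear_sum_assignment(cost)
            for r, c in zip(ri, ci):
                if cost[r, c] >= BIG:
                    continue
                tid = ids[r]
                active[tid] = (pts[c, 0], pts[c, 1], f)
                rows.append((tid, f, f * dt, pts[c, 0], pts[c, 1]))
                assigned_det.add(c)
        for c in range(len(pts)):
            if c not in assigned_det:
                active[next_id] = (pts[c, 0], pts[c, 1], f)
                rows.append((next_id, f, f * dt, pts[c, 0], pts[c, 1]))
                next_id += 1
        # retire tracks unseen for more than `memory` frames
        for tid in list(active.keys()):
            if f - active[tid][2] > memory:
                del active[tid]
                n_broken += 1

    df = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    df = df.sort_values(["particle_id", "frame"]).reset_index(drop=True)
    traj = TrajectorySet(df, dt=dt, pixel_size=pixel_size)
    lengths = df.groupby("particle_id").size()
    report = {
        "n_frames": len(localizations),
        "n_tracks": int(len(lengths)),
        "mean_track_length": float(lengths.mean()) if len(lengths) else 0.0,
        "n_retired_mid_movie": int(n_broken),
    }
    return traj, report


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------

def correct_drift(traj: TrajectorySet) -> TrajectorySet:
    """Subtract the cumulative per-frame ensemble-median displacement.

    Relative inter-particle displacements are unchanged.  With a single
    particle this removes all of its motion; a warning is emitted.
    """
    df = traj.data.copy()
    if traj.n_particles < 2:
        warnings.warn(
            "drift correction with fewer than 2 particles removes all motion",
            stacklevel=2,
        )
    frames = np.sort(df["frame"].unique())
    frame_pos = {
        f: dict(zip(g["particle_id"], zip(g["x_um"], g["y_um"])))
        for f, g in df.groupby("frame")
    }
    drift = {frames[0]: np.zeros(2)}
    for fprev, fcur in zip(frames[:-1], frames[1:]):
        common = set(frame_pos[fprev]) & set(frame_pos[fcur])
        if common:
            steps = np.array(
                [
                    [
                        frame_pos[fcur][p][0] - frame_pos[fprev][p][0],
                        frame_pos[fcur][p][1] - frame_pos[fprev][p][1],
                    ]
                    for p in common
                ]
            )
            step = np.median(steps, axis=0)
        else:
            step = np.zeros(2)
        drift[fcur] = drift[fprev] + step

    dx = df["frame"].map(lambda f: drift[f][0])
    dy = df["frame"].map(lambda f: drift[f][1])
    df["x_um"] = df["x_um"] - dx
    df["y_um"] = df["y_um"] - dy
    return TrajectorySet(df, dt=traj.dt, pixel_size=traj.pixel_size)


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------

def _tamsd_direct(xy: np.ndarray, max_lag: int) -> np.ndarray:
    """Time-averaged MSD over all start points, by explicit differencing."""
    n = len(xy)
    out = np.empty(max_lag)
    for k in range(1, max_lag + 1):
        d = xy[k:] - xy[:-k]
        out[k - 1] = np.mean(np.einsum("ij,ij->i", d, d))
    return out

def _tamsd_fft(xy: np.ndarray, max_lag: int) -> np.ndarray:
    """FFT-based time-averaged MSD (identical estimator, O(N log N))."""
    n = len(xy)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    s2 = np.zeros(n)
    for ax in range(xy.shape[1]):
        f = np.fft.rfft(xy[:, ax], nfft)
        s2 += np.fft.irfft(f * np.conj(f), nfft)[:n].real
    d2 = (xy**2).sum(axis=1)
    # S1 recursion: S1(k) = S1(k-1) - d2[k-1] - d2[n-k]
    s1 = np.empty(n)
    s1[0] = 2.0 * d2.sum()
    q = s1[0]
    for k in range(1, n):
        q -= d2[k - 1] + d2[n - k]
        s1[k] = q
    counts = n - np.arange(n)
    msd_all = (s1 - 2.0 * s2) / counts
    return msd_all[1 : max_lag + 1]


def compute_msd(
    traj: TrajectorySet,
    max_lag_fraction: float = 0.25,
    min_length: int = 10,
    averaging_mode: str = "ensemble_of_time_averages",
    method: str = "auto",
) -> MSDProfile:
    """Ensemble MSD profile from a trajectory set.

    Each trajectory contributes its time-averaged MSD over all start points
    for lags up to ``max_lag_fraction`` of its own length; the ensemble value
    at a lag is the unweighted mean over contributing trajectories (mode
    ``ensemble_of_time_averages``) or the pair-count-weighted mean (mode
    ``all_displacements``).  Trajectories shorter than ``min_length`` frames
    or with gaps are skipped.
    """
    if not (0 < max_lag_fraction <= 0.5):
        raise InvalidParameterError("max_lag_fraction must lie in (0, 0.5]")
    if averaging_mode not in ("ensemble_of_time_averages", "all_displacements"):
        raise InvalidParameterError(f"unknown averaging_mode {averaging_mode!r}")

    per_track: list[tuple[np.ndarray, int]] = []  # (tamsd values, n frames)
    for pid, grp in traj.iter_tracks():
        frames = grp["frame"].to_numpy()
        if len(frames) < min_length or np.any(np.diff(frames) != 1):
            continue
        xy = grp[["x_um", "y_um"]].to_numpy()
        max_lag = int(np.floor(max_lag_fraction * len(xy)))
        if max_lag < 1:
            continue
        use_fft = method == "fft" or (method == "auto" and len(xy) > 512)
        vals = (_tamsd_fft if use_fft else _tamsd_direct)(xy, max_lag)
        per_track.append((vals, len(xy)))

    if not per_track:
        raise EmptyProfileError("no trajectory long enough for an MSD profile")

    longest = max(len(v) for v, _ in per_track)
    sums = np.zeros(longest)
    wsums = np.zeros(longest)
    counts = np.zeros(longest, dtype=int)
    weights = np.zeros(longest)
    for vals, n in per_track:
        k = len(vals)
        sums[:k] += vals
        counts[:k] += 1
        npairs = n - np.arange(1, k + 1)
        wsums[:k] += vals * npairs
        weights[:k] += npairs

    if averaging_mode == "ensemble_of_time_averages":
        msd = sums / counts
        n_obs = counts
    else:
        msd = wsums / weights
        n_obs = weights.astype(int)

    lags = traj.dt * np.arange(1, longest + 1)
    return MSDProfile(lags, msd, n_obs, averaging_mode)
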