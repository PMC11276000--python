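"""Synthetic data generator with known ground truth for every analysis stage.

Emulates the raw observables of a condensate-aging study: 2D tracer-bead
trajectories in Newtonian / Maxwell / Kelvin-Voigt / arrested media,
multi-channel condensate images with age-dependent core-shell cluster
morphologies, exponential FRAP recoveries, heating/cooling cloud-point
ramps with optional hysteresis, and exponential droplet-fusion force
relaxations.  Every generator is deterministic given its seed and returns
(or records) the ground-truth parameters, so each downstream stage can be
validated by parameter recovery.

Unit conventions: lengths in um, times in s (force traces in ms),
temperatures in K for physics and degrees C for ramps, viscosity in Pa s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .tracking import InvalidParameterError, TrajectorySet, TRAJECTORY_COLUMNS
from .frap import FRAPCurve
from .phase import ForceTrace, RampTrace

KB_J_PER_K = 1.380649e-23  # Boltzmann constant

MATERIAL_KINDS = ("newtonian", "maxwell", "kelvin_voigt", "arrested")


def stokes_einstein_diffusivity(
    viscosity: float, temperature: float = 298.0, bead_radius: float = 0.1
) -> float:
    """Diffusion coefficient (um^2/s) of a sphere: D = kB*T / (6*pi*eta*R).

    ``viscosity`` in Pa s, ``temperature`` in K, ``bead_radius`` in um.
    """
    if viscosity <= 0 or temperature <= 0 or bead_radius <= 0:
        raise InvalidParameterError("viscosity, temperature and bead_radius must be > 0")
    d_m2_s = KB_J_PER_K * temperature / (6.0 * np.pi * viscosity * bead_radius * 1e-6)
    return d_m2_s * 1e12  # m^2 -> um^2


@dataclass
class MaterialModel:
    """Viscoelastic medium felt by a tracer bead.

    kind:
        ``newtonian`` — free diffusion at the terminal viscosity.
        ``maxwell`` — elastic at short times, flows at long times; realized
        as the sum of an Ornstein-Uhlenbeck confined term (stationary SD
        ``confinement_sd`` per axis, correlation time ``relaxation_time``)
        and an independent free-diffusion term at the terminal viscosity
        (a Jeffreys-type construction).
        ``kelvin_voigt`` — terminally elastic; pure confined term.
        ``arrested`` — bead does not move (localization noise only).
    """

    kind: str
    viscosity: float | None = None  # Pa s, terminal (newtonian / maxwell)
    confinement_sd: float | None = None  # um per axis (maxwell / kelvin_voigt)
    relaxation_time: float | None = None  # s (maxwell crossover / KV corral time)
    temperature: float = 298.0  # K
    bead_radius: float = 0.1  # um (200 nm diameter beads)

    def __post_init__(self) -> None:
        if self.kind not in MATERIAL_KINDS:
            raise InvalidParameterError(f"unknown material kind {self.kind!r}")
        if self.temperature <= 0 or self.bead_radius <= 0:
            raise InvalidParameterError("temperature and bead_radius must be > 0")
        if self.kind in ("newtonian", "maxwell"):
            if self.viscosity is None or self.viscosity <= 0:
                raise InvalidParameterError(f"{self.kind} requires viscosity > 0")
        if self.kind in ("maxwell", "kelvin_voigt"):
            if self.confinement_sd is None or self.confinement_sd <= 0:
                raise InvalidParameterError(f"{self.kind} requires confinement_sd > 0")
            if self.relaxation_time is None or self.relaxation_time <= 0:
                raise InvalidParameterError(f"{self.kind} requires relaxation_time > 0")

    @property
    def diffusivity(self) -> float | None:
        """Terminal diffusion coefficient in um^2/s, where applicable."""
        if self.kind in ("newtonian", "maxwell"):
            return stokes_einstein_diffusivity(
                self.viscosity, self.temperature, self.bead_radius
            )
        return None


def _ou_paths(rng, n_particles, n_frames, dt, sd, tau):
    """Stationary mean-reverting (OU) paths, exact discretization, per axis."""
    phi = np.exp(-dt / tau)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    x = np.empty((n_particles, n_frames))
    x[:, 0] = rng.normal(0.0, sd, n_particles)
    shocks = rng.normal(0.0, innov_sd, (n_particles, n_frames - 1))
    for i in range(1, n_frames):
        x[:, i] = phi * x[:, i - 1] + shocks[:, i - 1]
    return x


def gen_trajectories(
    model: MaterialModel,
    n_particles: int,
    n_frames: int,
    dt: float,
    loc_noise_sd: float = 0.0,
    drift_per_frame: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
) -> TrajectorySet:
    """Simulate 2D tracer-bead trajectories in the given medium.

    Newtonian increments have per-axis variance ``2*D*dt`` with D from the
    Stokes-Einstein relation; Kelvin-Voigt positions follow a stationary
    mean-reverting process with per-axis SD ``confinement_sd``; Maxwell is
    the sum of the two; arrested beads are static.  Localization noise is
    added i.i.d. per frame and drift accumulates across frames (common to
    all particles).
    """
    if n_particles < 1 or n_frames < 2:
        raise InvalidParameterError("need n_particles >= 1 and n_frames >= 2")
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    if loc_noise_sd < 0:
        raise InvalidParameterError("loc_noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    shape = (n_particles, n_frames)
    pos = np.zeros(shape + (2,))

    if model.kind in ("newtonian", "maxwell"):
        step_sd = np.sqrt(2.0 * model.diffusivity * dt)
        for ax in range(2):
            steps = rng.normal(0.0, step_sd, (n_particles, n_frames - 1))
            pos[:, 1:, ax] += np.cumsum(steps, axis=1)
    if model.kind in ("maxwell", "kelvin_voigt"):
        for ax in range(2):
            ou = _ou_paths(
                rng, n_particles, n_frames, dt, model.confinement_sd, model.relaxation_time
            )
            pos[:, :, ax] += ou
    # arrested: positions stay at the origin (plus noise below)

    # spread particles over a field of view so linking/drift tests are realistic
    origins = rng.uniform(0.0, 50.0, (n_particles, 1, 2))
    pos += origins

    drift = np.asarray(drift_per_frame, dtype=float)
    pos += np.arange(n_frames)[None, :, None] * drift[None, None, :]
    if loc_noise_sd > 0:
        pos = pos + rng.normal(0.0, loc_noise_sd, shape + (2,))

    pid = np.repeat(np.arange(n_particles), n_frames)
    frames = np.tile(np.arange(n_frames), n_particles)
    df = pd.DataFrame(
        {
            "particle_id": pid,
            "frame": frames,
            "t_s": frames * dt,
            "x_um": pos[:, :, 0].ravel(),
            "y_um": pos[:, :, 1].ravel(),
        },
        columns=TRAJECTORY_COLUMNS,
    )
    return TrajectorySet(df, dt=dt)


# ---------------------------------------------------------------------------
# condensate images
# ---------------------------------------------------------------------------

@dataclass
class SceneSpec:
    """Imaging geometry for a synthetic condensate field.

    Pixel grid is 0-based with pixel-centre coordinates: physical position =
    index * pixel_size.  ``noise`` is ``"none"``, ``"poisson"`` or
    ``"gaussian"`` (with ``noise_sd`` in intensity units).
    """

    image_shape: tuple[int, int] = (192, 192)
    pixel_size: float = 0.2196  # um/px
    condensate_center: tuple[float, float] | None = None  # um (x, y); default centre
    condensate_radius: float = 15.0  # um
    baseline: float = 100.0  # condensate interior intensity, a.u.
    background: float = 5.0  # outside-condensate intensity, a.u.
    psf_sigma: float = 0.1  # um
    noise: str = "poisson"
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be positive")
        if self.noise not in ("none", "poisson", "gaussian"):
            raise InvalidParameterError(f"unknown noise model {self.noise!r}")
        if self.condensate_center is None:
            h, w = self.image_shape
            self.condensate_center = (
                (w - 1) / 2 * self.pixel_size,
                (h - 1) / 2 * self.pixel_size,
            )


@dataclass
class AgingLaw:
    """Monotone growth of intra-condensate cluster size/brightness with age.

    Cluster radius (Gaussian sigma, um) saturates exponentially from
    ``initial_sigma`` to ``final_sigma`` with timescale ``timescale_h``;
    cluster amplitude ramps from 0 to ``final_amplitude`` with timescale
    ``amp_timescale_h``; the cluster count is fixed at ``n_clusters``.
    """

    initial_sigma: float = 0.0  # um
    final_sigma: float = 0.6  # um
    timescale_h: float = 2.0
    final_amplitude: float = 150.0  # a.u. above condensate baseline
    amp_timescale_h: float = 1.0
    n_clusters: int = 6

    def __post_init__(self) -> None:
        if self.final_sigma < self.initial_sigma:
            raise InvalidParameterError("cluster size must be non-decreasing with age")
        if self.timescale_h <= 0 or self.amp_timescale_h <= 0:
            raise InvalidParameterError("timescales must be positive")

    def sigma_at(self, age_h: float) -> float:
        return self.initial_sigma + (self.final_sigma - self.initial_sigma) * (
            1.0 - np.exp(-age_h / self.timescale_h)
        )

    def amplitude_at(self, age_h: float) -> float:
        return self.final_amplitude * (1.0 - np.exp(-age_h / self.amp_timescale_h))


@dataclass
class ImageStack:
    """Multi-channel image time series with ground truth.

    ``data`` has shape (n_ages, n_channels, H, W); ``ground_truth`` holds one
    dict per age with the cluster parameters actually rendered.
    """

    data: np.ndarray
    ages_h: list[float]
    channels: list[str]
    pixel_size: float
    ground_truth: list[dict]


def _render_gaussians(shape, pixel_size, clusters):
    """Sum of 2D Gaussians; clusters = iterable of (cx, cy, sigma, amplitude) in um."""
    h, w = shape
    y = np.arange(h)[:, None] * pixel_size
    x = np.arange(w)[None, :] * pixel_size
    img = np.zeros(shape)
    for cx, cy, sigma, amp in clusters:
        if amp <= 0 or sigma <= 0:
            continue
        img += amp * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * sigma**2))
    return img


def gen_condensate_stack(
    spec: SceneSpec,
    aging: AgingLaw,
    ages: list[float],
    channels: tuple[str, ...] = ("rna", "scaffold"),
    anti_correlated: bool = True,
    depletion_kappa: float = 0.8,
) -> ImageStack:
    """Render a multi-channel condensate image per age.

    The RNA channel is the condensate disk plus Gaussian clusters from the
    aging law, convolved with the PSF, plus noise.  When ``anti_correlated``,
    scaffold-role channels are depleted where clusters are bright
    (baseline - kappa * cluster signal, clipped at >= 0), emulating a
    core-shell architecture in which the RNA-rich core excludes the scaffold.
    Ground-truth cluster parameters are recorded per age.
    """
    if list(ages) != sorted(ages):
        raise InvalidParameterError("ages must be sorted ascending")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    cx0, cy0 = spec.condensate_center
    y = np.arange(h)[:, None] * spec.pixel_size
    x = np.arange(w)[None, :] * spec.pixel_size
    disk = ((x - cx0) ** 2 + (y - cy0) ** 2) <= spec.condensate_radius**2

    # fixed cluster centres across ages (clusters grow in place)
    r = spec.condensate_radius * 0.6 * np.sqrt(rng.uniform(0, 1, aging.n_clusters))
    th = rng.uniform(0, 2 * np.pi, aging.n_clusters)
    centers = np.stack([cx0 + r * np.cos(th), cy0 + r * np.sin(th)], axis=1)

    psf_sigma_px = spec.psf_sigma / spec.pixel_size
    frames = np.zeros((len(ages), len(channels), h, w))
    truth: list[dict] = []
    for ai, age in enumerate(ages):
        sigma = aging.sigma_at(age)
        amp = aging.amplitude_at(age)
        clusters = [(cx, cy, sigma, amp) for cx, cy in centers] if sigma > 0 and amp > 0 else []
        cluster_img = _render_gaussians((h, w), spec.pixel_size, clusters)
        rec = {
            "age_h": age,
            "cluster_sigma_um": sigma,
            "cluster_amplitude": amp,
            "cluster_centers_um": centers.tolist() if clusters else [],
            "sub_resolution": bool(clusters) and bool(sigma < spec.pixel_size / 2),
        }
        truth.append(rec)
        for ci, role in enumerate(channels):
            if role == "rna":
                img = spec.background + spec.baseline * disk + cluster_img * disk
            else:
                depletion = depletion_kappa * cluster_img if anti_correlated else 0.0
                img = spec.background + np.clip(spec.baseline - depletion, 0.0, None) * disk
            if psf_sigma_px > 0:
                img = gaussian_filter(img, psf_sigma_px)
            if spec.noise == "poisson":
                img = rng.poisson(np.clip(img, 0, None)).astype(float)
            elif spec.noise == "gaussian" and spec.noise_sd > 0:
                img = img + rng.normal(0.0, spec.noise_sd, img.shape)
            frames[ai, ci] = img
    return ImageStack(frames, list(ages), list(channels), spec.pixel_size, truth)


# ---------------------------------------------------------------------------
# FRAP curves
# ---------------------------------------------------------------------------

def gen_frap_curve(
    mobile_fraction: float,
    tau: float,
    bleach_depth: float = 0.8,
    n_points: int = 200,
    dt: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_prebleach: int = 10,
    acquisition_bleach_rate: float = 0.0,
) -> FRAPCurve:
    """Single-exponential FRAP recovery with a pre-bleach plateau at 1.

    Post-bleach intensity: ``I(t) = (1 - bleach_depth) +
    bleach_depth * mobile_fraction * (1 - exp(-t / tau))`` plus Gaussian
    noise.  ``acquisition_bleach_rate`` (1/s) applies a common exponential
    photobleaching decay to both the ROI and the reference channel, which
    double normalization should cancel.
    """
    if not 0.0 <= mobile_fraction <= 1.0:
        raise InvalidParameterError("mobile_fraction must lie in [0, 1]")
    if tau <= 0 or dt <= 0 or n_points < 2:
        raise InvalidParameterError("tau and dt must be > 0, n_points >= 2")
    if not 0.0 < bleach_depth <= 1.0:
        raise InvalidParameterError("bleach_depth must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    t = np.concatenate(
        [np.arange(-n_prebleach, 0) * dt, np.arange(n_points) * dt]
    )
    ideal = np.where(
        t < 0,
        1.0,
        (1.0 - bleach_depth)
        + bleach_depth * mobile_fraction * (1.0 - np.exp(-np.clip(t, 0, None) / tau)),
    )
    decay = np.exp(-acquisition_bleach_rate * (t - t[0]))
    roi = ideal * decay
    reference = decay.copy()
    if noise_sd > 0:
        roi = roi + rng.normal(0.0, noise_sd, roi.shape)
    return FRAPCurve(
        time=t,
        roi_intensity=roi,
        reference_intensity=reference,
        background_intensity=np.zeros_like(t),
        truth={"mobile_fraction": mobile_fraction, "tau_s": tau, "bleach_depth": bleach_depth},
    )


# ---------------------------------------------------------------------------
# temperature ramps
# ---------------------------------------------------------------------------

@dataclass
class RampExperiment:
    """A heating/cooling leg pair with the ground truth used to build it."""

    heating: RampTrace
    cooling: RampTrace
    truth: dict


def gen_ramp_trace(
    true_lcpt: float | None,
    reversible: bool,
    t_range: tuple[float, float] = (2.0, 80.0),
    n_points: int = 157,
    noise_sd: float = 0.02,
    hysteresis_offset: float = 1.0,
    seed: int = 0,
    transition_width: float = 0.15,
    amplitude: float = 1.0,
    baseline: float = 0.05,
    condition: dict | None = None,
) -> RampExperiment:
    """Sigmoidal cloud-point trace over a heating leg plus a cooling leg.

    The heating leg steps from ``baseline`` to ``baseline + amplitude``
    centred at ``true_lcpt`` (or stays flat when ``true_lcpt`` is None /
    outside ``t_range``: no transition).  The cooling leg returns to baseline
    when ``reversible``, otherwise stays elevated by ``hysteresis_offset``
    at the end of cooling.
    """
    if n_points < 8:
        raise InvalidParameterError("n_points must be at least 8")
    if transition_width <= 0:
        raise InvalidParameterError("transition_width must be positive")
    rng = np.random.default_rng(seed)
    t_lo, t_hi = t_range
    temps_up = np.linspace(t_lo, t_hi, n_points)
    temps_down = temps_up[::-1].copy()

    def sigmoid(temp):
        return 1.0 / (1.0 + np.exp(-(temp - true_lcpt) / transition_width))

    in_range = true_lcpt is not None and t_lo < true_lcpt < t_hi
    if in_range:
        heat = baseline + amplitude * sigmoid(temps_up)
        if reversible:
            cool = baseline + amplitude * sigmoid(temps_down)
        else:
            off = np.clip(hysteresis_offset, 0.0, amplitude)
            cool = baseline + off + (amplitude - off) * sigmoid(temps_down)
    else:
        heat = np.full(n_points, baseline)
        cool = np.full(n_points, baseline)
    if noise_sd > 0:
        heat = heat + rng.normal(0.0, noise_sd, n_points)
        cool = cool + rng.normal(0.0, noise_sd, n_points)

    cond = condition or {}
    return RampExperiment(
        heating=RampTrace("heating", temps_up, heat, cond),
        cooling=RampTrace("cooling", temps_down, cool, cond),
        truth={
            "true_lcpt_c": true_lcpt if in_range else None,
            "reversible": bool(reversible),
            "hysteresis_offset": hysteresis_offset if (in_range and not reversible) else 0.0,
        },
    )


# ---------------------------------------------------------------------------
# fusion force traces
# ---------------------------------------------------------------------------

def gen_fusion_trace(
    tau: float,
    diameters: tuple[float, float],
    n_points: int = 400,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    f0: float = 1.0,
    f_inf: float = 0.0,
) -> ForceTrace:
    """Exponential force relaxation after droplet contact.

    ``force(t) = f_inf + (f0 - f_inf) * exp(-t / tau)`` plus Gaussian noise;
    ``tau`` and ``dt`` in ms, droplet ``diameters`` in um (recorded as ground
    truth for downstream size normalization).
    """
    if tau <= 0 or dt <= 0 or n_points < 4:
        raise InvalidParameterError("tau and dt must be > 0, n_points >= 4")
    if any(d <= 0 for d in diameters):
        raise InvalidParameterError("droplet diameters must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(n_points) * dt
    force = f_inf + (f0 - f_inf) * np.exp(-t / tau)
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, n_points)
    return ForceTrace(
        time_ms=t,
        force=force,
        diameters_um=tuple(diameters),
        truth={"tau_ms": tau, "diameters_um": tuple(diameters)},
    )
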