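"""Viscoelastic interpretation of MSD profiles.

Classifies the material state sampled by a tracer bead (Newtonian liquid,
viscoelastic fluid, Kelvin-Voigt solid, or fully arrested) from the shape of
its MSD profile, and extracts the terminal viscosity from the long-lag
diffusive regime via the Stokes-Einstein relation.

The log-log slope alpha of MSD(tau) is the primary diagnostic: alpha ~ 1 at
all lags for a Newtonian liquid; sub-linear at short lags crossing over to
~1 for a Maxwell-type viscoelastic fluid; ~0 at long lags (a plateau) for a
Kelvin-Voigt solid; and flat at the static localization-error floor for an
arrested bead.  Slope thresholds are configurable; defaults are 0.8 (fluid)
and 0.2 (solid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .tracking import InvalidParameterError, MSDProfile

KB_J_PER_K = 1.380649e-23


class FitDomainError(ValueError):
    """The requested fit window contains unusable data."""


class TerminalRegimeError(RuntimeError):
    """The MSD never reaches a diffusive (alpha ~ 1) terminal regime."""


@dataclass
class ClassifierConfig:
    """Thresholds and windows for material-state classification.

    ``static_error_floor`` is the localization-noise MSD offset
    (``4*sigma_loc^2`` in um^2, 2D convention), typically calibrated from
    arrested control beads; when given it is subtracted before slopes are
    measured and used for the arrested test.  Window values are lag ranges
    in seconds; ``None`` means the default (first decade of lags for
    alpha_short, last decade for alpha_long).
    """

    alpha_fluid: float = 0.8
    alpha_solid: float = 0.2
    static_error_floor: float | None = None  # um^2
    floor_factor: float = 1.5
    short_window: tuple[float, float] | None = None
    long_window: tuple[float, float] | None = None


@dataclass
class RheologyResult:
    material_class: str  # newtonian | viscoelastic_fluid | kelvin_voigt_solid | arrested
    alpha_short: float
    alpha_long: float
    D_terminal: float | None = None  # um^2/s
    eta_terminal: float | None = None  # Pa s
    plateau: float | None = None  # um^2, Kelvin-Voigt only
    fit_windows: dict = field(default_factory=dict)
    goodness: dict = field(default_factory=dict)
    low_confidence: bool = False


def _window(profile: MSDProfile, lag_window) -> np.ndarray:
    lo, hi = lag_window
    return (profile.lags >= lo) & (profile.lags <= hi)


def fit_loglog_slope(
    profile: MSDProfile, lag_window: tuple[float, float]
) -> tuple[float, float, float]:
    """Least-squares slope of log(MSD) vs log(lag) over a lag window.

    Returns ``(alpha, prefactor, stderr)`` where MSD ~ prefactor * lag**alpha.
    """
    sel = _window(profile, lag_window)
    if sel.sum() < 4:
        raise FitDomainError("need at least 4 lags inside the fit window")
    if np.any(profile.msd[sel] <= 0):
        raise FitDomainError("MSD must be positive throughout the fit window")
    res = stats.linregress(np.log(profile.lags[sel]), np.log(profile.msd[sel]))
    return float(res.slope), float(np.exp(res.intercept)), float(res.stderr)


def default_windows(profile: MSDProfile) -> tuple[tuple[float, float], tuple[float, float]]:
    """First decade of lags (short) and last decade (long)."""
    lo, hi = profile.lags[0], profile.lags[-1]
    return (lo, min(10.0 * lo, hi)), (max(hi / 10.0, lo), hi)


def terminal_viscosity(
    profile: MSDProfile,
    bead_radius: float = 0.1,
    temperature: float = 298.0,
    terminal_window: tuple[float, float] | None = None,
    alpha_gate: tuple[float, float] = (0.8, 1.2),
) -> tuple[float, float]:
    """Terminal diffusivity and viscosity from the long-lag diffusive regime.

    The log-log slope over ``terminal_window`` (default: last decade of
    lags) must fall inside ``alpha_gate`` — otherwise the bead never reached
    free diffusion and :class:`TerminalRegimeError` is raised (classify the
    material instead).  D is the ordinary least-squares slope of MSD vs lag
    over the window divided by 4 (2D convention, insensitive to any constant
    static-error offset); eta = kB*T / (6*pi*R*D).
    """
    if terminal_window is None:
        terminal_window = default_windows(profile)[1]
    alpha, _, _ = fit_loglog_slope(profile, terminal_window)
    if not (alpha_gate[0] <= alpha <= alpha_gate[1]):
        raise TerminalRegimeError(
            f"no terminal viscosity: log-log slope {alpha:.2f} over "
            f"{terminal_window} is outside {alpha_gate}; classify the material instead"
        )
    sel = _window(profile, terminal_window)
    res = stats.linregress(profile.lags[sel], profile.msd[sel])
    d_terminal = res.slope / 4.0
    if d_terminal <= 0:
        raise TerminalRegimeError("non-positive MSD slope in terminal window")
    eta = KB_J_PER_K * temperature / (6.0 * np.pi * bead_radius * 1e-6 * d_terminal * 1e-12)
    return float(d_terminal), float(eta)


def classify_material(
    profile: MSDProfile, thresholds: ClassifierConfig | None = None
) -> RheologyResult:
    """Assign a material class from the MSD shape.

    Decision rule (on floor-corrected slopes when a static-error floor is
    configured):

    * everywhere at/below the static-error floor        -> ``arrested``
    * alpha_long >= alpha_fluid and alpha_short >= ...  -> ``newtonian``
    * alpha_long >= alpha_fluid, alpha_short below      -> ``viscoelastic_fluid``
    * alpha_long <  alpha_solid with a plateau above
      the floor                                         -> ``kelvin_voigt_solid``
    * intermediate alpha_long                           -> ``viscoelastic_fluid``
      flagged low-confidence
    """
    cfg = thresholds or ClassifierConfig()
    if profile.lags[-1] / profile.lags[0] < 10.0:
        raise InvalidParameterError("profile must span at least one decade of lags")

    floor = cfg.static_error_floor
    if floor is not None and np.all(profile.msd <= cfg.floor_factor * floor):
        short_w, long_w = default_windows(profile)
        return RheologyResult(
            "arrested",
            alpha_short=0.0,
            alpha_long=0.0,
            fit_windows={"short": short_w, "long": long_w},
            goodness={"max_msd": float(profile.msd.max()), "floor": floor},
        )

    work = profile if floor is None else profile.with_floor_subtracted(floor)
    short_default, long_default = default_windows(work)
    short_w = cfg.short_window or short_default
    long_w = cfg.long_window or long_default
    alpha_short, _, se_s = fit_loglog_slope(work, short_w)
    alpha_long, _, se_l = fit_loglog_slope(work, long_w)
    plateau_value = float(np.mean(work.msd[_window(work, long_w)]))

    result = RheologyResult(
        "viscoelastic_fluid",
        alpha_short=alpha_short,
        alpha_long=alpha_long,
        fit_windows={"short": short_w, "long": long_w},
        goodness={"alpha_short_se": se_s, "alpha_long_se": se_l},
    )
    if alpha_long >= cfg.alpha_fluid:
        result.material_class = (
            "newtonian" if alpha_short >= cfg.alpha_fluid else "viscoelastic_fluid"
        )
    elif alpha_long < cfg.alpha_solid and (
        floor is None or plateau_value > cfg.floor_factor * floor
    ):
        result.material_class = "kelvin_voigt_solid"
        result.plateau = plateau_value
    else:
        result.material_class = "viscoelastic_fluid"
        result.low_confidence = True
    return result


def estimate_static_floor(arrested_profile: MSDProfile, n_lags: int = 5) -> float:
    """Static-error MSD floor from an arrested control: mean short-lag MSD."""
    return float(np.mean(arrested_profile.msd[: max(1, n_lags)]))
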