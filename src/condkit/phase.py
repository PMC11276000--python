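"""RNA state diagrams from temperature ramps, and droplet-fusion relaxation.

Dilute RNA solutions can phase separate on heating (LCST-type behaviour)
with a lower cloud point temperature (LCPT), and the dense phase may
additionally percolate — form a system-spanning physically cross-linked RNA
network — which makes the condensation irreversible on cooling.  This
module detects cloud points on heating legs, classifies heating/cooling
pairs as reversible or irreversible, assembles per-condition classifications
into a state diagram over a cofactor (Mg2+) grid with a percolation
boundary, and fits exponential force-relaxation traces from optical-tweezer
droplet fusion, reporting the relaxation time normalized by droplet size
(ms/um).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

from .tracking import InvalidParameterError


@dataclass
class RampTrace:
    """One leg of a temperature ramp: monotone temperature vs signal."""

    leg: str  # "heating" | "cooling"
    temperature: np.ndarray  # degrees C
    signal: np.ndarray  # a.u. (turbidity / condensate count / area fraction)
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.leg not in ("heating", "cooling"):
            raise InvalidParameterError("leg must be 'heating' or 'cooling'")
        d = np.diff(self.temperature)
        if self.leg == "heating" and np.any(d <= 0):
            raise InvalidParameterError("heating leg temperature must increase")
        if self.leg == "cooling" and np.any(d >= 0):
            raise InvalidParameterError("cooling leg temperature must decrease")


@dataclass
class StatePoint:
    """Phase classification of one experimental condition."""

    condition: dict  # e.g. {"mg_mM": 6.25, "rna": "terra10"}
    classification: str  # "soluble" | "reversible_ps" | "percolated"
    lcpt: float | None = None  # degrees C, present iff a transition was detected
    hysteresis: float = 0.0  # a.u.


@dataclass
class StateDiagram:
    points: list[StatePoint]
    percolation_boundary_mM: float | None
    reversible_window_mM: tuple[float, float] | None
    monotone_consistent: bool


@dataclass
class ForceTrace:
    time_ms: np.ndarray
    force: np.ndarray
    diameters_um: tuple[float, float]
    truth: dict | None = None


@dataclass
class FusionFit:
    tau_ms: float
    f_contact: float
    f_relaxed: float
    normalized_tau_ms_per_um: float | None  # tau / mean droplet diameter
    converged: bool
    flags: list[str] = field(default_factory=list)


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(y, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")[: len(y)]


def detect_cloud_point(
    heating: RampTrace,
    k: float = 5.0,
    baseline_fraction: float = 0.2,
    smooth_window: int = 3,
    persistence: int = 3,
    rel_floor: float = 0.25,
) -> float | None:
    """LCPT = temperature of the first sustained ``baseline + k * sd`` crossing.

    The baseline is the first ``baseline_fraction`` of the (lightly
    smoothed) heating leg.  The threshold is never allowed below
    ``rel_floor`` of the trace's dynamic range above baseline, so that on
    (nearly) noiseless traces the crossing is located on the rising edge
    rather than in the numerical tail of the transition.  A crossing only
    counts when the signal stays above threshold for ``persistence``
    consecutive samples, which rejects isolated noise excursions; the
    crossing temperature is refined by linear interpolation between the
    bracketing samples.  Returns None when the trace never crosses (soluble
    at all temperatures), including the zero-variance flat case.
    """
    if heating.leg != "heating":
        raise InvalidParameterError("detect_cloud_point expects the heating leg")
    if len(heating.signal) < 8:
        raise InvalidParameterError("heating leg needs at least 8 points")
    sig = _smooth(heating.signal, smooth_window)
    n_base = max(int(len(sig) * baseline_fraction), 3)
    base = sig[:n_base]
    dyn = max(np.percentile(sig, 95) - base.mean(), 0.0)
    threshold = base.mean() + max(k * base.std(ddof=1), rel_floor * dyn)
    above = sig > threshold
    above[:n_base] = False
    run = 0
    i = None
    for j, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= min(persistence, len(sig) - n_base):
            i = j - run + 1
            break
    if i is None:
        return None
    if i == 0:
        return float(heating.temperature[0])
    s0, s1 = sig[i - 1], sig[i]
    t0, t1 = heating.temperature[i - 1], heating.temperature[i]
    frac = (threshold - s0) / (s1 - s0) if s1 > s0 else 0.0
    return float(t0 + frac * (t1 - t0))


def assess_reversibility(
    heating: RampTrace, cooling: RampTrace, tol: float = 0.1, tail_fraction: float = 0.05
) -> tuple[str, float]:
    """Compare the end-of-cooling signal with the heating baseline.

    Irreversible iff the signal at the end of cooling exceeds the heating
    baseline by strictly more than ``tol`` (a hysteresis exactly equal to
    ``tol`` counts as reversible).  Returns ``(classification, hysteresis)``.
    """
    if heating.leg != "heating" or cooling.leg != "cooling":
        raise InvalidParameterError("expected one heating and one cooling leg")
    if cooling.temperature[-1] > heating.temperature[0] + 1e-9:
        raise InvalidParameterError("cooling must end at/below the heating start temperature")
    overlap_lo = max(heating.temperature[0], cooling.temperature[-1])
    overlap_hi = min(heating.temperature[-1], cooling.temperature[0])
    if overlap_hi <= overlap_lo:
        raise InvalidParameterError("heating and cooling legs cover disjoint temperature ranges")

    n_base = max(int(len(heating.signal) * 0.2), 3)
    baseline = float(np.mean(heating.signal[:n_base]))
    n_tail = max(int(len(cooling.signal) * tail_fraction), 3)
    end_cool = float(np.mean(cooling.signal[-n_tail:]))
    hysteresis = end_cool - baseline
    # strict inequality with a float-roundoff guard: exactly-at-tolerance
    # counts as reversible
    irreversible = hysteresis - tol > 1e-9 * max(1.0, abs(tol))
    return ("irreversible" if irreversible else "reversible", hysteresis)


def classify_state(
    heating: RampTrace,
    cooling: RampTrace,
    pre_percolated: bool = False,
    k: float = 5.0,
    tol: float = 0.1,
) -> StatePoint:
    """Full per-condition classification: soluble / reversible_ps / percolated.

    ``pre_percolated`` marks conditions where clusters already exist at the
    lowest temperature (supplied as an experimental annotation, not inferred
    from the trace).
    """
    condition = dict(heating.condition)
    if pre_percolated:
        return StatePoint(condition, "percolated", lcpt=None, hysteresis=np.nan)
    lcpt = detect_cloud_point(heating, k=k)
    if lcpt is None:
        return StatePoint(condition, "soluble")
    verdict, hyst = assess_reversibility(heating, cooling, tol=tol)
    cls = "reversible_ps" if verdict == "reversible" else "percolated"
    return StatePoint(condition, cls, lcpt=lcpt, hysteresis=hyst)


_ORDER = {"soluble": 0, "reversible_ps": 1, "percolated": 2}


def build_state_diagram(points: list[StatePoint], grid_key: str = "mg_mM") -> StateDiagram:
    """Assemble per-condition classifications over a Mg2+ grid.

    The percolation boundary is the midpoint between the highest Mg2+
    classified soluble/reversible and the lowest classified percolated.
    A non-monotone classification sequence along Mg2+ is still assembled but
    flagged inconsistent.
    """
    if len({p.condition.get(grid_key) for p in points}) < 2:
        raise InvalidParameterError(f"need at least 2 distinct {grid_key} values")
    pts = sorted(points, key=lambda p: p.condition[grid_key])
    ranks = [_ORDER[p.classification] for p in pts]
    consistent = all(a <= b for a, b in zip(ranks, ranks[1:]))

    perc = [p.condition[grid_key] for p in pts if p.classification == "percolated"]
    nonperc = [p.condition[grid_key] for p in pts if p.classification != "percolated"]
    boundary = None
    if perc:
        lowest_perc = min(perc)
        below = [g for g in nonperc if g < lowest_perc]
        boundary = (max(below) + lowest_perc) / 2.0 if below else lowest_perc

    rev = [p.condition[grid_key] for p in pts if p.classification == "reversible_ps"]
    window = (min(rev), max(rev)) if rev else None
    return StateDiagram(pts, boundary, window, consistent)


def _relax(t, f_relaxed, delta_f, tau):
    return f_relaxed + delta_f * np.exp(-t / tau)


def fit_fusion_relaxation(trace: ForceTrace, diameters: tuple[float, float] | None = None) -> FusionFit:
    """Fit ``F(t) = F_inf + dF * exp(-t/tau)`` to a fusion force trace.

    The relaxation time is normalized by the arithmetic-mean droplet
    diameter (ms/um).  Fits whose tau exceeds a third of the trace span are
    flagged non-converged and report no normalized value (the trace does not
    constrain the relaxation).
    """
    diam = diameters or trace.diameters_um
    if any(d <= 0 for d in diam):
        raise InvalidParameterError("droplet diameters must be positive")
    t = np.asarray(trace.time_ms, dtype=float)
    y = np.asarray(trace.force, dtype=float)

    span = t[-1] - t[0]
    delta0 = y[0] - y[-1]
    model = Model(_relax)
    params = model.make_params(
        f_relaxed=y[-1], delta_f=delta0 if abs(delta0) > 1e-12 else 1e-3, tau=max(span / 5.0, 1e-6)
    )
    params["tau"].set(min=1e-9)
    try:
        out = model.fit(y, params, t=t)
        ok = bool(out.success)
    except Exception:
        ok = False
    if not ok or not np.isfinite(out.params["tau"].value):
        return FusionFit(np.nan, np.nan, np.nan, None, False, ["no_convergence"])

    tau = float(out.params["tau"].value)
    flags: list[str] = []
    if tau > span / 3.0:
        # flat/under-sampled relaxation: tau not constrained by the window
        return FusionFit(tau, np.nan, np.nan, None, False, ["tau_exceeds_span/3"])
    f_rel = float(out.params["f_relaxed"].value)
    dmean = float(np.mean(diam))
    return FusionFit(
        tau_ms=tau,
        f_contact=f_rel + float(out.params["delta_f"].value),
        f_relaxed=f_rel,
        normalized_tau_ms_per_um=tau / dmean,
        converged=True,
        flags=flags,
    )
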