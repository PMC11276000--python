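"""Interchange formats, run configuration, and the aging-pipeline driver.

All tables are plain CSV with unit-bearing headers (``t_s``, ``x_um``,
``lag_s``, ``msd_um2``, ``temperature_C``, ``t_ms`` ...), images are TIFF,
and results are JSON that embeds the resolved configuration and package
version so every output is reproducible from its own metadata.  Floats are
written with 17 significant digits so write-then-read round-trips are exact.

:func:`run_aging_pipeline` composes the analysis stages over a condensate
age series — spatial-autocorrelation cluster size, cluster fraction,
channel-pair Pearson correlation, MSD-based material classification and
terminal viscosity, and FRAP — either on supplied inputs or on synthetic
scenarios with known ground truth (``--simulate``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .tracking import InvalidParameterError, TrajectorySet, MSDProfile, compute_msd
from . import rheology as _rheo
from . import sac as _sac
from . import frap as _frap
from . import phase as _phase
from . import synthgen as _gen

_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# CSV / TIFF / JSON
# ---------------------------------------------------------------------------

def write_trajectories_csv(traj: TrajectorySet, path) -> None:
    traj.data.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectories_csv(path, pixel_size: float | None = None) -> TrajectorySet:
    df = pd.read_csv(path, float_precision="round_trip")
    t = np.sort(df["t_s"].unique())
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return TrajectorySet(df, dt=dt, pixel_size=pixel_size)


def write_msd_csv(profile: MSDProfile, path) -> None:
    pd.DataFrame(
        {"lag_s": profile.lags, "msd_um2": profile.msd, "n_obs": profile.n_obs}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_msd_csv(path, averaging_mode: str = "ensemble_of_time_averages") -> MSDProfile:
    df = pd.read_csv(path, float_precision="round_trip")
    return MSDProfile(
        df["lag_s"].to_numpy(), df["msd_um2"].to_numpy(), df["n_obs"].to_numpy(), averaging_mode
    )


def write_sac_csv(result: _sac.SACResult, path) -> None:
    pd.DataFrame({"lag_um": result.radial_lags, "corr": result.radial_corr}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def write_frap_csv(curve: _frap.FRAPCurve, path) -> None:
    cols = {"t_s": curve.time, "roi": curve.roi_intensity}
    if curve.reference_intensity is not None:
        cols["reference"] = curve.reference_intensity
    if curve.background_intensity is not None:
        cols["background"] = curve.background_intensity
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_frap_csv(path) -> _frap.FRAPCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    return _frap.FRAPCurve(
        df["t_s"].to_numpy(),
        df["roi"].to_numpy(),
        df["reference"].to_numpy() if "reference" in df else None,
        df["background"].to_numpy() if "background" in df else None,
    )


def write_ramp_csv(heating: _phase.RampTrace, cooling: _phase.RampTrace, path) -> None:
    df = pd.DataFrame(
        {
            "temperature_C": np.concatenate([heating.temperature, cooling.temperature]),
            "signal": np.concatenate([heating.signal, cooling.signal]),
            "leg": ["heating"] * len(heating.signal) + ["cooling"] * len(cooling.signal),
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_ramp_csv(path, condition: dict | None = None):
    df = pd.read_csv(path, float_precision="round_trip")
    legs = {}
    for leg in ("heating", "cooling"):
        sub = df[df["leg"] == leg]
        if len(sub):
            legs[leg] = _phase.RampTrace(
                leg, sub["temperature_C"].to_numpy(), sub["signal"].to_numpy(), condition or {}
            )
    return legs.get("heating"), legs.get("cooling")


def write_force_csv(trace: _phase.ForceTrace, path) -> None:
    pd.DataFrame({"t_ms": trace.time_ms, "force_pN": trace.force}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_force_csv(path, diameters_um=(1.0, 1.0)) -> _phase.ForceTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    return _phase.ForceTrace(df["t_ms"].to_numpy(), df["force_pN"].to_numpy(), tuple(diameters_um))


def write_tiff_stack(stack: _gen.ImageStack, path) -> None:
    """Multi-page TIFF (ages x channels collapsed to pages) + JSON sidecar."""
    path = Path(path)
    n_ages, n_ch, h, w = stack.data.shape
    tifffile.imwrite(
        path,
        stack.data.reshape(n_ages * n_ch, h, w).astype(np.float64),
        photometric="minisblack",
    )
    sidecar = {
        "ages_h": stack.ages_h,
        "channels": stack.channels,
        "pixel_size_um": stack.pixel_size,
        "ground_truth": stack.ground_truth,
    }
    path.with_suffix(".json").write_text(json.dumps(_jsonable(sidecar), indent=2))


def read_tiff_stack(path) -> _gen.ImageStack:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    pages = tifffile.imread(path)
    n_ages, n_ch = len(meta["ages_h"]), len(meta["channels"])
    data = np.asarray(pages).reshape(n_ages, n_ch, *pages.shape[-2:])
    return _gen.ImageStack(
        data, meta["ages_h"], meta["channels"], meta["pixel_size_um"], meta["ground_truth"]
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_results_json(results: dict, path, config: "RunConfig | dict | None" = None) -> None:
    """Write analysis results with the resolved config and package version."""
    payload = {
        "condkit_version": __version__,
        "config": _jsonable(dataclasses.asdict(config) if dataclasses.is_dataclass(config) else (config or {})),
        "results": _jsonable(results),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved parameters for a pipeline run (all units explicit)."""

    scenario: str = "wt"  # "wt" (percolating RNA) | "mut" (non-percolating control)
    ages_h: list[float] = field(default_factory=lambda: [0.25, 1.0, 2.0, 4.0, 8.0])
    seed: int = 0
    simulate: bool = True
    out_dir: str | None = None
    # units / hardware
    pixel_size_um: float = 0.2196
    bead_radius_um: float = 0.1
    temperature_K: float = 298.0
    # tracking / rheology
    n_particles: int = 60
    n_frames: int = 300
    loc_noise_sd_um: float = 0.02
    max_lag_fraction: float = 0.25
    # frap
    include_frap: bool = True
    save_figures: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# Synthetic scenarios for --simulate.  "wt" emulates a strongly percolating
# G-quadruplex-forming repeat RNA whose intra-condensate clusters grow with
# age and stiffen the medium to full dynamical arrest; "mut" emulates a
# G-to-U substituted control that never clusters and stays fluid.
def _wt_material(age_h: float) -> tuple[_gen.MaterialModel, float]:
    if age_h < 0.5:
        return _gen.MaterialModel("maxwell", viscosity=35.2, confinement_sd=0.01, relaxation_time=1.0), 1.0
    if age_h < 1.5:
        return _gen.MaterialModel("maxwell", viscosity=90.0, confinement_sd=0.01, relaxation_time=1.0), 2.0
    if age_h < 3.0:
        return _gen.MaterialModel("maxwell", viscosity=250.0, confinement_sd=0.01, relaxation_time=1.0), 5.0
    if age_h < 6.0:
        return _gen.MaterialModel("kelvin_voigt", confinement_sd=0.04, relaxation_time=1.0), 5.0
    return _gen.MaterialModel("arrested"), 5.0


def _mut_material(age_h: float) -> tuple[_gen.MaterialModel, float]:
    return _gen.MaterialModel("maxwell", viscosity=21.5, confinement_sd=0.01, relaxation_time=1.0), 1.0


SCENARIOS = {
    "wt": {
        "material": _wt_material,
        "aging": lambda: _gen.AgingLaw(
            initial_sigma=0.05, final_sigma=0.6, timescale_h=2.0,
            final_amplitude=150.0, amp_timescale_h=1.0, n_clusters=6,
        ),
        "frap_mobile": lambda age: 0.9 * np.exp(-age / 5.0) + 0.1,
    },
    "mut": {
        "material": _mut_material,
        "aging": lambda: _gen.AgingLaw(
            initial_sigma=0.0, final_sigma=0.0, timescale_h=2.0,
            final_amplitude=0.0, amp_timescale_h=1.0, n_clusters=0,
        ),
        "frap_mobile": lambda age: 0.85,
    },
}


def _masked_pearson(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    from scipy.stats import pearsonr

    return float(pearsonr(a[mask], b[mask])[0])


def run_aging_pipeline(config: RunConfig) -> dict:
    """Run the full per-age analysis battery and return a report dict.

    For each age: SAC cluster size (+floor flag), intensity-based cluster
    fraction, whole-condensate channel-pair Pearson r, ensemble MSD with
    material classification and terminal viscosity where the bead reaches
    free diffusion, and (optionally) a FRAP fit.  Stage failures are
    recorded per age and the pipeline continues; the report carries an
    ``ok`` flag.
    """
    if not config.ages_h:
        raise InvalidParameterError("empty age list")
    if list(config.ages_h) != sorted(config.ages_h):
        raise InvalidParameterError("ages must be sorted ascending")
    if not config.simulate:
        raise InvalidParameterError(
            "only --simulate runs are supported without experimental inputs"
        )
    scenario = SCENARIOS.get(config.scenario)
    if scenario is None:
        raise InvalidParameterError(f"unknown scenario {config.scenario!r}")

    rng = np.random.default_rng(config.seed)
    spec = _gen.SceneSpec(pixel_size=config.pixel_size_um, seed=int(rng.integers(2**31)))
    stack = _gen.gen_condensate_stack(spec, scenario["aging"](), list(config.ages_h))
    floor_um2 = 4.0 * config.loc_noise_sd_um**2

    per_age: list[dict] = []
    errors: list[str] = []
    for ai, age in enumerate(config.ages_h):
        rec: dict = {"age_h": age}
        rna = stack.data[ai, 0]
        scaffold = stack.data[ai, 1]
        try:
            mask = _sac.condensate_mask_otsu(rna)
            res = _sac.cluster_size(_sac.spatial_autocorrelation(rna, config.pixel_size_um, mask))
            rec["cluster_size_um"] = res.cluster_size
            rec["at_floor"] = res.at_floor
            rec["cluster_fraction"] = _sac.cluster_fraction(rna, mask)
            rec["pearson_r"] = _masked_pearson(rna, scaffold, mask)
        except Exception as exc:  # noqa: BLE001 - per-age failures are recorded
            errors.append(f"imaging stage failed at age {age}: {exc}")

        try:
            model, dt = scenario["material"](age)
            traj = _gen.gen_trajectories(
                model,
                config.n_particles,
                config.n_frames,
                dt,
                loc_noise_sd=config.loc_noise_sd_um,
                seed=int(rng.integers(2**31)),
            )
            profile = compute_msd(traj, max_lag_fraction=config.max_lag_fraction)
            cls = _rheo.classify_material(
                profile, _rheo.ClassifierConfig(static_error_floor=floor_um2)
            )
            rec["material_class"] = cls.material_class
            rec["alpha_long"] = cls.alpha_long
            rec["true_material"] = model.kind
            try:
                corrected = profile.with_floor_subtracted(floor_um2)
                d_term, eta = _rheo.terminal_viscosity(
                    corrected, config.bead_radius_um, config.temperature_K
                )
                rec["eta_terminal_Pa_s"] = eta
                rec["D_terminal_um2_s"] = d_term
            except _rheo.TerminalRegimeError:
                rec["eta_terminal_Pa_s"] = None
        except Exception as exc:  # noqa: BLE001
            errors.append(f"rheology stage failed at age {age}: {exc}")

        if config.include_frap:
            try:
                curve = _gen.gen_frap_curve(
                    mobile_fraction=float(scenario["frap_mobile"](age)),
                    tau=10.0,
                    noise_sd=0.01,
                    seed=int(rng.integers(2**31)),
                )
                fit = _frap.fit_frap(_frap.normalize_frap(curve))
                rec["frap_mobile_fraction"] = fit.mobile_fraction
                rec["frap_t_half_s"] = fit.t_half
            except Exception as exc:  # noqa: BLE001
                errors.append(f"frap stage failed at age {age}: {exc}")
        per_age.append(rec)

    report = {
        "scenario": config.scenario,
        "per_age": per_age,
        "errors": errors,
        "ok": not errors,
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_results_json(report, out / "aging_report.json", config)
        pd.DataFrame(per_age).to_csv(out / "aging_report.csv", index=False, float_format=_FLOAT_FMT)
        if config.save_figures:
            _save_pipeline_figures(report, stack, out)
    return report


def _save_pipeline_figures(report: dict, stack: _gen.ImageStack, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ages = [r["age_h"] for r in report["per_age"]]
    sizes = [r.get("cluster_size_um") for r in report["per_age"]]
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].plot(ages, sizes, "o-")
    axes[0].set_xlabel("age (h)")
    axes[0].set_ylabel("SAC cluster size (um)")
    etas = [r.get("eta_terminal_Pa_s") for r in report["per_age"]]
    axes[1].plot(ages, [e if e else np.nan for e in etas], "s-")
    axes[1].set_yscale("log")
    axes[1].set_xlabel("age (h)")
    axes[1].set_ylabel("terminal viscosity (Pa s)")
    fig.tight_layout()
    fig.savefig(out / "aging_summary.png", dpi=120)
    plt.close(fig)
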