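"""Study orchestration: tensile fit → six-step simulation → reports.

:func:`run_degradation_study` strings the whole analysis together the
way the bench campaign was organised: fit the degradation surface to a
tensile grid, run crimp → recoil → expand → recoil → fatigue on the
scaffold, then step degradation to each follow-up time (default 10, 20
and 30 days), extracting a radial-strength curve, the degradation map
and its maximum at every time point. Month-scale molecular-weight
kinetics are fitted alongside. Everything is deterministic for a fixed
config + seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, SolverError, StentDegError
from .kinetics import fit_first_order, predict_retention
from .material import build_curve_library, default_pristine_curve
from .stent import (
    StentGeometry,
    degrade_step,
    locate_max_degradation,
    new_state,
    radial_strength_curve,
    release_recoil,
    simulate_crimp,
    simulate_expansion,
    simulate_fatigue,
)
from .surface import SurfaceParams, fit_surface
from .synthetic import generate_mw_series, generate_tensile_dataset

__all__ = ["validate_config", "run_degradation_study", "DEFAULT_CONFIG"]

_GEOMETRY_KEYS = {
    "outer_diameter": 3.5,
    "wall_thickness": 0.125,
    "strut_width": 0.15,
    "crowns_per_hoop": 6,
    "hoops": 2,
    "bridges_per_ring": 3,
    "elements_per_strut": 8,
    "hoop_height": 1.0,
    "bridge_length": 0.4,
    "elements_per_bridge": 2,
    "n_fibers": 8,
}

DEFAULT_CONFIG = {
    "geometry": dict(_GEOMETRY_KEYS),
    "protocol": {
        "crimp_outer_diameter": 1.5,
        "expand_inner_diameter": 3.2,
        "p_dia_mmhg": 80.0,
        "p_sys_mmhg": 160.0,
        "vessel_compliance": 0.05,
        "crimp_increments": 40,
        "expand_increments": 40,
    },
    "degradation": {
        "time_points_days": [10.0, 20.0, 30.0],
        "fracture_threshold": 0.9,
        "min_strength_diameter": 2.0,
    },
    "material": {
        "source": "synthetic",  # or "csv"
        "tensile_csv": None,
        "plastic_csv": None,
        "noise_sd": 0.0,
        "true_params": {"a": 0.5, "b": 0.25, "c": 1.0, "m": 0.3, "n": 0.3},
    },
    "surface": {"family_id": "exp5", "n_starts": 12},
    "kinetics": {"time_points_months": [1.0, 3.0, 6.0]},
    "seed": 42,
}


def _merge(defaults: dict, given: dict, path: str, errors: list[str]) -> dict:
    out = {}
    for key, dval in defaults.items():
        if isinstance(dval, dict):
            sub = given.get(key, {})
            if not isinstance(sub, dict):
                errors.append(f"{path}{key}: expected a mapping")
                sub = {}
            out[key] = _merge(dval, sub, f"{path}{key}.", errors)
        else:
            out[key] = given.get(key, dval)
    for key in given:
        if key not in defaults:
            errors.append(f"{path}{key}: unknown key")
    return out


def validate_config(config: dict | None = None) -> dict:
    """Fill defaults, check ranges and units, reject unknown keys.

    Raises :class:`ConfigError` listing every violation at once.
    """
    errors: list[str] = []
    cfg = _merge(DEFAULT_CONFIG, config or {}, "", errors)

    proto = cfg["protocol"]
    if proto["p_dia_mmhg"] <= 0 or proto["p_sys_mmhg"] <= 0:
        errors.append("protocol: pressures must be > 0 mmHg")
    elif proto["p_sys_mmhg"] <= proto["p_dia_mmhg"]:
        errors.append("protocol: p_sys_mmhg must exceed p_dia_mmhg")
    if not 0 < proto["vessel_compliance"] < 1:
        errors.append("protocol: vessel_compliance must be a fraction in (0, 1)")
    if proto["crimp_outer_diameter"] >= cfg["geometry"]["outer_diameter"]:
        errors.append("protocol: crimp target must be below the nominal outer diameter")
    deg = cfg["degradation"]
    if not 0 < deg["fracture_threshold"] <= 1:
        errors.append("degradation: fracture_threshold must be in (0, 1]")
    tp = deg["time_points_days"]
    if any(t <= 0 for t in tp) or list(tp) != sorted(tp):
        errors.append("degradation: time_points_days must be positive and increasing")
    if cfg["material"]["source"] not in ("synthetic", "csv"):
        errors.append("material: source must be 'synthetic' or 'csv'")
    if cfg["material"]["source"] == "csv" and not cfg["material"]["tensile_csv"]:
        errors.append("material: csv source needs tensile_csv")
    if cfg["material"]["noise_sd"] < 0:
        errors.append("material: noise_sd must be >= 0")
    try:
        StentGeometry(**cfg["geometry"])
    except (ConfigError, TypeError) as exc:
        errors.append(f"geometry: {exc}")
    if errors:
        raise ConfigError("invalid config: " + "; ".join(errors))
    return cfg


def run_degradation_study(config: dict | None = None, outdir=None, return_state: bool = False):
    """Run the full degradation study; returns the summary dict.

    With ``outdir``, writes per-time-point radial-strength curves,
    Goodman points and degradation maps as CSV plus ``summary.json``.
    Partial outputs are kept if a later stage fails. With
    ``return_state`` the final :class:`~stentdeg.stent.SimulationState`
    is returned alongside the summary.
    """
    cfg = validate_config(config)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": cfg, "stages": {}}
    try:
        summary, state = _run(cfg, out, summary)
    except StentDegError as exc:
        stage = summary.get("failed_stage", "unknown")
        if out is not None:
            (out / "summary.json").write_text(_dumps(summary))
        raise type(exc)(f"stage '{stage}' failed: {exc}") from exc
    return (summary, state) if return_state else summary


def _dumps(obj) -> str:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o).__name__)

    return json.dumps(obj, indent=2, default=default)


def _run(cfg: dict, out, summary: dict) -> dict:
    # 1. tensile data and surface fit
    summary["failed_stage"] = "surface_fit"
    mat_cfg = cfg["material"]
    pristine = default_pristine_curve()
    if mat_cfg["source"] == "synthetic":
        true_params = SurfaceParams(**mat_cfg["true_params"])
        dataset = generate_tensile_dataset(
            true_params,
            pristine_curve=pristine,
            noise_sd=mat_cfg["noise_sd"],
            seed=cfg["seed"],
        )
    else:
        from .material import DegradationDataset

        dataset = DegradationDataset.from_csv(mat_cfg["tensile_csv"], mat_cfg["plastic_csv"])
        dataset.derive_reference(0.0, min(dataset.times), 0.1)
    fit = fit_surface(
        dataset,
        family_id=cfg["surface"]["family_id"],
        n_starts=cfg["surface"]["n_starts"],
        seed=cfg["seed"],
    )
    summary["stages"]["surface_fit"] = {
        "params": dict(zip("abcmn", map(float, fit.params.theta))),
        "rmse": fit.rmse,
    }

    # 2. deployment
    summary["failed_stage"] = "deployment"
    geometry = StentGeometry(**cfg["geometry"])
    library = build_curve_library(pristine)
    proto = cfg["protocol"]
    state = new_state(geometry, library)
    state = simulate_crimp(
        state, proto["crimp_outer_diameter"], n_inc=proto["crimp_increments"]
    )
    sigma_crimp = state.frame.max_abs_stress()
    state = release_recoil(state)
    sigma_recoil = state.frame.max_abs_stress()
    od_recoil1 = state.outer_diameter
    state = simulate_expansion(
        state, proto["expand_inner_diameter"], n_inc=proto["expand_increments"]
    )
    id_expanded = state.inner_diameter
    state = release_recoil(state)
    summary["stages"]["deployment"] = {
        "peak_stress_crimp_MPa": sigma_crimp,
        "peak_stress_after_recoil_MPa": sigma_recoil,
        "outer_diameter_after_recoil_mm": od_recoil1,
        "inner_diameter_expanded_mm": id_expanded,
        "outer_diameter_deployed_mm": state.outer_diameter,
        "peak_strain": float(state.frame.peak_strain.max()),
    }

    # 3. fatigue
    summary["failed_stage"] = "fatigue"
    state, goodman = simulate_fatigue(
        state,
        p_dia_mmhg=proto["p_dia_mmhg"],
        p_sys_mmhg=proto["p_sys_mmhg"],
        vessel_compliance=proto["vessel_compliance"],
    )
    goodman_df = pd.DataFrame(
        {
            "element": [p.location[0] for p in goodman],
            "gauss": [p.location[1] for p in goodman],
            "mean_stress_MPa": [p.mean_stress for p in goodman],
            "alternating_stress_MPa": [p.alternating_stress for p in goodman],
        }
    )
    if out is not None:
        goodman_df.to_csv(out / "goodman_points.csv", index=False)
    summary["stages"]["fatigue"] = {
        "n_points": len(goodman),
        "max_mean_stress_MPa": float(goodman_df["mean_stress_MPa"].abs().max()),
        "max_alternating_stress_MPa": float(goodman_df["alternating_stress_MPa"].max()),
    }

    # 4. degradation stepping with radial strength per time point
    summary["failed_stage"] = "degradation"
    deg = cfg["degradation"]
    pristine_strength = radial_strength_curve(state, deg["min_strength_diameter"])
    time_points = list(deg["time_points_days"])
    results = []
    elapsed = 0.0
    for t in time_points:
        state = degrade_step(state, t - elapsed, fit.params, deg["fracture_threshold"])
        elapsed = t
        curve = radial_strength_curve(state, deg["min_strength_diameter"])
        elem, dmax, coords = locate_max_degradation(state)
        dmap = state.point_table()[["element", "s_coordinate", "D"]]
        if out is not None:
            curve.to_frame().to_csv(out / f"radial_strength_{int(t)}d.csv", index=False)
            dmap.to_csv(out / f"degradation_map_{int(t)}d.csv", index=False)
        results.append(
            {
                "time_days": t,
                "peak_radial_force_N": curve.peak_force,
                "peak_radial_force_N_per_mm": curve.peak_force / curve.length,
                "strength_curve_complete": curve.complete,
                "max_degradation_degree": dmax,
                "max_degradation_element": int(elem),
                "max_degradation_on_crown": bool(state.mesh.is_crown[elem]),
                "max_degradation_coords_mm": [float(c) for c in coords],
                "outer_diameter_mm": state.outer_diameter,
                "n_inactive_points": int((~state.frame.active).sum()),
            }
        )
    summary["stages"]["degradation"] = {
        "pristine_peak_radial_force_N": pristine_strength.peak_force,
        "time_points": results,
    }

    # 5. molecular-weight kinetics (month scale)
    summary["failed_stage"] = "kinetics"
    mw_obs = generate_mw_series(times=cfg["kinetics"]["time_points_months"], seed=cfg["seed"])
    kin = {}
    for env in ("in_vivo", "in_vitro"):
        model = fit_first_order([o for o in mw_obs if o.environment == env])
        kin[env] = {
            "rate_constant_per_month": model.rate_constant,
            "retention_6mo": float(predict_retention(model, 6.0)),
        }
    summary["stages"]["kinetics"] = kin

    # 6. convergence log digest
    summary["convergence"] = {
        "n_converged_increments": sum(
            1 for rec in state.frame.log if rec.get("event") == "converged"
        ),
        "max_residual_ratio": max(
            (
                rec["residual"] / rec["reference"]
                for rec in state.frame.log
                if rec["reference"] > 1e-6  # skip force-free (fully unloaded) solves
            ),
            default=0.0,
        ),
    }
    summary.pop("failed_stage", None)
    if out is not None:
        (out / "summary.json").write_text(_dumps(summary))
    return summary, state
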