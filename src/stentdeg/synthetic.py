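"""Synthetic data generators emulating the study's measurement campaigns.

Three generators, all pure functions of (parameters, seed):

* :func:`generate_tensile_dataset` — a pre-stretch x time tensile grid
  drawn from a known degradation surface: degrees get additive Gaussian
  noise, elongations follow from the reference elongation, moduli wobble
  within +/-5% (pre-stretch and time have very minor influence on the
  elastic modulus), and plastic curves scale down monotonically with
  degree.
* :func:`generate_mw_series` — molecular-weight retention series per
  environment from first-order decay with lognormal measurement noise;
  default rates are anchored so the 6-month retentions are 61.8%
  (in vivo) and 68.5% (in vitro).
* :func:`generate_diameter_series` — near-constant stent outer-diameter
  follow-up series (the implanted scaffold holds its diameter over the
  observation window), with optional drift and caliper noise.

What these emulate — and what they do not — is discussed in the methods
note; they reproduce the statistical shape of the bench data, not raw
laboratory measurements.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import BENCH_CONDITIONS
from .errors import ConfigError, DomainError
from .kinetics import MwObservation, default_rate_constants
from .material import (
    DegradationDataset,
    MaterialCurve,
    TensileRecord,
    default_pristine_curve,
    scale_plastic_curve,
)
from .surface import SurfaceParams, evaluate_degree

__all__ = [
    "generate_tensile_dataset",
    "generate_mw_series",
    "generate_diameter_series",
    "make_fixture_files",
    "DEFAULT_GRID",
    "DEFAULT_SEED",
]

#: Pre-stretch levels and degradation times (days) of the bench campaign.
DEFAULT_GRID = ((0.0, 0.2, 0.4), (3.0, 10.0, 20.0, 30.0))
DEFAULT_SEED = 42
#: Cap on the +/- relative modulus perturbation ("very minor influence").
MODULUS_NOISE_CAP = 0.05
#: Noisy degrees are clamped below 1 so elongations stay positive.
DEGREE_CLAMP = (0.0, 0.95)


def generate_tensile_dataset(
    true_params: SurfaceParams,
    pristine_curve: MaterialCurve | None = None,
    grid=DEFAULT_GRID,
    noise_sd: float = 0.0,
    seed: int = DEFAULT_SEED,
) -> DegradationDataset:
    """Tensile grid sampled from a known degradation surface.

    Per cell: D* = D(ε, t) + N(0, noise_sd²) clamped to [0, 0.95];
    elongation = L0 (1 − D*); modulus = pristine x (1 + capped noise);
    plastic curve = pristine scaled down with D*. ``reference_elongation``
    is set to the generating L0, so degree tabulation round-trips
    exactly at zero noise.
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    pre_levels, times = (np.asarray(g, dtype=float) for g in grid)
    if pre_levels.size == 0 or times.size == 0:
        raise ConfigError("grid must contain at least one pre-stretch level and one time")
    pristine = pristine_curve or default_pristine_curve()
    l0 = pristine.failure_strain
    rng = np.random.default_rng(seed)
    records = []
    for eps in pre_levels:
        for t in times:
            d_true = float(evaluate_degree(true_params, eps, t))
            d_star = d_true + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            d_star = float(np.clip(d_star, *DEGREE_CLAMP))
            mod_noise = float(np.clip(rng.normal(0.0, 0.02), -MODULUS_NOISE_CAP, MODULUS_NOISE_CAP))
            records.append(
                TensileRecord(
                    pre_stretch=float(eps),
                    time=float(t),
                    elastic_modulus=pristine.elastic_modulus * (1.0 + mod_noise),
                    plastic_curve=scale_plastic_curve(pristine, d_star),
                    elongation_at_break=l0 * (1.0 - d_star),
                )
            )
    return DegradationDataset(
        records=records,
        reference_elongation=l0,
        metadata={"generator": "synthetic", "seed": seed, "noise_sd": noise_sd,
                  "bench_conditions": dict(BENCH_CONDITIONS)},
    )


def generate_mw_series(
    k_in_vivo: float | None = None,
    k_in_vitro: float | None = None,
    times=(1.0, 3.0, 6.0),
    noise_sd: float = 0.0,
    seed: int = DEFAULT_SEED,
) -> list[MwObservation]:
    """Retention observations for both environments.

    retention = exp(−k t) x exp(N(0, noise_sd²)) capped at 1. Default
    rates anchor the noiseless 6-month retentions at 0.618 / 0.685.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise DomainError("times must be >= 0 months")
    defaults = default_rate_constants()
    rates = {
        "in_vivo": defaults["in_vivo"] if k_in_vivo is None else float(k_in_vivo),
        "in_vitro": defaults["in_vitro"] if k_in_vitro is None else float(k_in_vitro),
    }
    for env, k in rates.items():
        if k < 0:
            raise DomainError(f"rate constant for {env} must be >= 0")
    rng = np.random.default_rng(seed)
    obs = []
    for env in ("in_vivo", "in_vitro"):
        for ti in t:
            r = np.exp(-rates[env] * ti)
            if noise_sd > 0:
                r *= np.exp(rng.normal(0.0, noise_sd))
            obs.append(MwObservation(time=float(ti), retention=float(min(r, 1.0)), environment=env))
    return obs


def generate_diameter_series(
    nominal_od: float = 3.45,
    times=(1.0, 3.0, 6.0),
    measurement_sd: float = 0.0,
    drift: float = 0.0,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Outer-diameter follow-up series, near-constant by default.

    ``drift`` is mm/month (default 0: the scaffold's diameter does not
    change significantly over the follow-up window); ``measurement_sd``
    is caliper/imaging noise in mm.
    """
    if measurement_sd < 0:
        raise DomainError("measurement_sd must be >= 0")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise DomainError("times must be >= 0 months")
    rng = np.random.default_rng(seed)
    od = nominal_od + drift * t
    if measurement_sd > 0:
        od = od + rng.normal(0.0, measurement_sd, size=t.shape)
    return pd.DataFrame({"time_months": t, "outer_diameter_mm": od})


def make_fixture_files(outdir, seed: int = DEFAULT_SEED, noise_sd: float = 0.02) -> dict:
    """Write the full synthetic fixture corpus as CSV; returns the paths.

    Bench-loop conditions are recorded as comment headers for
    provenance; they do not alter generation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = "".join(f"# {k}: {v}\n" for k, v in BENCH_CONDITIONS.items())
    params = SurfaceParams(a=0.5, b=0.25, c=1.0, m=0.3, n=0.3)
    ds = generate_tensile_dataset(params, noise_sd=noise_sd, seed=seed)
    tens_rows, plast_rows = [], []
    for r in ds.records:
        tens_rows.append(
            {
                "pre_stretch": r.pre_stretch,
                "time_days": r.time,
                "elastic_modulus_MPa": r.elastic_modulus,
                "elongation_at_break": r.elongation_at_break,
            }
        )
        for strain, stress in r.plastic_curve:
            plast_rows.append(
                {
                    "pre_stretch": r.pre_stretch,
                    "time_days": r.time,
                    "plastic_strain": strain,
                    "true_stress_MPa": stress,
                }
            )
    mw = generate_mw_series(noise_sd=noise_sd, seed=seed)
    mw_df = pd.DataFrame(
        [{"time_months": o.time, "retention": o.retention, "environment": o.environment} for o in mw]
    )
    dia = generate_diameter_series(measurement_sd=0.05, seed=seed)
    paths = {
        "tensile": outdir / "tensile_synthetic.csv",
        "plastic": outdir / "plastic_curves_synthetic.csv",
        "mw": outdir / "mw_retention_synthetic.csv",
        "diameter": outdir / "diameter_series_synthetic.csv",
    }
    for key, df in (
        ("tensile", pd.DataFrame(tens_rows)),
        ("plastic", pd.DataFrame(plast_rows)),
        ("mw", mw_df),
        ("diameter", dia),
    ):
        with open(paths[key], "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
    return paths
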