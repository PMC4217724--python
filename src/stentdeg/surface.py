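"""Strain- and time-dependent degradation surface D(ε, t).

Strained PLLA hydrolyses faster: chain scission is accelerated where the
network is loaded, so a specimen held at larger pre-stretch reaches a
given degradation degree sooner. The surface condenses the tensile grid
into a five-constant exponential law

    D(ε, t) = 1 − exp(−c · tⁿ · (b + a · εᵐ)),        a, b, c, m, n > 0

with ε the (engineering) pre-strain and t the degradation time in days.
By construction D(ε, 0) = 0, D saturates at 1, and D is non-decreasing
in both arguments — the qualitative behaviour the tensile data show.
The constants are recovered by weighted nonlinear least squares against
observed degrees (:func:`fit_surface`), multi-started from a
deterministic seed so fits are reproducible.

The family is registered under ``family_id="exp5"``; alternative
families can be registered in :data:`FAMILIES` and selected by id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ConfigError, DataError, DomainError, UnderdeterminedError
from .material import DegradationDataset, DegradationDegree, tabulate_degrees

__all__ = [
    "SurfaceParams",
    "FitResult",
    "evaluate_degree",
    "fit_surface",
    "check_monotonicity",
    "FAMILIES",
]

PARAM_NAMES = ("a", "b", "c", "m", "n")
#: Box constraints for all five constants during fitting.
PARAM_BOUNDS = (1e-6, 10.0)


def _exp5(theta, eps, t):
    a, b, c, m, n = theta
    eps = np.maximum(np.asarray(eps, dtype=float), 0.0)
    t = np.maximum(np.asarray(t, dtype=float), 0.0)
    return 1.0 - np.exp(-c * t**n * (b + a * eps**m))


#: family_id -> callable(theta, pre_stretch, time) -> D
FAMILIES = {"exp5": _exp5}


@dataclass(frozen=True)
class SurfaceParams:
    """The five positive constants of a degradation-surface family."""

    a: float
    b: float
    c: float
    m: float
    n: float
    family_id: str = "exp5"
    time_unit: str = "days"

    def __post_init__(self):
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise DomainError(f"surface constant {name} must be finite and > 0, got {v}")
        if self.family_id not in FAMILIES:
            raise ConfigError(f"unknown surface family {self.family_id!r}")

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.m, self.n])


@dataclass
class FitResult:
    """Outcome of a weighted surface fit."""

    params: SurfaceParams
    rmse: float
    residuals: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "family_id": self.params.family_id,
            "params": dict(zip(PARAM_NAMES, map(float, self.params.theta))),
            "rmse": float(self.rmse),
            "residuals": self.residuals.to_dict(orient="records"),
        }


def evaluate_degree(params: SurfaceParams, pre_stretch, time):
    """Evaluate D(ε, t); scalar in, :class:`DegradationDegree` out; arrays pass through.

    Negative strain or time raise; values are clamped to [0, 1] (the
    family maps there already, clamping guards rounding).
    """
    eps = np.asarray(pre_stretch, dtype=float)
    t = np.asarray(time, dtype=float)
    if np.any(eps < 0) or np.any(t < 0):
        raise DomainError("pre_stretch and time must be >= 0")
    d = np.clip(FAMILIES[params.family_id](params.theta, eps, t), 0.0, 1.0)
    if d.ndim == 0:
        return DegradationDegree(float(d))
    return d


def _observations(dataset: DegradationDataset) -> pd.DataFrame:
    table = tabulate_degrees(dataset)
    if not np.all(np.isfinite(table[["pre_stretch", "time_days", "degree"]].to_numpy())):
        raise DataError("non-finite observations in dataset")
    return table


def fit_surface(
    dataset: DegradationDataset,
    weights=None,
    family_id: str = "exp5",
    n_starts: int = 12,
    seed: int = 0,
) -> FitResult:
    """Weighted nonlinear least-squares fit of the surface constants.

    The objective is the weighted sum of squared deviations between the
    surface and the observed degrees. Deterministic multi-start: local
    trust-region least squares from ``n_starts`` starting points drawn
    from a seeded generator (plus a fixed nominal start), best fit wins.
    Result is independent of observation ordering.

    Raises :class:`UnderdeterminedError` for fewer than 5 observations
    or a degenerate grid.
    """
    if family_id not in FAMILIES:
        raise ConfigError(f"unknown surface family {family_id!r}")
    obs = _observations(dataset)
    if len(obs) < 5:
        raise UnderdeterminedError(
            f"need >=5 observations to identify 5 constants, got {len(obs)}"
        )
    dataset.require_fit_grid()
    # canonical ordering => fit invariant to input ordering
    obs = obs.sort_values(["pre_stretch", "time_days"]).reset_index(drop=True)
    if weights is None:
        w = np.ones(len(obs))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(obs),) or np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise DataError("weights must be positive finite, one per observation")
    sqw = np.sqrt(w)
    eps, t, d_obs = (obs[c].to_numpy() for c in ("pre_stretch", "time_days", "degree"))
    fam = FAMILIES[family_id]

    def resid(theta):
        return sqw * (fam(theta, eps, t) - d_obs)

    lo, hi = PARAM_BOUNDS
    rng = np.random.default_rng(seed)
    starts = [np.array([0.5, 0.25, 1.0, 0.3, 0.3])]
    starts += [np.exp(rng.uniform(np.log(0.02), np.log(3.0), size=5)) for _ in range(n_starts)]
    best = None
    for x0 in starts:
        try:
            sol = least_squares(resid, np.clip(x0, lo, hi), bounds=(lo, hi))
        except Exception:  # singular start; skip
            continue
        cost = float(np.sum(sol.fun**2))
        if best is None or cost < best[0] - 1e-14:
            best = (cost, sol.x)
    if best is None:
        raise DataError("all fit starts failed")
    theta = best[1]
    params = SurfaceParams(*theta, family_id=family_id)
    fitted = fam(theta, eps, t)
    rmse = float(np.sqrt(np.sum(w * (fitted - d_obs) ** 2) / np.sum(w)))
    residuals = pd.DataFrame(
        {
            "pre_stretch": eps,
            "time_days": t,
            "observed_degree": d_obs,
            "fitted_degree": fitted,
            "weight": w,
        }
    )
    return FitResult(params=params, rmse=rmse, residuals=residuals)


def check_monotonicity(
    params: SurfaceParams,
    strain_max: float = 0.5,
    time_max: float = 60.0,
    grid_n: int = 25,
) -> dict:
    """Grid check that D is non-decreasing in strain and time.

    Returns a report dict with ``monotone`` (bool), the grid used, and
    the worst (most negative) finite difference along each axis.
    """
    if grid_n < 2:
        raise ConfigError("grid_n must be >= 2")
    eps = np.linspace(0.0, strain_max, grid_n)
    t = np.linspace(0.0, time_max, grid_n)
    E, T = np.meshgrid(eps, t, indexing="ij")
    D = evaluate_degree(params, E.ravel(), T.ravel()).reshape(E.shape)
    d_eps = np.diff(D, axis=0)
    d_t = np.diff(D, axis=1)
    tol = -1e-12
    return {
        "monotone": bool(np.all(d_eps >= tol) and np.all(d_t >= tol)),
        "strain_grid": eps,
        "time_grid": t,
        "min_strain_increment": float(d_eps.min()) if d_eps.size else 0.0,
        "min_time_increment": float(d_t.min()) if d_t.size else 0.0,
    }
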