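"""Tensile-test data model and degradation-indexed material properties.

A semicrystalline PLLA stent loses ductility long before it loses
stiffness: hydrolysis cuts chains preferentially in strained regions, so
the elongation at break collapses while the elastic modulus barely moves.
The degradation degree ``D`` condenses this into a single damage-like
scalar,

    D = 1 - L / L0,

where ``L`` is the elongation at break of the degraded specimen and
``L0`` the (unmeasurable) pristine reference elongation. ``D = 0`` is
virgin material, ``D = 1`` complete degradation. ``L0`` is recovered from
an anchor assumption — a stated degree for one reference specimen — via
:func:`derive_reference_elongation`.

Elastic modulus, the plastic hardening curve and the failure strain are
tabulated against ``D`` and linearly interpolated between tabulated
curves (:func:`interpolate_properties`), mirroring field-variable
dependent material tables in a structural solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_FRACTURE_THRESHOLD
from .errors import ConfigError, DomainError, InvalidAnchorError, StateError

__all__ = [
    "DegradationDegree",
    "TensileRecord",
    "DegradationDataset",
    "MaterialCurve",
    "derive_reference_elongation",
    "compute_degradation_degree",
    "tabulate_degrees",
    "interpolate_properties",
    "fracture_check",
    "resample_plastic_curve",
    "scale_plastic_curve",
    "build_curve_library",
    "default_pristine_curve",
]


class DegradationDegree(float):
    """Degradation degree, a float constrained to [0, 1].

    Behaves as a plain float in arithmetic; construction validates the
    range so downstream material interpolation can rely on it.
    """

    def __new__(cls, value: float) -> "DegradationDegree":
        v = float(value)
        if not np.isfinite(v) or v < 0.0 or v > 1.0:
            raise DomainError(f"degradation degree must be in [0, 1], got {value!r}")
        return super().__new__(cls, v)


def _as_curve(plastic_curve) -> np.ndarray:
    arr = np.asarray(plastic_curve, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise DomainError("plastic_curve must be an (n, 2) array of (plastic strain, true stress)")
    strains, stresses = arr[:, 0], arr[:, 1]
    if not np.all(np.diff(strains) > 0) and arr.shape[0] > 1:
        raise DomainError("plastic_curve strains must be strictly increasing")
    if np.any(stresses < 0):
        raise DomainError("plastic_curve stresses must be non-negative")
    return arr


@dataclass(frozen=True)
class TensileRecord:
    """One tensile test: a specimen pre-stretched and degraded, then pulled.

    Parameters
    ----------
    pre_stretch : float
        Engineering strain held during degradation (0.0, 0.2, 0.4, ...).
    time : float
        Degradation time in days.
    elastic_modulus : float
        Young's modulus in MPa.
    plastic_curve : (n, 2) array_like
        Ordered (plastic strain, true stress MPa) pairs, strains strictly
        increasing, stresses non-negative.
    elongation_at_break : float
        Engineering strain at fracture, > 0.
    """

    pre_stretch: float
    time: float
    elastic_modulus: float
    plastic_curve: np.ndarray
    elongation_at_break: float

    def __post_init__(self):
        if self.pre_stretch < 0:
            raise DomainError("pre_stretch must be >= 0")
        if self.time < 0:
            raise DomainError("time must be >= 0 days")
        if not self.elastic_modulus > 0:
            raise DomainError("elastic_modulus must be > 0")
        if not self.elongation_at_break > 0:
            raise DomainError("elongation_at_break must be > 0")
        object.__setattr__(self, "plastic_curve", _as_curve(self.plastic_curve))


@dataclass
class DegradationDataset:
    """A grid of tensile records plus the derived pristine reference elongation.

    ``reference_elongation`` starts unset; call :meth:`derive_reference`
    (or :func:`derive_reference_elongation` directly) before computing
    degrees.
    """

    records: list[TensileRecord]
    reference_elongation: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.records = list(self.records)
        if not self.records:
            raise DomainError("dataset needs at least one record")
        if self.reference_elongation is not None:
            self._check_reference(self.reference_elongation)

    def _check_reference(self, l0: float) -> None:
        lmax = max(r.elongation_at_break for r in self.records)
        if l0 < lmax - 1e-12:
            raise DomainError(
                f"reference elongation {l0:.6g} is below the largest observed "
                f"elongation {lmax:.6g}; material cannot be less degraded than pristine"
            )

    @property
    def pre_stretch_levels(self) -> np.ndarray:
        return np.unique([r.pre_stretch for r in self.records])

    @property
    def times(self) -> np.ndarray:
        return np.unique([r.time for r in self.records])

    def record(self, pre_stretch: float, time: float) -> TensileRecord:
        for r in self.records:
            if np.isclose(r.pre_stretch, pre_stretch) and np.isclose(r.time, time):
                return r
        raise KeyError(f"no record at pre_stretch={pre_stretch}, time={time}")

    def derive_reference(
        self, anchor_pre_stretch: float, anchor_time: float, anchor_degree: float
    ) -> float:
        """Set ``reference_elongation`` from an anchor cell; returns L0."""
        anchor = self.record(anchor_pre_stretch, anchor_time)
        l0 = derive_reference_elongation(anchor, anchor_degree)
        self._check_reference(l0)
        self.reference_elongation = l0
        return l0

    def require_fit_grid(self) -> None:
        """Raise unless the grid can support a surface fit (>=2 x >=2)."""
        if len(self.pre_stretch_levels) < 2 or len(self.times) < 2:
            raise DomainError(
                "surface fitting needs >=2 distinct pre-stretch levels and >=2 times"
            )

    @classmethod
    def from_csv(cls, tensile_path, plastic_path=None, metadata=None) -> "DegradationDataset":
        """Load from the package CSV dialect.

        ``tensile_path`` columns: pre_stretch, time_days,
        elastic_modulus_MPa, elongation_at_break. Optional
        ``plastic_path`` columns: pre_stretch, time_days, plastic_strain,
        true_stress_MPa. Records without a companion plastic curve get a
        single-point perfectly-plastic placeholder at 0.6 x modulus/30
        (never used by the simulator, which requires real curves).
        """
        tens = pd.read_csv(tensile_path, comment="#")
        plast = pd.read_csv(plastic_path, comment="#") if plastic_path is not None else None
        records = []
        for _, row in tens.iterrows():
            key = (row["pre_stretch"], row["time_days"])
            if plast is not None:
                sel = plast[
                    np.isclose(plast["pre_stretch"], key[0])
                    & np.isclose(plast["time_days"], key[1])
                ]
                curve = sel[["plastic_strain", "true_stress_MPa"]].to_numpy()
            else:
                curve = np.array([[0.0, row["elastic_modulus_MPa"] / 30.0]])
            records.append(
                TensileRecord(
                    pre_stretch=float(row["pre_stretch"]),
                    time=float(row["time_days"]),
                    elastic_modulus=float(row["elastic_modulus_MPa"]),
                    plastic_curve=curve,
                    elongation_at_break=float(row["elongation_at_break"]),
                )
            )
        return cls(records=records, metadata=metadata or {})


@dataclass(frozen=True)
class MaterialCurve:
    """Elastoplastic material description at one degradation degree."""

    degradation_degree: DegradationDegree
    elastic_modulus: float
    plastic_curve: np.ndarray
    failure_strain: float

    def __post_init__(self):
        object.__setattr__(self, "degradation_degree", DegradationDegree(self.degradation_degree))
        if not self.elastic_modulus > 0:
            raise DomainError("elastic_modulus must be > 0")
        if not self.failure_strain > 0:
            raise DomainError("failure_strain must be > 0")
        object.__setattr__(self, "plastic_curve", _as_curve(self.plastic_curve))

    @property
    def yield_stress(self) -> float:
        return float(self.plastic_curve[0, 1])


def derive_reference_elongation(anchor_record: TensileRecord, anchor_degree: float) -> float:
    """Pristine reference elongation L0 from an anchored degradation degree.

    With the anchor specimen's elongation ``L_a`` assigned degree ``D_a``,
    ``L0 = L_a / (1 - D_a)``. ``D_a`` must lie in [0, 1).
    """
    if not 0.0 <= anchor_degree < 1.0:
        raise InvalidAnchorError(f"anchor degree must be in [0, 1), got {anchor_degree}")
    return anchor_record.elongation_at_break / (1.0 - anchor_degree)


def compute_degradation_degree(elongation: float, reference_elongation: float) -> DegradationDegree:
    """D = 1 - elongation / reference_elongation, clamped to [0, 1]."""
    if reference_elongation <= 0:
        raise DomainError("reference_elongation must be > 0")
    if elongation < 0:
        raise DomainError("elongation must be >= 0")
    if elongation > reference_elongation * (1 + 1e-12):
        raise DomainError(
            "elongation exceeds the pristine reference; material cannot be "
            "less degraded than pristine"
        )
    return DegradationDegree(min(max(1.0 - elongation / reference_elongation, 0.0), 1.0))


def tabulate_degrees(dataset: DegradationDataset) -> pd.DataFrame:
    """One row per record: pre_stretch, time_days, elongation, degree."""
    if dataset.reference_elongation is None:
        raise StateError("derive the reference elongation before tabulating degrees")
    rows = [
        {
            "pre_stretch": r.pre_stretch,
            "time_days": r.time,
            "elongation": r.elongation_at_break,
            "degree": float(
                compute_degradation_degree(r.elongation_at_break, dataset.reference_elongation)
            ),
        }
        for r in dataset.records
    ]
    return pd.DataFrame(rows).sort_values(["pre_stretch", "time_days"]).reset_index(drop=True)


def resample_plastic_curve(curve: np.ndarray, strain_grid: np.ndarray) -> np.ndarray:
    """Piecewise-linear resample onto ``strain_grid`` (flat beyond the ends)."""
    curve = _as_curve(curve)
    stresses = np.interp(strain_grid, curve[:, 0], curve[:, 1])
    return np.column_stack([strain_grid, stresses])


def interpolate_properties(
    D: float, curve_library: Sequence[MaterialCurve]
) -> MaterialCurve:
    """Linear interpolation of material properties in degradation degree.

    The library must be sorted by ``degradation_degree`` and share a
    common plastic-strain grid. ``D`` outside the tabulated range clamps
    to the nearest end; no extrapolation is performed.
    """
    if len(curve_library) == 0:
        raise DomainError("curve library is empty")
    degrees = np.array([c.degradation_degree for c in curve_library], dtype=float)
    if np.any(np.diff(degrees) < 0):
        raise DomainError("curve library must be sorted by degradation degree")
    grids = [c.plastic_curve[:, 0] for c in curve_library]
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
            raise DomainError("curve library must share a common plastic-strain grid")
    D = DegradationDegree(D) if 0.0 <= D <= 1.0 else float(D)
    d = float(min(max(float(D), degrees[0]), degrees[-1]))
    j = int(np.searchsorted(degrees, d, side="right"))
    if j == 0:
        return curve_library[0]
    if j >= len(degrees):
        # exactly at (or clamped to) the last node
        if np.isclose(d, degrees[-1]):
            return curve_library[-1]
        j = len(degrees) - 1
    lo, hi = curve_library[j - 1], curve_library[j]
    d0, d1 = degrees[j - 1], degrees[j]
    if np.isclose(d, d0):
        return lo
    if np.isclose(d, d1):
        return hi
    w = (d - d0) / (d1 - d0)
    stresses = (1 - w) * lo.plastic_curve[:, 1] + w * hi.plastic_curve[:, 1]
    return MaterialCurve(
        degradation_degree=DegradationDegree(min(max(d, 0.0), 1.0)),
        elastic_modulus=(1 - w) * lo.elastic_modulus + w * hi.elastic_modulus,
        plastic_curve=np.column_stack([grids[0], stresses]),
        failure_strain=(1 - w) * lo.failure_strain + w * hi.failure_strain,
    )


def fracture_check(D: float, threshold: float = DEFAULT_FRACTURE_THRESHOLD) -> bool:
    """True iff the point is considered fractured: D >= threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ConfigError(f"fracture threshold must be in (0, 1], got {threshold}")
    return float(D) >= threshold


# -- curve-library construction ----------------------------------------------

#: Fraction of plastic stress lost at complete degradation. The plastic
#: curve is scaled by (1 - PLASTIC_LOSS_AT_FULL_DEGRADATION * D): a point
#: at the fracture threshold D = 0.9 retains ~23% of its flow stress,
#: keeping deactivation (not softening) the failure mechanism.
PLASTIC_LOSS_AT_FULL_DEGRADATION = 0.85


def scale_plastic_curve(pristine: MaterialCurve, D: float) -> np.ndarray:
    """Plastic curve at degree ``D``: pristine ordinates scaled down monotonically."""
    D = DegradationDegree(D)
    factor = 1.0 - PLASTIC_LOSS_AT_FULL_DEGRADATION * float(D)
    return np.column_stack([pristine.plastic_curve[:, 0], pristine.plastic_curve[:, 1] * factor])


def build_curve_library(
    pristine: MaterialCurve,
    degrees: Iterable[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    modulus_factor: float = 1.0,
) -> list[MaterialCurve]:
    """Material curves over a grid of degradation degrees.

    The elastic modulus is held at ``modulus_factor`` x pristine (the
    tensile data show pre-stretch and time have very minor influence on
    it); flow stress scales down linearly with D; failure strain is
    L0 * (1 - D), floored at 1% strain so a fully degraded entry stays a
    valid curve (such points are deactivated by the fracture check anyway).
    """
    lib = []
    for d in degrees:
        dd = DegradationDegree(d)
        lib.append(
            MaterialCurve(
                degradation_degree=dd,
                elastic_modulus=pristine.elastic_modulus * modulus_factor,
                plastic_curve=scale_plastic_curve(pristine, dd),
                failure_strain=max(pristine.failure_strain * (1.0 - float(dd)), 0.01),
            )
        )
    return lib


def default_pristine_curve(
    elastic_modulus: float = 1700.0, failure_strain: float = 1.2214
) -> MaterialCurve:
    """Nominal undegraded PLLA curve used for simulation and data synthesis.

    Yield near 60 MPa hardening to ~175 MPa at unit plastic strain —
    representative of oriented semicrystalline PLLA tubing, consistent
    with tensile stresses in the 160–175 MPa range at large stent strains.
    """
    curve = np.array(
        [
            [0.00, 60.0],
            [0.02, 78.0],
            [0.05, 92.0],
            [0.10, 105.0],
            [0.20, 122.0],
            [0.40, 145.0],
            [0.70, 160.0],
            [1.00, 170.0],
            [1.40, 176.0],
        ]
    )
    return MaterialCurve(
        degradation_degree=DegradationDegree(0.0),
        elastic_modulus=elastic_modulus,
        plastic_curve=curve,
        failure_strain=failure_strain,
    )
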