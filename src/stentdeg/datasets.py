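"""Packaged fixture data: the pre-stretch x time tensile grid.

The tensile grid (elastic modulus and elongation at break on a
0/20/40% pre-stretch x 3/10/20/30 day grid) is shipped as a CSV. The
original stress–strain curves were published only graphically, so the
companion plastic-curve file is *synthetic*: the nominal pristine PLLA
hardening curve scaled down monotonically with each cell's degradation
degree — enough to exercise curve-library interpolation with realistic
shapes, but not measured data.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .material import (
    DegradationDataset,
    compute_degradation_degree,
    default_pristine_curve,
    derive_reference_elongation,
    scale_plastic_curve,
)

__all__ = ["load_table1", "table1_paths", "synthesize_plastic_companion"]

#: Anchor assumption used to derive the pristine reference elongation L0:
#: the 0% pre-stretch specimen is assigned degree 0.1 after 3 days.
TABLE1_ANCHOR = {"pre_stretch": 0.0, "time": 3.0, "degree": 0.1}

#: Five surface constants reported alongside the original tensile dataset
#: (a, b, c, m, n). Kept as provenance metadata only: the functional form
#: they parameterize was published only graphically, so this package
#: re-fits its own exponential family instead of reusing them.
REPORTED_SURFACE_CONSTANTS = (0.562, 0.2478, 1.094, 0.301, 0.285)

#: Bench conditions of the pulsatile in vitro degradation loop, recorded
#: for provenance; they do not enter any computation.
BENCH_CONDITIONS = {
    "pump_systolic_mmHg": 920.0,
    "pump_diastolic_mmHg": 840.0,
    "pulse_rate_per_min": 70.0,
    "medium": "PBS",
    "medium_pH": "7.4 +/- 0.2",
    "mock_vessel_compliance": 0.05,
    "temperature_C": 37.0,
}


def table1_paths():
    """(tensile_csv, plastic_csv) paths of the packaged fixture."""
    base = resources.files("stentdeg") / "data"
    return base / "table1_tensile.csv", base / "table1_plastic_synthetic.csv"


def synthesize_plastic_companion(tensile_csv) -> pd.DataFrame:
    """Synthetic plastic curves for each tensile grid cell.

    Each cell's degree is computed with the anchor-derived L0; the
    pristine hardening curve is then scaled by (1 - 0.85 D). Deterministic.
    """
    tens = pd.read_csv(tensile_csv, comment="#")
    anchor_l = tens[
        np.isclose(tens["pre_stretch"], TABLE1_ANCHOR["pre_stretch"])
        & np.isclose(tens["time_days"], TABLE1_ANCHOR["time"])
    ]["elongation_at_break"].iloc[0]
    l0 = anchor_l / (1.0 - TABLE1_ANCHOR["degree"])
    pristine = default_pristine_curve(failure_strain=l0)
    frames = []
    for _, row in tens.iterrows():
        d = compute_degradation_degree(row["elongation_at_break"], l0)
        curve = scale_plastic_curve(pristine, d)
        frames.append(
            pd.DataFrame(
                {
                    "pre_stretch": row["pre_stretch"],
                    "time_days": row["time_days"],
                    "plastic_strain": curve[:, 0],
                    "true_stress_MPa": np.round(curve[:, 1], 4),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def load_table1(derive_reference: bool = True) -> DegradationDataset:
    """The packaged tensile grid as a :class:`DegradationDataset`.

    With ``derive_reference`` (default) the pristine reference elongation
    is derived from the packaged anchor assumption so degrees can be
    tabulated immediately.
    """
    tensile, plastic = table1_paths()
    ds = DegradationDataset.from_csv(
        tensile,
        plastic,
        metadata={
            "anchor": dict(TABLE1_ANCHOR),
            "reported_surface_constants": REPORTED_SURFACE_CONSTANTS,
            "bench_conditions": dict(BENCH_CONDITIONS),
            "plastic_curves": "synthetic",
        },
    )
    if derive_reference:
        ds.derive_reference(
            TABLE1_ANCHOR["pre_stretch"], TABLE1_ANCHOR["time"], TABLE1_ANCHOR["degree"]
        )
    return ds
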