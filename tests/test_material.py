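import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stentdeg.errors import ConfigError, DomainError, InvalidAnchorError, StateError
from stentdeg.material import (
    DegradationDataset,
    DegradationDegree,
    MaterialCurve,
    TensileRecord,
    build_curve_library,
    compute_degradation_degree,
    default_pristine_curve,
    derive_reference_elongation,
    fracture_check,
    interpolate_properties,
    tabulate_degrees,
)

from conftest import TABLE1_DEGREES

L0 = 1.09927 / 0.9  # anchor-derived pristine reference elongation


def _record(elongation=1.0, **kw):
    defaults = dict(
        pre_stretch=0.0,
        time=3.0,
        elastic_modulus=1684.42,
        plastic_curve=np.array([[0.0, 60.0], [0.1, 100.0]]),
        elongation_at_break=elongation,
    )
    defaults.update(kw)
    return TensileRecord(**defaults)


class TestReferenceElongation:
    def test_anchor_closed_form(self):
        assert derive_reference_elongation(_record(1.09927), 0.1) == pytest.approx(
            1.221411, abs=1e-6
        )

    def test_zero_anchor_returns_input(self):
        assert derive_reference_elongation(_record(1.09927), 0.0) == 1.09927

    @pytest.mark.parametrize("bad", [1.0, 1.5, -0.1])
    def test_invalid_anchor(self, bad):
        with pytest.raises(InvalidAnchorError):
            derive_reference_elongation(_record(), bad)


class TestDegradationDegree:
    @pytest.mark.parametrize(
        "elongation, expected",
        [(0.555209, 0.545436), (0.36437, 0.701681)],
    )
    def test_fixture_cells(self, elongation, expected):
        assert float(compute_degradation_degree(elongation, L0)) == pytest.approx(
            expected, abs=1e-4
        )

    def test_pristine_and_complete(self):
        assert compute_degradation_degree(L0, L0) == 0.0
        assert compute_degradation_degree(0.0, L0) == 1.0

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            compute_degradation_degree(-0.1, L0)
        with pytest.raises(DomainError):
            compute_degradation_degree(L0 * 1.01, L0)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(0.0, 1.0))
    def test_round_trip(self, d):
        """D -> elongation -> D is the identity on [0, 1]."""
        assert float(compute_degradation_degree(L0 * (1 - d), L0)) == pytest.approx(
            d, abs=1e-12
        )

    def test_degree_type_bounds(self):
        with pytest.raises(DomainError):
            DegradationDegree(1.2)
        with pytest.raises(DomainError):
            DegradationDegree(-0.01)


class TestTabulateDegrees:
    def test_reproduces_fixture_grid(self, table1):
        table = tabulate_degrees(table1)
        assert len(table) == 12
        for (eps, t), expected in TABLE1_DEGREES.items():
            row = table[
                np.isclose(table.pre_stretch, eps) & np.isclose(table.time_days, t)
            ]
            assert float(row.degree.iloc[0]) == pytest.approx(expected, abs=1e-4)

    def test_requires_reference(self):
        ds = DegradationDataset(records=[_record()])
        with pytest.raises(StateError):
            tabulate_degrees(ds)

    def test_pristine_dataset_all_zero(self):
        ds = DegradationDataset(records=[_record(elongation=L0)], reference_elongation=L0)
        assert (tabulate_degrees(ds).degree == 0.0).all()

    def test_single_record(self):
        ds = DegradationDataset(records=[_record(0.5)], reference_elongation=L0)
        assert len(tabulate_degrees(ds)) == 1

    def test_modulus_nearly_degradation_independent(self, table1):
        """Moduli spread <10% while the degree spans 0.1-0.78."""
        moduli = np.array([r.elastic_modulus for r in table1.records])
        degrees = tabulate_degrees(table1).degree
        assert degrees.min() == pytest.approx(0.1, abs=1e-4)
        assert degrees.max() > 0.75
        assert np.abs(moduli / moduli.mean() - 1.0).max() < 0.10


class TestInterpolateProperties:
    def test_node_returns_library_curve(self, curve_library):
        node = curve_library[3]
        got = interpolate_properties(float(node.degradation_degree), curve_library)
        assert got is node

    def test_midpoint_is_arithmetic_mean(self, curve_library):
        lo, hi = curve_library[2], curve_library[3]
        mid = 0.5 * (float(lo.degradation_degree) + float(hi.degradation_degree))
        got = interpolate_properties(mid, curve_library)
        np.testing.assert_allclose(
            got.plastic_curve[:, 1],
            0.5 * (lo.plastic_curve[:, 1] + hi.plastic_curve[:, 1]),
        )
        assert got.elastic_modulus == pytest.approx(
            0.5 * (lo.elastic_modulus + hi.elastic_modulus)
        )

    def test_clamps_outside_range(self, curve_library):
        sub = curve_library[:-2]  # top node below 1
        top = interpolate_properties(float(sub[-1].degradation_degree), sub)
        assert interpolate_properties(1.5, sub) is top

    def test_continuity_and_monotonicity(self, curve_library):
        ds = np.linspace(0, 1, 101)
        stresses = np.array(
            [interpolate_properties(d, curve_library).plastic_curve[:, 1] for d in ds]
        )
        assert np.all(np.diff(stresses, axis=0) <= 1e-12)
        assert np.max(np.abs(np.diff(stresses, axis=0))) < 0.02 * stresses[0].max()

    def test_errors(self, curve_library):
        with pytest.raises(DomainError):
            interpolate_properties(0.5, [])
        with pytest.raises(DomainError):
            interpolate_properties(0.5, curve_library[::-1])


class TestFractureCheck:
    @pytest.mark.parametrize(
        "d, threshold, expected",
        [(0.9, 0.9, True), (0.0, 0.9, False), (1.0, 0.3, True), (1.0, 1.0, True)],
    )
    def test_threshold_logic(self, d, threshold, expected):
        assert fracture_check(d, threshold) is expected

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.1])
    def test_bad_threshold(self, bad):
        with pytest.raises(ConfigError):
            fracture_check(0.5, bad)


class TestRecordInvariants:
    def test_invalid_plastic_curves(self):
        with pytest.raises(DomainError):
            _record(plastic_curve=np.array([[0.1, 60.0], [0.05, 80.0]]))
        with pytest.raises(DomainError):
            _record(plastic_curve=np.array([[0.0, -5.0]]))

    def test_reference_below_observed_elongation_rejected(self):
        with pytest.raises(DomainError):
            DegradationDataset(records=[_record(1.5)], reference_elongation=1.0)

    def test_library_flow_stress_decreases_with_degree(self, curve_library):
        peaks = [c.plastic_curve[:, 1].max() for c in curve_library]
        assert all(a >= b for a, b in zip(peaks, peaks[1:]))

    def test_pristine_failure_strain_matches_reference(self, pristine_curve):
        assert pristine_curve.failure_strain == pytest.approx(L0, abs=1e-3)
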