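"""Error measures, cost functions and quantity scaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from areavenn import (
    Quantities7,
    RegionAreas,
    cost_F6,
    cost_F7,
    cost_F8,
    diag_error,
    error_report,
    is_good,
    region_error,
    scale_quantities,
    stress,
)
from areavenn.diagram import REGION_LABELS
from areavenn.geometry import region_areas

from conftest import TINY_REGION_EXAMPLE

UNIFORM = Quantities7.from_array(np.ones(7))


def areas_of(values, valid=True):
    return RegionAreas(dict(zip(REGION_LABELS, map(float, values))), valid)


positive7 = st.lists(
    st.floats(min_value=1e-3, max_value=1e6, allow_nan=False), min_size=7, max_size=7
)


class TestScaleQuantities:
    def test_equal_values_map_to_100(self):
        out = scale_quantities(Quantities7.from_array([5.0] * 7))
        assert all(v == pytest.approx(100.0) for v in out.q.values())

    def test_tiny_region_example_scaled_by_100_over_min(self):
        out = scale_quantities(Quantities7(TINY_REGION_EXAMPLE))
        assert out["bc"] == pytest.approx(100.0)
        assert out["a"] == pytest.approx(10018 * 100 / 3)

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            Quantities7.from_array([1, 2, 3, 4, 5, 6, 0])

    @settings(derandomize=True, max_examples=50)
    @given(positive7, st.floats(min_value=1e-3, max_value=1e3))
    def test_proportional_inputs_scale_identically(self, vals, k):
        w = Quantities7.from_array(vals)
        kw = Quantities7.from_array(np.asarray(vals) * k)
        np.testing.assert_allclose(
            scale_quantities(w).to_array(), scale_quantities(kw).to_array(), rtol=1e-9
        )


class TestRegionAndDiagError:
    def test_proportional_areas_have_zero_error(self):
        a = areas_of(3 * UNIFORM.to_array())
        assert diag_error(a, UNIFORM) == 0.0

    def test_doubled_region_hand_value(self):
        # |2/8 - 1/7| = 3/28, attained at the doubled region
        a = areas_of([2, 1, 1, 1, 1, 1, 1])
        assert region_error("a", a, UNIFORM) == pytest.approx(3 / 28)
        assert diag_error(a, UNIFORM) == pytest.approx(3 / 28)
        rep = error_report(a, UNIFORM)
        assert max(rep.region_errors, key=rep.region_errors.get) == "a"

    @settings(derandomize=True, max_examples=100)
    @given(positive7, positive7)
    def test_errors_bounded_by_unit_interval(self, avals, wvals):
        a = areas_of(avals)
        w = Quantities7.from_array(wvals)
        de = diag_error(a, w)
        assert 0.0 <= de <= 1.0
        for lab in REGION_LABELS:
            assert 0.0 <= region_error(lab, a, w) <= 1.0

    def test_invariance_under_scaling_both_sides(self):
        a = areas_of([4, 2, 7, 1, 3, 5, 6])
        w = Quantities7.from_array([2, 1, 9, 4, 2, 2, 3])
        kw = Quantities7.from_array(7 * w.to_array())
        ka = areas_of(3.3 * a.to_array())
        assert diag_error(a, w) == pytest.approx(diag_error(ka, kw), rel=1e-12)


class TestIsGood:
    def test_true_for_self_consistent_diagram(self, classic_venn):
        ra = region_areas(classic_venn)
        w = Quantities7.from_array(1000.0 * ra.to_array())
        assert is_good(classic_venn, w)

    def test_false_for_invalid_topology_despite_matching_areas(self):
        from areavenn import Ellipse, VennDiagram3

        d = VennDiagram3(
            {
                "a": Ellipse(0, 0, 1, 1),
                "b": Ellipse(5, 0, 1, 1),
                "c": Ellipse(10, 0, 1, 1),
            }
        )
        w = Quantities7.from_array(np.maximum(region_areas(d).to_array(), 1e-9))
        assert not is_good(d, w)


class TestCostFunctions:
    def test_zero_at_perfect_fit(self):
        w = Quantities7.from_array([4, 2, 7, 1, 3, 5, 6])
        a = areas_of(w.to_array())
        assert cost_F6(a, w) == 0.0
        assert cost_F7(a, w) == 0.0
        assert cost_F8(a, w) == 0.0

    def test_hand_values(self):
        w2 = Quantities7.from_array([2.0] * 7)
        a1 = areas_of([1.0] * 7)
        assert cost_F6(a1, w2) == pytest.approx(1.0)
        assert cost_F7(a1, w2) == pytest.approx(1.0)
        w3 = Quantities7.from_array([3.0] * 7)
        a2 = areas_of([2.0] * 7)
        assert cost_F6(a2, w3) == pytest.approx(0.5)
        assert cost_F7(a2, w3) == pytest.approx(0.25)
        assert cost_F8(a2, w3) == pytest.approx(0.5)

    def test_collapsed_region_costs_infinity(self):
        a = areas_of([0, 1, 1, 1, 1, 1, 1], valid=False)
        w = Quantities7.from_array([1.0] * 7)
        assert cost_F6(a, w) == np.inf
        assert cost_F7(a, w) == np.inf
        assert cost_F8(a, w) == np.inf

    def test_cost_diverges_as_region_collapses(self):
        w = Quantities7.from_array([2.0] * 7)
        costs = [
            cost_F6(areas_of([eps, 2, 2, 2, 2, 2, 2]), w)
            for eps in (1e-2, 1e-4, 1e-6)
        ]
        assert costs[0] < costs[1] < costs[2]


class TestStress:
    def test_zero_iff_proportional(self):
        w = Quantities7.from_array([4, 2, 7, 1, 3, 5, 6])
        assert stress(areas_of(2.5 * w.to_array()), w) == pytest.approx(0.0, abs=1e-15)

    def test_hand_value(self):
        # w uniform, one doubled area: beta = 8/7, rss = 6/7, tss = 10
        a = areas_of([2, 1, 1, 1, 1, 1, 1])
        assert stress(a, UNIFORM) == pytest.approx(3 / 35)

    @settings(derandomize=True, max_examples=100)
    @given(positive7, positive7)
    def test_unit_interval(self, avals, wvals):
        s = stress(areas_of(avals), Quantities7.from_array(wvals))
        assert 0.0 <= s <= 1.0 + 1e-12
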