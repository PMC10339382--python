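"""Response surfaces and trend classification."""

import numpy as np
import pytest

from toothmor import (
    ParameterGrid,
    Region,
    SnapshotTensor,
    classify_trend,
    extreme_vms,
    percent_increase,
    region_node_mask,
)
from toothmor.exceptions import ValidationError

GRID = ParameterGrid.uniform(50, 200, 3)


class TestExtremeVms:
    def test_zero_tensor_gives_a_zero_surface(self):
        t = SnapshotTensor(values=np.zeros((10, 3, 3)), grid=GRID)
        surf = extreme_vms(t, np.ones(10, dtype=bool))
        assert np.abs(surf.values).max() == 0.0

    def test_single_node_mask_returns_that_nodes_slice(self):
        rng = np.random.default_rng(0)
        vals = np.abs(rng.standard_normal((10, 3, 3)))
        t = SnapshotTensor(values=vals, grid=GRID)
        mask = np.zeros(10, dtype=bool)
        mask[4] = True
        surf = extreme_vms(t, mask)
        assert np.array_equal(surf.values, vals[4])

    def test_empty_mask_is_rejected(self):
        t = SnapshotTensor(values=np.ones((10, 3, 3)), grid=GRID)
        with pytest.raises(ValidationError):
            extreme_vms(t, np.zeros(10, dtype=bool))

    def test_root_and_ligament_surfaces_differ_on_fe_data(
        self, coarse_fe_tensor, coarse_mesh
    ):
        root = extreme_vms(coarse_fe_tensor, region_node_mask(coarse_mesh, Region.DENTIN))
        pdl = extreme_vms(coarse_fe_tensor, region_node_mask(coarse_mesh, Region.PDL))
        assert root.values.min() >= 0 and pdl.values.min() >= 0
        assert not np.allclose(root.values, pdl.values)

    def test_percentile_statistic_is_bounded_by_the_max(self):
        rng = np.random.default_rng(1)
        vals = np.abs(rng.standard_normal((50, 3, 3)))
        t = SnapshotTensor(values=vals, grid=GRID)
        mask = np.ones(50, dtype=bool)
        p = extreme_vms(t, mask, statistic="percentile", percentile=90.0)
        m = extreme_vms(t, mask, statistic="max")
        assert np.all(p.values <= m.values)


class TestPercentIncrease:
    def test_matches_the_between_extremes_definition(self):
        assert percent_increase([10.0, 20.9]) == pytest.approx(109.0)

    def test_constant_response_has_zero_increase(self):
        assert percent_increase([3.0, 3.0, 3.0]) == 0.0

    def test_decreases_are_signed(self):
        assert percent_increase([20.0, 10.0]) == pytest.approx(-50.0)

    def test_nonpositive_start_is_an_error(self):
        with pytest.raises(ValidationError):
            percent_increase([0.0, 5.0])

    def test_invariant_under_uniform_scaling(self):
        v = np.array([4.0, 5.5, 9.0])
        assert percent_increase(v) == pytest.approx(percent_increase(10 * v))


class TestClassifyTrend:
    X = np.array([50.0, 100.0, 150.0, 200.0])

    def test_exact_line_is_linear_with_negligible_rmse(self):
        res = classify_trend(self.X, 2 * self.X + 1)
        assert res.classification == "linear"
        assert res.rel_rmse_deg1 < 1e-12

    def test_exact_parabola_is_quadratic(self):
        assert classify_trend(self.X, self.X**2).classification == "quadratic"

    def test_quadratic_fit_never_beats_linear_fit_in_rmse(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            y = np.abs(rng.standard_normal(4)) + 0.5
            res = classify_trend(self.X, y)
            assert res.rel_rmse_deg2 <= res.rel_rmse_deg1 + 1e-14

    def test_noisy_linear_data_is_classified_linear_in_most_replicates(self):
        """1% multiplicative noise on a line: ≥95 of 100 seeded replicates
        stay classified as linear."""
        hits = 0
        base = 2 * self.X + 1
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = base + 0.01 * base.mean() * rng.standard_normal(4)
            if classify_trend(self.X, y).classification == "linear":
                hits += 1
        assert hits >= 95

    def test_too_few_points_for_quadratic_is_an_error(self):
        with pytest.raises(ValidationError):
            classify_trend(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
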