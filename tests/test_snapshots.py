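"""Snapshot factory: grids, FE tensor consistency, analytic surrogates."""

import numpy as np
import pytest

from toothmor import (
    LoadCase,
    ParameterGrid,
    SnapshotTensor,
    SurrogateSpec,
    generate_analytic_snapshots,
    generate_fe_snapshots,
    solve_static,
    surrogate_field,
    uniform_grid,
)
from toothmor.exceptions import ValidationError


class TestUniformGrid:
    def test_four_point_grid_over_the_force_range(self):
        assert np.array_equal(uniform_grid(50, 200, 4), [50.0, 100.0, 150.0, 200.0])

    def test_two_points_gives_the_endpoints(self):
        assert np.array_equal(uniform_grid(50, 200, 2), [50.0, 200.0])

    @pytest.mark.parametrize("args", [(200, 50, 4), (50, 200, 1), (50, 50, 3)])
    def test_bad_arguments_are_rejected(self, args):
        with pytest.raises(ValidationError):
            uniform_grid(*args)


class TestParameterGrid:
    def test_unsorted_axes_are_rejected(self):
        with pytest.raises(ValidationError, match="increasing"):
            ParameterGrid(np.array([100.0, 50.0, 200.0]), np.array([50.0, 200.0]))

    def test_uniformity_flag(self):
        assert ParameterGrid.uniform(50, 200, 4).is_uniform
        assert not ParameterGrid(
            np.array([50.0, 60.0, 200.0]), np.array([50.0, 200.0])
        ).is_uniform


class TestFeSnapshots:
    def test_shape_and_nonnegativity(self, coarse_fe_tensor, coarse_mesh):
        assert coarse_fe_tensor.values.shape == (coarse_mesh.n_nodes, 2, 2)
        assert coarse_fe_tensor.values.min() >= 0.0
        assert coarse_fe_tensor.provenance == "fe"
        assert coarse_fe_tensor.mesh_sha256 == coarse_mesh.sha256()

    def test_stored_slice_matches_a_fresh_single_solve(
        self, coarse_fe_tensor, coarse_mesh, materials, solver_opts
    ):
        """Regenerating one grid point reproduces the stored slice exactly."""
        grid = coarse_fe_tensor.grid
        i, j = 1, 0
        res = solve_static(
            coarse_mesh, materials,
            LoadCase(grid.fy_values[i], grid.fz_values[j]), solver_opts,
        )
        assert np.array_equal(coarse_fe_tensor.values[:, i, j], res.vms)

    def test_regeneration_is_bit_deterministic(
        self, coarse_fe_tensor, coarse_mesh, materials, solver_opts
    ):
        again = generate_fe_snapshots(
            coarse_mesh, materials, coarse_fe_tensor.grid, solver_opts
        )
        assert np.array_equal(coarse_fe_tensor.values, again.values)


class TestAnalyticSurrogate:
    def test_rank_one_tensor_has_vanishing_2x2_minors(self):
        t = generate_analytic_snapshots(
            SurrogateSpec(rank=1), 25, ParameterGrid.uniform(50, 200, 4)
        )
        unfold = t.values.reshape(25, -1)  # mode-1 unfolding, rank 1
        s = np.linalg.svd(unfold, compute_uv=False)
        assert s[1] / s[0] < 1e-12

    def test_seeded_perturbation_is_reproducible(self):
        grid = ParameterGrid.uniform(50, 200, 3)
        spec = SurrogateSpec(rank=2, perturbation=0.05, seed=11)
        a = generate_analytic_snapshots(spec, 20, grid)
        b = generate_analytic_snapshots(spec, 20, grid)
        assert np.array_equal(a.values, b.values)

    def test_continuous_evaluation_matches_grid_samples(self):
        grid = ParameterGrid.uniform(50, 200, 4)
        spec = SurrogateSpec(rank=1)
        t = generate_analytic_snapshots(spec, 30, grid)
        at_node = surrogate_field(spec, 30, grid, 100.0, 150.0)
        assert np.allclose(at_node, t.values[:, 1, 2], rtol=1e-12)

    @pytest.mark.parametrize("kwargs", [dict(rank=0), dict(perturbation=-1.0)])
    def test_invalid_specs_are_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            SurrogateSpec(**kwargs)


def test_snapshot_tensor_validates_shape_and_sign():
    grid = ParameterGrid.uniform(50, 200, 2)
    with pytest.raises(ValidationError, match="inconsistent"):
        SnapshotTensor(values=np.ones((5, 3, 2)), grid=grid)
    with pytest.raises(ValidationError, match="nonnegative"):
        SnapshotTensor(values=-np.ones((5, 2, 2)), grid=grid)
    with pytest.raises(ValidationError, match="finite"):
        SnapshotTensor(values=np.full((5, 2, 2), np.nan), grid=grid)
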