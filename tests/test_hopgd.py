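"""Separated decomposition: fixed point, greedy enrichment, evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toothmor import (
    ParameterGrid,
    SnapshotTensor,
    SurrogateSpec,
    decompose,
    evaluate,
    generate_analytic_snapshots,
    rank_one_fixed_point,
    reconstruct_at_grid,
)
from toothmor.exceptions import (
    ExtrapolationError,
    ValidationError,
    ZeroResidualError,
)

GRID4 = ParameterGrid.uniform(50.0, 200.0, 4)


def random_tensor(seed, shape=(20, 5, 5)):
    rng = np.random.default_rng(seed)
    return np.abs(rng.standard_normal(shape)) + 0.1


class TestRankOneFixedPoint:
    def test_exact_rank_one_converges_in_at_most_two_sweeps(self):
        t = generate_analytic_snapshots(SurrogateSpec(rank=1), 30, GRID4)
        a, g, h, sweeps = rank_one_fixed_point(t.values)
        assert sweeps <= 2
        rec = np.einsum("x,i,j->xij", a, g, h)
        err = np.linalg.norm(rec - t.values) / np.linalg.norm(t.values)
        assert err <= 1e-12

    def test_parametric_factors_are_unit_norm_with_positive_leading_entry(self):
        a, g, h, _ = rank_one_fixed_point(random_tensor(1))
        assert np.linalg.norm(g) == pytest.approx(1.0, abs=1e-12)
        assert np.linalg.norm(h) == pytest.approx(1.0, abs=1e-12)
        assert g[np.flatnonzero(g)[0]] > 0
        assert h[np.flatnonzero(h)[0]] > 0

    def test_correction_never_increases_the_residual(self):
        for seed in range(10):
            R = random_tensor(seed)
            before = np.linalg.norm(R)
            a, g, h, _ = rank_one_fixed_point(R)
            after = np.linalg.norm(R - np.einsum("x,i,j->xij", a, g, h))
            assert after <= before + 1e-12

    def test_zero_residual_signals_no_correction(self):
        with pytest.raises(ZeroResidualError):
            rank_one_fixed_point(np.zeros((4, 3, 3)))

    def test_non_finite_input_is_rejected(self):
        bad = np.ones((4, 3, 3))
        bad[0, 0, 0] = np.inf
        with pytest.raises(ValidationError):
            rank_one_fixed_point(bad)


class TestDecompose:
    def test_zero_tensor_yields_an_empty_model(self):
        t = SnapshotTensor(values=np.zeros((10, 4, 4)), grid=GRID4)
        model = decompose(t)
        assert model.n_modes == 0
        assert model.residual_history == []
        assert np.abs(reconstruct_at_grid(model)).max() == 0.0

    @pytest.mark.parametrize("rank, max_expected", [(1, 1), (3, 3)])
    def test_separable_tensors_are_recovered_with_their_rank(self, rank, max_expected):
        t = generate_analytic_snapshots(
            SurrogateSpec(rank=rank), 30, ParameterGrid.uniform(50, 200, 5)
        )
        model = decompose(t, tol_modes=1e-8)
        assert model.n_modes <= max_expected
        assert model.residual_history[-1] <= 1e-8

    def test_residual_history_is_non_increasing(self):
        t = SnapshotTensor(values=random_tensor(7), grid=ParameterGrid.uniform(50, 200, 5))
        model = decompose(t, tol_modes=1e-12, max_modes=15)
        hist = np.asarray(model.residual_history)
        assert np.all(np.diff(hist) <= 1e-12)

    def test_reconstruction_matches_the_recorded_final_residual(self):
        t = SnapshotTensor(values=random_tensor(3), grid=ParameterGrid.uniform(50, 200, 5))
        model = decompose(t, tol_modes=1e-6, max_modes=10)
        rec = reconstruct_at_grid(model)
        res = np.linalg.norm(rec - t.values) / np.linalg.norm(t.values)
        assert res == pytest.approx(model.residual_history[-1], abs=1e-10)


class TestEvaluate:
    @pytest.fixture(scope="class")
    @staticmethod
    def model():
        t = generate_analytic_snapshots(SurrogateSpec(rank=3), 30, GRID4)
        return decompose(t, tol_modes=1e-10)

    @pytest.mark.parametrize("scheme", ["linear", "cubic"])
    def test_grid_nodes_are_reproduced_exactly(self, model, scheme):
        rec = reconstruct_at_grid(model)
        for i, fy in enumerate(model.grid.fy_values):
            for j, fz in enumerate(model.grid.fz_values):
                v = evaluate(model, fy, fz, interp_scheme=scheme)
                ref = rec[:, i, j]
                assert np.linalg.norm(v - ref) <= 1e-12 * np.linalg.norm(ref)

    @pytest.mark.parametrize("query", [(40.0, 100.0), (100.0, 210.0)])
    def test_extrapolation_is_refused(self, model, query):
        with pytest.raises(ExtrapolationError):
            evaluate(model, *query)

    def test_interpolation_is_exact_for_linear_parametric_profiles(self):
        spec = SurrogateSpec(
            rank=1, fy_profiles=("linear",), fz_profiles=("linear",)
        )
        t = generate_analytic_snapshots(spec, 25, GRID4)
        model = decompose(t, tol_modes=1e-10)
        from toothmor import surrogate_field

        truth = surrogate_field(spec, 25, GRID4, 75.0, 175.0)
        v = evaluate(model, 75.0, 175.0)
        assert np.linalg.norm(v - truth) <= 1e-8 * np.linalg.norm(truth)


@given(seed=st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_greedy_monotonicity_property(seed):
    """Residual history is non-increasing for arbitrary positive tensors."""
    t = SnapshotTensor(
        values=random_tensor(seed, (12, 4, 4)), grid=GRID4
    )
    model = decompose(t, tol_modes=1e-12, max_modes=10)
    hist = np.asarray(model.residual_history)
    assert np.all(np.diff(hist) <= 1e-12)
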