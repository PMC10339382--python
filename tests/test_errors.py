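"""Error metric: δ identities, center placement, refinement convergence."""

import numpy as np
import pytest

from toothmor import (
    ParameterGrid,
    SurrogateSpec,
    decompose,
    error_report,
    generate_analytic_snapshots,
    relative_error,
    subdomain_centers,
)
from toothmor.exceptions import ValidationError, ZeroNormError


class TestSubdomainCenters:
    def test_canonical_grid_yields_nine_centers(self):
        centers = subdomain_centers(ParameterGrid.uniform(50, 200, 4))
        assert len(centers) == 9
        coords = {(c.fy, c.fz) for c in centers}
        assert coords == {(fy, fz) for fy in (75.0, 125.0, 175.0)
                          for fz in (75.0, 125.0, 175.0)}

    def test_two_point_grid_has_a_single_central_point(self):
        (c,) = subdomain_centers(ParameterGrid.uniform(50, 200, 2))
        assert (c.fy, c.fz) == (125.0, 125.0)

    def test_count_is_product_of_cell_counts(self):
        grid = ParameterGrid.uniform(50, 200, 5, 3)
        assert len(subdomain_centers(grid)) == 4 * 2


class TestRelativeError:
    def test_identical_fields_have_zero_error(self):
        u = np.linspace(1, 5, 20)
        assert relative_error(u, u) == 0.0

    def test_zero_prediction_has_unit_error(self):
        u = np.linspace(1, 5, 20)
        assert relative_error(np.zeros_like(u), u) == pytest.approx(1.0)

    def test_doubling_the_field_has_unit_error(self):
        u = np.linspace(1, 5, 20)
        assert relative_error(2 * u, u) == pytest.approx(1.0)

    def test_zero_reference_is_an_explicit_error(self):
        with pytest.raises(ZeroNormError):
            relative_error(np.ones(5), np.zeros(5))

    def test_length_mismatch_is_rejected(self):
        with pytest.raises(ValidationError):
            relative_error(np.ones(4), np.ones(5))


LINEAR_RANK1 = SurrogateSpec(rank=1, fy_profiles=("linear",), fz_profiles=("linear",))


class TestErrorReport:
    def test_exact_surrogate_with_linear_profiles_gives_negligible_delta(self):
        """Rank-1 training data with linear parametric profiles: the model
        is exact and linear interpolation is exact, so every δ ≈ 0."""
        grid = ParameterGrid.uniform(50, 200, 4)
        t = generate_analytic_snapshots(LINEAR_RANK1, 30, grid)
        model = decompose(t, tol_modes=1e-10)
        report = error_report(model, reference_source="analytic",
                              surrogate=LINEAR_RANK1)
        assert len(report.table) == 9
        assert (report.table["delta_pct"] <= 1e-8 * 100).all()
        assert not report.any_flagged

    def test_report_is_byte_deterministic(self):
        grid = ParameterGrid.uniform(50, 200, 3)
        spec = SurrogateSpec(rank=2, orthogonalize=False)
        t = generate_analytic_snapshots(spec, 25, grid)
        model = decompose(t, tol_modes=1e-8, max_modes=5)
        a = error_report(model, reference_source="analytic", surrogate=spec).to_csv()
        b = error_report(model, reference_source="analytic", surrogate=spec).to_csv()
        assert a == b

    def test_max_center_error_decreases_under_grid_refinement(self):
        """Smooth nonlinear surrogate: max δ strictly decreases across
        training grids 3x3 -> 5x5 -> 9x9."""
        spec = SurrogateSpec(
            rank=1, fy_profiles=("quadratic",), fz_profiles=("sine",)
        )
        maxima = []
        for n in (3, 5, 9):
            grid = ParameterGrid.uniform(50, 200, n)
            t = generate_analytic_snapshots(spec, 30, grid)
            model = decompose(t, tol_modes=1e-12)
            report = error_report(model, reference_source="analytic", surrogate=spec)
            maxima.append(report.table["delta_pct"].max())
        assert maxima[0] > maxima[1] > maxima[2]
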