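"""Static solver: patch test, equilibrium, symmetry, von Mises identities."""

import numpy as np
import pytest
from scipy.optimize import brentq

from toothmor import (
    LoadCase,
    Material,
    MaterialSet,
    Mesh,
    Region,
    SolverOptions,
    solve_static,
    von_mises_field,
)
from toothmor.exceptions import ValidationError

from conftest import make_square_mesh


def test_zero_load_gives_zero_displacement_and_stress(coarse_mesh, materials):
    res = solve_static(coarse_mesh, materials, LoadCase(0.0, 0.0), SolverOptions())
    assert np.abs(res.displacement).max() == 0.0
    assert np.abs(res.vms).max() == 0.0


def _homogeneous_uniaxial_oracle(E, nu, traction):
    """Exact homogeneous solution for a dead traction on the top edge.

    Plane strain, Saint Venant-Kirchhoff, F = diag(λx, λy): solve
    P_xx = 0 and P_yy = t for the principal stretches, then return the
    uniform Cauchy stress components.
    """
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))

    def lx_of_ly(ly):
        # P_xx = λx S_xx = 0 with S_xx = lam·tr(E) + 2μ E_xx
        # → E_xx = −lam·E_yy/(lam+2μ)
        Ey = 0.5 * (ly * ly - 1)
        Ex = -lam * Ey / (lam + 2 * mu)
        return np.sqrt(1 + 2 * Ex)

    def pyy(ly):
        lx = lx_of_ly(ly)
        Ex, Ey = 0.5 * (lx * lx - 1), 0.5 * (ly * ly - 1)
        return ly * (lam * (Ex + Ey) + 2 * mu * Ey) - traction

    ly = brentq(pyy, 0.9, 1.1, xtol=1e-15)
    lx = lx_of_ly(ly)
    Ex, Ey = 0.5 * (lx * lx - 1), 0.5 * (ly * ly - 1)
    tr = Ex + Ey
    J = lx * ly
    syy = ly * (lam * tr + 2 * mu * Ey) * ly / J
    szz = lam * tr / J
    return syy, szz


def test_patch_test_matches_the_homogeneous_closed_form():
    """Uniform traction on a homogeneous square: stress field is uniform
    and equals the closed-form solution to 1e-6 relative."""
    mesh, idx = make_square_mesh(n=4)
    mats = MaterialSet({Region.DENTIN: Material(kind="linear_elastic", E=1000.0, nu=0.3)})
    traction = 5.0
    res = solve_static(
        mesh, mats, LoadCase(fy=0.0, fz=-traction),
        SolverOptions(slice_depth=1.0, n_increments=1),
        constraints=[(idx[:, 0].copy(), 1), (np.array([idx[0, 0]]), 0)],
    )
    syy, szz = _homogeneous_uniaxial_oracle(1000.0, 0.3, traction)
    assert np.abs(res.stress[:, 1, 1] - syy).max() / abs(syy) < 1e-6
    assert np.abs(res.stress[:, 2, 2] - szz).max() / abs(szz) < 1e-6
    assert np.abs(res.stress[:, 0, 0]).max() / abs(syy) < 1e-6


def test_reactions_balance_the_applied_load(coarse_mesh, materials):
    res = solve_static(coarse_mesh, materials, LoadCase(120.0, 80.0), SolverOptions())
    scale = np.linalg.norm(res.applied_sum)
    assert np.linalg.norm(res.reaction_sum + res.applied_sum) / scale < 1e-8


def _reflect(mesh):
    """Mirror the mesh about the vertical axis, preserving orientation."""
    coords = mesh.node_coords.copy()
    coords[:, 0] *= -1.0
    elements = mesh.elements[:, [0, 2, 1]].copy()
    return Mesh(
        node_coords=coords,
        elements=elements,
        region_tag=mesh.region_tag.copy(),
        boundary_sets={k: v.copy() for k, v in mesh.boundary_sets.items()},
    )


def test_axial_load_yields_mirror_symmetric_stress(coarse_mesh, materials):
    """Pure axial load: solving on the reflected mesh reproduces the von
    Mises field at mirrored node positions within discretization error."""
    opts = SolverOptions()
    res = solve_static(coarse_mesh, materials, LoadCase(0.0, 100.0), opts)
    res_ref = solve_static(_reflect(coarse_mesh), materials, LoadCase(0.0, 100.0), opts)
    # node i of the reflected mesh sits at the mirror image of node i
    diff = np.linalg.norm(res.vms - res_ref.vms) / np.linalg.norm(res.vms)
    assert diff < 0.05


def test_displacement_scales_linearly_in_the_small_strain_limit(coarse_mesh, materials):
    """‖u(ε)‖ / ‖u(ε/2)‖ → 2 within 1% as loads shrink."""
    opts = SolverOptions(n_increments=1)
    eps = 1e-2
    u1 = solve_static(coarse_mesh, materials, LoadCase(50 * eps, 50 * eps), opts)
    u2 = solve_static(coarse_mesh, materials, LoadCase(25 * eps, 25 * eps), opts)
    ratio = np.linalg.norm(u1.displacement) / np.linalg.norm(u2.displacement)
    assert ratio == pytest.approx(2.0, rel=0.01)


@pytest.mark.parametrize(
    "tensor, expected",
    [
        (np.diag([3.0, 3.0, 3.0]), 0.0),  # hydrostatic
        (np.diag([2.5, 0.0, 0.0]), 2.5),  # uniaxial
        (np.array([[0, 1.2, 0], [1.2, 0, 0], [0, 0, 0]]), 1.2 * np.sqrt(3)),  # shear
    ],
)
def test_von_mises_closed_forms(tensor, expected):
    assert von_mises_field(tensor)[0] == pytest.approx(expected, abs=1e-12)


def test_von_mises_rejects_non_symmetric_input():
    bad = np.zeros((1, 3, 3))
    bad[0, 0, 1] = 1.0
    with pytest.raises(ValidationError, match="symmetric"):
        von_mises_field(bad)
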