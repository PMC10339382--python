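"""Ogden constitutive law: energy values, stress consistency, limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toothmor import ogden_cauchy_stress, ogden_energy
from toothmor.exceptions import ValidationError

MU, ALPHA, D = 0.5, 10.0, 0.4


def energy_of_F(F, mu=MU, alpha=ALPHA, d=D):
    J = np.linalg.det(F)
    lam = np.sqrt(np.linalg.eigvalsh(F @ F.T))
    lb = J ** (-1.0 / 3.0) * lam
    return ogden_energy(lb[0], lb[1], lb[2], J, mu, alpha, d)


def test_energy_vanishes_in_the_reference_state():
    assert ogden_energy(1.0, 1.0, 1.0, 1.0, MU, ALPHA, D) == 0.0


def test_volumetric_term_is_zero_for_isochoric_states():
    lam = 1.3
    iso = (lam, lam**-0.5, lam**-0.5)
    u_total = ogden_energy(*iso, 1.0, MU, ALPHA, D)
    # volumetric part alone: undeformed isochoric stretches, J != 1
    u_vol = ogden_energy(1.0, 1.0, 1.0, 1.2, MU, ALPHA, D)
    assert u_total == pytest.approx((2 * MU / ALPHA**2) * (sum(l**ALPHA for l in iso) - 3))
    assert u_vol == pytest.approx(0.2**2 / D)


def test_uniaxial_isochoric_energy_matches_hand_evaluated_closed_form():
    """λ̄ = (1.2, 1.2^-1/2, 1.2^-1/2), μ = 1 MPa, α = 2, J = 1."""
    lam = 1.2
    value = ogden_energy(lam, lam**-0.5, lam**-0.5, 1.0, 1.0, 2.0, D)
    # (2·1/2²)(1.2² + 2/1.2 − 3) = 0.5 · (1.44 + 1.666̄ − 3)
    assert value == pytest.approx(0.5 * (1.44 + 2.0 / 1.2 - 3.0), rel=1e-12)


@pytest.mark.parametrize(
    "bad", [(-1.0, 1.0, 1.0, 1.0), (1.0, 1.0, 1.0, -2.0), (0.0, 1.0, 1.0, 1.0)]
)
def test_nonpositive_stretch_or_volume_is_a_domain_error(bad):
    with pytest.raises(ValidationError):
        ogden_energy(*bad, MU, ALPHA, D)


def test_stress_vanishes_at_identity():
    assert np.abs(ogden_cauchy_stress(np.eye(3), MU, ALPHA, D)).max() == 0.0


def test_pure_dilatation_stress_is_hydrostatic_and_matches_energy_derivative():
    c = 1.05
    sig = ogden_cauchy_stress(c * np.eye(3), MU, ALPHA, D)
    dev = sig - np.trace(sig) / 3.0 * np.eye(3)
    assert np.abs(dev).max() < 1e-12
    # pressure vs central difference of the volumetric energy U(J)=(J-1)^2/D
    J = c**3
    h = 1e-6
    dUdJ = ((J + h - 1) ** 2 - (J - h - 1) ** 2) / (2 * h * D)
    assert sig[0, 0] == pytest.approx(dUdJ, rel=1e-6)


def test_small_simple_shear_recovers_the_shear_modulus():
    gamma = 1e-4
    F = np.eye(3)
    F[0, 1] = gamma
    sig = ogden_cauchy_stress(F, MU, ALPHA, D)
    assert sig[0, 1] == pytest.approx(MU * gamma, rel=0.01)


def test_inverted_deformation_gradient_is_rejected():
    F = np.diag([-1.0, 1.0, 1.0])
    with pytest.raises(ValidationError, match="det"):
        ogden_cauchy_stress(F, MU, ALPHA, D)


def test_stress_is_consistent_with_numeric_energy_differentiation():
    """σ = (dU/dF) Fᵀ / J at randomized admissible states, ≤ 1e-5 relative."""
    rng = np.random.default_rng(42)
    checked = 0
    while checked < 100:
        F = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
        if np.linalg.det(F) < 0.2:
            continue
        h = 1e-6
        P = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[i, j] += h
                Fm[i, j] -= h
                P[i, j] = (energy_of_F(Fp) - energy_of_F(Fm)) / (2 * h)
        sig_num = P @ F.T / np.linalg.det(F)
        sig = ogden_cauchy_stress(F, MU, ALPHA, D)
        scale = max(np.abs(sig).max(), 1e-12)
        assert np.abs(sig - sig_num).max() / scale < 1e-5
        checked += 1


@given(
    lam1=st.floats(0.5, 2.0),
    lam2=st.floats(0.5, 2.0),
    mu=st.floats(0.01, 10.0),
    alpha=st.floats(-8.0, 8.0).filter(lambda a: abs(a) > 0.5),
)
@settings(max_examples=200, deadline=None)
def test_isochoric_energy_is_nonnegative(lam1, lam2, mu, alpha):
    """AM-GM: the isochoric term is ≥ 0 for every admissible triple."""
    lam3 = 1.0 / (lam1 * lam2)
    u = ogden_energy(lam1, lam2, lam3, 1.0, mu, alpha, D)
    assert u >= -1e-12
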