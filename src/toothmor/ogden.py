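"""First-order compressible Ogden hyperelasticity for the periodontal ligament.

The strain energy density is the standard first-order compressible form in
isochoric principal stretches,

    U(λ̄1, λ̄2, λ̄3, J) = (2 μ / α²) (λ̄1^α + λ̄2^α + λ̄3^α − 3) + (1/D) (J − 1)²,

with λ̄i = J^(−1/3) λi, J = λ1 λ2 λ3, shear-like modulus μ (MPa), strain-
stiffening exponent α (dimensionless) and compressibility parameter D
(MPa⁻¹). With this normalization the ground-state shear modulus is exactly μ
and the ground-state bulk modulus is 2/D. A variant prefactor 2μα circulates
in some renderings of this law; it is dimensionally inconsistent with a
μ-as-shear-modulus reading and is not used here.

Cauchy stress follows from the spectral decomposition of the left
Cauchy–Green tensor b = F Fᵀ:

    σ_i = (2 μ / (α J)) (λ̄_i^α − (λ̄1^α + λ̄2^α + λ̄3^α)/3) + (2/D)(J − 1).
"""

from __future__ import annotations

import numpy as np

from .exceptions import ValidationError

__all__ = ["ogden_energy", "ogden_cauchy_stress", "ogden_principal_cauchy"]

_ISO_TOL = 1e-6  # relative tolerance on λ̄1·λ̄2·λ̄3 = 1


def ogden_energy(lam_bar1, lam_bar2, lam_bar3, J, mu, alpha, D):
    """Strain energy density U in MPa. Inputs may be scalars or arrays.

    Raises
    ------
    ValidationError
        For nonpositive stretches or volume ratio, or if the isochoric
        stretches do not multiply to one within tolerance.
    """
    l1, l2, l3, J = (np.asarray(v, dtype=float) for v in (lam_bar1, lam_bar2, lam_bar3, J))
    if np.any(l1 <= 0) or np.any(l2 <= 0) or np.any(l3 <= 0):
        raise ValidationError("isochoric principal stretches must be positive")
    if np.any(J <= 0):
        raise ValidationError("volume ratio J must be positive")
    if np.any(np.abs(l1 * l2 * l3 - 1.0) > _ISO_TOL):
        raise ValidationError("isochoric stretches must satisfy λ̄1·λ̄2·λ̄3 = 1")
    iso = (2.0 * mu / alpha**2) * (l1**alpha + l2**alpha + l3**alpha - 3.0)
    vol = (J - 1.0) ** 2 / D
    return iso + vol


def ogden_principal_cauchy(lam_bar, J, mu, alpha, D):
    """Principal Cauchy stresses (MPa) from isochoric stretches.

    Parameters
    ----------
    lam_bar : (..., 3) array
        Isochoric principal stretches.
    J : (...) array
        Volume ratio.
    """
    lb = np.asarray(lam_bar, dtype=float)
    J = np.asarray(J, dtype=float)
    powers = lb**alpha
    mean_pow = powers.mean(axis=-1, keepdims=True)
    dev = np.expand_dims(2.0 * mu / (alpha * J), -1) * (powers - mean_pow)
    p = (2.0 / D) * (J - 1.0)
    return dev + np.expand_dims(p, -1)


def ogden_cauchy_stress(F, mu, alpha, D):
    """Cauchy stress tensor for a single deformation gradient.

    Parameters
    ----------
    F : (3, 3) array
        Deformation gradient with det(F) > 0.

    Returns
    -------
    (3, 3) symmetric array, MPa.

    Raises
    ------
    ValidationError
        If det(F) ≤ 0 (inverted state).
    """
    F = np.asarray(F, dtype=float)
    if F.shape != (3, 3):
        raise ValidationError("F must be a 3x3 deformation gradient")
    J = float(np.linalg.det(F))
    if J <= 0.0:
        raise ValidationError("det(F) must be positive (element would be inverted)")
    b = F @ F.T
    evals, evecs = np.linalg.eigh(b)
    lam = np.sqrt(np.maximum(evals, 0.0))
    lam_bar = J ** (-1.0 / 3.0) * lam
    sig_princ = ogden_principal_cauchy(lam_bar, np.float64(J), mu, alpha, D)
    return (evecs * sig_princ) @ evecs.T
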