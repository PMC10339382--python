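"""Greedy separated (rank-one) decomposition of snapshot tensors.

The reduced model approximates the snapshot tensor S(x, Fy, Fz) by a sum of
M separable modes,

    S(x, i, j) ≈ Σ_m  a_m(x) · g_m(i) · h_m(j),

built greedily: each mode is the best rank-one correction to the current
residual, found by an alternating fixed-point iteration that cyclically
replaces each factor with its least-squares optimum given the other two.
The parametric factors g_m, h_m are stored with unit Euclidean norm (the
mode's magnitude lives in the spatial factor a_m) and a positive-first-entry
sign convention, so serialized models are comparable across runs.

Online queries at new (Fy, Fz) interpolate g_m and h_m along their axes
(piecewise linear by default, natural cubic spline optionally) and
recombine the modes — no finite-element solve is involved.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.interpolate import CubicSpline

from .exceptions import ExtrapolationError, ValidationError, ZeroResidualError
from .snapshots import ParameterGrid, SnapshotTensor

__all__ = [
    "SeparatedModel",
    "rank_one_fixed_point",
    "decompose",
    "evaluate",
    "reconstruct_at_grid",
]

_INTERP_SCHEMES = ("linear", "cubic")


@dataclass
class SeparatedModel:
    """Reduced model: M separable modes over a parameter grid.

    Attributes
    ----------
    space_vectors : (n_nodes, M) array, MPa
        Spatial factors carrying each mode's magnitude.
    fy_vectors, fz_vectors : (M, n_fy), (M, n_fz) arrays
        Unit-norm parametric factors.
    residual_history : list of float
        Relative Frobenius residual after each enrichment; non-increasing.
    interp_scheme : str
        ``"linear"`` or ``"cubic"`` parametric interpolation.
    """

    space_vectors: np.ndarray
    fy_vectors: np.ndarray
    fz_vectors: np.ndarray
    grid: ParameterGrid
    residual_history: List[float] = field(default_factory=list)
    interp_scheme: str = "linear"
    options_digest: str = ""

    @property
    def n_modes(self) -> int:
        return self.space_vectors.shape[1]

    def __post_init__(self):
        if self.interp_scheme not in _INTERP_SCHEMES:
            raise ValidationError(f"unknown interp scheme {self.interp_scheme!r}")


def _ls_factor(residual: np.ndarray, axis: int, a: np.ndarray,
               g: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Least-squares optimum of one factor given the other two."""
    if axis == 0:
        return np.einsum("xij,i,j->x", residual, g, h) / (g @ g * (h @ h))
    if axis == 1:
        return np.einsum("xij,x,j->i", residual, a, h) / (a @ a * (h @ h))
    return np.einsum("xij,x,i->j", residual, a, g) / (a @ a * (g @ g))


def _fix_signs(a, g, h):
    """Positive-first-nonzero-entry convention on the parametric factors."""
    for vec in (g, h):
        nz = np.flatnonzero(vec)
        if nz.size and vec[nz[0]] < 0:
            vec *= -1.0
            a *= -1.0
    return a, g, h


def rank_one_fixed_point(
    residual: np.ndarray,
    init: str = "svd",
    tol_fp: float = 1e-8,
    max_sweeps: int = 200,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Best rank-one correction a ⊗ g ⊗ h to a 3-way residual tensor.

    Alternates least-squares updates of the three factors until the relative
    change of the reconstructed rank-one term between sweeps drops below
    ``tol_fp``. Parametric factors are returned unit-norm with fixed sign.

    Parameters
    ----------
    init : {"svd", "ones"}
        Start the parametric factors from the leading left singular vectors
        of the corresponding unfoldings (robust, deterministic), or from
        all-ones vectors.

    Returns
    -------
    (space_vector, fy_vector, fz_vector, sweeps_used)

    Raises
    ------
    ZeroResidualError
        If the residual is identically zero (no correction exists).
    """
    R = np.asarray(residual, dtype=float)
    if R.ndim != 3:
        raise ValidationError("residual must be a 3-way tensor")
    if not np.all(np.isfinite(R)):
        raise ValidationError("residual tensor contains non-finite entries")
    if not tol_fp > 0:
        raise ValidationError("tol_fp must be positive")
    if not np.any(R):
        raise ZeroResidualError("residual tensor is identically zero")

    n_x, n_y, n_z = R.shape
    if init == "svd":
        # leading eigenvector of the unfolding Gram matrix (small: n_y, n_z)
        uy = R.transpose(1, 0, 2).reshape(n_y, -1)
        uz = R.transpose(2, 0, 1).reshape(n_z, -1)
        g = _leading_eigvec(uy @ uy.T)
        h = _leading_eigvec(uz @ uz.T)
    elif init == "ones":
        g = np.ones(n_y) / np.sqrt(n_y)
        h = np.ones(n_z) / np.sqrt(n_z)
    else:
        raise ValidationError(f"unknown init strategy {init!r}")

    a = _ls_factor(R, 0, None, g, h)
    prev_a, prev_g, prev_h = a.copy(), g.copy(), h.copy()
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        g = _ls_factor(R, 1, a, g, h)
        gn = np.linalg.norm(g)
        if gn == 0:
            break
        g /= gn
        h = _ls_factor(R, 2, a, g, h)
        hn = np.linalg.norm(h)
        if hn == 0:
            break
        h /= hn
        a = _ls_factor(R, 0, None, g, h)
        # relative change of the rank-one term between sweeps, computed
        # without forming the full tensors
        na2 = a @ a
        np2 = prev_a @ prev_a
        cross = (a @ prev_a) * (g @ prev_g) * (h @ prev_h)
        diff2 = max(na2 + np2 - 2.0 * cross, 0.0)
        if na2 > 0 and np.sqrt(diff2 / na2) < tol_fp:
            break
        prev_a, prev_g, prev_h = a.copy(), g.copy(), h.copy()
    a, g, h = _fix_signs(a, g, h)
    return a, g, h, sweeps


def _leading_eigvec(M: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(M)
    vec = v[:, -1]
    nz = np.flatnonzero(vec)
    if nz.size and vec[nz[0]] < 0:
        vec = -vec
    return vec


def decompose(
    tensor: SnapshotTensor,
    tol_modes: float = 1e-4,
    max_modes: int = 50,
    tol_fp: float = 1e-8,
    max_sweeps: int = 200,
    interp_scheme: str = "linear",
    init: str = "svd",
) -> SeparatedModel:
    """Greedy rank-one enrichment until the relative residual is small.

    Each accepted correction is subtracted from the running residual; the
    loop stops when the relative Frobenius residual drops to ``tol_modes``
    or ``max_modes`` is reached. The residual history is recorded per mode
    and is non-increasing by construction (each correction is a
    least-squares projection).
    """
    if not (tol_modes > 0 and tol_fp > 0):
        raise ValidationError("tolerances must be positive")
    T = np.asarray(tensor.values, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValidationError("snapshot tensor contains non-finite entries")

    norm_T = np.linalg.norm(T)
    R = T.copy()
    A, G, H = [], [], []
    history: List[float] = []
    digest = hashlib.sha256(
        json.dumps(
            {
                "tol_modes": tol_modes,
                "max_modes": max_modes,
                "tol_fp": tol_fp,
                "max_sweeps": max_sweeps,
                "interp_scheme": interp_scheme,
                "init": init,
                "source": tensor.config_digest,
            },
            sort_keys=True,
        ).encode()
    ).hexdigest()[:12]

    if norm_T > 0:
        while len(A) < max_modes:
            try:
                a, g, h, _ = rank_one_fixed_point(R, init, tol_fp, max_sweeps)
            except ZeroResidualError:
                break
            if not np.any(a):
                break
            R -= np.einsum("x,i,j->xij", a, g, h)
            A.append(a)
            G.append(g)
            H.append(h)
            history.append(float(np.linalg.norm(R) / norm_T))
            if history[-1] <= tol_modes:
                break

    m = len(A)
    n_x, n_y, n_z = T.shape
    return SeparatedModel(
        space_vectors=np.array(A).T.reshape(n_x, m) if m else np.zeros((n_x, 0)),
        fy_vectors=np.array(G).reshape(m, n_y) if m else np.zeros((0, n_y)),
        fz_vectors=np.array(H).reshape(m, n_z) if m else np.zeros((0, n_z)),
        grid=tensor.grid,
        residual_history=history,
        interp_scheme=interp_scheme,
        options_digest=digest,
    )


def _interp_factors(vectors: np.ndarray, axis: np.ndarray, value: float,
                    scheme: str) -> np.ndarray:
    """Interpolate each mode's parametric vector at one query value."""
    if not (axis[0] <= value <= axis[-1]):
        raise ExtrapolationError(
            f"query {value:g} outside training range [{axis[0]:g}, {axis[-1]:g}]; "
            "rebuild the model on a wider grid instead of extrapolating"
        )
    if scheme == "linear":
        j = int(np.clip(np.searchsorted(axis, value) - 1, 0, axis.size - 2))
        t = (value - axis[j]) / (axis[j + 1] - axis[j])
        return vectors[:, j] * (1.0 - t) + vectors[:, j + 1] * t
    if scheme == "cubic":
        return CubicSpline(axis, vectors, axis=1, bc_type="natural")(value)
    raise ValidationError(f"unknown interp scheme {scheme!r}")


def evaluate(model: SeparatedModel, fy: float, fz: float,
             interp_scheme: Optional[str] = None) -> np.ndarray:
    """Real-time query: nodal von Mises field at a new (Fy, Fz).

    Pure interpolation and mode recombination; issues no finite-element
    solve. Queries outside the training grid's bounding box raise
    :class:`~toothmor.exceptions.ExtrapolationError`.
    """
    scheme = interp_scheme or model.interp_scheme
    ghat = _interp_factors(model.fy_vectors, model.grid.fy_values, float(fy), scheme)
    hhat = _interp_factors(model.fz_vectors, model.grid.fz_values, float(fz), scheme)
    return model.space_vectors @ (ghat * hhat)


def reconstruct_at_grid(model: SeparatedModel) -> np.ndarray:
    """Σ_m outer products at the training grid (residual verification)."""
    if model.n_modes == 0:
        return np.zeros(
            (model.space_vectors.shape[0],) + model.grid.shape
        )
    return np.einsum(
        "xm,mi,mj->xij", model.space_vectors, model.fy_vectors, model.fz_vectors
    )
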