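"""Static plane-strain finite-element solver with von Mises post-processing.

Total-Lagrangian formulation on 6-node quadratic triangles (quadratic
displacements on straight-sided elements, 3-point Gauss quadrature).
Quadratic elements keep the nearly incompressible ligament usable without a
mixed formulation. The load is a uniformly distributed dead traction over
the crown's upper edge whose resultant equals the prescribed occlusal force,
divided by an out-of-plane slice depth that represents the real root's
third-dimension extent (a unit-depth slice would otherwise see unphysically
high tractions).

Sign convention: the lateral component Fy acts along +x, the axial component
Fz is the downward bite force, i.e. the applied resultant per unit depth is
(Fy, −Fz) / slice_depth.

Newton–Raphson with a per-element finite-difference tangent (correctness is
judged by the residual, not the tangent), incremental loading and automatic
step halving on divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .exceptions import (
    InvertedElementError,
    MaterialError,
    SolverError,
    ValidationError,
)
from .geometry import Mesh, Region
from .materials import Material, MaterialSet

__all__ = [
    "LoadCase",
    "SolverOptions",
    "StaticResult",
    "solve_static",
    "von_mises_field",
    "solve_call_count",
]

# module-level instrumentation: how many static solves have run (used to
# assert that reduced-model queries never fall back to the FE solver)
_SOLVE_CALLS = 0


def solve_call_count() -> int:
    """Number of :func:`solve_static` invocations in this process."""
    return _SOLVE_CALLS


@dataclass(frozen=True)
class LoadCase:
    """Occlusal load split into lateral (Fy, +x) and axial (Fz, downward) N."""

    fy: float
    fz: float

    def validate(self) -> None:
        if not (np.isfinite(self.fy) and np.isfinite(self.fz)):
            raise ValidationError("load components must be finite")


@dataclass(frozen=True)
class SolverOptions:
    """Newton/incrementation controls.

    ``slice_depth`` (mm) is the out-of-plane extent over which the occlusal
    force is spread; the solver works in force-per-unit-depth.
    """

    newton_tol: float = 1e-8
    max_iterations: int = 25
    n_increments: int = 4
    max_halvings: int = 6
    fd_step: float = 1e-7
    slice_depth: float = 30.0
    load_set: str = "LOAD"
    fixed_set: str = "FIXED"
    #: "auto": closed-form tangent for linear-elastic groups, finite
    #: differences for the hyperelastic ligament; "fd": differences for all
    tangent_mode: str = "auto"


@dataclass
class StaticResult:
    """Converged static solution.

    ``displacement`` and ``stress`` are given at the mesh's vertex nodes;
    ``stress`` holds full symmetric Cauchy tensors (3, 3) including the
    plane-strain out-of-plane component. ``vms`` is the nodal von Mises
    field. ``reaction_sum`` and ``applied_sum`` are per-unit-depth force
    resultants (N/mm) and balance each other.
    """

    displacement: np.ndarray
    stress: np.ndarray
    vms: np.ndarray
    reaction_sum: np.ndarray
    applied_sum: np.ndarray
    n_newton: int
    n_increments: int
    displacement_full: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# quadratic element machinery
# ---------------------------------------------------------------------------

# 3-point Gauss rule on the unit triangle (degree-2 exact), weights sum 1/2
_GAUSS_PTS = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
_GAUSS_W = np.array([1 / 6, 1 / 6, 1 / 6])


def _tri6_dshape(xi: float, eta: float) -> np.ndarray:
    """d N / d(xi, eta) for the 6-node triangle, shape (6, 2).

    Node order: vertices (v0, v1, v2) then midsides (v0v1, v1v2, v2v0);
    L0 = 1 − ξ − η is the barycentric coordinate of v0.
    """
    l0 = 1.0 - xi - eta
    return np.array(
        [
            [-(4 * l0 - 1), -(4 * l0 - 1)],
            [4 * xi - 1, 0.0],
            [0.0, 4 * eta - 1],
            [4 * (l0 - xi), -4 * xi],
            [4 * eta, 4 * xi],
            [-4 * eta, 4 * (l0 - eta)],
        ]
    )


class _QuadraticMesh:
    """Tri6 promotion of a linear mesh plus precomputed element geometry."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        nv = mesh.n_nodes
        tris = mesh.elements
        edge_mid: Dict[Tuple[int, int], int] = {}
        conn = np.empty((mesh.n_elements, 6), dtype=np.int64)
        mid_coords: List[np.ndarray] = []
        edge_count: Dict[Tuple[int, int], int] = {}
        for e, tri in enumerate(tris):
            conn[e, :3] = tri
            for s, (a, b) in enumerate(((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0]))):
                key = (min(a, b), max(a, b))
                edge_count[key] = edge_count.get(key, 0) + 1
                mid = edge_mid.get(key)
                if mid is None:
                    mid = nv + len(mid_coords)
                    edge_mid[key] = mid
                    mid_coords.append(0.5 * (mesh.node_coords[a] + mesh.node_coords[b]))
                conn[e, 3 + s] = mid
        self.conn = conn
        self.coords = np.vstack([mesh.node_coords, np.asarray(mid_coords)])
        self.n_q = self.coords.shape[0]
        self.edge_mid = edge_mid
        self.boundary_edges = [k for k, c in edge_count.items() if c == 1]

        # affine Jacobian per element (straight-sided tri6)
        p0 = mesh.node_coords[tris[:, 0]]
        p1 = mesh.node_coords[tris[:, 1]]
        p2 = mesh.node_coords[tris[:, 2]]
        jac = np.stack(
            [np.stack([p1[:, 0] - p0[:, 0], p2[:, 0] - p0[:, 0]], axis=-1),
             np.stack([p1[:, 1] - p0[:, 1], p2[:, 1] - p0[:, 1]], axis=-1)],
            axis=1,
        )  # (m, 2, 2), columns are d x/d xi, d x/d eta
        det = jac[:, 0, 0] * jac[:, 1, 1] - jac[:, 0, 1] * jac[:, 1, 0]
        inv = np.empty_like(jac)
        inv[:, 0, 0] = jac[:, 1, 1]
        inv[:, 0, 1] = -jac[:, 0, 1]
        inv[:, 1, 0] = -jac[:, 1, 0]
        inv[:, 1, 1] = jac[:, 0, 0]
        inv /= det[:, None, None]
        # dN/dX[m, g, a, j] = dN/dxi[g, a, k] * inv[m, k, j]
        dshape = np.stack([_tri6_dshape(*gp) for gp in _GAUSS_PTS])  # (3, 6, 2)
        self.dNdX = np.einsum("gak,mkj->mgaj", dshape, inv)
        self.wdet = _GAUSS_W[None, :] * det[:, None]  # (m, 3)

    def midnodes_within(self, vertex_set: np.ndarray) -> np.ndarray:
        """Midside nodes of boundary edges whose both ends lie in a set."""
        s = set(int(v) for v in vertex_set)
        return np.array(
            [self.edge_mid[e] for e in self.boundary_edges if e[0] in s and e[1] in s],
            dtype=np.int64,
        )


# ---------------------------------------------------------------------------
# constitutive kernels (vectorized over an element batch at one Gauss point)
# ---------------------------------------------------------------------------


def _svk_stress(F: np.ndarray, mat: Material):
    """First Piola–Kirchhoff (2x2) and Cauchy Voigt [xx,yy,zz,xy] for SVK."""
    lam, mu = mat.lame
    C = np.einsum("eki,ekj->eij", F, F)
    E = 0.5 * (C - np.eye(2))
    tr = E[:, 0, 0] + E[:, 1, 1]  # E_zz = 0 in plane strain
    S = lam * tr[:, None, None] * np.eye(2) + 2.0 * mu * E
    Szz = lam * tr
    P = np.einsum("eij,ejk->eik", F, S)
    J = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
    sig = np.einsum("eij,ejk,elk->eil", F, S, F) / J[:, None, None]
    voigt = np.stack([sig[:, 0, 0], sig[:, 1, 1], Szz / J, sig[:, 0, 1]], axis=-1)
    return P, voigt


def _ogden_stress(F: np.ndarray, mat: Material, elem_ids: np.ndarray):
    """First Piola–Kirchhoff (2x2) and Cauchy Voigt for the Ogden ligament."""
    J = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
    bad = ~(J > 0)
    if np.any(bad):
        eid = int(elem_ids[np.argmax(bad)])
        raise InvertedElementError(
            f"element {eid}: det(F) <= 0 (inverted)", element_id=eid
        )
    C = np.einsum("eki,ekj->eij", F, F)
    c11, c22, c12 = C[:, 0, 0], C[:, 1, 1], C[:, 0, 1]
    half_tr = 0.5 * (c11 + c22)
    disc = np.sqrt(np.maximum(0.25 * (c11 - c22) ** 2 + c12**2, 0.0))
    lam1 = np.sqrt(np.maximum(half_tr + disc, 1e-30))
    lam2 = np.sqrt(np.maximum(half_tr - disc, 1e-30))
    Jm13 = J ** (-1.0 / 3.0)
    lb = np.stack([Jm13 * lam1, Jm13 * lam2, Jm13], axis=-1)
    powers = lb**mat.alpha
    dev = (2.0 * mat.mu / (mat.alpha * J))[:, None] * (
        powers - powers.mean(axis=-1, keepdims=True)
    )
    p = (2.0 / mat.D) * (J - 1.0)
    sig_princ = dev + p[:, None]  # (e, 3)

    phi = 0.5 * np.arctan2(2.0 * c12, c11 - c22)
    N1 = np.stack([np.cos(phi), np.sin(phi)], axis=-1)
    N2 = np.stack([-np.sin(phi), np.cos(phi)], axis=-1)
    n1 = np.einsum("eij,ej->ei", F, N1)
    n2 = np.einsum("eij,ej->ei", F, N2)
    n1 /= np.linalg.norm(n1, axis=-1, keepdims=True)
    n2 /= np.linalg.norm(n2, axis=-1, keepdims=True)
    sig = sig_princ[:, 0, None, None] * np.einsum("ei,ej->eij", n1, n1) + sig_princ[
        :, 1, None, None
    ] * np.einsum("ei,ej->eij", n2, n2)

    Finv = np.empty_like(F)
    Finv[:, 0, 0] = F[:, 1, 1]
    Finv[:, 0, 1] = -F[:, 0, 1]
    Finv[:, 1, 0] = -F[:, 1, 0]
    Finv[:, 1, 1] = F[:, 0, 0]
    Finv /= J[:, None, None]
    P = J[:, None, None] * np.einsum("eij,ekj->eik", sig, Finv)  # J sig F^{-T}
    voigt = np.stack([sig[:, 0, 0], sig[:, 1, 1], sig_princ[:, 2], sig[:, 0, 1]], axis=-1)
    return P, voigt


def _batch_stress(F, mat, elem_ids):
    if mat.kind == "linear_elastic":
        return _svk_stress(F, mat)
    if mat.kind == "ogden1":
        return _ogden_stress(F, mat, elem_ids)
    raise MaterialError(f"unknown material kind {mat.kind!r}")


class _Assembler:
    """Internal-force and finite-difference-tangent assembly."""

    def __init__(self, qm: _QuadraticMesh, materials: MaterialSet):
        self.qm = qm
        tags = qm.mesh.region_tag
        materials.validate_covers(tags)
        self.groups = [
            (materials[Region(t)], np.flatnonzero(tags == t))
            for t in np.unique(tags)
        ]

    def _element_forces(self, ue: np.ndarray, mat: Material, ids: np.ndarray,
                        want_stress: bool = False):
        """Internal force (e, 6, 2) for one material batch; ue is (e, 6, 2)."""
        qm = self.qm
        f = np.zeros_like(ue)
        voigts = [] if want_stress else None
        for g in range(3):
            dN = qm.dNdX[ids, g]  # (e, 6, 2)
            H = np.einsum("eai,eaj->eij", ue, dN)
            F = H + np.eye(2)
            P, voigt = _batch_stress(F, mat, ids)
            f += qm.wdet[ids, g, None, None] * np.einsum("eij,eaj->eai", P, dN)
            if want_stress:
                voigts.append(voigt)
        if want_stress:
            return f, np.stack(voigts, axis=1)  # (e, 3gp, 4)
        return f

    def internal_force(self, u: np.ndarray) -> np.ndarray:
        qm = self.qm
        fglob = np.zeros((qm.n_q, 2))
        for mat, ids in self.groups:
            ue = u[qm.conn[ids]]
            f = self._element_forces(ue, mat, ids)
            np.add.at(fglob, qm.conn[ids], f)
        return fglob

    def gauss_stresses(self, u: np.ndarray):
        """Per-element, per-Gauss-point Cauchy Voigt stresses (m, 3, 4)."""
        qm = self.qm
        out = np.zeros((qm.mesh.n_elements, 3, 4))
        for mat, ids in self.groups:
            ue = u[qm.conn[ids]]
            _, voigt = self._element_forces(ue, mat, ids, want_stress=True)
            out[ids] = voigt
        return out

    def _fd_element_tangent(self, ue: np.ndarray, mat: Material,
                            ids: np.ndarray, h: float) -> np.ndarray:
        f0 = self._element_forces(ue, mat, ids)
        ke = np.empty((ids.size, 12, 12))
        for dof in range(12):
            a, i = divmod(dof, 2)
            up = ue.copy()
            up[:, a, i] += h
            fp = self._element_forces(up, mat, ids)
            ke[:, :, dof] = (fp - f0).reshape(ids.size, 12) / h
        return ke

    def _svk_element_tangent(self, ue: np.ndarray, mat: Material,
                             ids: np.ndarray) -> np.ndarray:
        """Consistent total-Lagrangian tangent for Saint Venant–Kirchhoff."""
        lam, mu = mat.lame
        qm = self.qm
        I2 = np.eye(2)
        ke = np.zeros((ids.size, 6, 2, 6, 2))
        for g in range(3):
            dN = qm.dNdX[ids, g]
            F = np.einsum("eai,eaj->eij", ue, dN) + I2
            E = 0.5 * (np.einsum("eki,ekj->eij", F, F) - I2)
            tr = np.trace(E, axis1=1, axis2=2)
            S = lam * tr[:, None, None] * I2 + 2.0 * mu * E
            B = np.einsum("eik,ejk->eij", F, F)
            gv = np.einsum("eij,eaj->eai", F, dN)
            s_ab = np.einsum("eai,eij,ebj->eab", dN, S, dN)
            d_ab = np.einsum("eai,ebi->eab", dN, dN)
            w = qm.wdet[ids, g]
            ke += w[:, None, None, None, None] * (
                np.einsum("eab,ik->eaibk", s_ab, I2)
                + lam * np.einsum("eai,ebk->eaibk", gv, gv)
                + mu * np.einsum("ebi,eak->eaibk", gv, gv)
                + mu * np.einsum("eik,eab->eaibk", B, d_ab)
            )
        return ke.reshape(ids.size, 12, 12)

    def tangent(self, u: np.ndarray, h: float, mode: str = "auto") -> sp.csr_matrix:
        """Global stiffness; see :class:`SolverOptions` for ``mode``."""
        qm = self.qm
        rows, cols, vals = [], [], []
        for mat, ids in self.groups:
            ue = u[qm.conn[ids]]
            if mode == "auto" and mat.kind == "linear_elastic":
                ke = self._svk_element_tangent(ue, mat, ids)
            else:
                ke = self._fd_element_tangent(ue, mat, ids, h)
            dofs = (2 * qm.conn[ids][:, :, None] + np.array([0, 1])).reshape(ids.size, 12)
            rows.append(np.repeat(dofs, 12, axis=1).ravel())
            cols.append(np.tile(dofs, (1, 12)).ravel())
            vals.append(ke.ravel())
        n = 2 * qm.n_q
        K = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
        return K.tocsr()


def _external_force(qm: _QuadraticMesh, load: LoadCase, opts: SolverOptions,
                    load_vertices: np.ndarray) -> np.ndarray:
    """Consistent nodal loads for a uniform dead traction on the load edge."""
    s = set(int(v) for v in load_vertices)
    edges = [e for e in qm.boundary_edges if e[0] in s and e[1] in s]
    if not edges:
        raise ValidationError("load node set contains no boundary edges")
    total_len = sum(
        float(np.linalg.norm(qm.coords[b] - qm.coords[a])) for a, b in edges
    )
    traction = np.array([load.fy, -load.fz]) / (total_len * opts.slice_depth)
    f = np.zeros((qm.n_q, 2))
    for a, b in edges:
        le = float(np.linalg.norm(qm.coords[b] - qm.coords[a]))
        mid = qm.edge_mid[(min(a, b), max(a, b))]
        f[a] += traction * le / 6.0
        f[b] += traction * le / 6.0
        f[mid] += traction * 2.0 * le / 3.0
    return f


def _newton(assembler, u, f_ext, free, opts):
    """Newton loop at fixed load level; returns (u, iterations) or raises."""
    ref = np.linalg.norm(f_ext.reshape(-1)[free])
    tol_abs = opts.newton_tol * max(ref, 1e-14)
    last = np.inf
    for it in range(opts.max_iterations + 1):
        r = assembler.internal_force(u) - f_ext
        rn = np.linalg.norm(r.reshape(-1)[free])
        if not np.isfinite(rn):
            raise SolverError("non-finite residual", last_residual=last)
        last = rn
        if rn <= tol_abs:
            return u, it
        if it == opts.max_iterations:
            break
        K = assembler.tangent(u, opts.fd_step, mode=opts.tangent_mode)
        Kff = K[free][:, free]
        du = spla.spsolve(Kff, -r.reshape(-1)[free])
        uf = u.reshape(-1)
        uf[free] += du
    raise SolverError(
        f"Newton did not converge in {opts.max_iterations} iterations "
        f"(residual {last:.3e}, tol {tol_abs:.3e})",
        last_residual=last,
    )


def solve_static(
    mesh: Mesh,
    materials: MaterialSet,
    load: LoadCase,
    opts: Optional[SolverOptions] = None,
    constraints: Optional[Sequence[Tuple[np.ndarray, int]]] = None,
) -> StaticResult:
    """Solve the static problem and recover nodal Cauchy/von Mises stress.

    Parameters
    ----------
    constraints
        Optional list of ``(vertex_ids, component)`` Dirichlet constraints
        replacing the default (both components of the mesh's FIXED set).
        Midside nodes of boundary edges internal to each set are constrained
        with it.

    Raises
    ------
    SolverError
        If Newton fails after exhausting the step-halving budget; carries
        the last residual norm.
    InvertedElementError
        If an element inverts in an accepted state.
    """
    global _SOLVE_CALLS
    _SOLVE_CALLS += 1

    opts = opts or SolverOptions()
    load.validate()
    qm = _QuadraticMesh(mesh)
    assembler = _Assembler(qm, materials)

    fixed_mask = np.zeros(2 * qm.n_q, dtype=bool)
    if constraints is None:
        verts = mesh.boundary_sets[opts.fixed_set]
        nodes = np.concatenate([verts, qm.midnodes_within(verts)])
        fixed_mask[2 * nodes] = True
        fixed_mask[2 * nodes + 1] = True
    else:
        for verts, comp in constraints:
            verts = np.asarray(verts, dtype=np.int64)
            nodes = np.concatenate([verts, qm.midnodes_within(verts)])
            fixed_mask[2 * nodes + comp] = True
    free = np.flatnonzero(~fixed_mask)

    f_ext = _external_force(qm, load, opts, mesh.boundary_sets[opts.load_set])

    u = np.zeros((qm.n_q, 2))
    gamma = 0.0
    dgamma = 1.0 / max(1, opts.n_increments)
    halvings = 0
    n_newton = 0
    n_inc = 0
    while gamma < 1.0 - 1e-12:
        target = min(1.0, gamma + dgamma)
        try:
            u_try, its = _newton(assembler, u.copy(), target * f_ext, free, opts)
        except SolverError as err:
            halvings += 1
            if halvings > opts.max_halvings:
                raise SolverError(
                    f"load stepping failed at level {target:.4f} after "
                    f"{opts.max_halvings} halvings: {err}",
                    last_residual=err.last_residual,
                ) from err
            dgamma *= 0.5
            continue
        u = u_try
        gamma = target
        n_newton += its
        n_inc += 1

    # stress recovery: Gauss values averaged to vertex nodes (wdet weights)
    gp_voigt = assembler.gauss_stresses(u)  # (m, 3, 4)
    nv = mesh.n_nodes
    acc = np.zeros((nv, 4))
    wacc = np.zeros(nv)
    w = qm.wdet  # (m, 3)
    contrib = np.einsum("mg,mgv->mv", w, gp_voigt)  # (m, 4)
    for k in range(3):
        np.add.at(acc, mesh.elements[:, k], contrib)
        np.add.at(wacc, mesh.elements[:, k], w.sum(axis=1))
    voigt_nodal = acc / wacc[:, None]

    stress = np.zeros((nv, 3, 3))
    stress[:, 0, 0] = voigt_nodal[:, 0]
    stress[:, 1, 1] = voigt_nodal[:, 1]
    stress[:, 2, 2] = voigt_nodal[:, 2]
    stress[:, 0, 1] = stress[:, 1, 0] = voigt_nodal[:, 3]

    r = assembler.internal_force(u) - f_ext
    reaction = r.reshape(-1).copy()
    reaction[free] = 0.0
    reaction_sum = reaction.reshape(-1, 2).sum(axis=0)
    applied_sum = f_ext.sum(axis=0)

    return StaticResult(
        displacement=u[:nv].copy(),
        stress=stress,
        vms=von_mises_field(stress),
        reaction_sum=reaction_sum,
        applied_sum=applied_sum,
        n_newton=n_newton,
        n_increments=n_inc,
        displacement_full=u,
    )


def von_mises_field(stress: np.ndarray) -> np.ndarray:
    """Nodal von Mises stress from symmetric Cauchy tensors (n, 3, 3).

    Includes the plane-strain out-of-plane normal component. Hydrostatic
    states map to zero; uniaxial stress s maps to |s|; pure shear τ maps to
    √3·τ.
    """
    s = np.asarray(stress, dtype=float)
    if s.ndim == 2:
        s = s[None]
    if s.shape[-2:] != (3, 3):
        raise ValidationError("stress must have shape (n, 3, 3)")
    if not np.allclose(s, np.swapaxes(s, -1, -2), rtol=1e-8, atol=1e-10 * max(1.0, float(np.abs(s).max()))):
        raise ValidationError("stress tensors must be symmetric")
    sxx, syy, szz = s[:, 0, 0], s[:, 1, 1], s[:, 2, 2]
    sxy, syz, sxz = s[:, 0, 1], s[:, 1, 2], s[:, 0, 2]
    vm = np.sqrt(
        0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
        + 3.0 * (sxy**2 + syz**2 + sxz**2)
    )
    return vm
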