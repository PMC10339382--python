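"""Accuracy assessment of the reduced model at subdomain centers.

The evaluation points are the Cartesian midpoints of the cells of the
snapshot grid in parameter space — the locations farthest from the training
data, where interpolation error peaks. For each center a high-fidelity
reference field U_ref is computed (a fresh finite-element solve, or the
analytic surrogate), the reduced model is queried for U, and the relative
L2 error

    δ = ‖U − U_ref‖₂ / ‖U_ref‖₂

is reported as a percentage, one row per center.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .exceptions import SolverError, ValidationError, ZeroNormError
from .fe import LoadCase, SolverOptions, solve_static
from .geometry import Mesh, Region
from .hopgd import SeparatedModel, evaluate
from .materials import MaterialSet
from .snapshots import ParameterGrid, SurrogateSpec, surrogate_field

__all__ = ["ErrorReport", "subdomain_centers", "relative_error", "error_report"]


def subdomain_centers(grid: ParameterGrid) -> List[LoadCase]:
    """Midpoints of consecutive grid values on each axis, as load cases.

    A grid with n_fy × n_fz points yields (n_fy − 1)·(n_fz − 1) centers;
    the canonical 4 × 4 grid over [50, 200] N gives the 9 centers
    {75, 125, 175}².
    """
    fy_mid = 0.5 * (grid.fy_values[:-1] + grid.fy_values[1:])
    fz_mid = 0.5 * (grid.fz_values[:-1] + grid.fz_values[1:])
    return [LoadCase(fy, fz) for fy in fy_mid for fz in fz_mid]


def relative_error(U: np.ndarray, U_ref: np.ndarray) -> float:
    """Relative L2 error δ = ‖U − U_ref‖₂ / ‖U_ref‖₂.

    Raises
    ------
    ZeroNormError
        If the reference field has zero norm (δ undefined).
    """
    U = np.asarray(U, dtype=float).ravel()
    U_ref = np.asarray(U_ref, dtype=float).ravel()
    if U.shape != U_ref.shape:
        raise ValidationError("fields must have equal length")
    ref_norm = np.linalg.norm(U_ref)
    if ref_norm == 0.0:
        raise ZeroNormError("reference field has zero L2 norm; δ is undefined")
    return float(np.linalg.norm(U - U_ref) / ref_norm)


@dataclass
class ErrorReport:
    """Per-center relative errors, shaped like a published error table."""

    table: pd.DataFrame
    reference: str
    model_digest: str
    mask: str = "all"

    @property
    def any_flagged(self) -> bool:
        return bool(self.table["flagged"].any())

    def to_csv(self, path=None):
        """CSV with a comment header recording provenance; deterministic."""
        buf = io.StringIO()
        buf.write(f"# reduced-model error report\n")
        buf.write(f"# reference={self.reference} mask={self.mask} "
                  f"model_digest={self.model_digest}\n")
        out = self.table.copy()
        out["delta_pct"] = out["delta_pct"].map(lambda d: f"{d:.1f}")
        out.to_csv(buf, index=False)
        text = buf.getvalue()
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _region_mask(mesh: Mesh, mask: str) -> np.ndarray:
    if mask == "all":
        return np.ones(mesh.n_nodes, dtype=bool)
    try:
        region = Region[mask.upper()]
    except KeyError:
        raise ValidationError(f"unknown region mask {mask!r}") from None
    keep = np.zeros(mesh.n_nodes, dtype=bool)
    keep[np.unique(mesh.elements[mesh.region_tag == region])] = True
    return keep


def error_report(
    model: SeparatedModel,
    reference_source: str = "fe",
    mesh: Optional[Mesh] = None,
    materials: Optional[MaterialSet] = None,
    solver_opts: Optional[SolverOptions] = None,
    surrogate: Optional[SurrogateSpec] = None,
    mask: str = "all",
) -> ErrorReport:
    """Relative error δ at every subdomain center of the model's grid.

    ``reference_source`` selects the high-fidelity route: ``"fe"`` runs a
    fresh static solve per center (requires ``mesh`` and ``materials``),
    ``"analytic"`` evaluates the surrogate construction (requires
    ``surrogate``). ``mask`` restricts δ to one tissue region ("dentin",
    "pdl", "bone") or uses every node ("all", the default).

    A failed reference solve flags its row and the run continues; callers
    should treat a report with flagged rows as a failed stage.
    """
    centers = subdomain_centers(model.grid)
    rows = []
    node_mask = _region_mask(mesh, mask) if mesh is not None else None
    if mask != "all" and mesh is None:
        raise ValidationError("a region mask requires the mesh")

    for lc in centers:
        flagged = False
        delta = np.nan
        try:
            if reference_source == "fe":
                if mesh is None or materials is None:
                    raise ValidationError("fe reference requires mesh and materials")
                ref = solve_static(mesh, materials, lc, solver_opts).vms
            elif reference_source == "analytic":
                if surrogate is None:
                    raise ValidationError("analytic reference requires the surrogate spec")
                n_nodes = model.space_vectors.shape[0]
                ref = surrogate_field(surrogate, n_nodes, model.grid, lc.fy, lc.fz)
            else:
                raise ValidationError(f"unknown reference source {reference_source!r}")
            U = evaluate(model, lc.fy, lc.fz)
            if node_mask is not None:
                U = U[node_mask]
                ref = ref[node_mask]
            delta = relative_error(U, ref)
        except SolverError:
            flagged = True
        rows.append(
            {
                "fy_N": lc.fy,
                "fz_N": lc.fz,
                "delta_pct": 100.0 * delta,
                "reference": reference_source,
                "flagged": flagged,
            }
        )
    return ErrorReport(
        table=pd.DataFrame(rows),
        reference=reference_source,
        model_digest=model.options_digest,
        mask=mask,
    )
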