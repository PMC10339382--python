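"""File formats: legacy-VTK ASCII export, plain-text mesh exchange, and
HDF5 array containers for snapshot tensors and reduced models.

Containers are self-describing: every file embeds the producing
configuration's digest and a checksum of its array payload, so a truncated
or tampered file is detected on load rather than silently producing
garbage. Round trips are bit-exact.
"""

from __future__ import annotations

import hashlib
from typing import Dict, Optional

import h5py
import numpy as np

from .exceptions import ContainerError, ValidationError
from .geometry import Mesh, Region
from .hopgd import SeparatedModel
from .snapshots import ParameterGrid, SnapshotTensor

__all__ = [
    "write_vtk",
    "write_mesh_text",
    "read_mesh_text",
    "save_snapshots",
    "load_snapshots",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# legacy VTK (ASCII unstructured grid)
# ---------------------------------------------------------------------------


def write_vtk(
    path,
    mesh: Mesh,
    point_data: Optional[Dict[str, np.ndarray]] = None,
    title: str = "toothmor field export",
) -> None:
    """Write the mesh (with region tags as cell data) and optional nodal
    scalar/vector fields in legacy VTK ASCII format."""
    pts = mesh.node_coords
    tris = mesh.elements
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(pts)} double",
    ]
    lines += [f"{x:.10g} {y:.10g} 0" for x, y in pts]
    lines.append(f"CELLS {len(tris)} {4 * len(tris)}")
    lines += [f"3 {a} {b} {c}" for a, b, c in tris]
    lines.append(f"CELL_TYPES {len(tris)}")
    lines += ["5"] * len(tris)  # VTK_TRIANGLE
    lines.append(f"CELL_DATA {len(tris)}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(t)) for t in mesh.region_tag]
    if point_data:
        lines.append(f"POINT_DATA {len(pts)}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.10g}" for v in arr]
            elif arr.ndim == 2 and arr.shape[1] == 2:
                lines.append(f"VECTORS {name} double")
                lines += [f"{u:.10g} {v:.10g} 0" for u, v in arr]
            else:
                raise ValidationError(f"cannot export field {name!r} of shape {arr.shape}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# plain-text mesh format (documented header, 0-based indices)
# ---------------------------------------------------------------------------

_MESH_MAGIC = "# toothmor mesh v1"


def write_mesh_text(path, mesh: Mesh) -> None:
    """Plain-text mesh: nodes, elements with region tag, boundary sets.

    Layout (0-based indices)::

        # toothmor mesh v1
        NODES <n>
        <x> <y>            (n lines)
        ELEMENTS <m>
        <v0> <v1> <v2> <region-name>   (m lines)
        SET <name> <k>
        <node index>       (k lines, one per node)
    """
    with open(path, "w") as fh:
        fh.write(_MESH_MAGIC + "\n")
        fh.write(f"NODES {mesh.n_nodes}\n")
        for x, y in mesh.node_coords:
            fh.write(f"{float(x)!r} {float(y)!r}\n")
        fh.write(f"ELEMENTS {mesh.n_elements}\n")
        for (a, b, c), t in zip(mesh.elements, mesh.region_tag):
            fh.write(f"{a} {b} {c} {Region(t).name}\n")
        for name in sorted(mesh.boundary_sets):
            ids = mesh.boundary_sets[name]
            fh.write(f"SET {name} {len(ids)}\n")
            for i in ids:
                fh.write(f"{i}\n")


def read_mesh_text(path) -> Mesh:
    """Read a mesh written by :func:`write_mesh_text` (lossless)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != _MESH_MAGIC:
        raise ContainerError(f"{path}: not a toothmor mesh file")
    pos = 1

    def expect(keyword):
        nonlocal pos
        parts = lines[pos].split()
        if parts[0] != keyword:
            raise ContainerError(f"{path}: expected {keyword} at line {pos + 1}")
        pos += 1
        return parts[1:]

    (n,) = expect("NODES")
    n = int(n)
    coords = np.array(
        [[float(tok) for tok in lines[pos + i].split()] for i in range(n)]
    )
    pos += n
    (m,) = expect("ELEMENTS")
    m = int(m)
    tris = np.empty((m, 3), dtype=np.int64)
    tags = np.empty(m, dtype=np.int64)
    for i in range(m):
        a, b, c, name = lines[pos + i].split()
        tris[i] = (int(a), int(b), int(c))
        tags[i] = Region[name]
    pos += m
    sets: Dict[str, np.ndarray] = {}
    while pos < len(lines) and lines[pos].strip():
        name, k = expect("SET")
        k = int(k)
        sets[name] = np.array([int(lines[pos + i]) for i in range(k)], dtype=np.int64)
        pos += k
    return Mesh(node_coords=coords, elements=tris, region_tag=tags, boundary_sets=sets)


# ---------------------------------------------------------------------------
# HDF5 containers
# ---------------------------------------------------------------------------


def _payload_checksum(arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def save_snapshots(path, tensor: SnapshotTensor) -> None:
    """Write a snapshot tensor container (datasets vms/fy/fz + metadata)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("vms", data=tensor.values)
        f.create_dataset("fy", data=tensor.grid.fy_values)
        f.create_dataset("fz", data=tensor.grid.fz_values)
        f.attrs["mesh_sha256"] = tensor.mesh_sha256
        f.attrs["provenance"] = tensor.provenance
        f.attrs["config_digest"] = tensor.config_digest
        f.attrs["checksum"] = _payload_checksum(
            [tensor.values, tensor.grid.fy_values, tensor.grid.fz_values]
        )


def load_snapshots(path) -> SnapshotTensor:
    try:
        with h5py.File(path, "r") as f:
            values = f["vms"][...]
            fy = f["fy"][...]
            fz = f["fz"][...]
            meta = dict(f.attrs)
    except (OSError, KeyError) as err:
        raise ContainerError(f"{path}: unreadable snapshot container: {err}") from err
    if _payload_checksum([values, fy, fz]) != meta.get("checksum"):
        raise ContainerError(f"{path}: checksum mismatch (corrupt container)")
    return SnapshotTensor(
        values=values,
        grid=ParameterGrid(fy, fz),
        mesh_sha256=str(meta.get("mesh_sha256", "")),
        provenance=str(meta.get("provenance", "fe")),
        config_digest=str(meta.get("config_digest", "")),
    )


def save_model(path, model: SeparatedModel) -> None:
    """Write a reduced model container (per-mode datasets + metadata)."""
    with h5py.File(path, "w") as f:
        for m in range(model.n_modes):
            f.create_dataset(f"space/{m}", data=model.space_vectors[:, m])
            f.create_dataset(f"fy/{m}", data=model.fy_vectors[m])
            f.create_dataset(f"fz/{m}", data=model.fz_vectors[m])
        f.attrs["n_modes"] = model.n_modes
        f.attrs["n_nodes"] = model.space_vectors.shape[0]
        f.attrs["fy_axis"] = model.grid.fy_values
        f.attrs["fz_axis"] = model.grid.fz_values
        f.attrs["residual_history"] = np.asarray(model.residual_history)
        f.attrs["interp_scheme"] = model.interp_scheme
        f.attrs["options_digest"] = model.options_digest
        f.attrs["checksum"] = _payload_checksum(
            [model.space_vectors, model.fy_vectors, model.fz_vectors]
        )


def load_model(path) -> SeparatedModel:
    try:
        with h5py.File(path, "r") as f:
            n_modes = int(f.attrs["n_modes"])
            n_nodes = int(f.attrs["n_nodes"])
            fy_axis = np.asarray(f.attrs["fy_axis"])
            fz_axis = np.asarray(f.attrs["fz_axis"])
            space = np.empty((n_nodes, n_modes))
            fyv = np.empty((n_modes, fy_axis.size))
            fzv = np.empty((n_modes, fz_axis.size))
            for m in range(n_modes):
                space[:, m] = f[f"space/{m}"][...]
                fyv[m] = f[f"fy/{m}"][...]
                fzv[m] = f[f"fz/{m}"][...]
            meta = dict(f.attrs)
    except (OSError, KeyError) as err:
        raise ContainerError(f"{path}: unreadable model container: {err}") from err
    if _payload_checksum([space, fyv, fzv]) != meta.get("checksum"):
        raise ContainerError(f"{path}: checksum mismatch (corrupt container)")
    return SeparatedModel(
        space_vectors=space,
        fy_vectors=fyv,
        fz_vectors=fzv,
        grid=ParameterGrid(fy_axis, fz_axis),
        residual_history=list(map(float, meta.get("residual_history", []))),
        interp_scheme=str(meta.get("interp_scheme", "linear")),
        options_digest=str(meta.get("options_digest", "")),
    )
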