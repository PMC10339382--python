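"""Procedural 2-D cross-section mesh of a tooth root anchored in bone.

The model domain is an idealized plane-strain slice through a transplanted
tooth: a dentin shell around a root canal, wrapped by a thin periodontal
ligament (PDL, ~200 µm), itself embedded in alveolar bone, with a rectangular
crown block on top where the masticatory load is applied.

The root profile is a "stadium" curve — two parallel vertical walls joined by
a semicircular apex. Every tissue layer is generated as a structured strip of
offset curves from that profile (dentin inward, ligament and bone outward),
which guarantees a conforming triangulation, strictly positive element areas,
and a ligament layer that topologically separates dentin from bone.

Units: millimetres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Dict

import numpy as np
import pandas as pd

from .exceptions import GeometryError

__all__ = [
    "Region",
    "GeometrySpec",
    "Mesh",
    "build_toy_mesh",
    "mesh_summary",
    "validate_mesh",
]


class Region(IntEnum):
    """Tissue region tag carried by every element."""

    DENTIN = 0
    PDL = 1
    BONE = 2


@dataclass(frozen=True)
class GeometrySpec:
    """Parameters of the idealized cross-section.

    Parameters
    ----------
    root_radius : float
        Half-width of the root at the gum line, mm.
    pdl_thickness : float
        Periodontal ligament thickness, mm. Default 0.2 mm (200 µm), the
        anatomical value for a healthy ligament.
    bone_outer_radius : float
        Offset distance of the outer (fixed) bone boundary from the tooth
        axis, mm. Must exceed ``root_radius + pdl_thickness``.
    crown_height : float
        Height of the rectangular crown block above the gum line, mm.
    element_size : float
        Target edge length of the triangulation at the root surface, mm.
        Must not exceed ``pdl_thickness`` so the ligament is resolved by at
        least one element through its thickness.
    plane_model : str
        Only ``"plane_strain"`` is supported.
    canal_radius_fraction : float
        Root-canal half-width as a fraction of ``root_radius``.
    wall_length_factor : float
        Length of the straight root walls as a multiple of ``root_radius``.
    """

    root_radius: float = 1.2
    pdl_thickness: float = 0.2
    bone_outer_radius: float = 2.4
    crown_height: float = 0.8
    element_size: float = 0.1
    plane_model: str = "plane_strain"
    canal_radius_fraction: float = 0.3
    wall_length_factor: float = 1.5

    def validate(self) -> None:
        if self.plane_model != "plane_strain":
            raise GeometryError(f"unsupported plane_model {self.plane_model!r}")
        if not self.pdl_thickness > 0:
            raise GeometryError("pdl_thickness must be positive")
        if not (0 < self.root_radius):
            raise GeometryError("root_radius must be positive")
        if not (self.root_radius + self.pdl_thickness < self.bone_outer_radius):
            raise GeometryError(
                "radii out of order: require 0 < root_radius < "
                "root_radius + pdl_thickness < bone_outer_radius"
            )
        if self.element_size > self.pdl_thickness:
            raise GeometryError(
                "element_size exceeds pdl_thickness: the ligament would not "
                "be resolved by a single element through its thickness"
            )
        if not self.element_size > 0:
            raise GeometryError("element_size must be positive")
        if not (0 < self.canal_radius_fraction < 1):
            raise GeometryError("canal_radius_fraction must lie in (0, 1)")
        if not self.crown_height > 0:
            raise GeometryError("crown_height must be positive")
        if not self.wall_length_factor > 0:
            raise GeometryError("wall_length_factor must be positive")


@dataclass
class Mesh:
    """Conforming linear triangulation with region tags and boundary sets.

    Attributes
    ----------
    node_coords : (n_nodes, 2) float array
        Vertex positions, mm.
    elements : (n_elements, 3) int array
        Counter-clockwise vertex indices.
    region_tag : (n_elements,) int array
        One :class:`Region` code per element.
    boundary_sets : dict
        Named node-index sets. ``"FIXED"`` is the outer bone boundary
        (constrained in the solver); ``"LOAD"`` is the upper crown edge
        where the occlusal traction acts.
    """

    node_coords: np.ndarray
    elements: np.ndarray
    region_tag: np.ndarray
    boundary_sets: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def signed_areas(self) -> np.ndarray:
        p = self.node_coords
        a, b, c = (p[self.elements[:, k]] for k in range(3))
        u, v = b - a, c - a
        return 0.5 * (u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])

    def sha256(self) -> str:
        """Content hash used to tie snapshot/model containers to a mesh."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.node_coords, dtype=np.float64).tobytes())
        h.update(np.ascontiguousarray(self.elements, dtype=np.int64).tobytes())
        h.update(np.ascontiguousarray(self.region_tag, dtype=np.int64).tobytes())
        for name in sorted(self.boundary_sets):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.boundary_sets[name], dtype=np.int64).tobytes())
        return h.hexdigest()


def _root_profile(spec: GeometrySpec):
    """Discretize the root surface (stadium curve) and its outward normals.

    Returns base points on the root surface ordered from the top of the left
    wall, down and around the apex, to the top of the right wall, together
    with unit outward normals. Offsetting ``base + d * normal`` produces the
    exact parallel curve for any ``d > -root_radius``.
    """
    r = spec.root_radius
    wall = spec.wall_length_factor * r
    h = spec.element_size

    n_wall = max(1, int(round(wall / h)))
    # even count keeps the apex discretization mirror-symmetric
    n_apex = max(4, int(round(np.pi * r / h)))
    if n_apex % 2:
        n_apex += 1

    pts = []
    nrm = []
    # left wall, top (y=0) to bottom (y=-wall); outward normal -x
    for y in np.linspace(0.0, -wall, n_wall + 1):
        pts.append((-r, y))
        nrm.append((-1.0, 0.0))
    # apex semicircle, centre (0, -wall), angle pi -> 2*pi (skip endpoints:
    # they coincide with the wall bottoms)
    theta = np.linspace(np.pi, 2.0 * np.pi, n_apex + 1)[1:-1]
    for t in theta:
        pts.append((r * np.cos(t), -wall + r * np.sin(t)))
        nrm.append((np.cos(t), np.sin(t)))
    # right wall, bottom to top; outward normal +x
    for y in np.linspace(-wall, 0.0, n_wall + 1):
        pts.append((r, y))
        nrm.append((1.0, 0.0))
    return np.asarray(pts), np.asarray(nrm)


def _layer_offsets(spec: GeometrySpec):
    """Radial offset values from the root surface, canal wall to bone outer."""
    h = spec.element_size
    t_dentin = spec.root_radius * (1.0 - spec.canal_radius_fraction)
    t_pdl = spec.pdl_thickness
    t_bone = spec.bone_outer_radius - spec.root_radius - t_pdl

    k_d = max(1, int(round(t_dentin / h)))
    k_p = max(1, int(round(t_pdl / h)))
    k_b = max(1, int(round(t_bone / h)))

    d = np.concatenate(
        [
            np.linspace(-t_dentin, 0.0, k_d + 1),
            np.linspace(0.0, t_pdl, k_p + 1)[1:],
            np.linspace(t_pdl, t_pdl + t_bone, k_b + 1)[1:],
        ]
    )
    tags = np.concatenate(
        [
            np.full(k_d, Region.DENTIN, dtype=np.int64),
            np.full(k_p, Region.PDL, dtype=np.int64),
            np.full(k_b, Region.BONE, dtype=np.int64),
        ]
    )
    return d, tags


def build_toy_mesh(spec: GeometrySpec) -> Mesh:
    """Build the layered cross-section mesh for a geometry specification.

    The construction is fully structured and therefore bit-deterministic:
    identical specs yield identical node coordinates and connectivity.

    Raises
    ------
    GeometryError
        If the spec violates one of its invariants, naming the violation.
    """
    spec.validate()

    base, normal, = _root_profile(spec)
    d, layer_tags = _layer_offsets(spec)
    n_arc = base.shape[0]
    n_lay = d.shape[0]

    # --- radial fan: node (i, k) = base_i + d_k * normal_i -----------------
    fan_xy = base[:, None, :] + d[None, :, None] * normal[:, None, :]

    key_of: Dict[tuple, int] = {}
    coords = []

    def node_id(x: float, y: float) -> int:
        key = (round(float(x), 9), round(float(y), 9))
        idx = key_of.get(key)
        if idx is None:
            idx = len(coords)
            key_of[key] = idx
            coords.append((float(x), float(y)))
        return idx

    fan_ids = np.empty((n_arc, n_lay), dtype=np.int64)
    for i in range(n_arc):
        for k in range(n_lay):
            fan_ids[i, k] = node_id(fan_xy[i, k, 0], fan_xy[i, k, 1])

    elements = []
    tags = []

    def add_quad(a, b, c, e, tag):
        elements.append((a, b, c))
        elements.append((a, c, e))
        tags.append(tag)
        tags.append(tag)

    for i in range(n_arc - 1):
        for k in range(n_lay - 1):
            add_quad(
                fan_ids[i, k],
                fan_ids[i + 1, k],
                fan_ids[i + 1, k + 1],
                fan_ids[i, k + 1],
                int(layer_tags[k]),
            )

    # --- crown block: rectangle [-r, r] x [0, crown_height] ----------------
    # Bottom-edge x positions over the dentin shell reuse the fan's exact
    # offsets so the interface is conforming; the stretch over the canal
    # mouth is meshed uniformly (it forms the roof of the canal cavity).
    r = spec.root_radius
    r_canal = spec.canal_radius_fraction * r
    h = spec.element_size
    k_dentin = int(np.sum(d <= 0.0))  # offsets spanning the dentin shell
    xs_right = r + d[:k_dentin]  # r_canal .. r (increasing)
    n_mouth = max(2, int(round(2.0 * r_canal / h)))
    xs_mouth = np.linspace(-r_canal, r_canal, n_mouth + 1)[1:-1]
    xs = np.concatenate([-xs_right[::-1], xs_mouth, xs_right])
    ys = np.linspace(0.0, spec.crown_height, max(1, int(round(spec.crown_height / h))) + 1)

    crown_ids = np.empty((xs.size, ys.size), dtype=np.int64)
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            crown_ids[i, j] = node_id(x, y)

    for i in range(xs.size - 1):
        for j in range(ys.size - 1):
            add_quad(
                crown_ids[i, j],
                crown_ids[i + 1, j],
                crown_ids[i + 1, j + 1],
                crown_ids[i, j + 1],
                int(Region.DENTIN),
            )

    node_coords = np.asarray(coords, dtype=np.float64)
    elements = np.asarray(elements, dtype=np.int64)
    region_tag = np.asarray(tags, dtype=np.int64)

    # enforce counter-clockwise orientation
    a, b, c = (node_coords[elements[:, k]] for k in range(3))
    u, v = b - a, c - a
    areas = 0.5 * (u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])
    flip = areas < 0
    elements[flip] = elements[flip][:, [0, 2, 1]]

    fixed = np.sort(fan_ids[:, -1])
    load = np.sort(crown_ids[:, -1])
    mesh = Mesh(
        node_coords=node_coords,
        elements=elements,
        region_tag=region_tag,
        boundary_sets={"FIXED": fixed, "LOAD": load},
    )
    validate_mesh(mesh)
    return mesh


def _edge_region_adjacency(mesh: Mesh):
    """Map undirected edge -> set of regions of elements sharing it."""
    adj: Dict[tuple, set] = {}
    for tri, tag in zip(mesh.elements, mesh.region_tag):
        for e in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            key = (min(e), max(e))
            adj.setdefault(key, set()).add(int(tag))
    return adj


def validate_mesh(mesh: Mesh) -> None:
    """Check every structural invariant of a layered mesh.

    Raises :class:`GeometryError` naming the first violated invariant.
    """
    if mesh.elements.min(initial=0) < 0 or mesh.elements.max(initial=-1) >= mesh.n_nodes:
        raise GeometryError("element connectivity references nonexistent nodes")
    for region in Region:
        if not np.any(mesh.region_tag == region):
            raise GeometryError(f"region {region.name} has no elements")
    areas = mesh.signed_areas()
    if np.any(areas <= 0):
        raise GeometryError("element signed areas must all be strictly positive")
    for name in ("FIXED", "LOAD"):
        if name not in mesh.boundary_sets or len(mesh.boundary_sets[name]) == 0:
            raise GeometryError(f"boundary set {name} is missing or empty")
    if np.intersect1d(mesh.boundary_sets["FIXED"], mesh.boundary_sets["LOAD"]).size:
        raise GeometryError("FIXED and LOAD boundary sets must be disjoint")
    for edge, regions in _edge_region_adjacency(mesh).items():
        if Region.DENTIN in regions and Region.BONE in regions:
            raise GeometryError(
                f"dentin element shares edge {edge} with a bone element: "
                "the ligament layer must separate them"
            )


def mesh_summary(mesh: Mesh) -> pd.DataFrame:
    """Tabulate node/element counts per region and boundary-set sizes.

    The mesh is validated first; an invalid mesh is rejected rather than
    summarized.
    """
    validate_mesh(mesh)
    rows = [("nodes", mesh.n_nodes)]
    for region in Region:
        rows.append((f"elements_{region.name}", int(np.sum(mesh.region_tag == region))))
    rows.append(("elements_total", mesh.n_elements))
    for name in sorted(mesh.boundary_sets):
        rows.append((f"boundary_{name}", len(mesh.boundary_sets[name])))
    return pd.DataFrame(rows, columns=["quantity", "count"])
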