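"""In-memory mesh containers.

Two containers carry all geometry through the pipeline:

* :class:`SurfaceMesh` — a triangulated surface in millimetres, used for the
  occlusal contact computation (lower crown and antagonist).
* :class:`VolumeMesh` — a 10-node tetrahedral mesh with a per-element tissue
  region and named node sets, used by the finite-element solver.

TET10 local node ordering follows the VTK ``QUADRATIC_TETRA`` convention:
nodes 0–3 are the corners, nodes 4–9 are the edge midpoints of edges
(0,1), (1,2), (0,2), (0,3), (1,3), (2,3) in that order.  All elements are
straight-sided: each midside node lies at the midpoint of its edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .errors import MeshError, ValidationError

#: Edges of a tetrahedron in TET10 midside order (local corner pairs).
TET10_EDGES = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))

#: The four faces of a TET10 element as (corner locals, midside locals).
#: Corner winding is arbitrary here; callers orient faces geometrically.
TET10_FACES = (
    ((0, 1, 2), (4, 5, 6)),
    ((0, 1, 3), (4, 8, 7)),
    ((1, 2, 3), (5, 9, 8)),
    ((0, 2, 3), (6, 9, 7)),
)


class Region(IntEnum):
    """Tissue regions of the tooth/support model."""

    ENAMEL = 0
    DENTINE = 1
    PULP = 2
    PDL = 3
    BONE = 4


#: Averaging / lookup priority at tissue interfaces (hardest tissue first);
#: used when a node is shared by elements of several regions.
REGION_PRIORITY = (Region.ENAMEL, Region.DENTINE, Region.BONE, Region.PDL, Region.PULP)


@dataclass
class SurfaceMesh:
    """Triangulated surface in mm with outward-oriented normals."""

    vertices: np.ndarray  # (V, 3) float64
    triangles: np.ndarray  # (T, 3) int
    facet_labels: np.ndarray | None = None  # (T,) optional per-triangle tag

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_areas(self) -> np.ndarray:
        a, b, c = (self.vertices[self.triangles[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def triangle_normals(self) -> np.ndarray:
        a, b, c = (self.vertices[self.triangles[:, i]] for i in range(3))
        n = np.cross(b - a, c - a)
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        if np.any(norm == 0.0):
            raise MeshError("degenerate (zero-area) triangle in surface mesh")
        return n / norm

    def triangle_centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def validate(self) -> None:
        if self.triangles.min(initial=0) < 0 or self.triangles.max(initial=-1) >= len(self.vertices):
            raise ValidationError("surface triangles reference missing vertices")
        edges = self.vertices[self.triangles]
        if np.any(np.ptp(edges, axis=1).sum(axis=1) == 0.0):
            raise ValidationError("surface mesh contains zero-edge triangles")
        if np.any(self.triangle_areas() <= 0.0):
            raise ValidationError("surface mesh contains zero-area triangles")

    def translated(self, offset: np.ndarray) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices + np.asarray(offset, dtype=float),
                           self.triangles, self.facet_labels)

    def as_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices, faces=self.triangles, process=False)


@dataclass
class VolumeMesh:
    """10-node tetrahedral mesh with tissue regions and named node sets."""

    nodes: np.ndarray  # (N, 3) float64, mm
    elements: np.ndarray  # (E, 10) int
    region: np.ndarray  # (E,) Region codes
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.elements = np.ascontiguousarray(self.elements, dtype=np.int64)
        self.region = np.ascontiguousarray(self.region, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_volumes(self) -> np.ndarray:
        """Signed volumes from the corner nodes (exact for straight elements)."""
        c = self.nodes[self.elements[:, :4]]
        d = c[:, 1:] - c[:, :1]
        return np.linalg.det(d) / 6.0

    def region_volumes(self) -> dict[Region, float]:
        vols = self.element_volumes()
        return {Region(r): float(vols[self.region == r].sum())
                for r in np.unique(self.region)}

    def boundary_faces(self) -> tuple[np.ndarray, np.ndarray]:
        """Boundary faces as (faces (F, 6) node ids, element index (F,)).

        A face is on the boundary when its corner triple occurs in exactly
        one element.  Corner winding is oriented outward (normal points away
        from the owning element's centroid); the three midside ids follow in
        edge order (c0-c1, c1-c2, c2-c0).
        """
        faces = []
        owners = []
        for corners, mids in TET10_FACES:
            f = np.concatenate(
                [self.elements[:, list(corners)], self.elements[:, list(mids)]], axis=1
            )
            faces.append(f)
            owners.append(np.arange(self.n_elements))
        faces = np.concatenate(faces, axis=0)
        owners = np.concatenate(owners)
        key = np.sort(faces[:, :3], axis=1)
        _, inverse, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        keep = counts[inverse] == 1
        faces, owners = faces[keep], owners[keep]
        # orient corner winding outward, and re-derive midsides to match
        a, b, c = (self.nodes[faces[:, i]] for i in range(3))
        normal = np.cross(b - a, c - a)
        centroid_f = (a + b + c) / 3.0
        centroid_e = self.nodes[self.elements[owners, :4]].mean(axis=1)
        flip = np.einsum("ij,ij->i", normal, centroid_f - centroid_e) < 0.0
        faces[flip, 1], faces[flip, 2] = faces[flip, 2].copy(), faces[flip, 1].copy()
        faces[flip, 3], faces[flip, 5] = faces[flip, 5].copy(), faces[flip, 3].copy()
        return faces, owners

    def boundary_node_ids(self) -> np.ndarray:
        faces, _ = self.boundary_faces()
        return np.unique(faces)

    def validate(self) -> None:
        if self.elements.shape[1] != 10:
            raise ValidationError("elements must have 10 nodes")
        if len(self.region) != self.n_elements:
            raise ValidationError("region array length does not match element count")
        if self.elements.min(initial=0) < 0 or self.elements.max(initial=-1) >= self.n_nodes:
            raise ValidationError("elements reference missing nodes")
        vols = self.element_volumes()
        if np.any(vols <= 0.0):
            bad = int(np.argmin(vols))
            raise MeshError(f"element {bad} has non-positive volume ({vols[bad]:.3e})")
        # straight-sidedness: midside nodes at edge midpoints
        for k, (i, j) in enumerate(TET10_EDGES):
            mid = 0.5 * (self.nodes[self.elements[:, i]] + self.nodes[self.elements[:, j]])
            if not np.allclose(self.nodes[self.elements[:, 4 + k]], mid, atol=1e-9):
                raise MeshError(f"midside nodes of edge {(i, j)} are off the edge midpoint")
        used = np.zeros(self.n_nodes, dtype=bool)
        used[self.elements.ravel()] = True
        if not used.all():
            raise MeshError(f"{int((~used).sum())} orphan node(s) in mesh")
        for name, ids in self.node_sets.items():
            ids = np.asarray(ids)
            if len(ids) and (ids.min() < 0 or ids.max() >= self.n_nodes):
                raise ValidationError(f"node set {name!r} references missing nodes")

    def jacobians_positive(self) -> bool:
        """True when every element has positive Jacobian at all quadrature points.

        For straight-sided TET10 the Jacobian is constant and equals the
        corner-tet Jacobian, but this checks the quadrature points explicitly.
        """
        from .tet10 import GAUSS4_POINTS, shape_gradients

        dN = shape_gradients(GAUSS4_POINTS)  # (G, 10, 3)
        coords = self.nodes[self.elements]  # (E, 10, 3)
        jac = np.einsum("enj,gnk->egjk", coords, dN)
        return bool(np.all(np.linalg.det(jac) > 0.0))
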