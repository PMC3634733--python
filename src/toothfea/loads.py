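"""Occlusal load construction from contact patches.

Each contact patch carries a uniform pressure directed along the inward
facet normal (perpendicular to the wear facet, compressive).  Patch force
magnitudes are proportional to patch areas, and one global scalar rescale
— applied after the consistent-load conversion — sets the magnitude of
the resultant force vector to the prescribed total (default 100 N).

The contact patches live on the smooth analytic crown surface while the
pressure is applied to boundary faces of the voxel volume mesh; the
bridge assigns each occlusal boundary face to the patch with the nearest
triangle footprint in the occlusal (x, z) projection, within one mesh
size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .contact import ContactResult
from .errors import LoadError, ValidationError
from .meshes import VolumeMesh

#: Prescribed resultant force magnitude (N) unless overridden.
DEFAULT_TOTAL_FORCE = 100.0


@dataclass
class LoadCase:
    """Consistent nodal forces whose resultant has a prescribed magnitude."""

    nodal_forces: np.ndarray  # (N, 3) in newtons
    total_magnitude: float  # N
    patch_forces: np.ndarray  # (P, 3) force carried by each patch, N

    @property
    def resultant(self) -> np.ndarray:
        return self.nodal_forces.sum(axis=0)

    def obliquity_deg(self) -> float:
        """Angle between the load resultant and the tooth long axis (y)."""
        r = self.resultant
        mag = np.linalg.norm(r)
        if mag == 0.0:
            return 0.0
        return float(np.degrees(np.arccos(min(1.0, abs(r[1]) / mag))))

    def scaled(self, factor: float) -> "LoadCase":
        return LoadCase(
            nodal_forces=self.nodal_forces * factor,
            total_magnitude=self.total_magnitude * factor,
            patch_forces=self.patch_forces * factor,
        )


def consistent_face_loads(face_coords: np.ndarray, traction: np.ndarray) -> np.ndarray:
    """Consistent nodal forces of a uniform traction on a 6-node face.

    For a straight-sided quadratic triangle the integral of the shape
    functions gives zero at the corners and A/3 at each midside node, so a
    uniform pressure loads only the midside nodes.  (The 3-point midpoint
    rule used here is exact for this quadratic integrand.)

    Parameters
    ----------
    face_coords : (6, 3) corner nodes then midside nodes, mm.
    traction : (3,) traction vector, N/mm^2.

    Returns
    -------
    (6, 3) nodal force vectors, N; their sum is traction * face area.
    """
    face_coords = np.asarray(face_coords, dtype=float)
    traction = np.asarray(traction, dtype=float)
    if face_coords.shape != (6, 3):
        raise ValidationError("face_coords must have shape (6, 3)")
    if not np.all(np.isfinite(traction)):
        raise ValidationError("traction must be finite")
    a, b, c = face_coords[:3]
    area = 0.5 * np.linalg.norm(np.cross(b - a, c - a))
    forces = np.zeros((6, 3))
    forces[3:] = (area / 3.0) * traction
    return forces


def normalize_patch_forces(
    areas: np.ndarray, normals: np.ndarray, total: float
) -> tuple[np.ndarray, float]:
    """Area-proportional patch forces along the inward normals, rescaled.

    Returns (patch force vectors (P, 3), the applied global scale).  Raises
    :class:`LoadError` when the area-weighted normals nearly cancel, which
    leaves the resultant-magnitude normalization indeterminate.
    """
    areas = np.asarray(areas, dtype=float)
    normals = np.asarray(normals, dtype=float)
    if total <= 0:
        raise LoadError(f"total force must be positive, got {total}")
    if len(areas) == 0:
        raise LoadError("no occlusal contacts")
    raw = -(areas[:, None] * normals)  # compressive: into the lower tooth
    resultant = raw.sum(axis=0)
    mag = np.linalg.norm(resultant)
    if mag < 1e-6 * areas.sum():
        raise LoadError("indeterminate normalization: patch normals cancel")
    scale = total / mag
    return raw * scale, scale


def build_load_case(
    mesh: VolumeMesh,
    contacts: ContactResult,
    total: float = DEFAULT_TOTAL_FORCE,
    match_distance: float = 1.0,
) -> LoadCase:
    """Convert contact patches to consistent nodal loads on the volume mesh.

    Raises :class:`LoadError` for an empty contact set, cancelling patch
    normals, or a patch whose footprint cannot be matched to any occlusal
    boundary face within ``match_distance``.
    """
    if contacts.n_patches == 0:
        raise LoadError("no occlusal contacts")
    if "OCCLUSAL_SURFACE" not in mesh.node_sets:
        raise LoadError("mesh has no OCCLUSAL_SURFACE node set")

    patch_dirs, _ = normalize_patch_forces(
        np.array([p.area for p in contacts.patches]),
        np.array([p.normal for p in contacts.patches]),
        total,
    )  # validates determinacy; per-face tractions recomputed below

    faces, _ = mesh.boundary_faces()
    occl = mesh.node_sets["OCCLUSAL_SURFACE"]
    on_occl = np.isin(faces, occl).all(axis=1)
    faces = faces[on_occl]
    if len(faces) == 0:
        raise LoadError("no occlusal boundary faces on the volume mesh")
    a, b, c = (mesh.nodes[faces[:, i]] for i in range(3))
    face_centroid = (a + b + c) / 3.0
    face_area = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    # patch assignment in the occlusal-plane (x, z) projection
    fxz = face_centroid[:, [0, 2]]
    dists = np.empty((contacts.n_patches, len(faces)))
    for i, patch in enumerate(contacts.patches):
        # centroids of the patch triangles live on the contact surface
        tree = cKDTree(patch_centroids_xz(contacts, i))
        dists[i], _ = tree.query(fxz)
    nearest_patch = np.argmin(dists, axis=0)
    within = dists[nearest_patch, np.arange(len(faces))] <= match_distance

    areas = np.array([p.area for p in contacts.patches])
    normals = np.array([p.normal for p in contacts.patches])
    raw_patch_forces = -(areas[:, None] * normals)

    nodal = np.zeros((mesh.n_nodes, 3))
    for i in range(contacts.n_patches):
        sel = within & (nearest_patch == i)
        if not sel.any():
            raise LoadError(
                f"contact patch {i} has no matching occlusal face within "
                f"{match_distance} mm"
            )
        total_face_area = face_area[sel].sum()
        traction = raw_patch_forces[i] / total_face_area
        for f in np.flatnonzero(sel):
            nodal[faces[f]] += consistent_face_loads(mesh.nodes[faces[f]], traction)

    resultant = nodal.sum(axis=0)
    mag = np.linalg.norm(resultant)
    if mag == 0.0:
        raise LoadError("zero resultant after load distribution")
    scale = total / mag
    return LoadCase(
        nodal_forces=nodal * scale,
        total_magnitude=float(total),
        patch_forces=raw_patch_forces * scale,
    )


def patch_centroids_xz(contacts: ContactResult, index: int) -> np.ndarray:
    """Occlusal-plane projection of one patch's triangle centroids."""
    patch = contacts.patches[index]
    if patch.triangle_centroids is None:  # pragma: no cover
        raise LoadError("contact patch lacks triangle centroid data")
    return patch.triangle_centroids[:, [0, 2]]
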