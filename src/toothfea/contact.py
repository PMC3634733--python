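"""Occlusal contact detection at maximum intercuspation.

The antagonist crown is translated along an approach direction until the
surfaces touch (without interpenetration), then every lower-crown triangle
within a proximity tolerance ``epsilon`` of the antagonist is marked as
colliding.  Colliding triangles are clustered into edge-connected contact
patches, each carrying its area, area-weighted outward normal and
centroid — the footprint over which the occlusal load is applied.

Only the static maximum-intercuspation instant is modelled; the kinematic
deflection/break-free phases of a chewing power stroke are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .errors import ContactError, ValidationError
from .meshes import SurfaceMesh
from .proximity import SurfaceDistance, ray_surface_first_hits

#: Default proximity tolerance (mm); ties to a 55 um scan-resolution scale.
DEFAULT_EPSILON = 0.05

#: Residual gap accepted by the approach phase (mm).
DEFAULT_GAP_TOL = 1e-6


@dataclass
class ContactPatch:
    """One edge-connected cluster of colliding lower-crown triangles."""

    triangle_ids: np.ndarray  # indices into the lower SurfaceMesh
    area: float  # mm^2
    normal: np.ndarray  # unit, area-weighted mean outward normal of the lower crown
    centroid: np.ndarray  # mm, area-weighted
    triangle_centroids: np.ndarray | None = None  # (T, 3) for footprint mapping

    def validate(self) -> None:
        if len(self.triangle_ids) == 0:
            raise ValidationError("contact patch has no triangles")
        if not self.area > 0:
            raise ValidationError("contact patch area must be positive")
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise ValidationError("contact patch normal is not unit length")


@dataclass
class ContactResult:
    """All contact patches at maximum intercuspation."""

    patches: list[ContactPatch] = field(default_factory=list)
    approach_offset: float = 0.0  # mm of antagonist translation applied
    total_area: float = 0.0  # mm^2

    @property
    def n_patches(self) -> int:
        return len(self.patches)


def approach_to_contact(
    lower: SurfaceMesh,
    upper: SurfaceMesh,
    direction: np.ndarray = (0.0, -1.0, 0.0),
    gap_tol: float = DEFAULT_GAP_TOL,
    max_travel: float = 100.0,
) -> float:
    """Largest translation of ``upper`` along ``direction`` before contact.

    Distances are measured by casting rays from each vertex of one surface
    onto the other along the approach direction (both ways), which is exact
    for vertex-against-face first contact.  Raises :class:`ContactError`
    when no contact is achievable within ``max_travel``.
    """
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0.0:
        raise ContactError("approach direction must be non-zero")
    d = d / norm

    hits = []
    for origins, target, ray_dir in (
        (upper.vertices, lower, d),
        (lower.vertices, upper, -d),
    ):
        t = ray_surface_first_hits(origins, ray_dir, target)
        t = t[np.isfinite(t)]
        t = t[t >= -gap_tol]
        if len(t):
            hits.append(float(t.min()))
    if not hits:
        raise ContactError("no contact achievable along the approach direction")
    offset = float(max(min(hits), 0.0))
    if offset > max_travel:
        raise ContactError(
            f"first contact at {offset:.3f} mm exceeds max travel {max_travel} mm"
        )
    return offset


def _triangle_adjacency(triangles: np.ndarray, subset: np.ndarray) -> sp.coo_matrix:
    """Edge-adjacency graph between the triangles listed in ``subset``."""
    tri = triangles[subset]
    edges = np.concatenate(
        [np.sort(tri[:, [0, 1]], axis=1),
         np.sort(tri[:, [1, 2]], axis=1),
         np.sort(tri[:, [0, 2]], axis=1)],
        axis=0,
    )
    owner = np.tile(np.arange(len(subset)), 3)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges, owner = edges[order], owner[order]
    same = np.all(edges[1:] == edges[:-1], axis=1)
    i, j = owner[:-1][same], owner[1:][same]
    n = len(subset)
    data = np.ones(len(i) * 2 + n)
    rows = np.concatenate([i, j, np.arange(n)])
    cols = np.concatenate([j, i, np.arange(n)])
    return sp.coo_matrix((data, (rows, cols)), shape=(n, n))


def detect_contact_patches(
    lower: SurfaceMesh,
    upper: SurfaceMesh,
    epsilon: float = DEFAULT_EPSILON,
) -> ContactResult:
    """Find lower-crown triangles within ``epsilon`` of the antagonist.

    A triangle collides when the minimum of its three vertex distances and
    centroid distance to the antagonist surface is <= ``epsilon``.  A fast
    centroid filter at 3x epsilon preselects candidates before the exact
    per-point confirmation.  Colliding triangles are clustered by edge
    adjacency (triangles touching only at a vertex belong to different
    patches).
    """
    if epsilon <= 0:
        raise ContactError(f"epsilon must be positive, got {epsilon}")
    upper_dist = SurfaceDistance(upper)
    centroids = lower.triangle_centroids()
    # prefilter radius: 3x epsilon, widened when triangles are coarse enough
    # that a vertex could be within epsilon while the centroid is not
    tri_pts = lower.vertices[lower.triangles]
    r_lower = float(np.linalg.norm(tri_pts - centroids[:, None, :], axis=2).max())
    prefilter = max(3.0 * epsilon, epsilon + r_lower + 1e-12)
    d_centroid = upper_dist.query(centroids, cutoff=prefilter)
    candidates = np.flatnonzero(d_centroid <= prefilter)
    if len(candidates) == 0:
        return ContactResult(patches=[], approach_offset=0.0, total_area=0.0)

    # exact confirmation on vertices + centroid of candidate triangles
    tri = lower.triangles[candidates]
    probe = np.concatenate([lower.vertices[tri.ravel()].reshape(-1, 3),
                            centroids[candidates]], axis=0)
    d_probe = upper_dist.query(probe, cutoff=epsilon)
    d_verts = d_probe[: 3 * len(candidates)].reshape(-1, 3).min(axis=1)
    d_cent = d_probe[3 * len(candidates):]
    contact = candidates[np.minimum(d_verts, d_cent) <= epsilon]
    if len(contact) == 0:
        return ContactResult(patches=[], approach_offset=0.0, total_area=0.0)

    adjacency = _triangle_adjacency(lower.triangles, contact)
    n_comp, labels = connected_components(adjacency, directed=False)

    areas = lower.triangle_areas()
    normals = lower.triangle_normals()
    cents = lower.triangle_centroids()
    patches = []
    for comp in range(n_comp):
        ids = contact[labels == comp]
        a = areas[ids]
        total = float(a.sum())
        n = (normals[ids] * a[:, None]).sum(axis=0)
        n_norm = np.linalg.norm(n)
        if n_norm == 0.0:  # pragma: no cover - opposing normals cancelling
            n = normals[ids[0]]
            n_norm = 1.0
        order = np.sort(ids)
        patch = ContactPatch(
            triangle_ids=order,
            area=total,
            normal=n / n_norm,
            centroid=(cents[ids] * a[:, None]).sum(axis=0) / total,
            triangle_centroids=cents[order],
        )
        patch.validate()
        patches.append(patch)
    patches.sort(key=lambda p: (-p.area, tuple(p.centroid)))
    return ContactResult(
        patches=patches,
        approach_offset=0.0,
        total_area=float(sum(p.area for p in patches)),
    )


def contact_at_intercuspation(
    lower: SurfaceMesh,
    upper: SurfaceMesh,
    direction: np.ndarray = (0.0, -1.0, 0.0),
    epsilon: float = DEFAULT_EPSILON,
    gap_tol: float = DEFAULT_GAP_TOL,
) -> tuple[ContactResult, SurfaceMesh]:
    """Approach, then detect: the full static occlusal-contact computation.

    Returns the contact result and the translated antagonist surface.
    """
    d = np.asarray(direction, dtype=float)
    offset = approach_to_contact(lower, upper, d, gap_tol=gap_tol)
    moved = upper.translated(offset * d / np.linalg.norm(d))
    result = detect_contact_patches(lower, moved, epsilon=epsilon)
    result.approach_offset = offset
    return result, moved


def contact_summary(result: ContactResult) -> pd.DataFrame:
    """Per-patch table (descending area, centroid lexicographic tie-break)."""
    rows = [
        {
            "patch": i,
            "n_triangles": len(p.triangle_ids),
            "area_mm2": p.area,
            "normal_x": p.normal[0],
            "normal_y": p.normal[1],
            "normal_z": p.normal[2],
            "centroid_x": p.centroid[0],
            "centroid_y": p.centroid[1],
            "centroid_z": p.centroid[2],
        }
        for i, p in enumerate(
            sorted(result.patches, key=lambda p: (-p.area, tuple(p.centroid)))
        )
    ]
    df = pd.DataFrame(
        rows,
        columns=["patch", "n_triangles", "area_mm2", "normal_x", "normal_y",
                 "normal_z", "centroid_x", "centroid_y", "centroid_z"],
    )
    return df
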