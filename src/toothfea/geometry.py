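"""Parametric multi-tissue premolar generator and wear operator.

This module stands in for segmented micro-CT specimens: it builds a
two-cusp lower-premolar crown (steep buccal cusp, lower lingual cusp, a
distal marginal ridge), an enamel cap over a dentine body with a pulp
chamber, a thin periodontal-ligament (PDL) layer, and an alveolar bone
block with planar mesial/distal cut faces — everything the downstream
contact/load/solve stages need, at a prescribed occlusal wear depth.

Coordinate convention
---------------------
x = lingual -> buccal, y = inferior -> superior (tooth long axis),
z = mesial -> distal; origin at the cervix centroid.  All lengths in mm.

Geometry model
--------------
The occlusal surface is a height field ``h0(x, z)``: the upper envelope of
two cusp cones (buccal and lingual), a distal marginal-ridge cone and a
flat occlusal floor.  Wear is planar truncation of the crown at height
``buccal_cusp_height - wear_depth`` (the computational analog of attrition
in a dental articulator, whose endpoint is a flattened cusp tip).  The
enamel cap is defined relative to the *unworn* surface, so sufficiently
deep wear exposes dentine on the worn plateau — the stage-3 condition.

The antagonist occlusal surface is built from complementary features: a
planar facet tangent to the outer (buccal-facing) flank of the buccal cusp
— the functional contact of the opposing tooth's lingual cusp incline — a
second facet on the disto-occlusal flank of the same cusp (toward the
distal margin), and a horizontal plane complementary to the wear plateau.
In maximum
intercuspation the facet loads are therefore oblique (tilted lingually)
for an unworn crown and near-axial once a wear plateau has formed.

Meshing is structured voxel-to-tetrahedra subdivision on a grid that is
independent of the wear depth, so every node below the truncation is
bit-identical across wear states of the same tooth — the basis for the
homologous cervical comparison.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .meshes import Region, SurfaceMesh, VolumeMesh
from .tet10 import promote_to_volume_mesh, structured_box_tet4

#: Alveolar crest: top of the bone block, below the cervix plane (mm).
ALVEOLAR_CREST_Y = -1.0

#: Vertical standoff at which the antagonist is initially positioned (mm).
ANTAGONIST_STANDOFF = 0.5

#: Default triangle spacing of the analytic contact surfaces (mm).
SURFACE_SPACING = 0.25


@dataclass(frozen=True)
class ToothParams:
    """Parameters of the synthetic premolar; lengths in mm, angles in degrees."""

    crown_height: float = 8.0
    buccal_cusp_height: float = 8.0
    lingual_cusp_height: float = 6.5
    buccal_cusp_slope: float = 50.0  # degrees from the occlusal plane
    cervix_radius: float = 3.5
    root_length: float = 10.0
    enamel_thickness: float = 1.2
    pulp_radius: float = 1.0
    pdl_thickness: float = 0.25
    bone_block: tuple[float, float, float] = (10.5, 11.5, 16.0)  # (x, y, z) extents
    wear_depth: float = 0.0
    mesh_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = (
            "crown_height", "buccal_cusp_height", "lingual_cusp_height",
            "cervix_radius", "root_length", "enamel_thickness", "pulp_radius",
            "pdl_thickness", "mesh_size",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive, got {getattr(self, name)}")
        if len(self.bone_block) != 3 or any(not b > 0 for b in self.bone_block):
            raise ValidationError(f"bone_block extents must be positive, got {self.bone_block}")
        if self.wear_depth < 0:
            raise ValidationError(f"wear_depth must be >= 0, got {self.wear_depth}")
        if not self.wear_depth < self.crown_height:
            raise ValidationError(
                f"wear_depth ({self.wear_depth}) must be < crown_height ({self.crown_height})"
            )
        if not 0.0 < self.buccal_cusp_slope < 85.0:
            raise ValidationError(
                f"buccal_cusp_slope must lie in (0, 85) degrees, got {self.buccal_cusp_slope}"
            )
        if not self.enamel_thickness < self.cervix_radius:
            raise ValidationError("enamel_thickness must be smaller than cervix_radius")
        if self.buccal_cusp_height > self.crown_height:
            raise ValidationError("buccal_cusp_height cannot exceed crown_height")
        if self.lingual_cusp_height > self.buccal_cusp_height:
            raise ValidationError("lingual_cusp_height cannot exceed buccal_cusp_height")
        if self.pulp_radius >= self.cervix_radius - self.enamel_thickness:
            raise ValidationError("pulp_radius must fit inside the dentine body")
        bx, by, bz = self.bone_block
        if self.cervix_radius + self.pdl_thickness >= min(bx, bz) / 2.0:
            raise ValidationError("bone_block too small for root + PDL in cross-section")
        # bone bottom (crest - by) must clear the PDL under the apex by >= 1 mm
        if ALVEOLAR_CREST_Y - by > -(self.root_length + self.pdl_thickness + 1.0):
            raise ValidationError("bone_block too shallow to contain the root and PDL")

    # derived geometry -------------------------------------------------------
    @property
    def slope(self) -> float:
        """Occlusal slope as a gradient (rise over run)."""
        return float(np.tan(np.radians(self.buccal_cusp_slope)))

    @property
    def buccal_cusp_center(self) -> tuple[float, float]:
        # the dominant buccal cusp tip of a lower premolar lies close to
        # the tooth axis; the small lingual cusp sits well lingually
        return (0.2 * self.cervix_radius, 0.0)

    @property
    def lingual_cusp_center(self) -> tuple[float, float]:
        return (-0.55 * self.cervix_radius, 0.0)

    @property
    def distal_ridge_center(self) -> tuple[float, float]:
        return (0.0, 0.62 * self.cervix_radius)

    @property
    def distal_ridge_height(self) -> float:
        return self.lingual_cusp_height - 1.0

    @property
    def occlusal_floor(self) -> float:
        return 0.45 * self.buccal_cusp_height

    @property
    def enamel_cap_vertical(self) -> float:
        """Vertical thickness of the occlusal enamel cap over a sloped flank."""
        return self.enamel_thickness / float(np.cos(np.radians(self.buccal_cusp_slope)))

    @property
    def truncation_height(self) -> float:
        return self.buccal_cusp_height - self.wear_depth

    @property
    def cervical_band(self) -> float:
        """Half-width of the cervical sampling band around y = 0."""
        return max(0.5, 0.8 * self.mesh_size)


@dataclass(frozen=True)
class WearStage:
    """Ordinal occlusal wear stage (1 = slight facets, 3 = dentine exposed)."""

    stage: int
    dentine_exposed: bool

    def __post_init__(self) -> None:
        if self.stage not in (1, 2, 3):
            raise ValidationError(f"wear stage must be 1, 2 or 3, got {self.stage}")
        if (self.stage == 3) != self.dentine_exposed:
            raise ValidationError("stage 3 if and only if dentine is exposed")


def wear_stage(params: ToothParams) -> WearStage:
    """Map a wear depth to an ordinal stage.

    Stage 1: depth within 25% of the occlusal enamel cap; stage 2: deeper
    facets that have not reached the enamel-dentine junction at the cusp
    tip; stage 3: the truncation plane cuts below the cap — dentine exposed.
    """
    cap = params.enamel_cap_vertical
    if params.wear_depth > cap:
        return WearStage(3, True)
    if params.wear_depth <= 0.25 * cap:
        return WearStage(1, False)
    return WearStage(2, False)


def apply_wear(params: ToothParams, wear_depth: float) -> ToothParams:
    """Return a copy of ``params`` truncated at the given wear depth."""
    if wear_depth < 0:
        raise ValidationError(f"wear_depth must be >= 0, got {wear_depth}")
    if wear_depth >= params.crown_height:
        raise ValidationError(
            f"wear_depth ({wear_depth}) must be < crown_height ({params.crown_height})"
        )
    return dataclasses.replace(params, wear_depth=float(wear_depth))


# --- occlusal height fields --------------------------------------------------

def _cone(x, z, center, height, slope):
    return height - slope * np.hypot(x - center[0], z - center[1])


def occlusal_height_unworn(params: ToothParams, x, z):
    """Unworn occlusal surface height ``h0(x, z)``."""
    s = params.slope
    h = _cone(x, z, params.buccal_cusp_center, params.buccal_cusp_height, s)
    h = np.maximum(h, _cone(x, z, params.lingual_cusp_center, params.lingual_cusp_height, s))
    h = np.maximum(h, _cone(x, z, params.distal_ridge_center, params.distal_ridge_height, s))
    return np.maximum(h, params.occlusal_floor)


def occlusal_height(params: ToothParams, x, z):
    """Worn occlusal surface height: ``min(h0, truncation plane)``."""
    return np.minimum(occlusal_height_unworn(params, x, z), params.truncation_height)


def antagonist_height(params: ToothParams, x, z):
    """Antagonist occlusal surface (seen from below), before standoff.

    The lower envelope of: a high dome (never in contact), facet planes
    tangent to the outer (buccal-facing), disto-occlusal and
    mesio-occlusal flanks of the buccal cusp (restricted to local
    footprints — the wear-facet pairs; the mesial/distal pair balances so
    the oblique resultant tilts lingually, not mesio-distally), and the
    horizontal plane complementary to the wear plateau.  Tangency means
    zero nominal gap on the functional facets, so a pure translation
    brings the crowns into maximum intercuspation.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    s = params.slope
    r = params.cervix_radius
    cb = params.buccal_cusp_center

    rho2 = x * x + z * z
    dome = params.buccal_cusp_height + 1.5 + 0.08 * rho2

    # Facet planes tangent to the buccal-cusp cone along two flank rays.
    # A tangent plane never dips below its own (concave) cone, and near the
    # buccal cusp that cone dominates the height field, so tangency cannot
    # interpenetrate; each facet is active only in a disc around its anchor
    # mid-flank (the wear-facet footprint).
    flank = r - cb[0]

    def facet(direction, anchor_frac, radius_frac):
        ux, uz = direction
        plane = params.buccal_cusp_height - s * ((x - cb[0]) * ux + (z - cb[1]) * uz)
        anchor = (cb[0] + anchor_frac * flank * ux, cb[1] + anchor_frac * flank * uz)
        dist = np.hypot(x - anchor[0], z - anchor[1])
        return np.where(dist <= radius_frac * flank, plane, np.inf)

    # The outer buccal facet is the dominant functional contact, placed high
    # on the flank so its lingually-directed push loads the crown with a
    # long moment arm about the cervix; the two occlusal-ridge facets are
    # smaller and balance each other mesiodistally.
    p1 = facet((1.0, 0.0), 0.45, 0.30)   # outer buccal flank
    p2 = facet((0.0, 1.0), 0.60, 0.20)   # disto-occlusal ridge flank
    p3 = facet((0.0, -1.0), 0.60, 0.20)  # mesio-occlusal ridge flank
    p2 = np.minimum(p2, p3)

    plate = np.full_like(dome, params.truncation_height)
    return np.minimum(np.minimum(dome, p1), np.minimum(p2, plate))


# --- analytic contact surfaces ----------------------------------------------

def _heightfield_mesh(params: ToothParams, height_fn, spacing: float,
                      flip: bool = False) -> SurfaceMesh:
    """Triangulate a height field over the crown footprint disc.

    The grid is symmetric and includes the x = 0 / z = 0 lines so that the
    tangency rays of the facet planes are sampled exactly.
    """
    r = params.cervix_radius
    m = int(np.ceil(2.0 * r / spacing))
    if m % 2:
        m += 1  # even cell count -> odd vertex count -> includes 0
    g = np.linspace(-r, r, m + 1)
    X, Z = np.meshgrid(g, g, indexing="ij")
    Y = height_fn(params, X, Z)
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def vid(i, j):
        return i * (m + 1) + j

    I, J = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    I, J = I.ravel(), J.ravel()
    # two triangles per cell, wound counter-clockwise seen from +y
    t1 = np.stack([vid(I, J), vid(I, J + 1), vid(I + 1, J)], axis=1)
    t2 = np.stack([vid(I + 1, J), vid(I, J + 1), vid(I + 1, J + 1)], axis=1)
    tris = np.concatenate([t1, t2], axis=0)
    centroids = verts[tris].mean(axis=1)
    keep = np.hypot(centroids[:, 0], centroids[:, 2]) <= r
    tris = tris[keep]
    if flip:
        tris = tris[:, [0, 2, 1]]
    used = np.unique(tris)
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return SurfaceMesh(vertices=verts[used], triangles=remap[tris])


def crown_surface(params: ToothParams, spacing: float = SURFACE_SPACING) -> SurfaceMesh:
    """The worn lower-crown occlusal surface (normals point up/outward)."""
    return _heightfield_mesh(params, occlusal_height, spacing, flip=False)


def antagonist_surface(params: ToothParams, spacing: float = SURFACE_SPACING,
                       standoff: float = ANTAGONIST_STANDOFF) -> SurfaceMesh:
    """The antagonist occlusal surface, positioned ``standoff`` mm above
    maximum intercuspation (normals point down, toward the lower crown)."""

    def shifted(p, x, z):
        a = antagonist_height(p, x, z)
        # clip the +inf footprint sentinels to the dome before meshing
        rho2 = np.asarray(x) ** 2 + np.asarray(z) ** 2
        dome = p.buccal_cusp_height + 1.5 + 0.08 * rho2
        return np.minimum(a, dome) + standoff

    return _heightfield_mesh(params, shifted, spacing, flip=True)


# --- tissue classification ---------------------------------------------------

def _root_radius(params: ToothParams, y):
    frac = np.clip(-np.asarray(y, dtype=float) / params.root_length, 0.0, 1.0)
    return params.cervix_radius * (1.0 - 0.72 * frac)


def classify_points(params: ToothParams, points: np.ndarray) -> np.ndarray:
    """Tissue region per point; -1 for points outside every tissue."""
    p = np.asarray(points, dtype=float)
    x, y, z = p[:, 0], p[:, 1], p[:, 2]
    rho = np.hypot(x, z)
    r = params.cervix_radius

    h_w = occlusal_height(params, x, z)
    in_crown = (y >= 0.0) & (y <= h_w) & (rho <= r)
    in_root = (y < 0.0) & (y >= -params.root_length) & (rho <= _root_radius(params, y))
    in_tooth = in_crown | in_root

    h0 = occlusal_height_unworn(params, x, z)
    enamel = in_crown & (
        (rho >= r - params.enamel_thickness) | (y >= h0 - params.enamel_cap_vertical)
    )

    canal_r = params.pulp_radius * np.clip(1.0 + y / (0.75 * params.root_length), 0.0, 1.0)
    chamber = (y >= 0.0) & (y <= 0.3 * params.buccal_cusp_height) & (rho <= params.pulp_radius)
    canal = (y < 0.0) & (rho <= canal_r)
    pulp = in_tooth & (chamber | canal) & ~enamel

    pdl_lo = -(params.root_length + params.pdl_thickness)
    pdl = (
        ~in_tooth
        & (y < ALVEOLAR_CREST_Y)
        & (y >= pdl_lo)
        & (rho <= _root_radius(params, np.maximum(y, -params.root_length)) + params.pdl_thickness)
    )

    bx, by, bz = params.bone_block
    bone = (
        ~in_tooth
        & ~pdl
        & (np.abs(x) <= bx / 2.0)
        & (np.abs(z) <= bz / 2.0)
        & (y <= ALVEOLAR_CREST_Y)
        & (y >= ALVEOLAR_CREST_Y - by)
    )

    region = np.full(len(p), -1, dtype=np.int64)
    region[bone] = Region.BONE
    region[pdl] = Region.PDL
    region[in_tooth] = Region.DENTINE
    region[in_tooth & enamel] = Region.ENAMEL
    region[pulp] = Region.PULP
    return region


# --- mesh generation ---------------------------------------------------------

def generate_tooth(params: ToothParams) -> tuple[VolumeMesh, SurfaceMesh]:
    """Generate the multi-tissue volume mesh and the antagonist surface.

    The voxel grid spans the bone block laterally and the full unworn crown
    height vertically, and does not depend on ``wear_depth``; wear only
    removes elements above the truncation plane.  Tissue is assigned per
    tetrahedron from its centroid.  Deterministic for fixed parameters.
    """
    params.validate()
    bx, by, bz = params.bone_block
    y_lo = ALVEOLAR_CREST_Y - by
    dims = (bx, params.buccal_cusp_height - y_lo, bz)
    origin = (-bx / 2.0, y_lo, -bz / 2.0)
    nodes4, elements4 = structured_box_tet4(dims, params.mesh_size, origin=origin)

    centroids = nodes4[elements4].mean(axis=1)
    region = classify_points(params, centroids)
    keep = region >= 0
    elements4, region = elements4[keep], region[keep]

    band = params.cervical_band
    tol = 1e-9
    crown_code = {int(Region.ENAMEL), int(Region.DENTINE)}

    mesh = promote_to_volume_mesh(
        nodes4, elements4, region,
        node_sets_from={
            "MESIAL_CUT": lambda n: n[:, 2] <= -bz / 2.0 + tol,
            "DISTAL_CUT": lambda n: n[:, 2] >= bz / 2.0 - tol,
        },
    )

    # surface-dependent node sets need boundary faces of the final mesh
    faces, owners = mesh.boundary_faces()
    on_tooth = np.isin(mesh.region[owners], list(crown_code))
    a, b, c = (mesh.nodes[faces[:, i]] for i in range(3))
    normals = np.cross(b - a, c - a)
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    f_centroid = (a + b + c) / 3.0

    occl = on_tooth & (normals[:, 1] > 0.2) & (f_centroid[:, 1] > 1.0)
    mesh.node_sets["OCCLUSAL_SURFACE"] = np.unique(faces[occl])

    tooth_boundary_nodes = np.unique(faces[on_tooth])
    ny = mesh.nodes[tooth_boundary_nodes]
    cervix = (np.abs(ny[:, 1]) <= band) & (ny[:, 0] > 0.0)
    mesh.node_sets["BUCCAL_CERVIX"] = tooth_boundary_nodes[cervix]

    mesh.validate()
    upper = antagonist_surface(params)
    return mesh, upper


def generate_validation_solid(
    kind: str,
    dims: tuple[float, float, float],
    mesh_size: float,
    region: Region = Region.DENTINE,
) -> VolumeMesh:
    """Single-region TET10 box with named face node sets (solver fixtures).

    ``kind`` is one of {"bar", "cantilever", "cube"} — it documents intent;
    the geometry is the axis-aligned box ``dims`` in all cases.  Node sets
    XMIN/XMAX/YMIN/YMAX/ZMIN/ZMAX hold the nodes of each face.
    """
    if kind not in ("bar", "cantilever", "cube"):
        raise ValidationError(f"unknown validation solid kind {kind!r}")
    dims = tuple(float(d) for d in dims)
    if any(d <= 0 for d in dims):
        raise ValidationError(f"dims must be positive, got {dims}")
    if mesh_size > min(dims):
        raise ValidationError(
            f"mesh_size {mesh_size} exceeds smallest dimension {min(dims)}"
        )
    nodes4, elements4 = structured_box_tet4(dims, mesh_size)
    tol = 1e-9
    sets = {}
    for ax, name in enumerate("xyz"):
        lo, hi = 0.0, dims[ax]
        sets[f"{name.upper()}MIN"] = (lambda n, ax=ax, lo=lo: n[:, ax] <= lo + tol)
        sets[f"{name.upper()}MAX"] = (lambda n, ax=ax, hi=hi: n[:, ax] >= hi - tol)
    mesh = promote_to_volume_mesh(
        nodes4, elements4, np.full(len(elements4), int(region)), node_sets_from=sets
    )
    mesh.validate()
    return mesh
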