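# Methods

`toothfea` asks a biomechanical question: does occlusal wear lower the
tensile stress at the buccal cervical margin of a lower second premolar?
High cervical tension under oblique occlusal loads is the proposed driver
of abfraction — the stress-mediated component of non-carious cervical
lesions (NCCLs) — so a tooth whose cusps have been worn flat should load
axially and spare its cervix. The package implements the full chain
needed to test this on a synthetic tooth: parametric multi-tissue
geometry at a controllable wear depth, occlusal contact detection against
an antagonist, facet-perpendicular loads normalized to a prescribed
resultant, a linear-elastic finite-element solve on quadratic tetrahedra,
and a homologous cervical stress comparison across wear states.

## Coordinate convention and units

x = lingual → buccal, y = inferior → superior (the tooth long axis),
z = mesial → distal; origin at the cervix centroid. Lengths are mm,
forces N, stresses MPa; elastic moduli are entered in GPa (dental
convention) and converted on load.

## The synthetic premolar

No tomographic specimen ships with the package; the geometry module is
the data generator. The occlusal surface is a height field: the upper
envelope of two cusp cones — a dominant, steep buccal cusp whose tip
lies near the tooth axis (0.2 cervix radii buccally; lower premolar
anatomy) and a lower lingual cusp — a distal marginal-ridge cone and a
flat occlusal floor. The crown is this height field over a cylindrical
cervix; the root is a tapering cone; an enamel cap (defined relative to
the *unworn* surface) covers a dentine body with a pulp chamber and root
canal; a 0.25 mm periodontal ligament (PDL) separates the root from an
alveolar bone block with planar mesial/distal cut faces.

Default parameters (crown height 8 mm, cervix radius 3.5 mm, buccal cusp
slope 50°, enamel 1.2 mm, root 10 mm, bone block 10.5 × 11.5 × 16 mm)
are nominal lower-second-premolar dimensions. The bone block leaves
roughly a tooth-width of bone mesial and distal of the socket, mirroring
a mandible section cut one tooth away on each side; a thinner margin
places the cut-face constraints close enough to contaminate the root
stress field. The PDL thickness and pulp dimensions are package
defaults, not literature values.

**Wear** is planar truncation of the crown at height
`buccal_cusp_height − wear_depth` — the computational endpoint of
attrition, which flattens cusp tips into facets. Because the enamel cap
is anchored to the unworn surface, truncation deeper than the cap
exposes dentine on the plateau. Ordinal wear stages map onto depth:
stage 1 up to 25 % of the occlusal cap thickness, stage 3 once the
plateau cuts below the cap (dentine exposed), stage 2 between.

**The antagonist** is the lower envelope of complementary features: a
high dome (never in contact), three planar wear facets tangent to the
buccal-cusp flanks — the dominant facet on the outer (buccal-facing)
incline, plus a balanced mesio-/disto-occlusal pair whose lateral pushes
cancel — and a horizontal plane complementary to the wear plateau.
Tangency means the nominal gap on every functional facet is zero, so a
pure translation reaches maximum intercuspation. The construction makes
the load physics emergent rather than scripted: with intact cusps the
contact sits on steep facets and the resultant tilts lingually (the
outer-flank contact pushes the crown toward the tongue); as the plateau
grows the plate contact dominates and the resultant straightens toward
the tooth axis while total contact area rises.

**Meshing** is structured voxel-to-tetrahedra subdivision (six
Kuhn/Freudenthal tets per cell, face-conforming) with per-tet tissue
classification at the centroid and promotion to straight-sided 10-node
tetrahedra. The grid is anchored to the unworn bounding box and does not
move with wear, so every node below the truncation is bit-identical
across wear states — this is what makes the "homologous nodes"
comparison exact. The boundary is deliberately left unsnapped
(stair-step): snapping quadratic elements to the implicit surface risks
inverted Jacobians, and moving boundary nodes would break the exact
cross-state homology. The price is boundary stress noise, addressed at
the recovery stage (below). Default target edge length is 1 mm
(≈ 14 000 elements, ≈ 75 000 unknowns per state); tests run the same
pipeline at 1.4–1.6 mm.

## Contact at maximum intercuspation

The antagonist starts 0.5 mm above the crown and is translated along the
approach direction (default −y) to first touch, found by casting rays
from each vertex of either surface onto the other (exact for
vertex-to-face contact; residual edge-edge penetration is bounded by the
gap tolerance, 10⁻⁶ mm). Colliding triangles are those of the lower
crown whose minimum vertex/centroid distance to the antagonist is at
most ε = 0.05 mm — a tolerance tied to the ~55 µm resolution of optical
scans of real occlusal surfaces. Distances use an exact
point-to-triangle kernel under a KD-tree broad phase, verified in the
tests against an all-pairs brute-force oracle. Colliding triangles are
clustered into patches by edge adjacency (vertex-touching clusters stay
separate); each patch carries its area, area-weighted outward normal and
centroid. Only the static maximum-intercuspation instant is modelled —
no chewing-stroke kinematics.

## Loads

Each patch receives a uniform pressure along its inward normal
(compressive, perpendicular to the wear facet), with magnitude
proportional to patch area. Pressures become consistent nodal forces on
the volume mesh's occlusal boundary faces: for a uniform traction on a
straight-sided quadratic triangle the corner forces vanish and each
midside node carries A/3 of the total — integrated here with the exact
3-midpoint rule. Because the contact surfaces are smooth analytic
meshes while the volume boundary is voxelized, patches map to boundary
faces by nearest footprint in the occlusal (x, z) projection within one
mesh size. After conversion, one global scalar rescales all nodal
forces so the resultant magnitude equals the prescribed total (default
100 N) to 10⁻⁸ relative; normalization after conversion is the fixed
convention. Configurations whose area-weighted normals nearly cancel
(resultant below 10⁻⁶ of the summed areas) are rejected as
indeterminate.

## Finite elements

Standard isoparametric TET10 linear elasticity. All five tissues are
homogeneous, isotropic and linearly elastic: enamel 84.1 GPa / 0.3,
dentine 18.6 / 0.31, pulp 0.002 / 0.45, PDL 0.0689 / 0.45, alveolar
bone 11.5 / 0.3 (trabecular and cortical bone are collapsed into the
single bone entry; the PDL is linearized). Stiffness uses the 4-point
degree-2 simplex rule — exact for straight-sided elements — and the
element routine is verified to 10⁻¹⁰ against an independent collapsed-
coordinate Gauss oracle. Constraints reproduce the mandible-section
restraint pattern: mesial cut face fixed in x only, distal cut face
fixed in y and z; a rank check of the rigid-body-mode basis restricted
to the constrained dofs runs before every solve and names the free mode
on failure. ("Medial" in the source description is read as the mesial
cut face.) Constrained dofs are eliminated (not penalized), the reduced
SPD system is solved by sparse LU with COLAMD ordering, and global
equilibrium (reactions + applied forces) is checked to 10⁻⁸ relative.

Stress recovery evaluates B-matrix strains directly at the elements'
nodal natural coordinates — for straight TET10 the strain field is
linear inside each element, so this equals extrapolation from the
integration points — and averages to nodes with element-volume weights
**within a single tissue**, chosen by hardness priority (enamel first),
so values are never smeared across bimaterial interfaces such as the
enamel-dentine junction. The patch test (prescribed linear displacement
field) recovers constant stress to 10⁻⁹ relative.

## Cervical comparison and zone report

The buccal cervix node set collects external enamel/dentine boundary
nodes with |y| within the cervical band (max(0.5 mm, 0.8 × mesh size))
and x > 0. Ten homologous sampling positions are fixed fractions of the
buccal azimuth arc; the node nearest each position is selected
deterministically (azimuth mismatch, then distance from the cervix
plane, then lowest id, with strictly increasing azimuths). Because
sub-occlusal nodes coincide exactly across wear states, arc positions
match exactly and the comparison is position-by-position.

Stair-step boundaries make single-node stresses oscillate about the
smooth-surface solution, and corner values do not converge under
refinement. The reported tensile values are therefore patch-recovered:
σ1 is averaged over external tooth-surface nodes within 1.25 × mesh
size of each node (a surface analog of superconvergent patch recovery).
The cervical sample, the zone σ1 statistics and the zone flag all use
this recovered field; σ3 and trace statistics (means over many nodes,
inherently stable) use the raw nodal field.

Anatomical zones are azimuth quadrants (buccal |az| ≤ 45°, etc.):
cervical zones within the cervical band, lateral-side zones from half
the root depth up to 0.35 × the worn crown height (below the loaded
occlusal table), and a root-apex zone below 85 % of the root length.
The pulp-chamber wall is excluded — it carries pressure-vessel hoop
tension irrelevant to the external stress maps. The zone report flags
the zone with the highest **mean** recovered σ1; a pointwise-max flag
would ride whichever stair corner is sharpest at a given resolution.

## What the defaults produce

At the default geometry, the three stage-representative wear depths
(0.2, 0.7 and 1.3 × the occlusal cap thickness) yield, at 1 mm
resolution: contact area growing ≈ 8 → 11 → 19 mm², load obliquity
falling ≈ 23° → 9° → 1°, mean recovered cervical σ1 falling
≈ 1.6 → 0.7 → 0.6 MPa, the highest-tension zone moving from the buccal
cervix (lingual cervix near zero) to the distal side, and a root apex in
net compression when worn. These are the qualitative signatures of the
abfraction mechanism; `scripts/acceptance.py` recomputes them from
scratch.

## What the generator does and does not emulate

It emulates the features the mechanism depends on: a steep, dominant
buccal cusp loaded on discrete wear facets; progressive flattening with
dentine exposure; compliant PDL suspension in a bone section constrained
at its cut faces; a 100 N resultant whose direction is dictated by facet
orientation. It does not emulate real crown morphology (fossae, ridges,
asymmetric facet histories), enamel anisotropy or regional property
gradients, nonlinear PDL response, frictional or kinematic contact, or
cyclic loading. Passing tests therefore demonstrate that the pipeline
reproduces the mechanism's signatures on an idealized premolar — not
specimen-level stress magnitudes, which depend on individual anatomy.
Absolute σ1 values here are accordingly smaller and smoother than
color-map peaks on real micro-CT geometries.

## Numerical choices and degenerate inputs

Tolerances: contact ε 0.05 mm; gap tolerance 10⁻⁶ mm; resultant
normalization exact to 10⁻⁸ relative; equilibrium residual 10⁻⁸;
rigid-mode rank threshold 10⁻⁹ relative. Ties in node selection break
toward the lowest node id. Degenerate inputs fail loudly: inverted
elements name the element, insufficient constraints name the free rigid
mode, cancelling patch normals raise an indeterminate-normalization
error, and a tooth whose parameters cannot contain root, PDL and pulp is
rejected at validation with the offending field named.

## Known limitations

Voxel stair-stepping limits pointwise surface-stress accuracy to the
recovered (smoothed) field; the wear operator is a plane, not a curved
facet history; the antagonist is rigid and its facets are ideal planes;
stage boundaries are a fixed mapping from truncation depth, not from
facet coalescence detection; and the solver is direct sparse LU, which
bounds practical problem size to a few hundred thousand unknowns.
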