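"""Linear-elastic finite-element solver on 10-node tetrahedra.

Units are mm / N / MPa throughout: elastic moduli are entered in GPa (the
convention of the dental literature) and converted to MPa on load, so the
recovered stresses come out directly in MPa.

All tissues are treated as homogeneous, linearly elastic and isotropic.
The stiffness quadrature is the 4-point degree-2 simplex rule, which is
exact for straight-sided quadratic tetrahedra.  Constraints are applied by
row/column elimination so constrained degrees of freedom are exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConstraintError, MeshError, SolverError, ValidationError
from .meshes import REGION_PRIORITY, Region, VolumeMesh
from .tet10 import GAUSS4_POINTS, GAUSS4_WEIGHTS, NODE_NATURAL, jacobians, shape_gradients

#: Voigt component order used everywhere: xx, yy, zz, xy, yz, xz
VOIGT = ("xx", "yy", "zz", "xy", "yz", "xz")

_AXIS = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material: modulus in GPa, Poisson's ratio."""

    E: float  # GPa
    nu: float

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValidationError(f"elastic modulus must be positive, got {self.E}")
        if not -1.0 < self.nu < 0.5:
            raise ValidationError(f"Poisson's ratio must lie in (-1, 0.5), got {self.nu}")

    @property
    def E_mpa(self) -> float:
        return self.E * 1000.0

    def elasticity_matrix(self) -> np.ndarray:
        """6x6 isotropic Hooke matrix in MPa (engineering shear strains)."""
        E, nu = self.E_mpa, self.nu
        lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
        mu = E / (2.0 * (1.0 + nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.diag_indices(3)] += 2.0 * mu
        D[3:, 3:] = np.eye(3) * mu
        return D


def default_materials() -> dict[Region, Material]:
    """Literature elastic properties of dental and supporting tissues (GPa).

    Trabecular and cortical bone are collapsed into a single alveolar-bone
    entry; the periodontal ligament (PDL) is linearized.
    """
    return {
        Region.ENAMEL: Material(84.1, 0.30),
        Region.DENTINE: Material(18.6, 0.31),
        Region.PULP: Material(0.002, 0.45),
        Region.PDL: Material(0.0689, 0.45),
        Region.BONE: Material(11.5, 0.30),
    }


@dataclass
class ConstraintSet:
    """Per-node fixed displacement axes (fixed value 0)."""

    fixed: dict[int, frozenset[str]] = field(default_factory=dict)

    @classmethod
    def from_node_sets(cls, mesh: VolumeMesh, spec: dict[str, str]) -> "ConstraintSet":
        """Build from {node_set_name: axes string}, e.g. {"MESIAL_CUT": "x"}."""
        fixed: dict[int, set[str]] = {}
        for set_name, axes in spec.items():
            if set_name not in mesh.node_sets:
                raise ConstraintError(f"mesh has no node set {set_name!r}")
            for ax in axes:
                if ax not in _AXIS:
                    raise ConstraintError(f"unknown axis {ax!r} in constraint spec")
            for nid in mesh.node_sets[set_name]:
                fixed.setdefault(int(nid), set()).update(axes)
        return cls({n: frozenset(a) for n, a in fixed.items()})

    def dof_mask(self, n_nodes: int) -> np.ndarray:
        """Boolean (3*n_nodes,) mask, True where the dof is constrained."""
        mask = np.zeros(3 * n_nodes, dtype=bool)
        for nid, axes in self.fixed.items():
            if nid < 0 or nid >= n_nodes:
                raise ConstraintError(f"constraint references missing node {nid}")
            for ax in axes:
                mask[3 * nid + _AXIS[ax]] = True
        return mask


def tooth_constraints(mesh: VolumeMesh) -> ConstraintSet:
    """The cut-surface restraint pattern of the mandible-section model.

    Nodes on the mesial cut face are restrained in x (bucco-lingual
    translation) only; nodes on the distal cut face are restrained in y and
    z (supero-inferior and mesio-distal).  Together these remove all six
    rigid-body modes of the block while leaving the section free to deform.
    """
    return ConstraintSet.from_node_sets(mesh, {"MESIAL_CUT": "x", "DISTAL_CUT": "yz"})


@dataclass
class DisplacementField:
    u: np.ndarray  # (N, 3), mm
    reactions: np.ndarray  # (N, 3), N — nonzero only at constrained dofs
    equilibrium_residual: float  # |sum reactions + sum applied| / |sum applied|


@dataclass
class StressField:
    """Nodal stress in MPa: Voigt tensor plus sorted principal values."""

    sigma: np.ndarray  # (N, 6) Voigt order xx, yy, zz, xy, yz, xz
    principal: np.ndarray  # (N, 3) with sigma1 >= sigma2 >= sigma3
    node_region: np.ndarray  # (N,) region whose elements the nodal average used

    @property
    def sigma1(self) -> np.ndarray:
        return self.principal[:, 0]

    @property
    def sigma3(self) -> np.ndarray:
        return self.principal[:, 2]

    def trace(self) -> np.ndarray:
        return self.sigma[:, :3].sum(axis=1)


def voigt_to_tensor(sigma: np.ndarray) -> np.ndarray:
    """(..., 6) Voigt -> (..., 3, 3) symmetric tensors."""
    s = np.asarray(sigma, dtype=float)
    t = np.empty(s.shape[:-1] + (3, 3))
    t[..., 0, 0], t[..., 1, 1], t[..., 2, 2] = s[..., 0], s[..., 1], s[..., 2]
    t[..., 0, 1] = t[..., 1, 0] = s[..., 3]
    t[..., 1, 2] = t[..., 2, 1] = s[..., 4]
    t[..., 0, 2] = t[..., 2, 0] = s[..., 5]
    return t


def principal_stresses(tensor: np.ndarray) -> np.ndarray:
    """Sorted principal stresses (descending) of symmetric tensors.

    Accepts a single (3, 3) tensor, a batch (..., 3, 3), or Voigt (..., 6).
    sigma1 > 0 is read as tension — the failure driver in brittle tissues.
    """
    t = np.asarray(tensor, dtype=float)
    if t.shape[-1] == 6 and (t.ndim == 1 or t.shape[-2:] != (3, 3)):
        t = voigt_to_tensor(t)
    asym = np.abs(t - np.swapaxes(t, -1, -2)).max()
    scale = max(np.abs(t).max(), 1.0)
    if asym > 1e-9 * scale:
        raise ValidationError(f"stress tensor not symmetric (asymmetry {asym:.3e})")
    t = 0.5 * (t + np.swapaxes(t, -1, -2))
    vals = np.linalg.eigvalsh(t)
    return vals[..., ::-1]


# --- stiffness ---------------------------------------------------------------

def _b_matrices(coords: np.ndarray, dN_ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strain-displacement matrices at evaluation points.

    coords: (E, 10, 3); dN_ref: (G, 10, 3).
    Returns B (E, G, 6, 30) and detJ (E, G).
    """
    jac, det = jacobians(coords, dN_ref)
    if np.any(det <= 0.0):
        e = int(np.argwhere(det <= 0.0)[0][0])
        raise MeshError(f"inverted element {e} (non-positive Jacobian)")
    jinv = np.linalg.inv(jac)  # (E, G, 3, 3)
    # dN/dx[e, g, n, k] = dN_ref[g, n, j] * jinv[e, g, j, k]
    dndx = np.einsum("gnj,egjk->egnk", dN_ref, jinv)
    E_, G = det.shape
    B = np.zeros((E_, G, 6, 30))
    dx, dy, dz = dndx[..., 0], dndx[..., 1], dndx[..., 2]
    B[..., 0, 0::3] = dx
    B[..., 1, 1::3] = dy
    B[..., 2, 2::3] = dz
    B[..., 3, 0::3] = dy
    B[..., 3, 1::3] = dx
    B[..., 4, 1::3] = dz
    B[..., 4, 2::3] = dy
    B[..., 5, 0::3] = dz
    B[..., 5, 2::3] = dx
    return B, det


def element_stiffness(coords: np.ndarray, material: Material) -> np.ndarray:
    """30x30 stiffness of one TET10 element (symmetric PSD, 6 rigid modes)."""
    coords = np.asarray(coords, dtype=float).reshape(1, 10, 3)
    dN = shape_gradients(GAUSS4_POINTS)
    B, det = _b_matrices(coords, dN)
    D = material.elasticity_matrix()
    K = np.einsum(
        "g,eg,egki,kl,eglj->eij", GAUSS4_WEIGHTS, det, B, D, B, optimize=True
    )
    return 0.5 * (K[0] + K[0].T)


def assemble(
    mesh: VolumeMesh, materials: dict[Region, Material], chunk: int = 4096
) -> sp.csr_matrix:
    """Assemble the global stiffness matrix (3N x 3N, CSR)."""
    for r in np.unique(mesh.region):
        if Region(r) not in materials:
            raise ValidationError(f"no material for region {Region(r).name}")
    dN = shape_gradients(GAUSS4_POINTS)
    n_dof = 3 * mesh.n_nodes
    dofs = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(-1, 30)
    rows_all, cols_all, vals_all = [], [], []
    order = np.arange(mesh.n_elements)
    for start in range(0, mesh.n_elements, chunk):
        idx = order[start : start + chunk]
        coords = mesh.nodes[mesh.elements[idx]]
        B, det = _b_matrices(coords, dN)
        K = np.zeros((len(idx), 30, 30))
        for r in np.unique(mesh.region[idx]):
            D = materials[Region(r)].elasticity_matrix()
            sel = mesh.region[idx] == r
            K[sel] = np.einsum(
                "g,eg,egki,kl,eglj->eij",
                GAUSS4_WEIGHTS, det[sel], B[sel], D, B[sel], optimize=True,
            )
        d = dofs[idx]
        rows_all.append(np.repeat(d, 30, axis=1).ravel())
        cols_all.append(np.tile(d, (1, 30)).ravel())
        vals_all.append(K.ravel())
    K = sp.coo_matrix(
        (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(n_dof, n_dof),
    ).tocsr()
    return 0.5 * (K + K.T)


def _rigid_modes(nodes: np.ndarray) -> np.ndarray:
    """(3N, 6) basis of rigid-body displacement modes about the centroid."""
    c = nodes.mean(axis=0)
    x = nodes - c
    n = len(nodes)
    R = np.zeros((3 * n, 6))
    for ax in range(3):
        R[ax::3, ax] = 1.0
    R[1::3, 3], R[2::3, 3] = -x[:, 2], x[:, 1]  # rotation about x
    R[0::3, 4], R[2::3, 4] = x[:, 2], -x[:, 0]  # rotation about y
    R[0::3, 5], R[1::3, 5] = -x[:, 1], x[:, 0]  # rotation about z
    return R


_MODE_NAMES = ("translation x", "translation y", "translation z",
               "rotation x", "rotation y", "rotation z")


def check_rigid_modes(mesh: VolumeMesh, constraints: ConstraintSet) -> None:
    """Verify the constraints remove all six rigid-body modes.

    A rigid mode survives when it is (a combination of modes) identically
    zero on every constrained dof; detect this via the rank of the mode
    basis restricted to the constrained dofs.
    """
    mask = constraints.dof_mask(mesh.n_nodes)
    if not mask.any():
        raise ConstraintError(
            "insufficient constraints: no dofs constrained; free rigid mode: translation x"
        )
    R = _rigid_modes(mesh.nodes)[mask]
    u, s, vt = np.linalg.svd(R, full_matrices=True)
    rank = int((s > 1e-9 * max(s[0], 1.0)).sum())
    if rank < 6:
        free = vt[rank]  # combination of modes invisible to the constraints
        name = _MODE_NAMES[int(np.argmax(np.abs(free)))]
        raise ConstraintError(f"insufficient constraints: free rigid mode ~ {name}")


def apply_constraints(
    K: sp.csr_matrix, f: np.ndarray, constraints: ConstraintSet
) -> tuple[sp.csc_matrix, np.ndarray, np.ndarray]:
    """Reduce the system by eliminating constrained (zero-valued) dofs.

    Returns (K_ff in CSC, f_f, free dof indices).
    """
    n_nodes = K.shape[0] // 3
    mask = constraints.dof_mask(n_nodes)
    free = np.flatnonzero(~mask)
    return K[free][:, free].tocsc(), f[free], free


def solve(
    mesh: VolumeMesh,
    materials: dict[Region, Material],
    nodal_forces: np.ndarray,
    constraints: ConstraintSet,
) -> DisplacementField:
    """Solve K u = f with the given constraints; returns displacements in mm.

    Verifies well-posedness (rigid-body modes) first, and reports the global
    equilibrium residual |sum reactions + sum applied| / |sum applied|.
    """
    check_rigid_modes(mesh, constraints)
    f = np.asarray(nodal_forces, dtype=float).reshape(-1)
    if f.shape[0] != 3 * mesh.n_nodes:
        raise ValidationError("nodal force vector length does not match mesh")
    K = assemble(mesh, materials)
    K_ff, f_f, free = apply_constraints(K, f, constraints)
    try:
        lu = spla.splu(K_ff, permc_spec="COLAMD")
        u_f = lu.solve(f_f)
    except RuntimeError as exc:  # pragma: no cover - singular factorization
        raise SolverError(f"sparse factorization failed: {exc}") from exc
    if not np.all(np.isfinite(u_f)):
        raise SolverError("non-finite displacements (singular constrained system)")
    u = np.zeros(3 * mesh.n_nodes)
    u[free] = u_f
    residual_vec = K @ u - f
    reactions = np.where(
        ~np.isin(np.arange(3 * mesh.n_nodes), free), residual_vec, 0.0
    )
    applied = f.reshape(-1, 3).sum(axis=0)
    total = reactions.reshape(-1, 3).sum(axis=0) + applied
    denom = np.linalg.norm(applied)
    resid = float(np.linalg.norm(total) / denom) if denom > 0 else float(np.linalg.norm(total))
    return DisplacementField(
        u=u.reshape(-1, 3),
        reactions=reactions.reshape(-1, 3),
        equilibrium_residual=resid,
    )


def recover_stress(
    mesh: VolumeMesh,
    materials: dict[Region, Material],
    displacement: DisplacementField | np.ndarray,
) -> StressField:
    """Nodal stress recovery with region-aware volume-weighted averaging.

    Strains are evaluated from the B-matrix directly at the elements' nodal
    natural coordinates (for straight-sided TET10 the strain field is linear
    inside the element, so this equals extrapolation from the integration
    points).  Each node is then averaged only over adjacent elements of a
    single tissue, chosen by hardness priority (enamel first), so stress is
    never smeared across bimaterial interfaces such as the enamel-dentine
    junction.
    """
    u = displacement.u if isinstance(displacement, DisplacementField) else np.asarray(displacement)
    if u.shape != (mesh.n_nodes, 3):
        raise ValidationError("displacement field shape does not match mesh")
    dN = shape_gradients(NODE_NATURAL)  # (10, 10, 3): B at each nodal point
    coords = mesh.nodes[mesh.elements]
    B, _ = _b_matrices(coords, dN)  # (E, 10, 6, 30)
    ue = u[mesh.elements].reshape(-1, 30)  # (E, 30)
    strain = np.einsum("egik,ek->egi", B, ue, optimize=True)  # (E, 10, 6)
    stress_e = np.empty_like(strain)
    for r in np.unique(mesh.region):
        D = materials[Region(r)].elasticity_matrix()
        sel = mesh.region == r
        stress_e[sel] = strain[sel] @ D.T
    vols = mesh.element_volumes()

    # node -> region by priority among adjacent elements
    n = mesh.n_nodes
    present = np.zeros((n, len(Region)), dtype=bool)
    for r in np.unique(mesh.region):
        sel = mesh.region == r
        present[np.unique(mesh.elements[sel]), r] = True
    node_region = np.empty(n, dtype=np.int64)
    node_region.fill(-1)
    for r in reversed(REGION_PRIORITY):  # lowest priority first, overwritten later
        node_region[present[:, r]] = int(r)

    sigma = np.zeros((n, 6))
    weight = np.zeros(n)
    flat_nodes = mesh.elements.ravel()
    elem_of = np.repeat(np.arange(mesh.n_elements), 10)
    w = vols[elem_of]
    # keep only contributions whose element region matches the node's region
    match = mesh.region[elem_of] == node_region[flat_nodes]
    np.add.at(sigma, flat_nodes[match],
              stress_e.reshape(-1, 6)[match] * w[match, None])
    np.add.at(weight, flat_nodes[match], w[match])
    sigma /= weight[:, None]
    principal = principal_stresses(voigt_to_tensor(sigma))
    return StressField(sigma=sigma, principal=principal, node_region=node_region)
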