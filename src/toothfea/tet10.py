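"""Quadratic tetrahedron (TET10) shape functions, quadrature and meshing helpers.

Reference element: the unit tetrahedron with natural coordinates
``(xi, eta, zeta)``; barycentric coordinates are ``L0 = 1 - xi - eta - zeta``,
``L1 = xi``, ``L2 = eta``, ``L3 = zeta``.  Node ordering is the VTK
``QUADRATIC_TETRA`` convention documented in :mod:`toothfea.meshes`.
"""

from __future__ import annotations

import numpy as np

from .errors import MeshError, ValidationError
from .meshes import TET10_EDGES, VolumeMesh

#: Natural coordinates (xi, eta, zeta) of the 10 nodes.
NODE_NATURAL = np.array(
    [
        [0.0, 0.0, 0.0],
        [1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0],
        [0.5, 0.0, 0.0],
        [0.5, 0.5, 0.0],
        [0.0, 0.5, 0.0],
        [0.0, 0.0, 0.5],
        [0.5, 0.0, 0.5],
        [0.0, 0.5, 0.5],
    ]
)

# 4-point, degree-2 rule: exact for the stiffness integrand of straight TET10.
_A = (5.0 + 3.0 * np.sqrt(5.0)) / 20.0
_B = (5.0 - np.sqrt(5.0)) / 20.0
GAUSS4_POINTS = np.array(
    [
        [_A, _B, _B],
        [_B, _A, _B],
        [_B, _B, _A],
        [_B, _B, _B],
    ]
)
GAUSS4_WEIGHTS = np.full(4, 1.0 / 24.0)  # reference tet volume is 1/6


def _bary(points: np.ndarray) -> np.ndarray:
    points = np.atleast_2d(points)
    L0 = 1.0 - points.sum(axis=1)
    return np.column_stack([L0, points])


def shape_functions(points: np.ndarray) -> np.ndarray:
    """Shape function values, shape (P, 10)."""
    L = _bary(points)
    corner = L[:, :4] * (2.0 * L[:, :4] - 1.0)
    mids = np.column_stack([4.0 * L[:, i] * L[:, j] for i, j in TET10_EDGES])
    return np.concatenate([corner, mids], axis=1)


def shape_gradients(points: np.ndarray) -> np.ndarray:
    """Shape function gradients w.r.t. natural coordinates, shape (P, 10, 3)."""
    L = _bary(points)
    dL = np.array(
        [[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )  # (4, 3)
    P = len(L)
    dN = np.empty((P, 10, 3))
    for i in range(4):
        dN[:, i, :] = (4.0 * L[:, i] - 1.0)[:, None] * dL[i]
    for k, (i, j) in enumerate(TET10_EDGES):
        dN[:, 4 + k, :] = 4.0 * (L[:, i][:, None] * dL[j] + L[:, j][:, None] * dL[i])
    return dN


def jacobians(coords: np.ndarray, dN: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched Jacobians.

    Parameters
    ----------
    coords : (E, 10, 3) element node coordinates.
    dN : (G, 10, 3) natural-coordinate shape gradients.

    Returns
    -------
    jac : (E, G, 3, 3) with ``jac[e, g, j, k] = d x_j / d xi_k``.
    det : (E, G) determinants.
    """
    jac = np.einsum("enj,gnk->egjk", coords, dN)
    return jac, np.linalg.det(jac)


def linear_to_quadratic(
    nodes: np.ndarray, elements: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Promote a 4-node tet mesh to straight-sided TET10.

    One midside node is created per unique edge and shared across elements.
    The returned node array is the input corner nodes followed by the edge
    midpoints (in lexicographic edge order).
    """
    nodes = np.asarray(nodes, dtype=np.float64)
    elements = np.asarray(elements, dtype=np.int64)
    if elements.ndim != 2 or elements.shape[1] != 4:
        raise ValidationError("expected a (E, 4) tet connectivity array")
    if len(np.unique(np.sort(elements, axis=1), axis=0)) != len(elements):
        raise MeshError("duplicate elements in tet mesh")
    if np.any(np.ptp(np.sort(elements, axis=1), axis=1) == 0) or np.any(
        np.diff(np.sort(elements, axis=1), axis=1) == 0
    ):
        raise MeshError("degenerate element (repeated corner node)")

    edges = np.concatenate(
        [np.sort(elements[:, [i, j]], axis=1) for i, j in TET10_EDGES], axis=0
    )  # (6E, 2)
    unique_edges, inverse = np.unique(edges, axis=0, return_inverse=True)
    mid = 0.5 * (nodes[unique_edges[:, 0]] + nodes[unique_edges[:, 1]])
    mid_ids = len(nodes) + inverse.reshape(6, -1).T  # (E, 6)
    return np.concatenate([nodes, mid]), np.concatenate([elements, mid_ids], axis=1)


# --- structured box meshing (Kuhn/Freudenthal subdivision) -------------------

# The six tets per cell follow the six monotone lattice paths from corner
# (0,0,0) to (1,1,1); this triangulation is face-conforming under translation.
_AXIS_PERMS = (
    (0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)
)


def _cell_tets() -> np.ndarray:
    """Local corner indices (bit-coded (ix, iy, iz)) of the 6 Kuhn tets."""
    tets = []
    for perm in _AXIS_PERMS:
        v = [0]
        code = [0, 0, 0]
        for axis in perm:
            code[axis] = 1
            v.append(code[0] | (code[1] << 1) | (code[2] << 2))
        tets.append(v)
    return np.array(tets)


_CELL_TETS = _cell_tets()


def structured_box_tet4(
    dims: tuple[float, float, float],
    mesh_size: float,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    divisions: tuple[int, int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Tetrahedralize an axis-aligned box into positively-oriented TET4s.

    Returns (nodes (N, 3), elements (E, 4)).
    """
    dims = np.asarray(dims, dtype=float)
    if np.any(dims <= 0):
        raise ValidationError("box dimensions must be positive")
    if divisions is None:
        if mesh_size <= 0:
            raise ValidationError("mesh_size must be positive")
        if mesh_size > dims.min():
            raise ValidationError(
                f"mesh_size {mesh_size} exceeds smallest box dimension {dims.min()}"
            )
        divisions = tuple(max(1, int(np.ceil(d / mesh_size))) for d in dims)
    nx, ny, nz = divisions
    xs = origin[0] + np.linspace(0.0, dims[0], nx + 1)
    ys = origin[1] + np.linspace(0.0, dims[1], ny + 1)
    zs = origin[2] + np.linspace(0.0, dims[2], nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    # cell corner ids, bit-coded local index (ix | iy<<1 | iz<<2)
    corners = np.stack(
        [nid(I + (b & 1), J + ((b >> 1) & 1), K + ((b >> 2) & 1)) for b in range(8)],
        axis=1,
    )  # (C, 8)
    elements = corners[:, _CELL_TETS].reshape(-1, 4)
    # enforce positive orientation
    c = nodes[elements]
    det = np.linalg.det(c[:, 1:] - c[:, :1])
    neg = det < 0
    elements[neg, 2], elements[neg, 3] = elements[neg, 3].copy(), elements[neg, 2].copy()
    return nodes, elements


def compact_mesh(nodes: np.ndarray, elements: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop unreferenced nodes and renumber connectivity (order-preserving)."""
    used = np.unique(elements)
    remap = -np.ones(len(nodes), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return nodes[used], remap[elements]


def promote_to_volume_mesh(
    nodes4: np.ndarray,
    elements4: np.ndarray,
    region: np.ndarray,
    node_sets_from: dict[str, callable] | None = None,
) -> VolumeMesh:
    """Compact a TET4 mesh, promote to TET10 and build coordinate node sets.

    ``node_sets_from`` maps set names to vectorized coordinate predicates
    evaluated on the final TET10 node array.
    """
    nodes4, elements4 = compact_mesh(nodes4, elements4)
    nodes, elements = linear_to_quadratic(nodes4, elements4)
    node_sets = {}
    if node_sets_from:
        for name, predicate in node_sets_from.items():
            node_sets[name] = np.flatnonzero(predicate(nodes))
    return VolumeMesh(nodes=nodes, elements=elements, region=np.asarray(region),
                      node_sets=node_sets)
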