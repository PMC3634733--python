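import dataclasses

import numpy as np
import pytest

import toothfea as tf


@pytest.fixture(scope="session")
def coarse_params() -> tf.ToothParams:
    """A coarse but complete synthetic premolar for fast pipeline tests."""
    return dataclasses.replace(tf.ToothParams(), mesh_size=1.6)


@pytest.fixture(scope="session")
def coarse_tooth(coarse_params):
    """(volume mesh, antagonist surface) of the coarse unworn premolar."""
    return tf.generate_tooth(coarse_params)


@pytest.fixture(scope="session")
def dentine_materials():
    return {tf.Region.DENTINE: tf.Material(18.6, 0.31)}


@pytest.fixture(scope="session")
def bar_mesh():
    """10 x 10 x 40 mm dentine bar, the axial-load verification solid."""
    return tf.generate_validation_solid("bar", (10.0, 10.0, 40.0), 4.0)


def face_loads(mesh, axis, value, traction):
    """Uniform traction on the boundary faces lying at coordinate `value`."""
    faces, _ = mesh.boundary_faces()
    a, b, c = (mesh.nodes[faces[:, i]] for i in range(3))
    cent = (a + b + c) / 3.0
    sel = np.abs(cent[:, axis] - value) < 1e-9
    f = np.zeros((mesh.n_nodes, 3))
    for fc in faces[sel]:
        f[fc] += tf.consistent_face_loads(mesh.nodes[fc], np.asarray(traction, float))
    return f


def axial_bar_constraints(mesh, length_axis=2):
    """Roller support on the far face plus minimal rigid-body fixes.

    Leaves the bar free to contract laterally so the closed-form uniaxial
    solution F L / (E A) holds exactly.
    """
    zmin = mesh.node_sets["ZMIN"]
    pts = mesh.nodes[zmin]
    corner = int(zmin[np.argmin(pts[:, 0] + pts[:, 1])])
    other = int(zmin[np.argmin(np.abs(pts[:, 1]) + np.abs(pts[:, 0] - pts[:, 0].max()))])
    fixed = {int(n): frozenset("z") for n in zmin}
    fixed[corner] = frozenset("xyz")
    fixed[other] = frozenset("yz")
    return tf.ConstraintSet(fixed)
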