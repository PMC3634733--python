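"""Load construction: consistent face loads and resultant normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import toothfea as tf
from toothfea.contact import ContactPatch, ContactResult
from toothfea.loads import build_load_case, consistent_face_loads, normalize_patch_forces


def quadratic_face(corners):
    corners = np.asarray(corners, dtype=float)
    mids = np.array([
        0.5 * (corners[0] + corners[1]),
        0.5 * (corners[1] + corners[2]),
        0.5 * (corners[2] + corners[0]),
    ])
    return np.concatenate([corners, mids])


class TestConsistentFaceLoads:
    def test_uniform_pressure_loads_only_midside_nodes(self):
        """Closed form for a straight quadratic triangle: corners get zero,
        each midside node gets p*A/3."""
        face = quadratic_face([[0, 0, 0], [2, 0, 0], [0, 2, 0]])
        area = 2.0
        p = 3.5
        forces = consistent_face_loads(face, [0.0, 0.0, p])
        np.testing.assert_allclose(forces[:3], 0.0, atol=1e-14)
        np.testing.assert_allclose(forces[3:, 2], p * area / 3.0, rtol=1e-12)
        np.testing.assert_allclose(forces.sum(axis=0), [0.0, 0.0, p * area], rtol=1e-12)

    def test_zero_traction_gives_zeros(self):
        face = quadratic_face([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        assert np.all(consistent_face_loads(face, [0.0, 0.0, 0.0]) == 0.0)

    def test_linearity_in_traction(self):
        face = quadratic_face([[0.2, 0.1, 0], [1.3, 0, 0.2], [0, 1.1, -0.1]])
        t = np.array([0.5, -1.0, 2.0])
        f1 = consistent_face_loads(face, t)
        f2 = consistent_face_loads(face, 2.0 * t)
        np.testing.assert_allclose(f2, 2.0 * f1, rtol=1e-12)

    def test_nonfinite_traction_rejected(self):
        face = quadratic_face([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        with pytest.raises(tf.ValidationError):
            consistent_face_loads(face, [np.nan, 0.0, 0.0])


class TestNormalization:
    def test_two_equal_patches_along_x_and_y(self):
        """Closed form: equal areas with normals -x and -y give each patch
        |F| = total/sqrt(2) and a resultant of magnitude `total`."""
        forces, _ = normalize_patch_forces(
            np.array([2.0, 2.0]),
            np.array([[-1.0, 0.0, 0.0], [0.0, -1.0, 0.0]]),
            100.0,
        )
        np.testing.assert_allclose(
            np.linalg.norm(forces, axis=1), 100.0 / np.sqrt(2.0), rtol=1e-12
        )
        assert np.linalg.norm(forces.sum(axis=0)) == pytest.approx(100.0, rel=1e-12)

    def test_single_patch_down_gives_axial_resultant(self):
        forces, _ = normalize_patch_forces(
            np.array([3.0]), np.array([[0.0, 1.0, 0.0]]), 100.0
        )
        np.testing.assert_allclose(forces[0], [0.0, -100.0, 0.0], atol=1e-12)

    def test_empty_patches_rejected(self):
        with pytest.raises(tf.LoadError, match="no occlusal contacts"):
            normalize_patch_forces(np.array([]), np.empty((0, 3)), 100.0)

    def test_cancelling_normals_rejected(self):
        with pytest.raises(tf.LoadError, match="indeterminate"):
            normalize_patch_forces(
                np.array([1.0, 1.0]),
                np.array([[0.0, 1.0, 0.0], [0.0, -1.0, 0.0]]),
                100.0,
            )

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.data())
    def test_area_proportionality_and_resultant_conservation(self, data):
        """Patch force magnitudes stay proportional to areas and the
        resultant magnitude equals the prescribed total."""
        n = data.draw(st.integers(1, 6))
        areas = np.array(
            data.draw(st.lists(st.floats(0.1, 50.0), min_size=n, max_size=n))
        )
        raw = np.array(
            data.draw(
                st.lists(
                    st.tuples(
                        st.floats(-1.0, 1.0), st.floats(0.1, 1.0), st.floats(-1.0, 1.0)
                    ),
                    min_size=n, max_size=n,
                )
            )
        )
        normals = raw / np.linalg.norm(raw, axis=1, keepdims=True)
        forces, scale = normalize_patch_forces(areas, normals, 100.0)
        mags = np.linalg.norm(forces, axis=1)
        np.testing.assert_allclose(mags / areas, scale, rtol=1e-9)
        assert np.linalg.norm(forces.sum(axis=0)) == pytest.approx(100.0, rel=1e-9)


@pytest.fixture(scope="module")
def unworn_state(coarse_params, coarse_tooth):
    mesh, upper = coarse_tooth
    lower = tf.crown_surface(coarse_params)
    contacts, _ = tf.contact_at_intercuspation(lower, upper)
    return mesh, contacts


def subdivide(surface):
    """Uniform 1-to-4 triangle subdivision (geometry unchanged)."""
    import toothfea.meshes as M

    v = surface.vertices
    tris = surface.triangles
    edges = np.sort(
        np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [0, 2]]]), axis=1
    )
    uniq, inv = np.unique(edges, axis=0, return_inverse=True)
    mids = 0.5 * (v[uniq[:, 0]] + v[uniq[:, 1]])
    mid_ids = len(v) + inv.reshape(3, -1)
    m01, m12, m02 = mid_ids
    new = np.concatenate([
        np.stack([tris[:, 0], m01, m02], axis=1),
        np.stack([m01, tris[:, 1], m12], axis=1),
        np.stack([m02, m12, tris[:, 2]], axis=1),
        np.stack([m01, m12, m02], axis=1),
    ])
    return M.SurfaceMesh(vertices=np.concatenate([v, mids]), triangles=new)


def test_resultant_invariant_under_surface_refinement():
    """Subdividing the contact surface leaves the normalized resultant
    vector unchanged (area-proportional normalization is discretization
    independent when the contact region is resolution-stable)."""
    from test_contact import square_mesh
    from toothfea.contact import detect_contact_patches

    lower = square_mesh(n=4, y=0.0)
    upper = square_mesh(n=4, y=0.0, flip=True)
    resultants = []
    for low in (lower, subdivide(lower)):
        result = detect_contact_patches(low, upper, epsilon=0.05)
        forces, _ = normalize_patch_forces(
            np.array([p.area for p in result.patches]),
            np.array([p.normal for p in result.patches]),
            100.0,
        )
        resultants.append(forces.sum(axis=0))
    assert np.linalg.norm(resultants[1] - resultants[0]) < 1e-6 * 100.0


class TestBuildLoadCase:
    def test_synthetic_tooth_has_multiple_patches(self, unworn_state):
        _, contacts = unworn_state
        assert contacts.n_patches >= 2

    def test_resultant_magnitude_is_total(self, unworn_state, coarse_params):
        mesh, contacts = unworn_state
        lc = build_load_case(mesh, contacts, 100.0, match_distance=coarse_params.mesh_size)
        assert np.linalg.norm(lc.resultant) == pytest.approx(100.0, rel=1e-8)

    def test_patch_forces_proportional_to_areas(self, unworn_state, coarse_params):
        mesh, contacts = unworn_state
        lc = build_load_case(mesh, contacts, 100.0, match_distance=coarse_params.mesh_size)
        mags = np.linalg.norm(lc.patch_forces, axis=1)
        areas = np.array([p.area for p in contacts.patches])
        ratio = mags / areas
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)

    def test_forces_only_on_occlusal_nodes(self, unworn_state, coarse_params):
        mesh, contacts = unworn_state
        lc = build_load_case(mesh, contacts, 100.0, match_distance=coarse_params.mesh_size)
        loaded = np.flatnonzero(np.abs(lc.nodal_forces).sum(axis=1) > 0)
        assert np.isin(loaded, mesh.node_sets["OCCLUSAL_SURFACE"]).all()

    def test_empty_contacts_rejected(self, unworn_state):
        mesh, _ = unworn_state
        with pytest.raises(tf.LoadError, match="no occlusal contacts"):
            build_load_case(mesh, ContactResult(), 100.0)

    def test_scaled_load_case(self, unworn_state, coarse_params):
        mesh, contacts = unworn_state
        lc = build_load_case(mesh, contacts, 100.0, match_distance=coarse_params.mesh_size)
        lc2 = lc.scaled(2.0)
        np.testing.assert_allclose(lc2.nodal_forces, 2.0 * lc.nodal_forces)
        assert lc2.total_magnitude == 200.0
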