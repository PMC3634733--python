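"""Synthetic premolar generator: parameters, wear operator, mesh validity."""

import dataclasses

import numpy as np
import pytest

import toothfea as tf
from toothfea.geometry import occlusal_height, occlusal_height_unworn


class TestParams:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("crown_height", -1.0),
            ("wear_depth", -0.1),
            ("wear_depth", 8.0),  # >= crown_height
            ("buccal_cusp_slope", 0.0),
            ("buccal_cusp_slope", 89.0),
            ("enamel_thickness", 4.0),  # >= cervix_radius
            ("pulp_radius", 3.0),  # does not fit in dentine
            ("mesh_size", 0.0),
        ],
    )
    def test_invalid_parameters_name_the_field(self, field, value):
        with pytest.raises(tf.ValidationError):
            dataclasses.replace(tf.ToothParams(), **{field: value})

    def test_apply_wear_bounds(self):
        p = tf.ToothParams()
        assert tf.apply_wear(p, 1.0).wear_depth == 1.0
        with pytest.raises(tf.ValidationError):
            tf.apply_wear(p, p.crown_height)
        with pytest.raises(tf.ValidationError):
            tf.apply_wear(p, -0.5)


class TestWearStage:
    def test_no_wear_is_stage_one(self):
        assert tf.wear_stage(tf.ToothParams()) == tf.WearStage(1, False)

    def test_wear_past_enamel_cap_exposes_dentine(self):
        p = tf.ToothParams()
        deep = tf.apply_wear(p, p.enamel_cap_vertical + 0.1)
        assert tf.wear_stage(deep) == tf.WearStage(3, True)

    def test_intermediate_wear_is_stage_two(self):
        p = tf.ToothParams()
        mid = tf.apply_wear(p, 0.6 * p.enamel_cap_vertical)
        assert tf.wear_stage(mid) == tf.WearStage(2, False)

    def test_stage_monotone_in_depth(self):
        p = tf.ToothParams()
        stages = [tf.wear_stage(tf.apply_wear(p, d)).stage
                  for d in np.linspace(0.0, 2.8, 12)]
        assert stages == sorted(stages)

    def test_inconsistent_stage_rejected(self):
        with pytest.raises(tf.ValidationError):
            tf.WearStage(3, False)


class TestOcclusalSurface:
    def test_unworn_crown_height_equals_buccal_cusp_height(self):
        p = tf.ToothParams()
        cb = p.buccal_cusp_center
        assert occlusal_height_unworn(p, cb[0], cb[1]) == pytest.approx(
            p.buccal_cusp_height
        )
        surf = tf.crown_surface(p)
        assert surf.vertices[:, 1].max() == pytest.approx(
            p.buccal_cusp_height, abs=2.0 * 0.25
        )

    def test_truncation_caps_the_surface(self):
        p = tf.apply_wear(tf.ToothParams(), 1.5)
        g = np.linspace(-3.0, 3.0, 41)
        X, Z = np.meshgrid(g, g)
        h = occlusal_height(p, X, Z)
        assert h.max() <= p.truncation_height + 1e-12

    def test_wear_monotonically_lowers_the_surface(self):
        p = tf.ToothParams()
        g = np.linspace(-3.0, 3.0, 21)
        X, Z = np.meshgrid(g, g)
        prev = None
        for d in [0.0, 0.5, 1.0, 1.8, 2.6]:
            h = occlusal_height(tf.apply_wear(p, d), X, Z)
            if prev is not None:
                assert np.all(h <= prev + 1e-12)
            prev = h


class TestGenerateTooth:
    def test_all_five_regions_present_unworn(self, coarse_tooth):
        mesh, _ = coarse_tooth
        assert set(np.unique(mesh.region)) == {int(r) for r in tf.Region}

    def test_required_node_sets_populated(self, coarse_tooth):
        mesh, _ = coarse_tooth
        for name in ("MESIAL_CUT", "DISTAL_CUT", "OCCLUSAL_SURFACE", "BUCCAL_CERVIX"):
            assert len(mesh.node_sets[name]) > 0

    def test_buccal_cervix_nodes_on_buccal_half(self, coarse_tooth):
        mesh, _ = coarse_tooth
        assert np.all(mesh.nodes[mesh.node_sets["BUCCAL_CERVIX"], 0] > 0.0)

    def test_mesh_valid_and_jacobians_positive(self, coarse_tooth):
        mesh, _ = coarse_tooth
        mesh.validate()  # orphan nodes, midpoints, volumes
        assert mesh.jacobians_positive()

    def test_region_volumes_sum_to_total(self, coarse_tooth):
        mesh, _ = coarse_tooth
        total = mesh.element_volumes().sum()
        assert sum(mesh.region_volumes().values()) == pytest.approx(total, rel=1e-9)

    def test_determinism_same_params_same_mesh(self, coarse_params):
        m1, s1 = tf.generate_tooth(coarse_params)
        m2, s2 = tf.generate_tooth(coarse_params)
        assert np.array_equal(m1.nodes, m2.nodes)
        assert np.array_equal(m1.elements, m2.elements)
        assert np.array_equal(m1.region, m2.region)
        assert np.array_equal(s1.vertices, s2.vertices)

    def test_no_enamel_above_truncation_plane(self, coarse_params):
        deep = tf.apply_wear(coarse_params, 3.0)
        mesh, _ = tf.generate_tooth(deep)
        enamel = mesh.elements[mesh.region == int(tf.Region.ENAMEL)]
        centroids = mesh.nodes[enamel[:, :4]].mean(axis=1)
        assert centroids[:, 1].max() <= deep.truncation_height + 1e-9

    def test_enamel_volume_strictly_decreases_with_wear(self, coarse_params):
        """Recomputed per-region tetrahedron volume sums across a depth grid."""
        depths = [0.0, 0.8, 1.6, 2.4, 3.2]
        volumes = []
        for d in depths:
            mesh, _ = tf.generate_tooth(tf.apply_wear(coarse_params, d))
            volumes.append(mesh.region_volumes()[tf.Region.ENAMEL])
        assert all(a > b for a, b in zip(volumes, volumes[1:]))

    def test_subcervical_nodes_identical_across_wear_states(self, coarse_params):
        """The fixed voxel grid preserves exact cross-state homology."""
        m1, _ = tf.generate_tooth(coarse_params)
        m2, _ = tf.generate_tooth(tf.apply_wear(coarse_params, 2.0))
        low1 = {tuple(q) for q in np.round(m1.nodes[m1.nodes[:, 1] < 0.0], 9)}
        low2 = {tuple(q) for q in np.round(m2.nodes[m2.nodes[:, 1] < 0.0], 9)}
        assert low1 == low2


class TestAntagonist:
    def test_antagonist_sits_above_the_crown(self, coarse_params):
        lower = tf.crown_surface(coarse_params)
        upper = tf.antagonist_surface(coarse_params)
        assert upper.vertices[:, 1].min() >= lower.vertices[:, 1].max() * 0 + 0.0
        # no interpenetration anywhere in the occlusal projection
        from toothfea.geometry import antagonist_height, occlusal_height as oh

        g = np.linspace(-3.4, 3.4, 69)
        X, Z = np.meshgrid(g, g)
        gap = antagonist_height(coarse_params, X, Z) - oh(coarse_params, X, Z)
        assert gap[np.isfinite(gap)].min() >= -1e-9

    def test_downward_normals(self, coarse_params):
        upper = tf.antagonist_surface(coarse_params)
        assert upper.triangle_normals()[:, 1].mean() < 0.0
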