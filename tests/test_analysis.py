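"""Cervical sampling, wear comparison, zone report, prevalence."""

import numpy as np
import pytest

import toothfea as tf
from toothfea.analysis import (
    sample_cervical_nodes,
    surface_smoothed_sigma1,
    tooth_surface_nodes,
)
from toothfea.fem import StressField


def synthetic_stress(mesh, fn):
    """StressField whose sigma1 equals fn(node coords); tensor is diag(s1,0,0)."""
    vals = np.asarray(fn(mesh.nodes), dtype=float) * np.ones(mesh.n_nodes)
    sigma = np.zeros((mesh.n_nodes, 6))
    sigma[:, 0] = vals
    zeros = np.zeros_like(vals)
    principal = -np.sort(-np.column_stack([vals, zeros, zeros]), axis=1)
    return StressField(sigma=sigma, principal=principal,
                       node_region=np.zeros(mesh.n_nodes, dtype=int))


class TestCervicalSampling:
    def test_ten_distinct_strictly_ordered_nodes(self, coarse_tooth):
        mesh, _ = coarse_tooth
        sample = sample_cervical_nodes(mesh, 10)
        assert len(np.unique(sample.node_ids)) == 10
        assert np.all(np.diff(sample.arc_positions) > 0.0)
        assert np.all((sample.arc_positions > 0.0) & (sample.arc_positions < 1.0))

    def test_single_node_near_arc_midpoint(self, coarse_tooth):
        mesh, _ = coarse_tooth
        sample = sample_cervical_nodes(mesh, 1)
        assert sample.n == 1
        assert abs(sample.arc_positions[0] - 0.5) < 0.2

    def test_homology_across_wear_states(self, coarse_params):
        """Same parametric tooth, different wear: identical arc positions."""
        m1, _ = tf.generate_tooth(coarse_params)
        m2, _ = tf.generate_tooth(tf.apply_wear(coarse_params, 2.0))
        s1 = sample_cervical_nodes(m1, 10)
        s2 = sample_cervical_nodes(m2, 10)
        np.testing.assert_allclose(s1.arc_positions, s2.arc_positions, atol=1e-12)
        np.testing.assert_allclose(
            m1.nodes[s1.node_ids], m2.nodes[s2.node_ids], atol=1e-12
        )

    def test_requesting_more_nodes_than_available_errors(self, coarse_tooth):
        mesh, _ = coarse_tooth
        with pytest.raises(tf.ValidationError):
            sample_cervical_nodes(mesh, 10_000)


class TestCompareWearStates:
    def test_identical_inputs_give_zero_deltas(self, coarse_tooth):
        mesh, _ = coarse_tooth
        stress = synthetic_stress(mesh, lambda p: p[:, 0] + 2.0)
        s = sample_cervical_nodes(mesh, 10).with_stress(stress)
        cmp = tf.compare_wear_states(s, s)
        np.testing.assert_allclose(cmp.deltas, 0.0)
        assert cmp.mean_delta == 0.0

    def test_load_scaling_scales_deltas(self, coarse_tooth):
        mesh, _ = coarse_tooth
        stress1 = synthetic_stress(mesh, lambda p: p[:, 0] + 2.0)
        stress2 = synthetic_stress(mesh, lambda p: 2.0 * (p[:, 0] + 2.0))
        base = sample_cervical_nodes(mesh, 10)
        cmp1 = tf.compare_wear_states(base.with_stress(stress1),
                                      base.with_stress(synthetic_stress(mesh, lambda p: 0 * p[:, 0])))
        cmp2 = tf.compare_wear_states(base.with_stress(stress2),
                                      base.with_stress(synthetic_stress(mesh, lambda p: 0 * p[:, 0])))
        np.testing.assert_allclose(cmp2.deltas, 2.0 * cmp1.deltas, rtol=1e-12)

    def test_mismatched_positions_rejected(self, coarse_tooth):
        mesh, _ = coarse_tooth
        stress = synthetic_stress(mesh, lambda p: p[:, 0])
        a = sample_cervical_nodes(mesh, 10).with_stress(stress)
        import dataclasses

        b = dataclasses.replace(a, arc_positions=a.arc_positions + 0.05)
        with pytest.raises(tf.ValidationError, match="arc positions"):
            tf.compare_wear_states(a, b)

    def test_missing_stress_rejected(self, coarse_tooth):
        mesh, _ = coarse_tooth
        s = sample_cervical_nodes(mesh, 10)
        with pytest.raises(tf.ValidationError, match="sigma1"):
            tf.compare_wear_states(s, s)


class TestPatternReport:
    def test_zero_stress_gives_zero_statistics(self, coarse_tooth, coarse_params):
        mesh, _ = coarse_tooth
        stress = synthetic_stress(mesh, lambda p: 0.0 * p[:, 0])
        df = tf.pattern_report(stress, mesh, coarse_params)
        filled = df[df["n_nodes"] > 0]
        assert len(filled) == len(df)  # every zone has nodes
        assert np.allclose(filled["mean_sigma1_mpa"], 0.0)
        assert np.allclose(filled["mean_trace_mpa"], 0.0)

    def test_flag_marks_the_tensile_zone(self, coarse_tooth, coarse_params):
        mesh, _ = coarse_tooth
        # tension grows buccally (x+), so the buccal cervix band must win
        # among near-cervix nodes; restrict the field to the cervical band
        def fn(p):
            band = np.abs(p[:, 1]) < coarse_params.cervical_band
            return np.where(band & (p[:, 0] > 0), 10.0, 0.0)

        df = tf.pattern_report(synthetic_stress(mesh, fn), mesh, coarse_params)
        flagged = df.loc[df["highest_tension"], "zone"].tolist()
        assert flagged == ["buccal_cervix"]

    def test_statistics_permutation_invariant(self, coarse_tooth, coarse_params):
        mesh, _ = coarse_tooth
        stress = synthetic_stress(mesh, lambda p: p[:, 0] * p[:, 1])
        df1 = tf.pattern_report(stress, mesh, coarse_params)
        df2 = tf.pattern_report(stress, mesh, coarse_params)
        assert df1.equals(df2)


class TestSmoothing:
    def test_constant_field_unchanged(self, coarse_tooth):
        mesh, _ = coarse_tooth
        stress = synthetic_stress(mesh, lambda p: np.full(len(p), 3.0))
        sm = surface_smoothed_sigma1(stress, mesh, radius=2.0)
        ids = tooth_surface_nodes(mesh)
        np.testing.assert_allclose(sm[ids], 3.0)
        assert np.isnan(sm[np.setdiff1d(np.arange(mesh.n_nodes), ids)]).all()

    def test_single_spike_attenuated(self, coarse_tooth):
        mesh, _ = coarse_tooth
        ids = tooth_surface_nodes(mesh)
        spike = ids[len(ids) // 2]

        def fn(p):
            v = np.zeros(len(p))
            v[spike] = 100.0
            return v

        stress = synthetic_stress(mesh, fn)
        sm = surface_smoothed_sigma1(stress, mesh, radius=2.5)
        assert sm[spike] < 50.0  # averaged down by its neighborhood

    def test_invalid_radius_rejected(self, coarse_tooth):
        mesh, _ = coarse_tooth
        stress = synthetic_stress(mesh, lambda p: p[:, 0])
        with pytest.raises(tf.ValidationError):
            surface_smoothed_sigma1(stress, mesh, radius=0.0)


class TestPrevalence:
    def test_mehrgarh_ratio(self):
        """10 affected of 225 individuals -> 4.4% at one decimal."""
        assert tf.nccl_prevalence(10, 225) == 4.4

    def test_bounds_checked(self):
        with pytest.raises(tf.ValidationError):
            tf.nccl_prevalence(-1, 10)
        with pytest.raises(tf.ValidationError):
            tf.nccl_prevalence(11, 10)
        with pytest.raises(tf.ValidationError):
            tf.nccl_prevalence(1, 0)
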