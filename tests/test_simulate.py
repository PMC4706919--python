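"""Synthetic-cohort generator: correlation targets, planted effects, fixtures."""

import numpy as np
import pytest

from longconn.connectome import build_fc_stack, compute_fc, extract_node_timeseries
from longconn.edge_stats import stack_edge_values
from longconn.simulate import (
    SimulationConfig,
    block_labels,
    generate_category_map,
    generate_cohort,
    generate_volume_fixture,
    population_fc,
    resolve_effect_edges,
)


def _edge_positions(n, edges):
    """Canonical edge-vector positions of (small, large) node pairs."""
    ii, jj = np.tril_indices(n, k=-1)
    lut = {(int(b), int(a)): k for k, (a, b) in enumerate(zip(ii, jj))}
    return [lut[tuple(e)] for e in edges]


class TestCohortCorrelationStructure:
    def test_sample_fc_matches_population_within_block(self):
        """Within-block sample FC ~ within_block_corr, averaged over subjects."""
        cfg = SimulationConfig(
            n_nodes=24, n_controls=25, n_patients=25, n_blocks=3,
            effect_type="none", within_block_corr=0.6, between_block_corr=0.1,
            seed=7,
        )
        coh = generate_cohort(cfg)
        labels = np.array(coh.truth["block_labels"])
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(cfg.n_nodes, dtype=bool)
        fcs = np.stack([compute_fc(ts).values for ts in coh.timeseries])
        mean_fc = fcs.mean(axis=0)
        assert abs(mean_fc[same & off].mean() - 0.6) < 0.05
        assert abs(mean_fc[~same].mean() - 0.1) < 0.05

    def test_noiseless_within_block_correlation_is_exactly_one(self):
        cfg = SimulationConfig(
            n_nodes=12, n_controls=1, n_patients=1, n_blocks=2,
            effect_type="none", within_block_corr=1.0, between_block_corr=0.2,
            seed=3,
        )
        coh = generate_cohort(cfg)
        fc = compute_fc(coh.timeseries[0]).values
        labels = np.array(coh.truth["block_labels"])
        same = (labels[:, None] == labels[None, :]) & ~np.eye(12, dtype=bool)
        assert np.allclose(fc[same], 1.0)

    def test_determinism_bitwise(self):
        cfg = dict(n_nodes=20, n_controls=3, n_patients=3, n_blocks=2,
                   effect_type="group", effect_edges=6, effect_delta_z=0.2,
                   seed=42)
        a = generate_cohort(SimulationConfig(**cfg))
        b = generate_cohort(SimulationConfig(**cfg))
        for ta, tb in zip(a.timeseries, b.timeseries):
            assert np.array_equal(ta.data, tb.data)
        assert a.truth == b.truth

    def test_ar1_noise_has_unit_variance_and_lag1_corr(self):
        cfg = SimulationConfig(
            n_nodes=4, n_controls=30, n_patients=30, n_blocks=1,
            within_block_corr=0.0, between_block_corr=0.0,
            noise_model="ar1", ar1_phi=0.6, effect_type="none",
            n_timepoints=400, seed=9,
        )
        coh = generate_cohort(cfg)
        x = np.concatenate([ts.data for ts in coh.timeseries])
        lag1 = np.mean([np.corrcoef(r[:-1], r[1:])[0, 1] for r in x])
        assert abs(x.var() - 1.0) < 0.05
        assert abs(lag1 - 0.6) < 0.05


class TestPlantedEffect:
    def test_population_delta_exact_on_effect_edges(self):
        cfg = SimulationConfig(
            n_nodes=60, n_controls=4, n_patients=4, n_blocks=4,
            effect_type="group", effect_edges=10, effect_delta_z=0.2, seed=2,
        )
        r0, r1 = population_fc(cfg, False), population_fc(cfg, True)
        for i, j in resolve_effect_edges(cfg):
            dz = np.arctanh(r1[i, j]) - np.arctanh(r0[i, j])
            assert dz == pytest.approx(0.2, abs=1e-12)

    def test_population_contamination_zero_when_pattern_psd(self):
        """Moderate increments on a path leave every other edge untouched."""
        cfg = SimulationConfig(
            n_nodes=60, n_controls=4, n_patients=4, n_blocks=4,
            effect_type="group", effect_edges=10, effect_delta_z=0.2, seed=2,
        )
        r0, r1 = population_fc(cfg, False), population_fc(cfg, True)
        diff = r1 - r0
        for i, j in resolve_effect_edges(cfg):
            diff[i, j] = diff[j, i] = 0.0
        assert np.abs(diff).max() == 0.0

    def test_monte_carlo_group_delta_recovery(self):
        """Mean patient-minus-control Fisher z on effect edges ~ delta (0.5)."""
        cfg = SimulationConfig(
            n_nodes=40, n_controls=50, n_patients=50, n_blocks=4,
            within_block_corr=0.3, between_block_corr=0.05,
            effect_type="group", effect_edges=8, effect_delta_z=0.5, seed=7,
        )
        coh = generate_cohort(cfg)
        stack = build_fc_stack(coh.timeseries, coh.design)
        y, _, patient = stack_edge_values(stack, "z")
        m = y.mean(axis=1)
        ks = _edge_positions(cfg.n_nodes, coh.truth["effect_edges"])
        dz = m[patient].mean(0)[ks] - m[~patient].mean(0)[ks]
        assert abs(dz.mean() - 0.5) < 0.05

    def test_effect_restricted_to_affected_conditions(self):
        """Interaction effect raises only the patient subacute session."""
        cfg = SimulationConfig(
            n_nodes=30, n_controls=40, n_patients=40, n_blocks=3,
            within_block_corr=0.3, between_block_corr=0.05,
            effect_type="interaction", effect_edges=6, effect_delta_z=0.5,
            seed=13,
        )
        coh = generate_cohort(cfg)
        stack = build_fc_stack(coh.timeseries, coh.design)
        y, _, patient = stack_edge_values(stack, "z")
        ks = _edge_positions(cfg.n_nodes, coh.truth["effect_edges"])
        pat_sub = y[patient, 1][:, ks].mean()
        pat_ac = y[patient, 0][:, ks].mean()
        ctl_sub = y[~patient, 1][:, ks].mean()
        assert pat_sub - pat_ac == pytest.approx(0.5, abs=0.07)
        assert abs(ctl_sub - pat_ac) < 0.07

    def test_infeasible_increment_names_offending_edge(self):
        """A cross-block increment beyond the residual headroom is rejected."""
        with pytest.raises(ValueError, match=r"effect edge \(0, 9\)"):
            generate_cohort(
                SimulationConfig(
                    n_nodes=10, n_controls=2, n_patients=2, n_blocks=2,
                    within_block_corr=0.6, between_block_corr=0.1,
                    effect_type="group", effect_edges=[(0, 9)],
                    effect_delta_z=2.0, seed=0,
                )
            )

    def test_disconnected_explicit_effect_edges_rejected(self):
        with pytest.raises(ValueError, match="connected"):
            generate_cohort(
                SimulationConfig(
                    n_nodes=10, n_controls=2, n_patients=2,
                    effect_type="group", effect_edges=[(0, 1), (3, 4)],
                    n_blocks=1, within_block_corr=0.2, between_block_corr=0.2,
                    seed=0,
                )
            )

    def test_effect_edges_form_single_connected_component(self):
        cfg = SimulationConfig(
            n_nodes=50, n_controls=2, n_patients=2, n_blocks=4,
            effect_type="group", effect_edges=12, effect_delta_z=0.2, seed=5,
        )
        coh = generate_cohort(cfg)
        edges = [tuple(e) for e in coh.truth["effect_edges"]]
        nodes = {n for e in edges for n in e}
        assert len(edges) == 12
        # a path over 13 nodes
        assert len(nodes) == 13


class TestVolumeFixture:
    def test_round_trip_extraction_recovers_series(self):
        cfg = SimulationConfig(
            n_nodes=10, n_controls=1, n_patients=1, n_blocks=2,
            effect_type="none", seed=0,
        )
        ts = generate_cohort(cfg).timeseries[0]
        fx = generate_volume_fixture(cfg, ts)
        ext = extract_node_timeseries(
            fx.bold, fx.landmarks, fx.gm_mask, 5.0, node_ids=fx.node_ids
        )
        assert np.allclose(ext.data, ts.data, atol=1e-12)

    def test_grid_too_small_raises_sizing_error(self):
        cfg = SimulationConfig(
            n_nodes=10, n_controls=1, n_patients=1, n_blocks=2,
            effect_type="none", seed=0,
        )
        ts = generate_cohort(cfg).timeseries[0]
        with pytest.raises(ValueError, match="too small"):
            generate_volume_fixture(cfg, ts, grid_shape=(8, 8, 8))

    def test_landmark_outside_mask_errors_in_extraction(self):
        cfg = SimulationConfig(
            n_nodes=4, n_controls=1, n_patients=1, n_blocks=1,
            within_block_corr=0.2, between_block_corr=0.2,
            effect_type="none", seed=0,
        )
        ts = generate_cohort(cfg).timeseries[0]
        fx = generate_volume_fixture(cfg, ts)
        bad = fx.landmarks.copy()
        bad[0] += 500.0  # far outside the grid
        with pytest.raises(ValueError, match="n000"):
            extract_node_timeseries(
                fx.bold, bad, fx.gm_mask, 5.0, node_ids=fx.node_ids
            )

    def test_all_neighborhoods_nonempty_at_full_node_count(self):
        """358 disjoint 5-mm neighborhoods fit on the auto-sized grid."""
        cfg = SimulationConfig(
            n_nodes=358, n_controls=1, n_patients=1, effect_type="none",
            n_timepoints=4, seed=0,
        )
        ts = generate_cohort(cfg).timeseries[0]
        fx = generate_volume_fixture(cfg, ts)
        ext = extract_node_timeseries(
            fx.bold, fx.landmarks, fx.gm_mask, 5.0, node_ids=fx.node_ids
        )
        assert ext.n_nodes == 358
        # separations >= 12 mm keep neighborhoods disjoint
        d = np.linalg.norm(
            fx.landmarks[:, None, :] - fx.landmarks[None, :, :], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 12.0


class TestCategoryMap:
    def test_full_map_uses_the_five_major_names(self):
        cm = generate_category_map(358, seed=1)
        f = cm.to_frame()
        assert len(f) == 358
        assert set(f["major"]) == {
            "Action", "Perception", "Cognition", "Interoception", "Emotion"
        }

    def test_single_node_map(self):
        cm = generate_category_map(1, seed=0)
        assert len(cm.major) == 1

    def test_seed_determinism(self):
        a = generate_category_map(50, seed=5).to_frame()
        b = generate_category_map(50, seed=5).to_frame()
        assert a.equals(b)

    def test_sublabels_nest_under_major(self):
        cm = generate_category_map(200, seed=2)
        for nid, sub in cm.sub.items():
            assert cm.parent[sub] == cm.major[nid]


def test_block_labels_partition_all_nodes_evenly():
    lab = block_labels(358, 8)
    assert len(lab) == 358
    sizes = np.bincount(lab)
    assert sizes.min() >= 44 and sizes.max() <= 45
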