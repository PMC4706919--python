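"""Mixed 2x2 ANOVA and simple-effect t-tests at the edge level."""

import numpy as np
import pandas as pd
import pytest

from longconn.edge_stats import (
    EdgeStatMap,
    edgewise_stats,
    mixed_anova_2x2,
    simple_effect_tests,
    stack_edge_values,
)


def _pooled_t(a, b):
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


class TestMixedAnovaIdentities:
    def test_f_equals_squared_t_on_100_random_datasets(self):
        """F_interaction == t^2 on within-subject differences and
        F_group == t^2 on subject session means, to 1e-10."""
        rng = np.random.default_rng(41)
        for _ in range(100):
            n0 = int(rng.integers(3, 15))
            n1 = int(rng.integers(3, 15))
            y = rng.standard_normal((n0 + n1, 2))
            patient = np.array([False] * n0 + [True] * n1)
            res = mixed_anova_2x2(y, patient)
            m = y.mean(axis=1)
            d = y[:, 1] - y[:, 0]
            t_m = _pooled_t(m[~patient], m[patient])
            t_d = _pooled_t(d[~patient], d[patient])
            assert abs(res["group"]["F"] - t_m**2) < 1e-10
            assert abs(res["interaction"]["F"] - t_d**2) < 1e-10

    def test_matches_pingouin_mixed_anova(self):
        """Independent oracle: classical mixed ANOVA from pingouin,
        unequal group sizes."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(17)
        for _ in range(5):
            n0, n1 = 7, 5
            y = rng.standard_normal((n0 + n1, 2))
            patient = np.array([False] * n0 + [True] * n1)
            res = mixed_anova_2x2(y, patient)
            df = pd.DataFrame(
                {
                    "y": y.ravel(),
                    "subj": np.repeat(np.arange(n0 + n1), 2),
                    "time": np.tile([0, 1], n0 + n1),
                    "group": np.repeat(patient.astype(int), 2),
                }
            )
            tab = pg.mixed_anova(
                data=df, dv="y", within="time", between="group", subject="subj"
            ).set_index("Source")
            assert res["group"]["F"] == pytest.approx(tab.loc["group", "F"], rel=1e-9)
            assert res["time"]["F"] == pytest.approx(tab.loc["time", "F"], rel=1e-9)
            assert res["interaction"]["F"] == pytest.approx(
                tab.loc["Interaction", "F"], rel=1e-9
            )

    def test_null_f_mean_matches_f_distribution(self):
        """Under the null, E[F] = df2 / (df2 - 2) (Monte-Carlo, 10%)."""
        rng = np.random.default_rng(5)
        n0, n1 = 12, 8
        y = rng.standard_normal((n0 + n1, 2, 4000))
        patient = np.array([False] * n0 + [True] * n1)
        res = mixed_anova_2x2(y, patient)
        df2 = n0 + n1 - 2
        expected = df2 / (df2 - 2)
        for eff in ("group", "time", "interaction"):
            assert res[eff]["F"].mean() == pytest.approx(expected, rel=0.10)

    def test_all_identical_values_guarded_to_zero_with_flag(self):
        y = np.full((6, 2), 3.7)
        patient = np.array([False] * 3 + [True] * 3)
        res = mixed_anova_2x2(y, patient)
        for eff in ("group", "time", "interaction"):
            assert res[eff]["F"] == 0.0
            assert bool(res[eff]["degenerate"]) is True

    def test_group_with_single_subject_rejected(self):
        y = np.zeros((3, 2))
        with pytest.raises(ValueError, match="2 subjects"):
            mixed_anova_2x2(y, np.array([True, False, False]))

    def test_missing_session_shape_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            mixed_anova_2x2(np.zeros((4, 3)), np.array([True, True, False, False]))


class TestEdgewiseStats:
    def test_edge_count_for_five_nodes(self, small_null_stack):
        sub = small_null_stack
        smap = edgewise_stats(sub, "group")
        assert smap.n_edges == sub.n_nodes * (sub.n_nodes - 1) // 2

    def test_planted_group_effect_raises_statistics_on_truth_edges(
        self, planted_cohort, planted_stack
    ):
        smap = edgewise_stats(planted_stack, "group", scale="z")
        n = planted_stack.n_nodes
        ii, jj = smap.edge_index()
        lut = {(int(b), int(a)): k for k, (a, b) in enumerate(zip(ii, jj))}
        ks = [lut[tuple(e)] for e in planted_cohort.truth["effect_edges"]]
        on = smap.stat[ks].mean()
        rest = np.delete(smap.stat, ks).mean()
        assert on > 10 * rest

    def test_identical_groups_give_zero_group_f(self, small_null_cohort):
        """Patient matrices byte-identical to controls -> F_group all 0."""
        from longconn.connectome import FCStack, compute_fc

        coh = small_null_cohort
        ctrl = [ts for ts in coh.timeseries if ts.subject_id.startswith("ctrl")][:8]
        mats, rows = [], []
        for k in range(4):
            for src, sid, grp in (
                (ctrl[2 * k], f"c{k}", "control"),
                (ctrl[2 * k], f"p{k}", "patient"),
            ):
                for sess_src, session in zip((src, ctrl[2 * k + 1]), ("acute", "subacute")):
                    fc = compute_fc(sess_src)
                    fc.subject_id, fc.session = sid, session
                    mats.append(fc)
                    rows.append(
                        {"subject_id": sid, "group": grp, "session": session}
                    )
        stack = FCStack(mats, pd.DataFrame(rows))
        smap = edgewise_stats(stack, "group")
        assert np.all(smap.stat == 0.0)

    def test_sign_convention_positive_for_planted_patient_increase(
        self, planted_cohort, planted_stack
    ):
        smap = edgewise_stats(planted_stack, "group")
        ii, jj = smap.edge_index()
        lut = {(int(b), int(a)): k for k, (a, b) in enumerate(zip(ii, jj))}
        for e in planted_cohort.truth["effect_edges"]:
            assert smap.sign[lut[tuple(e)]] > 0

    def test_r_and_z_scales_both_supported(self, small_null_stack):
        a = edgewise_stats(small_null_stack, "group", scale="z")
        b = edgewise_stats(small_null_stack, "group", scale="r")
        assert a.n_edges == b.n_edges
        assert not np.allclose(a.stat, b.stat)


class TestSimpleEffects:
    def test_hand_computed_pooled_t(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([4.0, 5.0, 6.0])
        t = _pooled_t(b, a)  # {1,2,3} relative to {4,5,6}
        assert t == pytest.approx(-3.674, abs=5e-4)

    def test_unpaired_group_t_matches_scipy(self, small_null_stack):
        from scipy import stats as sps

        smap = simple_effect_tests(small_null_stack, "group_t_unpaired", session="acute")
        y, _, patient = stack_edge_values(small_null_stack, "z")
        v = y[:, 0]
        ref = sps.ttest_ind(v[patient], v[~patient], axis=0).statistic
        assert np.allclose(smap.stat, ref, atol=1e-10)

    def test_paired_t_matches_scipy(self, small_null_stack):
        from scipy import stats as sps

        smap = simple_effect_tests(small_null_stack, "time_t_paired", group="control")
        y, _, patient = stack_edge_values(small_null_stack, "z")
        d = y[~patient]
        ref = sps.ttest_rel(d[:, 1], d[:, 0], axis=0).statistic
        assert np.allclose(smap.stat, ref, atol=1e-10)

    def test_identical_sessions_guarded_to_zero(self):
        y = np.zeros((5, 2, 3))
        y[:, 0] = y[:, 1] = np.arange(15).reshape(5, 3)
        # build via mixed_anova path: paired differences are exactly 0
        res = mixed_anova_2x2(y, np.array([False] * 3 + [True] * 2))
        assert np.all(res["time"]["F"] == 0.0)
        assert np.all(res["time"]["degenerate"])

    def test_constant_nonzero_differences_flagged(self, small_null_stack):
        """All-equal positive paired differences: infinite t guarded."""
        y = np.zeros((6, 2, 2))
        y[:, 1] = 1.0  # every difference exactly +1
        res = mixed_anova_2x2(y, np.array([False] * 3 + [True] * 3))
        assert np.all(res["time"]["degenerate"])
        assert np.all(res["time"]["F"] == 0.0)
        assert np.all(res["time"]["sign"] > 0)


class TestNullCalibration:
    def test_edgewise_pvalues_uniform_under_global_null(self):
        """KS test on F-derived p-values over thousands of null edges."""
        from scipy import stats as sps

        rng = np.random.default_rng(99)
        n0, n1 = 12, 8
        y = rng.standard_normal((n0 + n1, 2, 5000))
        patient = np.array([False] * n0 + [True] * n1)
        res = mixed_anova_2x2(y, patient)
        df2 = n0 + n1 - 2
        for eff in ("group", "interaction", "time"):
            p = sps.f.sf(res[eff]["F"], 1, df2)
            assert sps.kstest(p, "uniform").pvalue > 0.01

    def test_null_t_variance_close_to_t_distribution(self):
        """Empirical variance of edge-wise t within 10% of df/(df-2)."""
        rng = np.random.default_rng(123)
        n0, n1 = 12, 8
        y = rng.standard_normal((n0 + n1, 2, 5000))
        patient = np.array([False] * n0 + [True] * n1)
        res = mixed_anova_2x2(y, patient)
        t = res["group"]["sign"] * np.sqrt(res["group"]["F"])
        df2 = n0 + n1 - 2
        assert t.var() == pytest.approx(df2 / (df2 - 2), rel=0.10)


def test_stat_map_tsv_and_matrix_rendering(tmp_path, small_null_stack):
    smap = edgewise_stats(small_null_stack, "group")
    p = tmp_path / "stats.tsv"
    smap.write_tsv(p)
    df = pd.read_csv(p, sep="\t")
    assert len(df) == smap.n_edges
    mat = smap.to_matrix()
    assert mat.shape == (small_null_stack.n_nodes,) * 2
    assert np.allclose(mat, mat.T)
    assert np.all(np.diag(mat) == 0)
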