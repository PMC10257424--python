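import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

import mpmri as m
from mpmri.cohort import simulate_correlated_cohort, simulate_summary_cohort
from mpmri.stats import MRI_PARAMETERS


def brute_force_bky(pvals, alpha):
    """Independent literal transcription of the two-stage step-up procedure."""
    p = np.asarray(pvals, float)
    mtot = p.size
    order = np.argsort(p)
    ps = p[order]
    a1 = alpha / (1 + alpha)
    r1 = 0
    for k in range(mtot, 0, -1):
        if ps[k - 1] <= k * a1 / mtot:
            r1 = k
            break
    rejected = np.zeros(mtot, bool)
    if r1 == mtot:
        rejected[:] = True
    elif r1 > 0:
        m0 = mtot - r1
        r2 = 0
        for k in range(mtot, 0, -1):
            if ps[k - 1] <= k * a1 / m0:
                r2 = k
                break
        rejected[:r2] = True
    out = np.zeros(mtot, bool)
    out[order] = rejected
    return out


class TestScalars:
    def test_roi_median_conventions(self):
        grid = m.Grid(2, 2, 30.0)
        vals = np.array([[1.0, 2.0], [3.0, 4.0]])
        pmap = m.ParametricMap(vals, "ms", np.ones((2, 2), bool), grid)
        assert m.roi_median(pmap, np.ones((2, 2), bool)) == 2.5
        const = m.ParametricMap(np.full((2, 2), 7.0), "ms", np.ones((2, 2), bool), grid)
        assert m.roi_median(const, np.ones((2, 2), bool)) == 7.0
        with pytest.raises(ValueError, match="no valid voxels"):
            m.roi_median(pmap, np.zeros((2, 2), bool))

    def test_roi_median_excluding_hot_region_matches_direct_recomputation(self):
        grid = m.Grid(4, 4, 30.0)
        vals = np.full((4, 4), 10.0)
        vals[:2, :2] = 1000.0  # necrotic hot corner
        pmap = m.ParametricMap(vals, "ms", np.ones((4, 4), bool), grid)
        roi = np.ones((4, 4), bool)
        roi[:2, :2] = False
        assert m.roi_median(pmap, roi) == np.median(vals[roi])
        assert m.roi_median(pmap, roi) == 10.0

    def test_percent_change(self):
        assert m.percent_change(100.0, 120.0) == 20.0
        assert m.percent_change(100.0, 100.0) == 0.0
        assert round(m.percent_change(335.0, 449.0)) == 34
        with pytest.raises(ValueError):
            m.percent_change(0.0, 5.0)

    def test_water_content(self):
        assert m.water_content(1.0, 0.2) == 80.0
        assert m.water_content(1.0, 1.0) == 0.0
        assert m.water_content(1.0, 0.0) == 100.0
        with pytest.raises(ValueError):
            m.water_content(1.0, 1.2)


class TestCVws:
    def test_hand_computed_example(self):
        res = m.cv_ws([(9.0, 11.0), (11.0, 9.0)])
        assert res.cv_percent == pytest.approx(100 * np.sqrt(8 / 4) / 10)
        assert res.n_pairs == 2

    def test_identical_pairs_give_zero(self):
        assert m.cv_ws([(5.0, 5.0), (7.0, 7.0), (9.0, 9.0)]).cv_percent == 0.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        pairs=st.lists(
            st.tuples(st.floats(1.0, 100.0), st.floats(1.0, 100.0)),
            min_size=2,
            max_size=10,
        ),
        scale=st.floats(0.01, 50.0),
        seed=st.integers(0, 1000),
    )
    def test_invariance_under_reordering_and_scaling(self, pairs, scale, seed):
        arr = np.array(pairs)
        base = m.cv_ws(arr).cv_percent
        perm = np.random.default_rng(seed).permutation(len(arr))
        assert m.cv_ws(arr[perm]).cv_percent == pytest.approx(base)
        assert m.cv_ws(arr * scale).cv_percent == pytest.approx(base)

    def test_pair_mean_variant_differs_for_unequal_pairs(self):
        arr = [(10.0, 12.0), (100.0, 90.0)]
        a = m.cv_ws(arr, variant="grand_mean").cv_percent
        b = m.cv_ws(arr, variant="pair_mean").cv_percent
        assert a != pytest.approx(b)


class TestBKY:
    def test_spec_like_family_of_five(self):
        q = m.bky_qvalues(np.array([0.001, 0.001, 0.001, 0.001, 0.5]))
        assert np.all(q[:4] < 0.05)
        assert q[4] > 0.05

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000), msize=st.integers(2, 20))
    def test_qvalue_thresholding_equals_literal_decisions(self, seed, msize):
        rng = np.random.default_rng(seed)
        p = rng.random(msize) ** rng.uniform(0.5, 3.0)
        q = m.bky_qvalues(p)
        for alpha in (0.01, 0.05, 0.10, 0.25):
            np.testing.assert_array_equal(q <= alpha, brute_force_bky(p, alpha))

    def test_agrees_with_statsmodels_two_stage(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p = rng.random(rng.integers(3, 25))
            np.testing.assert_array_equal(
                m.bky_reject(p, 0.05),
                multipletests(p, alpha=0.05, method="fdr_tsbky")[0],
            )

    def test_qvalues_monotone_in_sorted_p(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = np.sort(rng.random(12))
            q = m.bky_qvalues(p)
            assert np.all(np.diff(q) >= -1e-12)


class TestPearson:
    def test_identity_vector(self):
        x = np.arange(10.0)
        res = m.pearson_with_p(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-12

    @pytest.mark.parametrize(
        "r,n,printed",
        [
            (0.44, 47, 0.002),
            (-0.44, 47, 0.002),
            (-0.46, 57, 0.0003),
        ],
    )
    def test_summary_entry_point_reproduces_printed_p(self, r, n, printed):
        p = m.pearson_p_from_summary(r, n)
        assert float(f"{p:.1g}") == printed

    @pytest.mark.parametrize("r,n", [(0.55, 55), (-0.74, 47)])
    def test_strong_correlations_below_reporting_floor(self, r, n):
        assert m.pearson_p_from_summary(r, n) < 1e-4

    def test_matches_permutation_oracle_on_short_vectors(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(10)
        y = 0.8 * x + 0.6 * rng.standard_normal(10)
        res = m.pearson_with_p(x, y)
        n_perm = 100_000
        perms = np.array([rng.permutation(y) for _ in range(n_perm)])
        r_null = (
            (perms - perms.mean(1, keepdims=True))
            @ ((x - x.mean()) / np.linalg.norm(x - x.mean()))
        )
        r_null /= np.linalg.norm(perms[0] - perms[0].mean())
        p_perm = (np.sum(np.abs(r_null) >= abs(res.r)) + 1) / (n_perm + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(res.p - p_perm) < max(4 * se, 0.002)

    def test_zero_variance_is_flagged(self):
        res = m.pearson_with_p(np.ones(5), np.arange(5.0))
        assert res.flagged and np.isnan(res.r)


class TestCorrelationMatrix:
    def _cohort(self, n=200, seed=0):
        cols = ["t2_ms", "mtr_pct", "adc", "percent_ha"]
        corr = np.array(
            [
                [1.0, -0.7, 0.5, 0.45],
                [-0.7, 1.0, -0.4, -0.45],
                [0.5, -0.4, 1.0, 0.55],
                [0.45, -0.45, 0.55, 1.0],
            ]
        )
        table = simulate_correlated_cohort(
            cols, corr, n=n, seed=seed,
            means={"t2_ms": 55, "mtr_pct": 35, "adc": 800, "percent_ha": 20},
            sds={"t2_ms": 5, "mtr_pct": 4, "adc": 80, "percent_ha": 8},
        )
        return cols, corr, table

    def test_known_covariance_round_trip(self):
        cols, corr, table = self._cohort()
        res = m.correlation_matrix(table, cols, stratum="all")
        for _, row in res.iterrows():
            i, j = cols.index(row["a"]), cols.index(row["b"])
            assert row["r"] == pytest.approx(corr[i, j], abs=3.5 / np.sqrt(200))

    def test_symmetry_and_unit_diagonal(self):
        cols, _, table = self._cohort(n=50, seed=3)
        res = m.correlation_matrix(table, cols).set_index(["a", "b"])
        for c in cols:
            assert res.loc[(c, c), "r"] == 1.0

    def test_perfectly_correlated_columns(self):
        table = pd.DataFrame(
            {
                "subject": ["s1"] * 2 + ["s2"] * 2 + ["s3"] * 2,
                "group": "A",
                "arm": "saline",
                "timepoint": ["pre", "post"] * 3,
                "x": [1, 1.0, 2, 2, 3, 3],
                "y": [2, 2.0, 4, 4, 6, 6],
            }
        )
        res = m.correlation_matrix(table, ["x", "y"]).set_index(["a", "b"])
        assert res.loc[("x", "y"), "r"] == pytest.approx(1.0)

    def test_low_ha_excluded_from_treated_stratum_only(self):
        cols, _, table = self._cohort(n=40, seed=5)
        table = table.copy()
        table["arm"] = "treated"
        table["percent_ha"] = np.random.default_rng(0).uniform(0.0, 1.5, len(table))
        res = m.correlation_matrix(table, cols, stratum="treated")
        assert "percent_ha" not in set(res["a"]) | set(res["b"])
        res_all = m.correlation_matrix(table, cols, stratum="all")
        assert "percent_ha" in set(res_all["a"])

    def test_absent_column_rejected(self):
        _, _, table = self._cohort(n=10, seed=1)
        with pytest.raises(ValueError, match="absent"):
            m.correlation_matrix(table, ["nope"])


class TestMultiTTest:
    def test_mirrored_null_gives_p_one(self):
        rows = []
        vals = [(-1.0, 1.0), (-2.0, 2.0), (-3.0, 3.0)]
        for arm in ("saline", "treated"):
            for i, (lo, hi) in enumerate(vals):
                sid = f"{arm}{i}"
                rows.append(dict(subject=sid, group="A", arm=arm, timepoint="pre", t1_ms=100.0))
                # identical mirrored percent changes in both arms
                delta = lo if arm == "saline" else lo
                rows.append(
                    dict(subject=sid, group="A", arm=arm, timepoint="post", t1_ms=100.0 + delta)
                )
        table = pd.DataFrame(rows)
        res = m.multi_ttest_fdr(table, parameters=("t1_ms",))
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_configured_effect_detected_with_correct_sign(self):
        table = simulate_summary_cohort(
            n_per_arm=8, seed=4, effects_pct={"adc": -25.0},
            within_sd={k: 0.03 for k in MRI_PARAMETERS},
        )
        res = m.multi_ttest_fdr(table).set_index("parameter")
        assert res.loc["adc", "q"] < 0.05
        assert res.loc["adc", "mean_change_treated"] < 0
        assert res.loc["volume_mm3", "q"] < 0.05  # growth differs by design

    def test_degenerate_variance_flagged_not_raised(self):
        table = simulate_summary_cohort(
            n_per_arm=3, seed=0, within_sd={k: 0.0 for k in MRI_PARAMETERS},
            between_sd=0.0, effects_pct={}, saline_growth_pct=10.0, treated_growth_pct=10.0,
        )
        res = m.multi_ttest_fdr(table, parameters=("t1_ms", "adc")).set_index("parameter")
        assert bool(res.loc["t1_ms", "degenerate"])
        assert np.isnan(res.loc["t1_ms", "p"])


class TestANOVA:
    def test_identical_groups_are_null(self):
        vals = np.tile(np.array([1.0, 2.0, 3.0, 4.0, 5.0]), 3)
        groups = np.repeat(["a", "b", "c"], 5)
        f_p, pairwise = m.anova_multi(vals, groups)
        assert f_p >= 0.99
        assert np.all(pairwise["p"] >= 0.99)

    def test_single_separated_group_detected(self):
        rng = np.random.default_rng(6)
        vals = np.concatenate(
            [rng.normal(0, 1, 6), rng.normal(0, 1, 6), rng.normal(10, 1, 6)]
        )
        groups = np.repeat(["a", "b", "c"], 6)
        f_p, pairwise = m.anova_multi(vals, groups)
        assert f_p < 1e-6
        pw = pairwise.set_index(["group_a", "group_b"])
        assert pw.loc[("a", "c"), "q"] < 0.05
        assert pw.loc[("b", "c"), "q"] < 0.05
        assert pw.loc[("a", "b"), "q"] > 0.05

    def test_permutation_calibration_of_anova_p(self):
        # under random label permutation the ANOVA p-value is uniform
        rng = np.random.default_rng(8)
        vals = rng.standard_normal(18)
        groups = np.repeat(["a", "b", "c"], 6)
        ps = []
        for _ in range(1000):
            ps.append(m.anova_multi(vals, rng.permutation(groups))[0])
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            m.anova_multi(np.arange(5.0), np.repeat(["a"], 5))
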