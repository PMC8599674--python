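"""Statistical battery: t-tests, BH-FDR, edge clusters, covariate models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from morphnet import (
    cluster_significant_edges,
    edgewise_group_test,
    fdr_bh,
    fisher_z_interval,
    gmv_pain_glm,
    nodewise_degree_test,
    pearson_correlation,
    roi_gmv_group_test,
    welch_or_student_ttest,
)
from morphnet.exceptions import ConfigError, ZeroVarianceError
from morphnet.stats import EdgeStatsResult


def bh_stepup_oracle(p: np.ndarray, q: float):
    """Direct transcription of the BH step-up definition."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    thresh = q * np.arange(1, m + 1) / m
    below = np.nonzero(ranked <= thresh)[0]
    reject = np.zeros(m, dtype=bool)
    if below.size:
        reject[order[: below[-1] + 1]] = True
    adj = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adj, 1.0)
    return adjusted, reject


class TestTTest:
    def test_identical_samples(self):
        t, p = welch_or_student_ttest([1, 2, 3], [1, 2, 3])
        assert t == 0.0
        assert p == 1.0

    def test_hand_computed_student(self):
        # mean diff -3, pooled sd 1, se = sqrt(2/3)
        t, p = welch_or_student_ttest([1, 2, 3], [4, 5, 6], variant="student")
        assert t == pytest.approx(-3 / np.sqrt(2 / 3), rel=1e-6)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
        t1, p1 = welch_or_student_ttest(x, y)
        t2, p2 = welch_or_student_ttest(x + 100, y + 100)
        assert t1 == pytest.approx(t2)
        assert p1 == pytest.approx(p2)

    def test_zero_pooled_variance(self):
        with pytest.raises(ZeroVarianceError):
            welch_or_student_ttest([1, 1, 1], [1, 1, 1])

    def test_welch_differs_under_unequal_variance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 0.1, 8), rng.normal(0, 3, 20)
        ts, _ = welch_or_student_ttest(x, y, "student")
        tw, _ = welch_or_student_ttest(x, y, "welch")
        assert ts != tw


class TestFdrBH:
    def test_stepup_hand_example(self):
        q, mask = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04, 0.05]), q=0.05)
        assert mask.all()  # p_(i) <= i*q/m for every i
        assert np.allclose(q, 0.05)

    def test_single_p(self):
        q, mask = fdr_bh(np.array([0.04]), q=0.05)
        assert q[0] == pytest.approx(0.04)
        assert mask[0]

    def test_all_ones(self):
        _, mask = fdr_bh(np.ones(10), q=0.05)
        assert not mask.any()

    def test_empty(self):
        q, mask = fdr_bh(np.array([]), q=0.05)
        assert q.size == 0 and mask.size == 0

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            m = rng.integers(1, 40)
            p = rng.uniform(0, 1, m) ** rng.uniform(0.5, 3)
            q_level = rng.choice([0.01, 0.05, 0.1])
            got_q, got_mask = fdr_bh(p, q_level)
            exp_q, exp_mask = bh_stepup_oracle(p, q_level)
            assert np.allclose(got_q, exp_q, atol=1e-12)
            assert np.array_equal(got_mask, exp_mask)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_adjusted_dominates_raw_and_agrees_with_oracle(self, p_list):
        p = np.array(p_list)
        qvals, mask = fdr_bh(p, 0.05)
        assert np.all(qvals >= p - 1e-12)
        exp_q, exp_mask = bh_stepup_oracle(p, 0.05)
        assert np.allclose(qvals, exp_q, atol=1e-12)
        assert np.array_equal(mask, exp_mask)


def _edge_result(roi_ids, sig_edges, t_by_edge, alpha=0.05):
    """Construct an EdgeStatsResult with a hand-chosen significance mask."""
    n = len(roi_ids)
    iu, ju = np.triu_indices(n, k=1)
    ids = np.asarray(roi_ids)
    t = np.zeros(len(iu))
    mask = np.zeros(len(iu), dtype=bool)
    for (a, b), tv in t_by_edge.items():
        e = np.nonzero((ids[iu] == min(a, b)) & (ids[ju] == max(a, b)))[0][0]
        t[e] = tv
        mask[e] = (min(a, b), max(a, b)) in sig_edges
    p = np.where(mask, 0.001, 0.8)
    return EdgeStatsResult(
        roi_ids=list(roi_ids), edge_i=iu, edge_j=ju, t=t, p=p, q=p, mask=mask,
        mean_a=np.zeros(len(iu)), mean_b=np.zeros(len(iu)), alpha=alpha,
    )


class TestEdgewiseAndClusters:
    def test_identical_stacks_give_zero_rejections(self):
        rng = np.random.default_rng(2)
        stack = rng.uniform(0.2, 0.9, (8, 5, 5))
        stack = (stack + stack.transpose(0, 2, 1)) / 2
        for k in range(8):
            np.fill_diagonal(stack[k], 1.0)
        res = edgewise_group_test(stack, stack, [1, 2, 3, 4, 5])
        assert not res.mask.any()
        assert np.allclose(res.t, 0.0)
        assert np.allclose(res.p, 1.0)

    def test_group_label_swap_negates_t(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.2, 0.9, (8, 4, 4))
        b = rng.uniform(0.2, 0.9, (9, 4, 4))
        for s in (a, b):
            s[:] = (s + s.transpose(0, 2, 1)) / 2
            for k in range(len(s)):
                np.fill_diagonal(s[k], 1.0)
        ids = [1, 2, 3, 4]
        r1 = edgewise_group_test(a, b, ids)
        r2 = edgewise_group_test(b, a, ids)
        assert np.allclose(r1.t, -r2.t)
        assert np.allclose(r1.p, r2.p)
        assert np.allclose(r1.q, r2.q)

    def test_single_chain_cluster_retained(self):
        edges = {(1, 2), (2, 3), (3, 4), (4, 5), (5, 6)}
        res = _edge_result(range(1, 8), edges, {e: 2.0 for e in edges})
        clusters = cluster_significant_edges(res, min_cluster_edges=4)
        assert len(clusters) == 1
        assert clusters[0].size == 5
        assert clusters[0].sign == 1

    def test_short_chains_dropped(self):
        edges = {(1, 2), (2, 3), (3, 4), (5, 6), (6, 7), (7, 8)}
        res = _edge_result(range(1, 9), edges, {e: 2.0 for e in edges})
        assert cluster_significant_edges(res, min_cluster_edges=4) == []

    def test_mixed_sign_chain_splits(self):
        edges = {(1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7), (7, 8), (8, 9),
                 (9, 10), (10, 11)}
        t_by_edge = {e: (2.0 if e[0] <= 5 else -2.0) for e in edges}
        res = _edge_result(range(1, 12), edges, t_by_edge)
        clusters = cluster_significant_edges(res, min_cluster_edges=4)
        # chain of 5 positive edges and chain of 5 negative edges
        assert sorted((c.sign, c.size) for c in clusters) == [(-1, 5), (1, 5)]


class TestNodewiseDegree:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(4)
        base = rng.integers(1, 10, (10, 6, 5)).astype(float)
        table, reported = nodewise_degree_test(
            base, base.copy(), np.linspace(0.05, 0.15, 6), [1, 2, 3, 4, 5])
        assert not table["significant"].any()
        assert reported == []

    def test_zero_variance_cell_is_neutral(self):
        a = np.ones((6, 2, 3))
        b = np.ones((6, 2, 3))
        a[:, :, 1] = np.arange(6)[:, None]
        b[:, :, 1] = np.arange(6)[:, None] + 0.1
        table, _ = nodewise_degree_test(a, b, [0.05, 0.07], [1, 2, 3])
        dead = table[table["roi_id"] != 2]
        assert np.all(dead["t"] == 0.0)
        assert np.all(dead["p"] == 1.0)


class TestGMVModels:
    @staticmethod
    def _tables(n=12, seed=0, tiv_const=False, gmv_from_tiv=False):
        rng = np.random.default_rng(seed)
        sids = [f"s{i}" for i in range(2 * n)]
        tiv = np.full(2 * n, 500.0) if tiv_const else rng.normal(500, 30, 2 * n)
        subj = pd.DataFrame({
            "subject_id": sids,
            "group": ["A"] * n + ["B"] * n,
            "tiv_mm3": tiv,
            "pain_score": rng.uniform(4, 9, 2 * n),
        })
        rows = []
        for i, sid in enumerate(sids):
            for roi in (1, 2):
                base = (0.1 * tiv[i] + rng.normal(0, 1e-6)) if gmv_from_tiv \
                    else rng.normal(100, 5)
                rows.append({"subject_id": sid, "roi_id": roi, "gmv_mm3": base})
        return pd.DataFrame(rows), subj

    def test_constant_tiv_reduces_to_plain_ttest(self):
        gmv, subj = self._tables(tiv_const=True, seed=1)
        with pytest.warns(UserWarning, match="constant"):
            res = roi_gmv_group_test(gmv, subj)
        for _, row in res.iterrows():
            sub = gmv[gmv["roi_id"] == row["roi_id"]].merge(subj, on="subject_id")
            x = sub.loc[sub["group"] == "A", "gmv_mm3"]
            y = sub.loc[sub["group"] == "B", "gmv_mm3"]
            t, p = welch_or_student_ttest(x, y, "student")
            assert row["t"] == pytest.approx(t, rel=1e-9)
            assert row["p"] == pytest.approx(p, rel=1e-9)

    def test_pure_covariate_effect_not_significant(self):
        gmv, subj = self._tables(gmv_from_tiv=True, seed=2)
        res = roi_gmv_group_test(gmv, subj)
        # the group coefficient sees only the tiny residual noise: a null t
        assert np.all(np.abs(res["t"]) < 3.5)
        assert not res["significant"].any()

    def test_tiv_shift_invariance(self):
        gmv, subj = self._tables(seed=3)
        r1 = roi_gmv_group_test(gmv, subj)
        subj2 = subj.assign(tiv_mm3=subj["tiv_mm3"] + 1000.0)
        r2 = roi_gmv_group_test(gmv, subj2)
        assert np.allclose(r1["t"], r2["t"])
        assert np.allclose(r1["p"], r2["p"])

    def test_pain_glm_permutation_destroys_signal(self):
        rng = np.random.default_rng(5)
        n = 20
        sids = [f"s{i}" for i in range(n)]
        pain = rng.uniform(3, 9, n)
        subj = pd.DataFrame({
            "subject_id": sids, "group": ["A"] * n,
            "tiv_mm3": rng.normal(500, 20, n), "pain_score": pain,
        })
        gmv = pd.DataFrame({
            "subject_id": sids, "roi_id": 1,
            "gmv_mm3": 50 + 10 * pain + rng.normal(0, 1, n),
        })
        res = gmv_pain_glm(gmv, subj)
        assert res.loc[0, "primary"]
        assert res.loc[0, "significant"]
        subj_perm = subj.assign(pain_score=rng.permutation(pain))
        res_perm = gmv_pain_glm(gmv, subj_perm)
        assert abs(res_perm.loc[0, "t"]) < abs(res.loc[0, "t"])
        assert not res_perm.loc[0, "primary"]


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 4.0, 7.0, 9.0])
        assert pearson_correlation(x, x)[0] == pytest.approx(1.0)
        assert pearson_correlation(-x + 3, x)[0] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroVarianceError):
            pearson_correlation(np.ones(5), np.arange(5.0))

    def test_too_short_rejected(self):
        with pytest.raises(ConfigError):
            pearson_correlation(np.arange(3.0), np.arange(3.0))

    def test_fisher_z_interval_covers_r(self):
        lo, hi = fisher_z_interval(0.67, 16)
        assert lo < 0.67 < hi
        assert hi - lo > 0.2  # n = 16 is a wide band
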