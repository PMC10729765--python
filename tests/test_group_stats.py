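"""Group statistics: Welch t against a direct formula evaluation, BH-FDR
against a definitional threshold scan, rank-sum against full enumeration,
and top-fraction edge selection arithmetic."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from wplinet.group_stats import (
    band_direction_summary,
    edge_index_pairs,
    edgewise_ttest,
    fdr_correct,
    metric_ranksum,
    metric_stats_table,
    top_fraction_edges,
    upper_triangle,
)


def welch_oracle(a, b):
    """Welch t and two-sided p from the textbook formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, p


def bh_oracle(p, q):
    """Definitional BH: reject the k smallest p where k is the largest rank
    with p_(k) <= k q / m, scanning every threshold."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, bool)
    reject[order[:k_star]] = True
    return reject


def ranksum_enumeration(a, b):
    """Exact two-sided Mann-Whitney p by enumerating every group labeling."""
    pooled = np.concatenate([a, b])
    n1, n = len(a), len(pooled)
    ranks = sps.rankdata(pooled)

    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    us = np.array([u_of(c) for c in itertools.combinations(range(n), n1)])
    p_le = (us <= u_obs).mean()
    p_ge = (us >= u_obs).mean()
    return min(1.0, 2 * min(p_le, p_ge))


class TestEdgewiseTtest:
    def test_identical_groups_give_null_result(self):
        v = np.array([[1.0], [2.0], [3.0]])
        out = edgewise_ttest(v, v.copy(), ["a", "b"])
        assert (out["t"] == 0).all()
        assert (out["p_raw"] == 1).all()
        assert not out["significant"].any()

    def test_matches_welch_formula(self):
        a = np.array([[0.1], [0.2], [0.3], [0.4]])
        b = np.array([[0.5], [0.6], [0.7], [0.8]])
        out = edgewise_ttest(a, b, ["x", "y"])
        t, p = welch_oracle(a[:, 0], b[:, 0])
        assert out.loc[0, "t"] == pytest.approx(t, abs=1e-12)
        assert out.loc[0, "p_raw"] == pytest.approx(p, abs=1e-12)
        assert out.loc[0, "direction"] == "decrease"

    def test_degenerate_edge_flagged(self):
        # 3 channels -> 3 edges; edge 0 constant and equal across groups
        a = np.column_stack([np.full(3, 0.5), [0.1, 0.2, 0.3], [0.2, 0.3, 0.1]])
        b = np.column_stack([np.full(3, 0.5), [0.6, 0.7, 0.8], [0.7, 0.8, 0.6]])
        out = edgewise_ttest(a, b, ["x", "y", "z"])
        assert out.loc[0, "degenerate"]
        assert out.loc[0, "t"] == 0 and out.loc[0, "p_raw"] == 1
        assert not out.loc[1, "degenerate"]

    def test_row_count_is_edge_count(self, rng):
        n_ch = 6
        n_edges = n_ch * (n_ch - 1) // 2
        a = rng.random((5, n_edges))
        b = rng.random((4, n_edges))
        out = edgewise_ttest(a, b, [f"c{i}" for i in range(n_ch)])
        assert len(out) == n_edges
        assert (out["p_adj"] >= out["p_raw"] - 1e-15).all()

    def test_null_raw_p_calibration(self, rng):
        """Under no group effect, raw p < 0.05 at roughly the nominal rate."""
        a = rng.standard_normal((10, 171))
        b = rng.standard_normal((10, 171))
        out = edgewise_ttest(a, b, [f"c{i}" for i in range(19)])
        frac = (out["p_raw"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * math.sqrt(0.05 * 0.95 / 171)

    def test_planted_increase_reported_as_increase(self, rng):
        a = rng.normal(0.5, 0.02, size=(8, 10))
        b = rng.normal(0.5, 0.02, size=(8, 10))
        a[:, 3] += 0.3
        out = edgewise_ttest(a, b, [f"c{i}" for i in range(5)])
        assert out.loc[3, "significant"]
        assert out.loc[3, "direction"] == "increase"


class TestFdr:
    def test_bh_hand_example(self):
        p_adj, reject = fdr_correct(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
        assert reject.all()
        np.testing.assert_allclose(p_adj, 0.04)

    def test_all_ones_rejects_none(self):
        _, reject = fdr_correct(np.ones(10), q=0.05)
        assert not reject.any()

    def test_matches_threshold_scan_oracle(self, rng):
        for _ in range(20):
            p = rng.random(50) ** 2
            _, reject = fdr_correct(p, q=0.05)
            np.testing.assert_array_equal(reject, bh_oracle(p, 0.05))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fdr_correct(np.array([]))
        with pytest.raises(ValueError):
            fdr_correct(np.array([1.5]))


class TestTopFraction:
    def _stats(self, n_edges, n_sig, rng):
        n_ch = 19
        pairs = edge_index_pairs(n_ch)
        assert len(pairs) == n_edges
        df = pd.DataFrame(
            {
                "node_i": [str(i) for i, _ in pairs],
                "node_j": [str(j) for _, j in pairs],
                "t": rng.standard_normal(n_edges),
                "p_adj": rng.uniform(0.06, 1.0, n_edges),
                "direction": "increase",
            }
        )
        df["significant"] = False
        df.loc[: n_sig - 1, "significant"] = n_sig > 0
        df.loc[: n_sig - 1, "p_adj"] = rng.uniform(0, 0.05, n_sig)
        return df

    def test_caps_at_ceiling_of_fraction(self, rng):
        out = top_fraction_edges(self._stats(171, 40, rng), fraction=0.10)
        assert len(out) == 18  # ceil(17.1)

    def test_keeps_all_when_fewer_significant(self, rng):
        out = top_fraction_edges(self._stats(171, 5, rng), fraction=0.10)
        assert len(out) == 5

    def test_empty_when_none_significant(self, rng):
        out = top_fraction_edges(self._stats(171, 0, rng), fraction=0.10)
        assert len(out) == 0

    def test_ranked_by_adjusted_p(self, rng):
        out = top_fraction_edges(self._stats(171, 40, rng), fraction=0.10)
        assert (np.diff(out["p_adj"]) >= 0).all()


class TestRankSum:
    def test_separated_triples(self):
        r = metric_ranksum([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0
        assert r.p == pytest.approx(0.1)  # 2/20 labelings as extreme
        assert r.method == "exact"

    def test_identical_groups_degenerate(self):
        r = metric_ranksum([2.0, 2.0], [2.0, 2.0])
        assert r.p == 1.0 and r.degenerate

    def test_exact_equals_enumeration_small_samples(self, rng):
        for n1 in range(1, 6):
            for n2 in range(n1, min(8, 10 - n1) + 1):
                a = rng.normal(size=n1)
                b = rng.normal(size=n2) + 0.5
                r = metric_ranksum(a, b)
                assert r.method == "exact"
                assert r.p == pytest.approx(ranksum_enumeration(a, b), abs=1e-12)

    def test_study_group_sizes_exact_close_to_asymptotic(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=5) + 2.0
        p_exact = sps.mannwhitneyu(a, b, method="exact").pvalue
        r = metric_ranksum(a, b)
        assert r.method == "asymptotic"
        assert abs(r.p - p_exact) < 0.01

    def test_requires_observations(self):
        with pytest.raises(ValueError):
            metric_ranksum([], [1.0])


class TestTablesAndSummary:
    def test_metric_stats_table_shape(self, rng):
        bands = ["delta", "theta", "alpha", "beta", "gamma"]
        rows_a, rows_b = [], []
        for band in bands:
            for s in range(6):
                rows_a.append({"band": band, "D": rng.random(), "CC": rng.random(),
                               "CPL": 1 + rng.random(), "GE": rng.random()})
            for s in range(4):
                rows_b.append({"band": band, "D": rng.random(), "CC": rng.random(),
                               "CPL": 1 + rng.random(), "GE": rng.random()})
        out = metric_stats_table(pd.DataFrame(rows_a), pd.DataFrame(rows_b), bands)
        assert len(out) == 20
        assert (out["p"] > 0).all() and (out["p"] <= 1).all()

    def test_band_direction_summary_verdicts(self):
        df = pd.DataFrame(
            {"significant": [True, True, False], "direction": ["increase"] * 3}
        )
        assert band_direction_summary(df)["verdict"] == "increase"
        df["significant"] = False
        assert band_direction_summary(df)["verdict"] == "ns"

    def test_upper_triangle_ordering(self):
        m = np.arange(16).reshape(4, 4)
        sym = np.triu(m, 1)
        got = upper_triangle(sym + sym.T)
        np.testing.assert_array_equal(got, [1, 2, 3, 6, 7, 11])
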