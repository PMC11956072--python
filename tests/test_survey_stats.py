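"""Descriptive summaries, rank-sum and cluster-adjusted chi-square tests.

The chi-square implementation is checked against an independently coded
direct-formula oracle (explicit-loop linearized covariance, Satterthwaite
correction) and the Mann-Whitney implementation against exhaustive
enumeration of value assignments.
"""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from dqqkit.survey import (
    cluster_adjusted_chi2,
    intra_cluster_correlation,
    mann_whitney_u,
    median_iqr,
    proportion_summary,
)

# ---------------------------------------------------------------------------
# Oracles (independent implementations used only by tests)
# ---------------------------------------------------------------------------


def oracle_rao_scott(outcome, group, cluster, weights=None):
    """Direct-formula Rao-Scott second-order F p-value, coded with loops."""
    outcome = list(outcome)
    group = list(group)
    cluster = list(cluster)
    n = len(outcome)
    w = [1.0] * n if weights is None else list(weights)
    out_levels = sorted(set(map(str, outcome)))
    grp_levels = sorted(set(map(str, group)))
    R, C = len(grp_levels), len(out_levels)
    clusters = []
    for c in cluster:
        if c not in clusters:
            clusters.append(c)
    K = len(clusters)

    W = sum(w)
    phat = [0.0] * (R * C)
    for i in range(n):
        cell = grp_levels.index(str(group[i])) * C + out_levels.index(str(outcome[i]))
        phat[cell] += w[i] / W
    pr = [sum(phat[r * C + c] for c in range(C)) for r in range(R)]
    pc = [sum(phat[r * C + c] for r in range(R)) for c in range(C)]
    X2 = 0.0
    for r in range(R):
        for c in range(C):
            e = pr[r] * pc[c]
            X2 += n * (phat[r * C + c] - e) ** 2 / e

    # cluster totals of w_i * (onehot_i - phat) / W
    Z = [[0.0] * (R * C) for _ in range(K)]
    for i in range(n):
        k = clusters.index(cluster[i])
        cell = grp_levels.index(str(group[i])) * C + out_levels.index(str(outcome[i]))
        for j in range(R * C):
            Z[k][j] += w[i] * ((1.0 if j == cell else 0.0) - phat[j]) / W
    V = [[0.0] * (R * C) for _ in range(R * C)]
    for k in range(K):
        for a in range(R * C):
            for b in range(R * C):
                V[a][b] += (K / (K - 1)) * Z[k][a] * Z[k][b]
    V0 = [
        [((phat[a] if a == b else 0.0) - phat[a] * phat[b]) / n for b in range(R * C)]
        for a in range(R * C)
    ]

    d = (R - 1) * (C - 1)
    H = []
    for r in range(R - 1):
        for c in range(C - 1):
            row = []
            for a in range(R):
                for b in range(C):
                    val = 0.0
                    if a == r and b == c:
                        val += 1.0
                    if a == r:
                        val -= pc[c]
                    if b == c:
                        val -= pr[r]
                    row.append(val)
            H.append(row)
    H = np.array(H)
    Vh = H @ np.array(V) @ H.T
    V0h = H @ np.array(V0) @ H.T
    eig = np.linalg.eigvals(np.linalg.solve(V0h, Vh)).real
    dbar = eig.mean()
    a2 = max(0.0, (eig**2).mean() / dbar**2 - 1.0)
    df1 = d / (1 + a2)
    df2 = df1 * (K - 1)
    F = X2 / (d * dbar)
    return X2, float(stats.f.sf(F, df1, df2))


def oracle_mw_exact_p(x, y):
    """Two-sided exact Mann-Whitney p by enumerating value assignments.

    U is computed directly from pairwise comparisons (ties count half),
    independently of the rank-based route in the implementation.
    """

    def u_of(xs, ys):
        return sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys)

    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    dev = abs(u_of(x, y) - mu)
    hits = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_of(xs, ys) - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------


class TestProportionSummary:
    def test_reported_proportion_with_frequency(self):
        flags = [True] * 300 + [False] * 179
        s = proportion_summary(flags)
        assert round(s.proportion_pct, 1) == 62.6
        assert s.frequency == 300 and s.n == 479

    def test_all_false(self):
        s = proportion_summary([False] * 10)
        assert s.proportion_pct == 0.0 and s.frequency == 0

    def test_weights_shift_percentage_not_frequency(self):
        flags = [True] * 50 + [False] * 50
        weighted = proportion_summary(flags, weights=[2.0] * 50 + [1.0] * 50)
        assert weighted.frequency == 50
        assert weighted.proportion_pct == pytest.approx(100 * 100 / 150)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            proportion_summary([])


class TestMedianIqr:
    @pytest.mark.parametrize(
        "values, expected",
        [
            (list(range(1, 10)), (5.0, 3.0, 7.0)),
            ([7.5], (7.5, 7.5, 7.5)),
            ([0, 0, 9, 9], (4.5, 0.0, 9.0)),  # linear-interpolation rule
        ],
    )
    def test_percentile_rule(self, values, expected):
        assert median_iqr(values) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        res = mann_whitney_u([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert res.p_value == pytest.approx(1.0)

    def test_constant_samples_warn_with_p_one(self):
        res = mann_whitney_u([3, 3, 3], [3, 3])
        assert res.p_value == 1.0
        assert any("identical" in w for w in res.warnings)

    def test_exact_small_sample(self):
        assert mann_whitney_u([1, 2], [3, 4]).p_value == pytest.approx(1 / 3)

    @pytest.mark.parametrize(
        "x, y",
        [
            ([1, 2, 2, 5], [2, 3, 3]),
            ([0, 0, 1, 1, 2], [1, 1, 1, 3]),
            ([1, 2, 3, 4, 5, 6, 7, 8], [2, 2, 4, 9, 9]),
            ([1.5, 1.5, 1.5], [1.5, 1.5, 2.0]),
        ],
    )
    def test_matches_enumeration_oracle_with_ties(self, x, y):
        res = mann_whitney_u(x, y)
        assert res.p_value == pytest.approx(oracle_mw_exact_p(x, y), abs=1e-9)

    def test_asymptotic_matches_scipy_without_continuity(self, rng):
        x = rng.integers(0, 10, 40)
        y = rng.integers(1, 11, 55)
        res = mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                                 use_continuity=False)
        assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)

    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=6),
        st.lists(st.integers(0, 5), min_size=2, max_size=6),
    )
    def test_invariant_under_strictly_monotone_transform(self, x, y):
        base = mann_whitney_u(x, y)
        transformed = mann_whitney_u([3.0 * v**3 + 2 for v in x], [3.0 * v**3 + 2 for v in y])
        assert transformed.p_value == pytest.approx(base.p_value, abs=1e-12)
        assert transformed.statistic == pytest.approx(base.statistic)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1, 2])


# ---------------------------------------------------------------------------
# Cluster-adjusted chi-square
# ---------------------------------------------------------------------------


def _two_group_instance(rng, n_clusters=6, per_cluster=5, weighted=False):
    cl = np.repeat(np.arange(n_clusters), per_cluster)
    n = cl.size
    grp = rng.random(n) < 0.5
    out = (rng.random(n) < 0.4 + 0.05 * (cl % 2)).astype(int)
    w = rng.uniform(0.5, 2.0, n) if weighted else None
    # ensure both levels of both variables appear
    grp[0], grp[1] = True, False
    out[0], out[1] = 0, 1
    return out, grp, cl, w


class TestClusterAdjustedChi2:
    def test_no_association_gives_near_zero_statistic(self):
        out = [0, 1] * 20
        grp = ["a"] * 20 + ["b"] * 20
        cl = list(range(40))
        res = cluster_adjusted_chi2(out, grp, cl)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value > 0.99

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_direct_formula_oracle(self, rng, weighted):
        """2x2 instances over 6 clusters match the loop-coded oracle to 6 dp."""
        for _ in range(5):
            out, grp, cl, w = _two_group_instance(rng, weighted=weighted)
            res = cluster_adjusted_chi2(out, grp, cl, weights=w)
            x2, p = oracle_rao_scott(out, grp, cl, weights=w)
            assert res.statistic == pytest.approx(x2, abs=1e-6)
            assert res.p_value == pytest.approx(p, abs=1e-6)

    def test_three_by_three_matches_oracle(self, rng):
        cl = np.repeat(np.arange(8), 6)
        out = rng.integers(0, 3, cl.size)
        grp = rng.integers(0, 3, cl.size)
        res = cluster_adjusted_chi2(out, grp, cl)
        x2, p = oracle_rao_scott(out, grp, cl)
        assert res.statistic == pytest.approx(x2, abs=1e-6)
        assert res.p_value == pytest.approx(p, abs=1e-6)
        assert res.design_df == 4

    def test_one_respondent_per_cluster_approximates_classical_pearson(self, rng):
        """Independent respondents: adjusted test = classical X2 scaled by (n-1)/n."""
        n = 300
        out = rng.integers(0, 2, n)
        grp = np.where(rng.random(n) < 0.5, "x", "y")
        res = cluster_adjusted_chi2(out, grp, np.arange(n))
        tab = pd.crosstab(pd.Series(grp), pd.Series(out)).to_numpy()
        classical = stats.chi2_contingency(tab, correction=False)
        assert res.statistic == pytest.approx(classical.statistic, abs=1e-8)
        # F(1, n-1) reference on X2*(n-1)/n vs chi2(1): close for moderate n
        assert res.p_value == pytest.approx(classical.pvalue, abs=0.01)

    def test_fewer_than_two_clusters_rejected(self):
        with pytest.raises(ValueError, match="cluster"):
            cluster_adjusted_chi2([0, 1, 0, 1], ["a", "a", "b", "b"], ["c1"] * 4)

    def test_single_level_outcome_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            cluster_adjusted_chi2([1, 1, 1, 1], ["a", "a", "b", "b"], ["c1", "c2", "c3", "c4"])

    def test_correction_field_recorded(self, rng):
        out, grp, cl, _ = _two_group_instance(rng)
        assert cluster_adjusted_chi2(out, grp, cl).correction == "rao_scott_second_order"
        first = cluster_adjusted_chi2(out, grp, cl, correction="first_order")
        assert first.correction == "rao_scott_first_order"


class TestIntraClusterCorrelation:
    def test_perfect_clustering_gives_one(self):
        cl = np.repeat(np.arange(4), 5)
        values = np.repeat([0.0, 1.0, 0.0, 1.0], 5)
        assert intra_cluster_correlation(values, cl) == pytest.approx(1.0)

    def test_independent_outcome_near_zero(self, rng):
        cl = np.repeat(np.arange(200), 10)
        values = rng.integers(0, 2, cl.size).astype(float)
        assert abs(intra_cluster_correlation(values, cl)) < 0.02

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            intra_cluster_correlation([0.0, 1.0], ["c1", "c1"])


class TestComparisonFormatting:
    def test_p_display_floors_below_a_thousandth(self):
        from dqqkit.survey import format_p

        assert format_p(0.0004) == "p < 0.001"
        assert format_p(0.0261) == "p = 0.026"
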