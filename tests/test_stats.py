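"""Inferential statistics against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as st

from hepflow.core import CHANNELS_32
from hepflow.stats import (
    AdjacencyGraph,
    bh_fdr,
    build_adjacency,
    cluster_perm_test,
    correlate_gate,
    mannwhitney_u,
    pointwise_perm_fdr,
    rm_anova_gg,
    standard_montage_positions,
    ttest_summary,
)


class TestAdjacency:
    def test_collinear_channels_form_chain(self):
        montage = {"A": [0.0, 0.0], "B": [1.0, 0.0], "C": [2.0, 0.0]}
        adj = build_adjacency(montage, method="distance")
        assert adj.neighbors["A"] == {"B"}
        assert adj.neighbors["B"] == {"A", "C"}
        assert adj.neighbors["C"] == {"B"}

    def test_standard_cap_fronto_central_neighbors(self):
        adj = build_adjacency(standard_montage_positions(CHANNELS_32))
        assert {"FC1", "FC2"} <= adj.neighbors["Fz"]

    def test_symmetry_and_irreflexivity(self):
        adj = build_adjacency(standard_montage_positions(CHANNELS_32))
        for a, ns in adj.neighbors.items():
            assert a not in ns
            for b in ns:
                assert a in adj.neighbors[b]

    def test_connected_for_standard_cap(self):
        adj = build_adjacency(standard_montage_positions(CHANNELS_32))
        seen, stack = {"Fz"}, ["Fz"]
        while stack:
            for n in adj.neighbors[stack.pop()]:
                if n not in seen:
                    seen.add(n)
                    stack.append(n)
        assert len(seen) == 32

    def test_asymmetric_graph_rejected(self):
        with pytest.raises(ValueError, match="asymmetric"):
            AdjacencyGraph(labels=["A", "B"],
                           neighbors={"A": {"B"}, "B": set()})

    def test_too_few_channels(self):
        with pytest.raises(ValueError):
            build_adjacency({"A": [0, 0], "B": [1, 0]})


CHAIN2 = [np.array([1]), np.array([0])]


def exhaustive_signflip_cluster_p(diffs, neighbors, alpha=0.05):
    """Oracle: exact Monte-Carlo p by enumerating all 2^n sign patterns.

    Independent implementation: per-pattern t maps via scipy, cluster
    masses via brute-force connected components over explicit edges.
    """
    n, C, T = diffs.shape
    thr = st.t.ppf(1 - alpha / 2, n - 1)

    def tmap(x):
        return st.ttest_1samp(x, 0.0, axis=0).statistic

    def masses(tm):
        bins = [(c, t) for c in range(C) for t in range(T)]
        out = []
        for sign in (1, -1):
            live = {b for b in bins if sign * tm[b] > thr}
            while live:
                comp = {live.pop()}
                grew = True
                while grew:
                    grew = False
                    for (c, t) in list(live):
                        for (c2, t2) in comp:
                            ok = (c == c2 and abs(t - t2) == 1) or (
                                t == t2 and c in neighbors[c2]
                            )
                            if ok:
                                comp.add((c, t))
                                live.discard((c, t))
                                grew = True
                                break
                out.append(sum(tm[b] for b in comp))
        return out

    obs = masses(tmap(diffs))
    null = []
    for signs in itertools.product([-1, 1], repeat=n):
        flipped = diffs * np.array(signs)[:, None, None]
        m = masses(tmap(flipped))
        null.append(max((abs(x) for x in m), default=0.0))
    null = np.array(null)
    return {
        round(m, 6): float((null >= abs(m)).mean()) for m in obs
    }


class TestClusterPermTest:
    def test_identical_inputs_no_clusters(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 2, 4))
        res = cluster_perm_test(x, x.copy(), CHAIN2, n_perm=100, seed=0)
        assert res.clusters == []
        assert res.null_distribution.shape == (100,)

    def test_monte_carlo_p_matches_exhaustive_enumeration(self):
        # 5 subjects, 2 channels x 3 bins: 2^5 = 32 sign patterns
        rng = np.random.default_rng(42)
        a = rng.normal(size=(5, 2, 3))
        a[:, 0, :2] += 1.8
        b = rng.normal(size=(5, 2, 3))
        res = cluster_perm_test(a, b, CHAIN2, n_perm=10000, seed=1)
        assert res.clusters, "expected at least one cluster"
        neighbors = {0: {1}, 1: {0}}
        oracle = exhaustive_signflip_cluster_p(a - b, neighbors)
        for cl in res.clusters:
            exact = oracle[round(cl.mass, 6)]
            assert cl.p == pytest.approx(max(exact, 1 / 10001),
                                         abs=2 / np.sqrt(10000))

    def test_p_lower_bound(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(8, 2, 3)) + 5.0
        b = rng.normal(size=(8, 2, 3))
        res = cluster_perm_test(a, b, CHAIN2, n_perm=200, seed=2)
        assert min(c.p for c in res.clusters) >= 1 / 201

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(8, 2, 5))
        b = rng.normal(size=(8, 2, 5)) - 0.8
        r1 = cluster_perm_test(a, b, CHAIN2, n_perm=500, seed=9)
        perm = rng.permutation(8)
        r2 = cluster_perm_test(a[perm], b[perm], CHAIN2, n_perm=500, seed=9)
        m1 = sorted(round(c.mass, 9) for c in r1.clusters)
        m2 = sorted(round(c.mass, 9) for c in r2.clusters)
        assert m1 == m2

    def test_matches_mne_implementation(self):
        # independent cross-check of observed clusters against MNE
        import mne
        from scipy import sparse

        rng = np.random.default_rng(1)
        n, C, T = 10, 3, 8
        x = rng.normal(size=(n, C, T))
        x[:, 1, 3:6] += 1.2
        chain3 = [np.array([1]), np.array([0, 2]), np.array([1])]
        res = cluster_perm_test(x, np.zeros_like(x), chain3, n_perm=2000,
                                seed=3)
        adjm = sparse.coo_matrix(
            ([1] * 4, ([0, 1, 1, 2], [1, 0, 2, 1])), shape=(C, C)
        )
        thr = st.t.ppf(0.975, n - 1)
        t_obs, clusters, pvals, _ = mne.stats.spatio_temporal_cluster_1samp_test(
            x.transpose(0, 2, 1), threshold=thr, adjacency=adjm,
            n_permutations=2000, seed=3, out_type="indices", tail=0,
            verbose="error",
        )
        mine = sorted(round(abs(c.mass), 6) for c in res.clusters)
        theirs = sorted(
            round(abs(t_obs[ti, ci].sum()), 6) for ti, ci in clusters
        )
        assert mine == theirs
        assert min(c.p for c in res.clusters) == pytest.approx(
            pvals.min(), abs=0.01
        )

    def test_independent_design(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(10, 2, 4)) + 2.0
        b = rng.normal(size=(12, 2, 4))
        res = cluster_perm_test(a, b, CHAIN2, n_perm=500, paired=False,
                                seed=4)
        assert res.clusters and res.clusters[0].p < 0.05

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="3"):
            cluster_perm_test(np.zeros((2, 2, 3)), np.zeros((2, 2, 3)),
                              CHAIN2)


class TestPointwisePermFdr:
    def test_identical_inputs_no_survivors(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 2, 4))
        p, mask = pointwise_perm_fdr(x, x.copy(), n_perm=200, seed=0)
        assert not mask.any()

    def test_single_bin_matches_exact_enumeration(self):
        # n = 6 paired samples in one bin: exact sign-flip test has 2^6
        # equally likely t values
        rng = np.random.default_rng(5)
        d = rng.normal(size=6) + 1.0
        a = d.reshape(6, 1, 1)
        b = np.zeros_like(a)
        t_obs = st.ttest_1samp(d, 0).statistic
        null = [
            abs(st.ttest_1samp(d * np.array(s), 0).statistic)
            for s in itertools.product([-1, 1], repeat=6)
        ]
        exact = np.mean(np.array(null) >= abs(t_obs))
        p, _ = pointwise_perm_fdr(a, b, n_perm=4000, seed=1)
        assert p[0, 0] == pytest.approx(max(exact, 1 / 4001), abs=0.02)

    def test_strong_block_survives(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(12, 2, 6))
        a[:, 0, :3] += 3.0
        b = rng.normal(size=(12, 2, 6))
        p, mask = pointwise_perm_fdr(a, b, n_perm=1000, seed=2)
        assert mask[0, :3].all()


class TestBhFdr:
    def brute_force(self, p, q):
        """Step-up procedure applied literally from its definition."""
        p = np.asarray(p)
        m = len(p)
        order = np.argsort(p)
        k_max = 0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= rank * q / m:
                k_max = rank
        mask = np.zeros(m, dtype=bool)
        mask[order[:k_max]] = True
        return mask

    def test_worked_example(self):
        # step-up by hand: thresholds k*q/m = .0125, .025, .0375, .05;
        # p_(3) = 0.04 > 0.0375, so exactly the first two survive
        p = [0.001, 0.009, 0.04, 0.9]
        _, mask = bh_fdr(p, q=0.05)
        assert mask.tolist() == [True, True, False, False]

    def test_all_survive_when_uniformly_small(self):
        _, mask = bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert mask.all()

    def test_single_p_unchanged(self):
        adj, mask = bh_fdr([0.03], q=0.05)
        assert adj[0] == pytest.approx(0.03)
        assert mask[0]

    def test_none_survive_at_p_one(self):
        _, mask = bh_fdr([1.0, 1.0, 1.0])
        assert not mask.any()

    def test_empty_input(self):
        adj, mask = bh_fdr([])
        assert adj.size == 0 and mask.size == 0

    def test_matches_bruteforce_definition_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            m = rng.integers(1, 12)
            p = rng.uniform(size=m) ** rng.uniform(0.3, 3)
            q = rng.choice([0.01, 0.05, 0.1])
            adj, mask = bh_fdr(p, q)
            np.testing.assert_array_equal(mask, self.brute_force(p, q))
            # adjusted p monotone in rank
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-12)


class TestCorrelateGate:
    def test_perfect_linear_gaussian_is_pearson(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        e = correlate_gate(x, 2 * x + 1)
        assert e.method == "pearson_r"
        assert e.coefficient == pytest.approx(1.0)

    def test_monotone_transform_forces_spearman(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        e = correlate_gate(x, np.exp(3 * x))
        assert e.method == "spearman_rho"
        assert e.coefficient == pytest.approx(1.0)
        assert e.shapiro_p_y < 0.05

    def test_null_calibration(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(20):
            x = rng.normal(size=1000)
            y = rng.normal(size=1000)
            e = correlate_gate(x, y)
            if abs(e.coefficient) < 0.08 and e.p > 0.01:
                hits += 1
        assert hits >= 19

    def test_missing_pairs_dropped(self):
        x = np.array([1.0, 2, 3, 4, 5, np.nan])
        y = np.array([2.0, 4, 6, 8, 10, 12])
        e = correlate_gate(x, y)
        assert e.n == 5 and e.n_dropped == 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate_gate(np.ones(10), np.arange(10.0))


def mixed_anova_oracle(data, groups):
    """Split-plot sums of squares coded directly from textbook formulas."""
    n, k = data.shape
    uniq = sorted(set(groups))
    g = len(uniq)
    gm = data.mean()
    ss_cells = 0.0
    ss_group = 0.0
    ss_inter = 0.0
    level_means = data.mean(axis=0)
    for gv in uniq:
        sel = np.array([x == gv for x in groups])
        nj = sel.sum()
        gmean = data[sel].mean()
        ss_group += k * nj * (gmean - gm) ** 2
        cell = data[sel].mean(axis=0)
        ss_inter += nj * ((cell - gmean - level_means + gm) ** 2).sum()
    subj_means = data.mean(axis=1)
    ss_subj = k * ((subj_means - gm) ** 2).sum() - ss_group
    ss_cond = n * ((level_means - gm) ** 2).sum()
    ss_err = ((data - subj_means[:, None]) ** 2).sum() - ss_cond - ss_inter
    ms = {
        "cond": ss_cond / (k - 1),
        "group": ss_group / (g - 1),
        "inter": ss_inter / ((g - 1) * (k - 1)),
        "subj": ss_subj / (n - g),
        "err": ss_err / ((n - g) * (k - 1)),
    }
    return {
        "condition": ms["cond"] / ms["err"],
        "group": ms["group"] / ms["subj"],
        "interaction": ms["inter"] / ms["err"],
    }


class TestRmAnovaGg:
    def test_two_levels_epsilon_is_one(self):
        rng = np.random.default_rng(0)
        res = rm_anova_gg(rng.normal(size=(10, 2)))
        assert res["condition"].epsilon == 1.0

    def test_epsilon_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            k = rng.integers(3, 6)
            data = rng.normal(size=(12, k)) * rng.uniform(0.5, 2, size=k)
            eps = rm_anova_gg(data)["condition"].epsilon
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(2)
        subj_eff = rng.normal(0, 1, 12)
        data = subj_eff[:, None] + np.array([0.0, 1.0, 2.0]) + \
            rng.normal(0, 0.8, (12, 3))
        groups = ["a"] * 6 + ["b"] * 6
        mine = rm_anova_gg(data, groups)
        oracle = mixed_anova_oracle(data, groups)
        for eff in ("condition", "group", "interaction"):
            assert mine[eff].F == pytest.approx(oracle[eff], abs=1e-6)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(3)
        n, k = 14, 4
        data = rng.normal(size=(n, k)) + np.linspace(0, 1.5, k)
        groups = np.array(["a", "b"] * 7)
        mine = rm_anova_gg(data, groups)
        df = pd.DataFrame({
            "subj": np.repeat(np.arange(n), k),
            "cond": list(range(k)) * n,
            "grp": np.repeat(groups, k),
            "y": data.ravel(),
        })
        ref = pg.mixed_anova(data=df, dv="y", within="cond",
                             subject="subj", between="grp").set_index("Source")
        assert mine["condition"].F == pytest.approx(
            ref.loc["cond", "F"], abs=1e-6)
        assert mine["group"].F == pytest.approx(ref.loc["grp", "F"], abs=1e-6)
        assert mine["interaction"].F == pytest.approx(
            ref.loc["Interaction", "F"], abs=1e-6)
        assert mine["condition"].eta_sq == pytest.approx(
            ref.loc["cond", "np2"], abs=1e-6)
        # single-group design: epsilon definitions coincide
        pure = rm_anova_gg(data)
        wide = df[df.grp == df.grp].pivot(index="subj", columns="cond",
                                          values="y")
        assert pure["condition"].epsilon == pytest.approx(
            pg.epsilon(wide, correction="gg"), abs=1e-9)

    def test_epsilon_one_reproduces_uncorrected_p(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(10, 3))
        res = rm_anova_gg(data)["condition"]
        p_unc = float(st.f.sf(res.F, 2, 18))
        assert res.p_uncorrected == pytest.approx(p_unc, rel=1e-12)

    def test_missing_cells_rejected(self):
        data = np.ones((5, 3))
        data[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_gg(data)


class TestTtestSummary:
    def test_identical_groups(self):
        r = ttest_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert r.t == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_agrees_with_raw_data_ttest(self):
        rng = np.random.default_rng(5)
        x = rng.normal(10, 2, 25)
        y = rng.normal(11, 2, 30)
        r = ttest_summary(x.mean(), x.std(ddof=1), 25,
                          y.mean(), y.std(ddof=1), 30)
        ref = st.ttest_ind(y, x, equal_var=True)
        assert r.t == pytest.approx(ref.statistic, rel=1e-12)
        assert r.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            ttest_summary(1.0, 0.0, 5, 2.0, 0.0, 5)


class TestMannWhitney:
    def test_complete_separation(self):
        u, _ = mannwhitney_u([1, 2, 3, 4], [5, 6, 7, 8])
        assert u == 0.0

    def test_identical_multisets(self):
        x = [1.0, 2.0, 3.0]
        u, _ = mannwhitney_u(x, list(x))
        assert u == pytest.approx(len(x) ** 2 / 2)

    def test_small_sample_matches_enumeration(self):
        # all C(8,4) = 70 assignments of the pooled sample to groups
        x = np.array([1.2, 3.4, 2.2, 5.0])
        y = np.array([2.8, 4.1, 6.0, 7.3])
        u_obs, p = mannwhitney_u(x, y)
        pooled = np.concatenate([x, y])
        ranks = st.rankdata(pooled)
        n = 4
        stats_null = []
        for idx in itertools.combinations(range(8), n):
            rx = ranks[list(idx)].sum()
            u = rx - n * (n + 1) / 2
            stats_null.append(min(u, n * n - u))
        u_min = min(u_obs, 16 - u_obs)
        exact = np.mean([s <= u_min for s in stats_null])
        assert p == pytest.approx(exact, abs=1e-9)
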