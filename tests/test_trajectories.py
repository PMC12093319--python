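"""Per-metabolite mixed models, BH, elbow rule, clustering, aged-phenotype
flags."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from metaboclock import (
    GroupMeanMatrix,
    SimulationConfig,
    choose_k_elbow,
    elbow_from_wss,
    fit_metabolite_lmms,
    flag_aged_phenotype,
    group_means,
    hierarchical_cluster,
    normalize,
    simulate_metabolome,
    term_overlap_counts,
)

from conftest import manual_table, meta_row


def brute_force_bh(p, q):
    """Step-up BH by direct definition: reject all p(i) <= i*q/m after the
    largest such i."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p)
    thresh = (np.arange(1, m + 1) * q) / m
    below = p[order] <= thresh
    k = np.max(np.nonzero(below)[0]) + 1 if below.any() else 0
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


class TestBenjaminiHochberg:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_multipletests_matches_brute_force_step_up(self, seed):
        # the BH routine the pipeline relies on, checked against the
        # definitional step-up procedure
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=int(rng.integers(3, 60)))
        q = float(rng.choice([0.01, 0.05, 0.1]))
        reject, qvals, *_ = multipletests(p, alpha=q, method="fdr_bh")
        np.testing.assert_array_equal(reject, brute_force_bh(p, q))
        np.testing.assert_array_equal(qvals < q, brute_force_bh(p, q) & (qvals < q))


@pytest.fixture(scope="module")
def lmm_input():
    table, truth = simulate_metabolome(SimulationConfig(seed=12, n_metabolites=40))
    return normalize(table).exclude([("A", 9)]), truth


class TestMetaboliteLMMs:
    def test_planted_regime_offset_is_recovered(self):
        rng = np.random.default_rng(7)
        meta = []
        i = 0
        for regime in ("A", "C"):
            for rep in range(4):
                for age in (21, 28, 35):
                    i += 1
                    meta.append(meta_row(i, regime=regime, age=age,
                                         replicate=f"{regime}{rep}"))
        x = rng.normal(0, 0.1, size=(len(meta), 8))
        regimes = np.array([m["regime"] for m in meta])
        x[regimes == "A", 0] += 2.0  # strong selection effect on one metabolite
        table = manual_table(x, meta, stage="normalized")
        res = fit_metabolite_lmms(table, fdr=0.01)
        assert res.significant("selection") == ["met_0001"]

    def test_q_values_monotone_in_p_and_flags_match_threshold(self, lmm_input):
        table, _ = lmm_input
        res = fit_metabolite_lmms(table)
        for term in ("selection", "age", "interaction"):
            sub = res.table.dropna(subset=[f"p_{term}"]).sort_values(f"p_{term}")
            assert (np.diff(sub[f"q_{term}"]) >= -1e-12).all()
            np.testing.assert_array_equal(
                res.table[f"sig_{term}"], (res.table[f"q_{term}"] < 0.01).fillna(False)
            )

    def test_zero_replicate_variance_matches_fixed_effects_fit(self):
        # all replicates identical in distribution -> boundary fit; LRT
        # p-values should agree with an OLS likelihood-ratio oracle
        import scipy.stats as stats
        import statsmodels.api as sm

        from metaboclock._lmm import dummy_columns, interaction_columns

        rng = np.random.default_rng(1)
        # replicates are exact copies of each other, so the between-replicate
        # variance is exactly zero and every ML fit sits on the boundary
        base = {(regime, age, d): rng.normal(size=3)
                for regime in ("A", "C") for age in (21, 35) for d in range(2)}
        meta, rows = [], []
        i = 0
        for regime in ("A", "C"):
            for rep in range(3):
                for age in (21, 35):
                    for d in range(2):
                        i += 1
                        meta.append(meta_row(i, regime=regime, age=age,
                                             replicate=f"{regime}{rep}"))
                        rows.append(base[(regime, age, d)])
        y = np.asarray(rows)
        table = manual_table(y, meta, stage="normalized")
        res = fit_metabolite_lmms(table, fdr=0.01)

        sel = dummy_columns(np.array([m["regime"] for m in meta]))
        age = dummy_columns(np.array([m["age_days"] for m in meta]))
        ones = np.ones((len(meta), 1))
        inter = interaction_columns(sel, age)

        def ols_llf(x, yv):
            return sm.OLS(yv, x).fit().llf

        for j, met in enumerate(table.values.columns):
            yv = y[:, j]
            full = ols_llf(np.hstack([ones, sel, age, inter]), yv)
            main = ols_llf(np.hstack([ones, sel, age]), yv)
            sel_only = ols_llf(np.hstack([ones, sel]), yv)
            p_age = stats.chi2.sf(2 * (main - sel_only), 1)
            assert res.table.loc[met, "re_var"] < 1e-6
            assert res.table.loc[met, "p_age"] == pytest.approx(p_age, abs=1e-3)

    def test_single_regime_rejected(self, lmm_input):
        table, _ = lmm_input
        only_a = table.subset(table.metadata["regime"] == "A")
        with pytest.raises(ValueError):
            fit_metabolite_lmms(only_a)


class TestOverlapCounts:
    def _results(self, flags):
        from metaboclock.trajectories import LMMResultTable

        tab = pd.DataFrame(flags, columns=["sig_selection", "sig_age", "sig_interaction"])
        tab.index = [f"m{i}" for i in range(len(tab))]
        for t in ("selection", "age", "interaction"):
            tab[f"p_{t}"] = 0.5
            tab[f"q_{t}"] = 0.5
        tab["converged"] = True
        return LMMResultTable(table=tab, fdr=0.01)

    def test_no_flags_all_zero(self):
        counts = term_overlap_counts(self._results([[False] * 3] * 5))
        assert counts["any"] == 0
        assert all(v == 0 for k, v in counts.items())

    def test_all_flagged_everything_in_triple_intersection(self):
        counts = term_overlap_counts(self._results([[True] * 3] * 4))
        assert counts["selection+age+interaction"] == 4
        assert counts["selection only"] == 0
        assert counts["any"] == 4

    def test_planted_memberships_counted_exactly(self):
        flags = [
            [True, False, False],
            [True, True, False],
            [True, True, False],
            [False, False, True],
            [False, False, False],
        ]
        counts = term_overlap_counts(self._results(flags))
        assert counts["selection"] == 3
        assert counts["selection only"] == 1
        assert counts["selection+age only"] == 2
        assert counts["interaction only"] == 1
        assert counts["any"] == 4


class TestGroupMeans:
    def test_study_design_yields_eight_columns_with_day9_retained(self, study_table):
        table, _ = study_table
        gm = group_means(normalize(table))
        assert list(gm.matrix.columns) == [
            ("A", 9), ("A", 21), ("A", 28), ("A", 35),
            ("C", 21), ("C", 28), ("C", 35), ("C", 70),
        ]
        assert gm.matrix.shape == (202, 8)

    def test_single_sample_groups_and_duplication_idempotence(self):
        rng = np.random.default_rng(0)
        meta = [meta_row(1, age=21), meta_row(2, age=28)]
        x = rng.normal(size=(2, 4))
        gm = group_means(manual_table(x, meta, stage="normalized"))
        np.testing.assert_allclose(gm.matrix[("A", 21)], x[0])
        doubled = group_means(
            manual_table(np.vstack([x, x]), meta + [meta_row(3, age=21),
                                                    meta_row(4, age=28)],
                         stage="normalized")
        )
        np.testing.assert_allclose(doubled.matrix.to_numpy(), gm.matrix.to_numpy())


class TestElbow:
    def test_analytic_kink_recovered(self):
        # piecewise-linear WSS with slope change only at K = 7
        k = np.arange(1, 21)
        wss = np.where(k <= 7, 100.0 - 12.0 * (k - 1), 100.0 - 12.0 * 6 - 0.5 * (k - 7))
        assert elbow_from_wss(wss) == 7

    def test_tie_breaks_toward_smaller_k(self):
        wss = [10.0, 6.0, 4.0, 3.0, 2.5, 2.0]  # d2 equal at K=2 and ... pick 2
        assert elbow_from_wss(wss) == 2

    def test_planted_four_blobs_recovered(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            # equidistant (simplex) centroids: the WSS kink sits at the true K
            centers = 10.0 * np.eye(4, 6)
            rows = np.vstack([c + rng.normal(0, 0.3, size=(12, 6)) for c in centers])
            m = GroupMeanMatrix(pd.DataFrame(rows, index=[f"m{i}" for i in range(48)]))
            k, wss = choose_k_elbow(m, k_max=12, n_init=5, seed=seed)
            w = wss.to_numpy()
            assert (np.diff(w) <= 0.01 * w[:-1] + 1e-9).all()  # restart tolerance
            hits += k == 4
        assert hits >= 9

    def test_k_max_bounds(self):
        m = GroupMeanMatrix(pd.DataFrame(np.eye(5), index=list("abcde")))
        with pytest.raises(ValueError, match="k_max"):
            choose_k_elbow(m, k_max=5)
        with pytest.raises(ValueError, match="at least 3"):
            choose_k_elbow(m, k_max=2)


class TestHierarchicalClustering:
    def test_identical_rows_co_cluster(self):
        rows = np.array([[0.0, 0.0], [0.0, 0.0], [9.0, 9.0]])
        m = GroupMeanMatrix(pd.DataFrame(rows, index=["a", "b", "c"]))
        sol = hierarchical_cluster(m, 2)
        assert sol.assignments["a"] == sol.assignments["b"] != sol.assignments["c"]

    def test_row_permutation_leaves_partition_unchanged(self):
        rng = np.random.default_rng(4)
        rows = np.vstack([rng.normal(c, 0.2, size=(6, 3)) for c in (0, 5, 10)])
        names = [f"m{i}" for i in range(18)]
        m = GroupMeanMatrix(pd.DataFrame(rows, index=names))
        sol1 = hierarchical_cluster(m, 3)
        perm = rng.permutation(18)
        m2 = GroupMeanMatrix(pd.DataFrame(rows[perm], index=[names[i] for i in perm]))
        sol2 = hierarchical_cluster(m2, 3)
        parts1 = {frozenset(sol1.assignments.index[sol1.assignments == c])
                  for c in sol1.assignments.unique()}
        parts2 = {frozenset(sol2.assignments.index[sol2.assignments == c])
                  for c in sol2.assignments.unique()}
        assert parts1 == parts2

    def test_planted_blobs_recovered_and_duplicates_rejected(self):
        rng = np.random.default_rng(2)
        rows = np.vstack([rng.normal(c * 10, 0.2, size=(5, 4)) for c in range(5)])
        names = [f"m{i}" for i in range(25)]
        sol = hierarchical_cluster(GroupMeanMatrix(pd.DataFrame(rows, index=names)), 5)
        for blob in range(5):
            blob_names = names[blob * 5:(blob + 1) * 5]
            assert sol.assignments[blob_names].nunique() == 1
        dup = GroupMeanMatrix(pd.DataFrame(np.eye(3), index=["a", "a", "b"]))
        with pytest.raises(ValueError, match="duplicate"):
            hierarchical_cluster(dup, 2)


def _aged_matrix():
    """Three planted clusters: rows 0-4 aged (C70 matches A exactly),
    rows 5-9 young-like, rows 10-14 constant."""
    rng = np.random.default_rng(0)
    cols = [("A", 21), ("A", 28), ("A", 35), ("C", 21), ("C", 28), ("C", 35), ("C", 70)]
    n = 15
    m = np.zeros((n, len(cols)))
    a_val, c_val = 2.0, -2.0
    m[:5, 0:3] = a_val
    m[:5, 3:6] = c_val
    m[:5, 6] = a_val  # C70 equals the A centroid -> aged phenotype
    m[5:10, 0:3] = a_val
    m[5:10, 3:6] = c_val
    m[5:10, 6] = c_val  # C70 tracks young C -> not aged
    # rows 10-14 identical everywhere -> ties, not flagged
    frame = pd.DataFrame(m, index=[f"m{i}" for i in range(n)],
                         columns=pd.MultiIndex.from_tuples(cols))
    frame += rng.normal(0, 1e-6, size=frame.shape)  # break exact row duplicates
    return GroupMeanMatrix(frame)


class TestAgedPhenotypeFlags:
    def test_planted_aged_cluster_is_exactly_recovered(self):
        gm = _aged_matrix()
        assignments = pd.Series([1] * 5 + [2] * 5 + [3] * 5, index=gm.matrix.index,
                                name="cluster")
        from metaboclock.trajectories import ClusterSolution

        sol = ClusterSolution(row_linkage=None, col_linkage=None, k=3,
                              assignments=assignments)
        flags = flag_aged_phenotype(sol, gm)
        assert flags == {1: True, 2: False, 3: False}

    def test_missing_required_columns_rejected(self):
        gm = _aged_matrix()
        trimmed = GroupMeanMatrix(gm.matrix.drop(columns=[("C", 70)]))
        assignments = pd.Series(1, index=gm.matrix.index, name="cluster")
        from metaboclock.trajectories import ClusterSolution

        sol = ClusterSolution(row_linkage=None, col_linkage=None, k=1,
                              assignments=assignments)
        with pytest.raises(ValueError, match="required columns"):
            flag_aged_phenotype(sol, trimmed)
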