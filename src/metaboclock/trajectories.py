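"""Per-metabolite trajectory models, clustering, and aged-phenotype flags.

Each metabolite's normalized abundance is modeled as
``value ~ regime + age + regime x age + (1 | replicate)`` with age as an
unordered categorical factor (the design samples discrete timepoints);
term p-values come from likelihood-ratio tests between nested ML fits and
are Benjamini-Hochberg adjusted within each term across metabolites.

Group-mean abundance profiles (one column per regime x age cell) are then
clustered: the cluster count K is chosen by the K-means elbow rule (the K
with the largest discrete second difference of the within-cluster sum of
squares), and cluster assignments come from cutting a complete-linkage
Euclidean dendrogram into K groups.  Clusters whose old-control profile
(C day 70) resembles the younger accelerated-regime profiles more than the
younger control profiles are flagged as carrying the "aged phenotype".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from ._lmm import dummy_columns, fit_ml, interaction_columns, lr_test
from .tables import AbundanceTable

__all__ = [
    "LMMResultTable",
    "GroupMeanMatrix",
    "ClusterSolution",
    "fit_metabolite_lmms",
    "term_overlap_counts",
    "group_means",
    "choose_k_elbow",
    "elbow_from_wss",
    "hierarchical_cluster",
    "flag_aged_phenotype",
]

TERMS = ("selection", "age", "interaction")


@dataclass
class LMMResultTable:
    """Per-metabolite term p-values, BH q-values, and significance flags."""

    table: pd.DataFrame  # index metabolite; p_/q_/sig_ per term, re_var, converged
    fdr: float

    def significant(self, term: str) -> list[str]:
        return self.table.index[self.table[f"sig_{term}"]].tolist()

    @property
    def n_converged(self) -> int:
        return int(self.table["converged"].sum())


@dataclass
class GroupMeanMatrix:
    """Metabolite x (regime, age) matrix of mean normalized abundances."""

    matrix: pd.DataFrame  # columns: MultiIndex (regime, age_days), regime-major


@dataclass
class ClusterSolution:
    """Row/column dendrograms, the chosen K, and the K-cut row partition."""

    row_linkage: np.ndarray = field(repr=False)
    col_linkage: np.ndarray = field(repr=False)
    k: int
    assignments: pd.Series  # metabolite -> cluster id (1..K)
    wss: pd.Series | None = None  # WSS over candidate K
    aged_flags: dict | None = None


def fit_metabolite_lmms(table: AbundanceTable, fdr: float = 0.01) -> LMMResultTable:
    """Fit the selection/age/interaction mixed model per metabolite.

    Likelihood-ratio tests: interaction = full vs main-effects model;
    age = main-effects vs selection-only; selection = main-effects vs
    age-only.  BH adjustment is applied per term across converged
    metabolites; non-converging metabolites are flagged, not fatal.
    """
    if table.stage != "normalized":
        raise ValueError("fit_metabolite_lmms expects a normalized table")
    meta = table.metadata
    reps_per_regime = meta.groupby("regime")["replicate"].nunique()
    if (reps_per_regime < 2).any():
        raise ValueError("each regime needs at least 2 replicate populations")

    sel = dummy_columns(meta["regime"].to_numpy())
    age = dummy_columns(meta["age_days"].to_numpy())
    ones = np.ones((len(meta), 1))
    inter = interaction_columns(sel, age)
    x_full = np.hstack([ones, sel, age, inter])
    x_main = np.hstack([ones, sel, age])
    x_sel = np.hstack([ones, sel])
    x_age = np.hstack([ones, age])
    groups = meta["replicate"].to_numpy()

    rows = {}
    for met in table.values.columns:
        y = table.values[met].to_numpy(dtype=float)
        try:
            full = fit_ml(y, x_full, groups)
            main = fit_ml(y, x_main, groups)
            sel_only = fit_ml(y, x_sel, groups)
            age_only = fit_ml(y, x_age, groups)
            rows[met] = {
                "p_selection": lr_test(main, age_only),
                "p_age": lr_test(main, sel_only),
                "p_interaction": lr_test(full, main),
                "re_var": float(np.asarray(full.cov_re)[0, 0]),
                "converged": True,
            }
        except Exception:
            rows[met] = {
                "p_selection": np.nan,
                "p_age": np.nan,
                "p_interaction": np.nan,
                "re_var": np.nan,
                "converged": False,
            }
    tab = pd.DataFrame.from_dict(rows, orient="index")
    tab.index.name = "metabolite"
    if tab["converged"].sum() < 3:
        raise ValueError("fewer than 3 metabolites converged; input is unusable")
    ok = tab["converged"]
    for term in TERMS:
        q = pd.Series(np.nan, index=tab.index)
        q.loc[ok] = multipletests(tab.loc[ok, f"p_{term}"], method="fdr_bh")[1]
        tab[f"q_{term}"] = q
        tab[f"sig_{term}"] = (q < fdr).fillna(False)
    return LMMResultTable(table=tab, fdr=fdr)


def term_overlap_counts(results: LMMResultTable) -> dict:
    """UpSet-style counts of significant metabolites per term combination.

    Keys: each term (total significant for it), exclusive combinations
    joined by '+', and 'any' (total unique significant metabolites).
    """
    tab = results.table
    flags = {t: set(tab.index[tab[f"sig_{t}"]]) for t in TERMS}
    counts: dict[str, int] = {t: len(s) for t, s in flags.items()}
    counts["any"] = len(set().union(*flags.values()))
    from itertools import combinations

    for r in range(1, len(TERMS) + 1):
        for combo in combinations(TERMS, r):
            inside = set.intersection(*(flags[t] for t in combo)) if combo else set()
            outside = set().union(*(flags[t] for t in TERMS if t not in combo)) if len(
                combo
            ) < len(TERMS) else set()
            counts["+".join(combo) + " only" if r < 3 else "+".join(combo)] = len(
                inside - outside
            )
    return counts


def group_means(table: AbundanceTable) -> GroupMeanMatrix:
    """Mean normalized abundance per metabolite per (regime, age) group."""
    if table.stage != "normalized":
        raise ValueError("group_means expects a normalized table")
    grouped = table.values.groupby(
        [table.metadata["regime"], table.metadata["age_days"]]
    ).mean()
    grouped.index.names = ["regime", "age_days"]
    grouped = grouped.sort_index()  # regime-major, age-ascending
    return GroupMeanMatrix(matrix=grouped.T)


def elbow_from_wss(wss) -> int:
    """K with the largest discrete second difference of a WSS curve.

    ``wss`` is indexed K = 1..k_max (a sequence or a Series); the second
    difference d2(K) = [WSS(K+1) - WSS(K)] - [WSS(K) - WSS(K-1)] is defined
    for K = 2..k_max-1 and ties break toward smaller K.
    """
    w = np.asarray(wss, dtype=float)
    if len(w) < 3:
        raise ValueError("need WSS for at least 3 values of K")
    d2 = w[2:] - 2.0 * w[1:-1] + w[:-2]  # index i corresponds to K = i + 2
    return int(np.argmax(d2)) + 2


def choose_k_elbow(
    matrix: GroupMeanMatrix, k_max: int = 200, n_init: int = 25, seed: int = 0
) -> tuple[int, pd.Series]:
    """Choose the cluster count by the K-means WSS second-difference elbow.

    K-means (Lloyd) is run for K = 1..k_max with ``n_init`` seeded restarts
    each, keeping the minimum WSS per K.
    """
    x = matrix.matrix.to_numpy()
    if k_max > x.shape[0] - 1:
        raise ValueError(f"k_max={k_max} exceeds n_rows - 1 = {x.shape[0] - 1}")
    if k_max < 3:
        raise ValueError("k_max must be at least 3 for a second difference to exist")
    wss = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(1, k_max + 1):
            km = KMeans(n_clusters=k, n_init=n_init, random_state=seed + k, algorithm="lloyd")
            km.fit(x)
            wss.append(km.inertia_)
    curve = pd.Series(wss, index=pd.RangeIndex(1, k_max + 1, name="K"), name="WSS")
    return elbow_from_wss(curve), curve


def hierarchical_cluster(matrix: GroupMeanMatrix, k: int) -> ClusterSolution:
    """Complete-linkage Euclidean dendrograms; rows cut into K clusters."""
    if k < 2:
        raise ValueError("K must be at least 2")
    m = matrix.matrix
    if m.index.duplicated().any():
        raise ValueError("duplicate row identifiers")
    row_link = linkage(m.to_numpy(), method="complete", metric="euclidean")
    col_link = linkage(m.to_numpy().T, method="complete", metric="euclidean")
    labels = fcluster(row_link, t=k, criterion="maxclust")
    return ClusterSolution(
        row_linkage=row_link,
        col_linkage=col_link,
        k=k,
        assignments=pd.Series(labels, index=m.index, name="cluster"),
    )


def flag_aged_phenotype(
    solution: ClusterSolution, matrix: GroupMeanMatrix
) -> dict[int, bool]:
    """Flag row clusters whose old-control profile matches the A regime.

    Restricted to a cluster's rows, the cluster is flagged when BOTH
    (a) the C day-70 column is strictly closer (Euclidean) to the centroid
    of the A {21, 28, 35} columns than to the centroid of the C {21, 28, 35}
    columns, and (b) the A columns are on average strictly closer to C
    day-70 than to the young-C centroid.
    """
    m = matrix.matrix
    need = [("A", 21), ("A", 28), ("A", 35), ("C", 21), ("C", 28), ("C", 35), ("C", 70)]
    missing = [c for c in need if c not in m.columns]
    if missing:
        raise ValueError(f"group-mean matrix lacks required columns: {missing}")
    a_cols = [("A", a) for a in (21, 28, 35)]
    c_cols = [("C", a) for a in (21, 28, 35)]
    flags: dict[int, bool] = {}
    for cluster in sorted(solution.assignments.unique()):
        rows = solution.assignments.index[solution.assignments == cluster]
        sub = m.loc[rows]
        c70 = sub[("C", 70)].to_numpy()
        a_centroid = sub[a_cols].to_numpy().mean(axis=1)
        c_centroid = sub[c_cols].to_numpy().mean(axis=1)
        cond_a = np.linalg.norm(c70 - a_centroid) < np.linalg.norm(c70 - c_centroid)
        d_to_c70 = np.mean([np.linalg.norm(sub[c].to_numpy() - c70) for c in a_cols])
        d_to_young_c = np.mean(
            [np.linalg.norm(sub[c].to_numpy() - c_centroid) for c in a_cols]
        )
        cond_b = d_to_c70 < d_to_young_c
        flags[int(cluster)] = bool(cond_a and cond_b)
    return flags
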