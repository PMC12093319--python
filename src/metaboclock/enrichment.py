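"""Network-diffusion pathway enrichment with a permutation null.

Metabolite clusters are scored against a metabolite/pathway graph by a
random walk with restart seeded uniformly on the cluster's metabolites; a
pathway node's diffusion score is compared to the scores obtained from
random equal-size metabolite draws, giving an empirical p-value (the
"p.score") with the +1 pseudo-count correction, followed by BH FDR across
pathway nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "MetaboliteNetwork",
    "EnrichmentResult",
    "diffusion_scores",
    "permutation_enrichment",
]


@dataclass
class MetaboliteNetwork:
    """Undirected metabolite/pathway graph with typed nodes.

    Node attribute ``type`` is one of ``metabolite``, ``intermediate``, or
    ``pathway``.  Diffusion requires connectivity, so analyses restrict to
    the largest connected component and report what was dropped.
    """

    graph: nx.Graph

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("type") == node_type
        )

    @property
    def metabolite_nodes(self) -> list[str]:
        return self.nodes_of_type("metabolite")

    @property
    def pathway_nodes(self) -> list[str]:
        return self.nodes_of_type("pathway")

    def largest_component(self) -> tuple["MetaboliteNetwork", list[str]]:
        """The subgraph on the largest component plus the dropped nodes."""
        if self.graph.number_of_nodes() == 0:
            raise ValueError("empty network")
        comps = sorted(nx.connected_components(self.graph), key=len, reverse=True)
        keep = comps[0]
        dropped = sorted(set(self.graph.nodes) - keep)
        if dropped:
            log.info("restricting to largest component; dropping %d nodes", len(dropped))
        return MetaboliteNetwork(self.graph.subgraph(keep).copy()), dropped

    # -- TSV dialect: two-column edge list + node-type sidecar -------------

    def write(self, edges_path: str | Path, nodes_path: str | Path) -> None:
        edges = pd.DataFrame(sorted(self.graph.edges), columns=["source", "target"])
        edges.to_csv(edges_path, sep="\t", index=False)
        nodes = pd.DataFrame(
            [(n, d.get("type", "metabolite")) for n, d in sorted(self.graph.nodes(data=True))],
            columns=["node", "type"],
        )
        nodes.to_csv(nodes_path, sep="\t", index=False)

    @classmethod
    def read(cls, edges_path: str | Path, nodes_path: str | Path) -> "MetaboliteNetwork":
        edges = pd.read_csv(edges_path, sep="\t")
        nodes = pd.read_csv(nodes_path, sep="\t")
        g = nx.Graph()
        for _, row in nodes.iterrows():
            g.add_node(row["node"], type=row["type"])
        g.add_edges_from(edges.itertuples(index=False, name=None))
        return cls(g)


@dataclass
class EnrichmentResult:
    """Per-pathway diffusion scores with empirical p ("p.score") and FDR."""

    table: pd.DataFrame  # index pathway: score, p_score, fdr, significant, rank
    cluster_size: int
    n_perm: int

    def significant_pathways(self) -> list[str]:
        t = self.table[self.table["significant"]].sort_values("p_score")
        return t.index.tolist()


def _walk_kernel(network: MetaboliteNetwork, restart_prob: float):
    """Restart-walk propagation kernel K: score(seeds S) = mean of K[:, S].

    K = r (I - (1 - r) P)^{-1} with P the column-stochastic transition
    matrix; each column of K is the stationary score vector of a walk
    restarting at that single node, and columns sum to 1.
    """
    if not 0.0 < restart_prob <= 1.0:
        raise ValueError("restart probability must be in (0, 1]")
    nodes = sorted(network.graph.nodes)
    a = nx.to_numpy_array(network.graph, nodelist=nodes)
    deg = a.sum(axis=0)
    if (deg == 0).any():
        raise ValueError("isolated node in component; cannot build transition matrix")
    p = a / deg  # column-stochastic
    n = len(nodes)
    kernel = restart_prob * np.linalg.inv(np.eye(n) - (1.0 - restart_prob) * p)
    return nodes, kernel


def diffusion_scores(
    network: MetaboliteNetwork, seed_metabolites: set, restart_prob: float = 0.5
) -> pd.Series:
    """Stationary random-walk-with-restart scores from a uniform seed set.

    Scores over all nodes of the largest connected component sum to 1.
    """
    comp, _ = network.largest_component()
    nodes, kernel = _walk_kernel(comp, restart_prob)
    index = {n: i for i, n in enumerate(nodes)}
    mapped = [index[m] for m in seed_metabolites if m in index]
    if not mapped:
        raise ValueError("no seed metabolite maps to the network")
    scores = kernel[:, mapped].mean(axis=1)
    return pd.Series(scores, index=pd.Index(nodes, name="node"), name="score")


def permutation_enrichment(
    network: MetaboliteNetwork,
    cluster_metabolites: set,
    n_perm: int = 10_000,
    min_cluster: int = 4,
    restart_prob: float = 0.5,
    fdr: float = 0.05,
    seed: int = 0,
) -> EnrichmentResult | None:
    """Empirical pathway enrichment of one metabolite cluster.

    Observed pathway diffusion scores are compared with scores of ``n_perm``
    random equal-size draws from all annotated (in-network) metabolites;
    empirical p = (1 + #{perm >= observed}) / (1 + n_perm), BH-adjusted
    across pathway nodes.  Clusters with fewer than ``min_cluster``
    annotated metabolites are skipped (returns ``None``) with a logged
    notice.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1; empirical p is undefined otherwise")
    comp, _ = network.largest_component()
    nodes, kernel = _walk_kernel(comp, restart_prob)
    index = {n: i for i, n in enumerate(nodes)}
    annotated = [m for m in sorted(cluster_metabolites) if m in index]
    if len(annotated) < min_cluster:
        log.info(
            "cluster has %d annotated metabolites (< %d); skipping enrichment",
            len(annotated),
            min_cluster,
        )
        return None
    pathways = [p for p in comp.pathway_nodes]
    if not pathways:
        raise ValueError("network has no pathway nodes to test")
    met_pool = np.array([index[m] for m in comp.metabolite_nodes])
    path_rows = np.array([index[p] for p in pathways])
    seed_cols = np.array([index[m] for m in annotated])

    observed = kernel[np.ix_(path_rows, seed_cols)].mean(axis=1)
    rng = np.random.default_rng(seed)
    k = len(seed_cols)
    exceed = np.zeros(len(pathways), dtype=np.int64)
    chunk = max(1, min(n_perm, 200_000 // max(1, len(pathways) * k // 64 + 1)))
    done = 0
    kp = kernel[path_rows][:, met_pool]  # pathways x candidate metabolites
    while done < n_perm:
        b = min(chunk, n_perm - done)
        draws = np.stack([rng.choice(len(met_pool), size=k, replace=False) for _ in range(b)])
        perm_scores = kp[:, draws].mean(axis=2)  # pathways x b
        exceed += (perm_scores >= observed[:, None]).sum(axis=1)
        done += b
    p_emp = (1.0 + exceed) / (1.0 + n_perm)
    q = multipletests(p_emp, method="fdr_bh")[1]
    tab = pd.DataFrame(
        {"score": observed, "p_score": p_emp, "fdr": q, "significant": q < fdr},
        index=pd.Index(pathways, name="pathway"),
    )
    tab = tab.sort_values(["p_score", "pathway"])
    tab["rank"] = np.arange(1, len(tab) + 1)
    return EnrichmentResult(table=tab, cluster_size=len(annotated), n_perm=n_perm)
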