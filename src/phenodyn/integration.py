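"""Cross-modality comparisons and the phenome-wide network.

Task-vs-rest connectome correlation, structure-function edge overlap with
a randomization null, interhemispheric edge proportions across densities,
edge-length statistics, and the phenome-wide association graph with its
class-based exclusion rules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .connectome import Connectome, binarize_at_density
from .graphs import UNASSIGNED, detect_communities

__all__ = [
    "task_connectome",
    "struct_func_overlap",
    "interhemispheric_proportion",
    "edge_distance_stats",
    "PhenomeGraph",
    "build_phenome_network",
]


def task_connectome(contrasts: pd.DataFrame) -> Connectome:
    """Meta-analytic task connectome: parcel correlations across contrasts.

    ``contrasts`` is parcel x contrast activation statistics.  Constant
    parcel rows get zero correlation with a warning record.
    """
    mat = contrasts.values.astype(float)
    if mat.shape[1] < 3:
        raise ValueError("need >= 3 contrasts")
    if np.any(np.all(~np.isfinite(mat), axis=1)):
        raise ValueError("all-missing parcel row")
    warn = []
    sd = mat.std(axis=1)
    const = sd == 0
    for i in np.flatnonzero(const):
        warn.append(f"constant parcel row {contrasts.index[i]}: zeroed")
    mc = mat - mat.mean(axis=1, keepdims=True)
    denom = np.outer(sd, sd) * mat.shape[1]
    cov = mc @ mc.T
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(denom > 0, cov / denom, 0.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    return Connectome(weights=corr, estimator="task",
                      parcel_ids=np.asarray(contrasts.index), warnings=warn)


def _edge_set(c: Connectome) -> np.ndarray:
    iu, ju = np.triu_indices(c.n_parcels, k=1)
    return c.weights[iu, ju] != 0


def struct_func_overlap(f: Connectome, s: Connectome, densities,
                        s_density: float = 0.10, n_perm: int = 1000,
                        seed: int = 0) -> pd.DataFrame:
    """Fraction of functional edges with nonzero structural connectivity.

    The structural matrix is binarized at ``s_density``; for each
    functional density the overlap is the fraction of functional edges
    that are also structural edges.  The chance level is the mean overlap
    over ``n_perm`` uniform relocations of the structural edges (edge
    count preserved, degrees not).
    """
    densities = list(densities)
    if not densities:
        raise ValueError("empty density sweep")
    if f.n_parcels != s.n_parcels:
        raise ValueError("parcel sets differ")
    rng = np.random.default_rng(seed)
    s_bin = binarize_at_density(s, s_density)
    s_edges = _edge_set(s_bin)
    n_pairs = s_edges.size
    m_struct = int(s_edges.sum())

    rows = []
    for d in densities:
        f_bin = binarize_at_density(f, d)
        f_edges = _edge_set(f_bin)
        m_func = int(f_edges.sum())
        overlap = float((f_edges & s_edges).sum() / m_func) if m_func else 0.0
        chance = np.empty(n_perm)
        for i in range(n_perm):
            perm = np.zeros(n_pairs, dtype=bool)
            perm[rng.choice(n_pairs, size=m_struct, replace=False)] = True
            chance[i] = (f_edges & perm).sum() / m_func if m_func else 0.0
        rows.append((d, overlap, float(chance.mean()), float(chance.std())))
    return pd.DataFrame(rows, columns=["density", "overlap", "chance",
                                       "chance_sd"])


def interhemispheric_proportion(g: Connectome, hemisphere_labels,
                                densities) -> pd.DataFrame:
    """Proportion of surviving edges that cross hemispheres, per density."""
    hemi = np.asarray(hemisphere_labels)
    if hemi.size != g.n_parcels or pd.isnull(hemi).any():
        raise ValueError("hemisphere labels required for every parcel")
    iu, ju = np.triu_indices(g.n_parcels, k=1)
    cross = hemi[iu] != hemi[ju]
    rows = []
    for d in densities:
        edges = _edge_set(binarize_at_density(g, d))
        m = int(edges.sum())
        prop = float((edges & cross).sum() / m) if m else 0.0
        rows.append((d, prop))
    return pd.DataFrame(rows, columns=["density", "prop_interhemispheric"])


def edge_distance_stats(g: Connectome, centroids: np.ndarray) -> dict:
    """Euclidean edge lengths (mm) of surviving edges: mean and quantiles."""
    dist = squareform(pdist(np.asarray(centroids, dtype=float)))
    iu, ju = np.triu_indices(g.n_parcels, k=1)
    edges = _edge_set(g)
    lengths = dist[iu, ju][edges]
    if lengths.size == 0:
        return {"mean_mm": 0.0, "median_mm": 0.0, "q25_mm": 0.0,
                "q75_mm": 0.0, "lengths": lengths}
    return {
        "mean_mm": float(lengths.mean()),
        "median_mm": float(np.median(lengths)),
        "q25_mm": float(np.quantile(lengths, 0.25)),
        "q75_mm": float(np.quantile(lengths, 0.75)),
        "lengths": lengths,
    }


class PhenomeGraph:
    """Variable-level association graph with class metadata."""

    def __init__(self, nodes: pd.DataFrame, edges: pd.DataFrame,
                 assignment: np.ndarray, modularity: float | None):
        self.nodes = nodes          # columns: var, class, module
        self.edges = edges          # columns: var_a, var_b, sign, r, q
        self.assignment = assignment
        self.modularity = modularity

    @property
    def is_empty(self) -> bool:
        return len(self.edges) == 0

    def to_networkx(self):
        import networkx as nx
        g = nx.Graph()
        for _, row in self.nodes.iterrows():
            g.add_node(row["var"], var_class=row["class"],
                       module=int(row["module"]))
        for _, row in self.edges.iterrows():
            g.add_edge(row["var_a"], row["var_b"], sign=row["sign"],
                       r=float(row["r"]))
        return g

    def write_graphml(self, path):
        import networkx as nx
        nx.write_graphml(self.to_networkx(), path)


def build_phenome_network(assoc_results: pd.DataFrame, q: float = 0.05,
                          excluded_within_classes=("wgcna", "metab", "fullmetab"),
                          excluded_classes=("netdat",), seed: int = 0
                          ) -> PhenomeGraph:
    """Graph of significant cross-variable associations.

    Edges are associations with BH-adjusted p below ``q``.  Variables of
    the ``excluded_classes`` never enter; pairs within one of the
    ``excluded_within_classes`` (same class on both sides) are dropped.
    Modules come from the seeded community detector; the modularity
    coefficient of that partition is reported (None for an empty graph).
    """
    df = assoc_results.copy()
    if "p_bh" not in df.columns:
        raise ValueError("assoc results must carry BH-adjusted p-values")
    df = df[df["p_bh"] < q]
    df = df[~df["class_a"].isin(excluded_classes)
            & ~df["class_b"].isin(excluded_classes)]
    same = df["class_a"] == df["class_b"]
    df = df[~(same & df["class_a"].isin(excluded_within_classes))]

    var_class = {}
    for _, row in df.iterrows():
        var_class[row["var_a"]] = row["class_a"]
        var_class[row["var_b"]] = row["class_b"]
    names = sorted(var_class)
    index = {v: i for i, v in enumerate(names)}

    edges = pd.DataFrame({
        "var_a": df["var_a"].values,
        "var_b": df["var_b"].values,
        "sign": np.where(df["r"].values >= 0, "+", "-"),
        "r": df["r"].values,
        "q": df["p_bh"].values,
    })

    n = len(names)
    if n == 0:
        nodes = pd.DataFrame(columns=["var", "class", "module"])
        return PhenomeGraph(nodes, edges, np.zeros(0, dtype=int), None)

    adj = np.zeros((n, n))
    for _, row in edges.iterrows():
        i, j = index[row["var_a"]], index[row["var_b"]]
        adj[i, j] = adj[j, i] = 1.0
    graph = Connectome(weights=adj, estimator="full",
                       parcel_ids=np.asarray(names, dtype=object))
    assignment = detect_communities(graph, seed=seed)

    modularity = None
    if len(edges):
        import igraph as ig
        iu, ju = np.triu_indices(n, k=1)
        present = adj[iu, ju] != 0
        g = ig.Graph(n=n, edges=list(zip(iu[present].tolist(),
                                         ju[present].tolist())))
        memb = assignment.copy()
        nxt = memb.max() + 1 if (memb != UNASSIGNED).any() else 0
        for i in np.flatnonzero(memb == UNASSIGNED):
            memb[i] = nxt
            nxt += 1
        modularity = float(g.modularity(memb.tolist()))

    nodes = pd.DataFrame({
        "var": names,
        "class": [var_class[v] for v in names],
        "module": assignment,
    })
    return PhenomeGraph(nodes, edges, assignment, modularity)
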