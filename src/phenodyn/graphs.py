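"""Graph cartography: communities, consensus partitions, modularity, hubs.

Community detection runs a seeded map-equation optimizer (Infomap, via
igraph) behind a pluggable interface.  The consensus layer collapses
assignments across edge-density thresholds: small modules (eight or fewer
parcels) are dissolved, each node keeps its label at the sparsest threshold
where it was assigned, and modules present at only a single threshold are
removed.  Hub cartography classifies nodes by within-module degree z-score
and participation coefficient.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectome import Connectome, full_correlation, mean_connectome, binarize_at_density

__all__ = [
    "UNASSIGNED",
    "Partition",
    "detect_communities",
    "consensus_partition",
    "signed_modularity",
    "global_efficiency",
    "participation_and_hubs",
    "state_contrast_graphs",
]

UNASSIGNED = -1


@dataclass
class Partition:
    """Parcel -> module assignment (-1 = unassigned) with consensus metadata."""

    assignment: np.ndarray
    thresholds_used: list = field(default_factory=list)
    per_threshold: dict = field(default_factory=dict)

    @property
    def n_modules(self) -> int:
        labels = self.assignment[self.assignment != UNASSIGNED]
        return int(np.unique(labels).size)


def _to_igraph(c: Connectome) -> ig.Graph:
    n = c.n_parcels
    iu, ju = np.triu_indices(n, k=1)
    present = c.weights[iu, ju] != 0
    edges = list(zip(iu[present].tolist(), ju[present].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = c.weights[iu[present], ju[present]].tolist()
    return g


def detect_communities(c: Connectome, seed: int = 0,
                       method: str = "infomap") -> np.ndarray:
    """Seeded community assignment of a binarized connectome.

    ``method`` selects the base optimizer: "infomap" (map equation, default)
    or "multilevel" (modularity maximization).  Nodes in an edgeless graph
    are all UNASSIGNED.  Deterministic for a fixed seed.
    """
    g = _to_igraph(c)
    if g.ecount() == 0:
        return np.full(c.n_parcels, UNASSIGNED)
    ig.set_random_number_generator(random.Random(int(seed)))
    if method == "infomap":
        memb = g.community_infomap(trials=5).membership
    elif method == "multilevel":
        memb = g.community_multilevel().membership
    else:
        raise ValueError(f"unknown community method {method!r}")
    assignment = np.asarray(memb, dtype=int)
    # isolated nodes carry no community information
    deg = np.asarray(g.degree())
    assignment[deg == 0] = UNASSIGNED
    return assignment


def _filter_small(assignment: np.ndarray, min_module_size: int) -> np.ndarray:
    out = assignment.copy()
    for lab in np.unique(out):
        if lab == UNASSIGNED:
            continue
        if int(np.sum(out == lab)) < min_module_size:
            out[out == lab] = UNASSIGNED
    return out


def _match_labels(reference_sets: dict, assignment: np.ndarray,
                  next_label: int) -> tuple[np.ndarray, int]:
    """Relabel modules to best-Jaccard reference labels (ties: lower ids)."""
    labels = [l for l in np.unique(assignment) if l != UNASSIGNED]
    pairs = []
    for lab in labels:
        members = set(np.flatnonzero(assignment == lab).tolist())
        for ref, ref_members in reference_sets.items():
            inter = len(members & ref_members)
            if inter == 0:
                continue
            jac = inter / len(members | ref_members)
            pairs.append((-jac, lab, ref, members))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    mapping = {}
    used_refs = set()
    for negjac, lab, ref, members in pairs:
        if lab in mapping or ref in used_refs:
            continue
        mapping[lab] = ref
        used_refs.add(ref)
    out = np.full_like(assignment, UNASSIGNED)
    for lab in labels:
        if lab not in mapping:
            mapping[lab] = next_label
            next_label += 1
        out[assignment == lab] = mapping[lab]
    return out, next_label


def consensus_partition(assignments_by_density: dict,
                        min_module_size: int = 9) -> Partition:
    """Collapse threshold-wise assignments into a consensus partition.

    Per threshold, modules smaller than ``min_module_size`` parcels are
    dissolved to UNASSIGNED (the "eight or fewer parcels" rule at the
    default).  Module identity is tracked across thresholds by maximal
    Jaccard overlap with the sparsest threshold's modules.  Each node takes
    its label at the sparsest (lowest-density) threshold where it is
    assigned; labels that survive at only one threshold are then removed
    (when more than one threshold was supplied).
    """
    if not assignments_by_density:
        raise ValueError("need at least one threshold")
    densities = sorted(assignments_by_density)
    filtered = {}
    reference_sets: dict = {}
    next_label = 0
    for d in densities:
        a = _filter_small(np.asarray(assignments_by_density[d], dtype=int),
                          min_module_size)
        a, next_label = _match_labels(reference_sets, a, next_label)
        for lab in np.unique(a):
            if lab == UNASSIGNED:
                continue
            members = set(np.flatnonzero(a == lab).tolist())
            if lab in reference_sets:
                reference_sets[lab] |= members
            else:
                reference_sets[lab] = members
        filtered[d] = a

    n = filtered[densities[0]].size
    consensus = np.full(n, UNASSIGNED)
    for i in range(n):
        for d in densities:
            if filtered[d][i] != UNASSIGNED:
                consensus[i] = filtered[d][i]
                break

    if len(densities) > 1:
        presence = {}
        for d in densities:
            for lab in np.unique(filtered[d]):
                if lab != UNASSIGNED:
                    presence.setdefault(lab, set()).add(d)
        for lab, ds in presence.items():
            if len(ds) == 1:
                consensus[consensus == lab] = UNASSIGNED

    # contiguous module ids in order of first appearance
    relabel = {}
    out = np.full(n, UNASSIGNED)
    for i in range(n):
        lab = consensus[i]
        if lab == UNASSIGNED:
            continue
        if lab not in relabel:
            relabel[lab] = len(relabel)
        out[i] = relabel[lab]
    per_threshold = {d: filtered[d] for d in densities}
    return Partition(assignment=out, thresholds_used=list(densities),
                     per_threshold=per_threshold)


def signed_modularity(c: Connectome, p: Partition | np.ndarray) -> float:
    """Signed, weighted modularity with asymmetric negative weighting.

    Positive and negative parts each get a Newman-style modularity with
    their own null model; the negative part is down-weighted by
    ``s- / (s+ + s-)`` (the standard convention for signed correlation
    matrices).  Unassigned nodes are treated as singleton modules.
    """
    assignment = p.assignment if isinstance(p, Partition) else np.asarray(p)
    w = c.weights
    n = w.shape[0]
    labels = assignment.astype(float).copy()
    una = labels == UNASSIGNED
    labels[una] = -np.arange(1, una.sum() + 1, dtype=float) - 0.5  # unique singletons
    delta = labels[:, None] == labels[None, :]

    wp = np.where(w > 0, w, 0.0)
    wn = np.where(w < 0, -w, 0.0)
    vp, vn = wp.sum(), wn.sum()
    if vp + vn == 0:
        return 0.0

    def q_part(mat, v):
        if v == 0:
            return 0.0
        s = mat.sum(axis=1)
        null = np.outer(s, s) / v
        return float(np.sum((mat - null) * delta) / v)

    qp = q_part(wp, vp)
    qn = q_part(wn, vn)
    return qp - (vn / (vp + vn)) * qn


def global_efficiency(c: Connectome) -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    Positive weights map to lengths 1/w; non-positive weights carry no
    edge.  Disconnected pairs contribute zero.
    """
    w = c.weights
    n = w.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    d = shortest_path(csr_matrix(lengths), method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def participation_and_hubs(c: Connectome, p: Partition | np.ndarray,
                           z_hub: float = 1.0, p_split: float = 0.3) -> pd.DataFrame:
    """Per-node strength, within-module degree z-score, participation, hub class.

    P_i = 1 - sum_m (k_im / k_i)^2 where the sum runs over every category a
    neighbour can fall in (including "unassigned"), so sum_m k_im = k_i
    holds exactly.  Hubs require within-module z > ``z_hub``; connector hubs
    additionally have participation >= ``p_split``, the rest are provincial.
    Unassigned or isolated nodes are never hubs; isolated nodes get P = 0
    with a flag.
    """
    assignment = p.assignment if isinstance(p, Partition) else np.asarray(p)
    adj = (c.weights != 0).astype(float)
    k = adj.sum(axis=1)
    n = adj.shape[0]

    cats = np.unique(assignment)
    k_im = np.zeros((n, cats.size))
    for j, m in enumerate(cats):
        k_im[:, j] = adj[:, assignment == m].sum(axis=1)

    part = np.zeros(n)
    flags = np.array([""] * n, dtype=object)
    nz = k > 0
    part[nz] = 1.0 - np.sum((k_im[nz] / k[nz, None]) ** 2, axis=1)
    flags[~nz] = "isolated"

    z = np.zeros(n)
    for m in cats:
        if m == UNASSIGNED:
            continue
        members = assignment == m
        j = int(np.flatnonzero(cats == m)[0])
        km = k_im[members, j]
        sd = km.std()
        if sd > 0:
            z[members] = (km - km.mean()) / sd

    hub_class = np.array(["none"] * n, dtype=object)
    is_hub = (z > z_hub) & (assignment != UNASSIGNED) & nz
    hub_class[is_hub & (part >= p_split)] = "connector"
    hub_class[is_hub & (part < p_split)] = "provincial"

    return pd.DataFrame({
        "strength": c.weights.sum(axis=1),
        "degree": k,
        "within_z": z,
        "participation": part,
        "hub_class": hub_class,
        "flag": flags,
    }, index=[str(i) for i in c.parcel_ids])


def state_contrast_graphs(sessions, density: float = 0.01, seed: int = 0,
                          exclusion_mm: float | None = None,
                          centroids: np.ndarray | None = None):
    """Fed vs fasted mean-connectome graphs, partitions, hubs and transitions.

    Sessions are grouped by their ``state`` attribute; each state needs at
    least two sessions.  Returns ``(fed, fasted, transitions)`` where each
    state entry is a dict with keys graph/partition/hubs and ``transitions``
    is a table of nodes whose hub class differs between states.
    """
    by_state: dict = {}
    for s in sessions:
        by_state.setdefault(s.state, []).append(s)
    for st in ("fed", "fasted"):
        if len(by_state.get(st, [])) < 2:
            raise ValueError(f"state {st!r} needs >= 2 sessions")

    result = {}
    for st in ("fed", "fasted"):
        mean_c = mean_connectome([full_correlation(s) for s in by_state[st]])
        graph = binarize_at_density(mean_c, density, exclusion_mm=exclusion_mm,
                                    centroids=centroids)
        assignment = detect_communities(graph, seed=seed)
        partition = consensus_partition({density: assignment})
        hubs = participation_and_hubs(graph, partition)
        result[st] = {"graph": graph, "partition": partition, "hubs": hubs}

    fed_cls = result["fed"]["hubs"]["hub_class"]
    fas_cls = result["fasted"]["hubs"]["hub_class"]
    changed = fed_cls != fas_cls
    transitions = pd.DataFrame({
        "fed_class": fed_cls[changed],
        "fasted_class": fas_cls[changed],
    })
    return result["fed"], result["fasted"], transitions
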