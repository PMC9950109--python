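"""Binding-mode comparison and clustering.

Interaction graphs of the same fragment are compared with a subgraph
matching kernel (SMK): a sum over injective, label-preserving mappings of
up to ``max_nodes`` nodes, each weighted by a distance-tolerant edge
kernel. Binding modes are the DBSCAN clusters (eps = 0.23, min_samples = 2)
of the 1 - similarity matrix; clusters whose graphs all embed into graphs
of another cluster are merged (the inclusion correction), because a
sub-pattern of a binding mode is not a new mode.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN

from .config import PipelineConfig
from .interact import InteractionGraph

__all__ = [
    "SmkParams", "ModeClustering", "smk_similarity", "smk_raw_kernel",
    "dbscan", "count_binding_modes", "graph_included",
    "merge_included_clusters", "symmetry_rmsd", "similarity_matrix",
]


@dataclass
class SmkParams:
    max_subgraph_nodes: int = 3
    edge_dmax: float = 1.0

    def __post_init__(self):
        if self.max_subgraph_nodes < 1:
            raise ValueError("max_subgraph_nodes must be >= 1")
        if self.edge_dmax <= 0:
            raise ValueError("edge_dmax must be positive")


@dataclass
class ModeClustering:
    labels: np.ndarray          # cluster id per graph, noise already resolved
    n_modes: int
    merged_pairs: list = field(default_factory=list)


def _edge_kernel(d1, d2, dmax):
    return max(0.0, 1.0 - abs(d1 - d2) / dmax)


def smk_raw_kernel(g1: InteractionGraph, g2: InteractionGraph,
                   p: SmkParams | None = None) -> float:
    """Unnormalized SMK: sum over unordered node subsets S of g1
    (1 <= |S| <= max_nodes) and injective label-preserving maps f: S -> g2
    of the product of pairwise edge kernels (delta node kernel)."""
    p = p or SmkParams()
    lab1, lab2 = g1.labels, g2.labels
    n1, n2 = len(lab1), len(lab2)
    if n1 == 0 or n2 == 0:
        return 0.0
    d1, d2 = g1.distance_matrix(), g2.distance_matrix()
    cand = [[j for j in range(n2) if lab2[j] == lab1[i]] for i in range(n1)]
    total = 0.0
    kmax = min(p.max_subgraph_nodes, n1)
    for k in range(1, kmax + 1):
        for subset in itertools.combinations(range(n1), k):
            if any(not cand[i] for i in subset):
                continue
            for assign in itertools.product(*(cand[i] for i in subset)):
                if len(set(assign)) != k:
                    continue
                w = 1.0
                for (a, b) in itertools.combinations(range(k), 2):
                    w *= _edge_kernel(d1[subset[a], subset[b]],
                                      d2[assign[a], assign[b]], p.edge_dmax)
                    if w == 0.0:
                        break
                total += w
    return total


def smk_similarity(g1: InteractionGraph, g2: InteractionGraph,
                   p: SmkParams | None = None) -> float:
    """Normalized SMK similarity k12 / sqrt(k11 * k22) in [0, 1];
    an empty graph scores 0 against anything."""
    p = p or SmkParams()
    if g1.n_nodes == 0 or g2.n_nodes == 0:
        return 0.0
    k12 = smk_raw_kernel(g1, g2, p)
    if k12 == 0.0:
        return 0.0
    k11 = smk_raw_kernel(g1, g1, p)
    k22 = smk_raw_kernel(g2, g2, p)
    return float(min(1.0, k12 / np.sqrt(k11 * k22)))


def similarity_matrix(graphs, p: SmkParams | None = None) -> np.ndarray:
    p = p or SmkParams()
    n = len(graphs)
    sim = np.eye(n)
    selfk = [smk_raw_kernel(g, g, p) for g in graphs]
    for i in range(n):
        if graphs[i].n_nodes == 0:
            sim[i, i] = 1.0
    for i, j in itertools.combinations(range(n), 2):
        if graphs[i].n_nodes == 0 or graphs[j].n_nodes == 0:
            s = 0.0
        else:
            k12 = smk_raw_kernel(graphs[i], graphs[j], p)
            s = min(1.0, k12 / np.sqrt(selfk[i] * selfk[j])) if k12 else 0.0
        sim[i, j] = sim[j, i] = s
    return sim


def dbscan(distances: np.ndarray, eps: float, min_samples: int = 2) -> np.ndarray:
    """DBSCAN on a precomputed distance matrix; noise labelled -1.

    With min_samples = 2 this equals connected components of the
    eps-threshold graph, isolated points being noise."""
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("distances must be nonnegative")
    if len(D) == 1:
        return np.array([-1])
    model = DBSCAN(eps=eps, min_samples=min_samples, metric="precomputed")
    return model.fit_predict(np.ascontiguousarray(D))


def _resolve_noise(labels: np.ndarray) -> np.ndarray:
    """Give each noise point its own cluster id (a singleton binding mode)."""
    labels = labels.copy()
    nxt = labels.max(initial=-1) + 1
    for i, l in enumerate(labels):
        if l == -1:
            labels[i] = nxt
            nxt += 1
    return labels


def graph_included(g_small: InteractionGraph, g_big: InteractionGraph,
                   edge_tol: float = 0.5) -> bool:
    """True iff all of g_small's nodes embed injectively into g_big with
    matching labels and every edge-length difference <= edge_tol."""
    lab_s, lab_b = g_small.labels, g_big.labels
    ns, nb = len(lab_s), len(lab_b)
    if ns == 0:
        return True
    if ns > nb:
        return False
    ds, db = g_small.distance_matrix(), g_big.distance_matrix()
    cand = [[j for j in range(nb) if lab_b[j] == lab_s[i]] for i in range(ns)]
    if any(not c for c in cand):
        return False

    order = sorted(range(ns), key=lambda i: len(cand[i]))

    def backtrack(pos, assign):
        if pos == ns:
            return True
        i = order[pos]
        for j in cand[i]:
            if j in assign.values():
                continue
            if all(abs(ds[i, i2] - db[j, j2]) <= edge_tol
                   for i2, j2 in assign.items()):
                assign[i] = j
                if backtrack(pos + 1, assign):
                    return True
                del assign[i]
        return False

    return backtrack(0, {})


def merge_included_clusters(labels: np.ndarray, graphs,
                            edge_tol: float = 0.5) -> ModeClustering:
    """Merge cluster A into B when every graph of A embeds in some graph of
    B; transitive closure via union-find. Never increases the mode count."""
    labels = np.asarray(labels)
    ids = sorted(set(labels.tolist()))
    members = {c: [g for g, l in zip(graphs, labels) if l == c] for c in ids}

    parent = {c: c for c in ids}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    merged_pairs = []
    for a, b in itertools.permutations(ids, 2):
        # an interaction-free graph embeds vacuously everywhere; letting it
        # merge would bridge unrelated modes, so empty clusters stay put
        if all(g.n_nodes == 0 for g in members[a]) and \
           any(g.n_nodes > 0 for g in members[b]):
            continue
        if all(any(graph_included(ga, gb, edge_tol) for gb in members[b])
               for ga in members[a]):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
                merged_pairs.append((a, b))

    root_ids = {c: find(c) for c in ids}
    remap = {r: k for k, r in enumerate(sorted(set(root_ids.values())))}
    new_labels = np.array([remap[root_ids[l]] for l in labels])
    return ModeClustering(labels=new_labels,
                          n_modes=len(remap),
                          merged_pairs=merged_pairs)


def count_binding_modes(graphs, config: PipelineConfig | None = None) -> ModeClustering:
    """Number of distinct binding modes among a fragment's interaction
    graphs: DBSCAN on 1 - SMK similarity (eps = mode_eps), singletons as
    their own modes, then the inclusion-merge correction."""
    config = config or PipelineConfig()
    if len(graphs) == 0:
        raise ValueError("need at least one interaction graph")
    if len(graphs) == 1:
        return ModeClustering(labels=np.array([0]), n_modes=1)
    p = SmkParams(config.smk_max_nodes, config.smk_edge_dmax)
    sim = similarity_matrix(graphs, p)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    raw = dbscan(dist, eps=config.mode_eps,
                 min_samples=config.cluster_min_samples)
    resolved = _resolve_noise(raw)
    return merge_included_clusters(resolved, graphs, config.merge_edge_tol)


def symmetry_rmsd(mol1, mol2=None, conf_id1: int = 0, conf_id2: int = 0) -> float:
    """Minimum heavy-atom RMSD after optimal rigid superposition, minimized
    over graph automorphisms (symmetry-aware, like a rigid-body fit that is
    blind to equivalent atom namings).

    Accepts two RDKit molecules of the same chemical species (or one
    molecule and two conformer ids).
    """
    from rdkit import Chem
    from rdkit.Chem import rdMolAlign

    if mol2 is None:
        probe = Chem.Mol(mol1)
        ref = Chem.Mol(mol1)
        return float(rdMolAlign.GetBestRMS(
            Chem.RemoveHs(probe), Chem.RemoveHs(ref),
            prbId=conf_id1, refId=conf_id2))
    m1, m2 = Chem.RemoveHs(Chem.Mol(mol1)), Chem.RemoveHs(Chem.Mol(mol2))
    if Chem.MolToSmiles(m1) != Chem.MolToSmiles(m2):
        raise ValueError("conformers are not the same chemical species")
    return float(rdMolAlign.GetBestRMS(m1, m2, prbId=conf_id1, refId=conf_id2))
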