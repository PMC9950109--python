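"""Pharmacophore-labeled cavity clouds and their comparison.

The binding cavity of a bound fragment is described as a lattice of points
within 4 A of the fragment's heavy atoms, clash-free and buried inside the
protein, each labeled by the pharmacophoric type of the nearest protein
heavy atom (charged > H-bonding > aromatic > hydrophobic, else DUMMY).
Two cavities are compared by label-aware rigid registration (descriptor
matching + RANSAC + label-constrained ICP); the score is the fraction of
the smaller cloud's points with a same-label counterpart within 1.5 A
after alignment, computed in both directions with the best kept. Cavities
cluster together when their score reaches 0.47.

The lattice is anchored to a ligand-derived canonical frame (PCA axes with
moment-based sign fixing), which makes cloud generation equivariant under
rigid motion of the whole complex.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .config import PipelineConfig
from .structio import LigandInstance, ProteinSite
from .interact import protein_atom_types

__all__ = [
    "LabeledCloud", "CavityComparison", "generate_cavity_cloud",
    "cavity_similarity", "count_cavities", "cavity_score_matrix",
    "CLOUD_LABELS",
]

CLOUD_LABELS = ("HYDROPHOBIC", "AROMATIC", "HB_DONOR", "HB_ACCEPTOR",
                "POSITIVE", "NEGATIVE", "DUMMY")

# 14 lattice ray directions: 6 axial + 8 body diagonals (canonical frame)
_DIRS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
    + [[sx, sy, sz] for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)],
    dtype=float)
_DIRS /= np.linalg.norm(_DIRS, axis=1, keepdims=True)
_RAY_RADIUS = 1.5  # A, capture radius around each ray


@dataclass
class LabeledCloud:
    points: np.ndarray                  # (N, 3) A
    labels: np.ndarray                  # (N,) strings from CLOUD_LABELS
    grid_spacing: float = 1.5

    def __post_init__(self):
        self.points = np.asarray(self.points, float).reshape(-1, 3)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.points) != len(self.labels):
            raise ValueError("points and labels length mismatch")

    def __len__(self):
        return len(self.points)

    def label_counts(self) -> dict:
        out: dict = {}
        for l in self.labels:
            out[l] = out.get(l, 0) + 1
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LabeledCloud":
        return LabeledCloud(self.points @ np.asarray(rotation).T + translation,
                            self.labels.copy(), self.grid_spacing)

    def write_xyz(self, path):
        lines = [f"{x:.3f}\t{y:.3f}\t{z:.3f}\t{l}"
                 for (x, y, z), l in zip(self.points, self.labels)]
        from pathlib import Path
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_xyz(cls, path, grid_spacing=1.5):
        from pathlib import Path
        pts, labs = [], []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            x, y, z, l = line.split("\t")
            pts.append([float(x), float(y), float(z)])
            labs.append(l)
        return cls(np.array(pts), np.array(labs, dtype=object), grid_spacing)


@dataclass
class CavityComparison:
    score: float
    rotation: np.ndarray | None = None
    translation: np.ndarray | None = None
    direction: int = 0            # which cloud was moved (1 or 2)
    low_confidence: bool = False


# ---------------------------------------------------------------------------
# Cloud generation

def _canonical_frame(lig_xyz: np.ndarray, ref_xyz: np.ndarray):
    """Complex-anchored orthonormal frame, centered on the ligand.

    Axes are the PCA directions of the ligand + site heavy atoms (the
    ligand alone can be collinear or planar, which leaves the frame
    underdetermined); signs are fixed by third moments with a first-moment
    fallback, and the triad is made right-handed. The frame moves rigidly
    with the complex, so the lattice anchored to it is equivariant."""
    center = lig_xyz.mean(axis=0)
    pts = np.vstack([lig_xyz, ref_xyz]) if len(ref_xyz) else lig_xyz
    centered = pts - center
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    axes = vecs[:, ::-1].T  # rows, descending variance
    for k in range(2):
        proj = centered @ axes[k]
        m3 = np.sum(proj ** 3)
        if abs(m3) < 1e-6 * max(1.0, np.abs(proj).max() ** 3):
            m3 = np.sum(proj)
        if m3 < 0:
            axes[k] = -axes[k]
    axes[2] = np.cross(axes[0], axes[1])
    return center, axes


def _pharmacophore_label(residue, atom) -> str:
    types = protein_atom_types(residue, atom)
    if "positive" in types:
        return "POSITIVE"
    if "negative" in types:
        return "NEGATIVE"
    if "donor" in types:
        return "HB_DONOR"
    if "acceptor" in types:
        return "HB_ACCEPTOR"
    if "aromatic" in types:
        return "AROMATIC"
    if "hydrophobic" in types:
        return "HYDROPHOBIC"
    return "DUMMY"


def generate_cavity_cloud(site: ProteinSite, ligand: LigandInstance,
                          config: PipelineConfig | None = None) -> LabeledCloud:
    """Lattice points near the fragment that are clash-free and buried.

    Keep a lattice point iff (a) >= clash_dist from every protein heavy
    atom, (b) <= cavity_fragment_dist (4 A) from a fragment heavy atom,
    (c) buried: >= cavity_burial_min_rays of the 14 lattice directions hit
    a protein heavy atom within cavity_burial_range.
    """
    config = config or PipelineConfig()
    if site.is_empty:
        raise ValueError("cannot build a cavity cloud from an empty site")
    lig_xyz = ligand.heavy_coords()
    prot = []
    prot_meta = []
    for res in site.residues:
        for a in res.heavy_atoms():
            prot.append(a.coords)
            prot_meta.append((res, a))
    prot_xyz = np.array(prot)
    center, axes = _canonical_frame(lig_xyz, prot_xyz)

    h = config.cavity_grid_spacing
    reach = config.cavity_fragment_dist
    lig_frame = (lig_xyz - center) @ axes.T
    lo = np.floor((lig_frame.min(axis=0) - reach) / h).astype(int)
    hi = np.ceil((lig_frame.max(axis=0) + reach) / h).astype(int)
    gx, gy, gz = [np.arange(a, b + 1) * h for a, b in zip(lo, hi)]
    grid = np.stack(np.meshgrid(gx, gy, gz, indexing="ij"), axis=-1).reshape(-1, 3)
    pts = grid @ axes + center  # back to world coordinates

    lig_tree = cKDTree(lig_xyz)
    prot_tree = cKDTree(prot_xyz)
    near_lig = lig_tree.query(pts)[0] <= reach
    clash_free = prot_tree.query(pts)[0] >= config.cavity_clash_dist
    pts = pts[near_lig & clash_free]
    if len(pts) == 0:
        return LabeledCloud(np.empty((0, 3)), np.empty(0, dtype=object), h)

    # buriedness: rays in the canonical frame so the test is equivariant
    dirs = _DIRS @ axes
    rng_r = config.cavity_burial_range
    keep = np.zeros(len(pts), dtype=bool)
    neighborhoods = prot_tree.query_ball_point(pts, rng_r + _RAY_RADIUS)
    for i, (x, nb) in enumerate(zip(pts, neighborhoods)):
        if not nb:
            continue
        rel = prot_xyz[nb] - x
        axial = rel @ dirs.T                      # (k, 14)
        rad2 = (rel ** 2).sum(1)[:, None] - axial ** 2
        hit = (axial > 0) & (axial <= rng_r) & (rad2 <= _RAY_RADIUS ** 2)
        keep[i] = int(hit.any(axis=0).sum()) >= config.cavity_burial_min_rays
    pts = pts[keep]
    if len(pts) == 0:
        return LabeledCloud(np.empty((0, 3)), np.empty(0, dtype=object), h)

    dist, idx = prot_tree.query(pts)
    labels = np.array([
        _pharmacophore_label(*prot_meta[j]) if d <= config.cavity_fragment_dist
        else "DUMMY"
        for d, j in zip(dist, idx)], dtype=object)
    return LabeledCloud(pts, labels, h)


# ---------------------------------------------------------------------------
# Registration

def _descriptors(pts: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-point histogram of neighbor labels x 2 distance bins (<2, 2-4 A)."""
    n = len(pts)
    lab_idx = np.array([CLOUD_LABELS.index(l) for l in labels])
    desc = np.zeros((n, len(CLOUD_LABELS) * 2))
    tree = cKDTree(pts)
    pairs = tree.query_pairs(4.0, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
        bins = (d >= 2.0).astype(int)
        for (i, j), b in zip(pairs, bins):
            desc[i, lab_idx[j] * 2 + b] += 1
            desc[j, lab_idx[i] * 2 + b] += 1
    return desc


def _kabsch(P: np.ndarray, Q: np.ndarray):
    """Rigid transform (R, t) minimizing ||R P + t - Q||."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, cq - R @ cp


def _kabsch_batch(P: np.ndarray, Q: np.ndarray):
    """Batched Kabsch for (T,3,3) triple sets; returns (T,3,3) R, (T,3) t."""
    cp = P.mean(axis=1, keepdims=True)
    cq = Q.mean(axis=1, keepdims=True)
    H = np.einsum("tki,tkj->tij", P - cp, Q - cq)
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("tij,tkj->tik", Vt.transpose(0, 2, 1), U))
    D = np.zeros_like(U)
    D[:, 0, 0] = D[:, 1, 1] = 1.0
    D[:, 2, 2] = np.sign(det)
    R = np.einsum("tij,tjk,tlk->til", Vt.transpose(0, 2, 1), D, U)
    t = cq[:, 0, :] - np.einsum("tij,tj->ti", R, cp[:, 0, :])
    return R, t


def _label_trees(pts, labels):
    trees = {}
    for l in set(labels.tolist()):
        mask = labels == l
        trees[l] = (cKDTree(pts[mask]), np.where(mask)[0])
    return trees


def _count_matched(moved_pts, moved_labels, trees, cutoff):
    """How many points of (moved_pts, labels) have a same-label partner in
    the cloud indexed by ``trees`` within ``cutoff``."""
    n = 0
    for l, (tree, _) in trees.items():
        mask = moved_labels == l
        if not mask.any():
            continue
        d, _ = tree.query(moved_pts[mask], distance_upper_bound=cutoff)
        n += int(np.sum(np.isfinite(d)))
    return n


def _register_direction(A: LabeledCloud, B: LabeledCloud, rng,
                        config: PipelineConfig):
    """Move A onto B; return (R, t, matched count of the smaller cloud)."""
    nA, nB = len(A), len(B)
    labels_shared = set(A.labels.tolist()) & set(B.labels.tolist())
    if not labels_shared:
        return None
    descA = _descriptors(A.points, A.labels)
    descB = _descriptors(B.points, B.labels)
    treesB = _label_trees(B.points, B.labels)
    treesA = _label_trees(A.points, A.labels)

    # candidate correspondences: same label, closest descriptors (top 5)
    cand = [None] * nA
    for l, (tree, idxB) in treesB.items():
        maskA = np.where(A.labels == l)[0]
        if not len(maskA):
            continue
        dd = np.abs(descA[maskA][:, None, :] - descB[idxB][None, :, :]).sum(-1)
        order = np.argsort(dd, axis=1)[:, :5]
        for row, i in enumerate(maskA):
            cand[i] = idxB[order[row]]
    valid = [i for i in range(nA) if cand[i] is not None and len(cand[i])]
    if len(valid) < 3:
        return None
    valid = np.array(valid)

    T = config.ransac_iterations
    src_idx = np.stack([rng.choice(valid, size=3, replace=False)
                        for _ in range(T)])
    dst_idx = np.stack([
        [cand[i][rng.integers(len(cand[i]))] for i in trip]
        for trip in src_idx])
    P = A.points[src_idx]          # (T,3,3)
    Q = B.points[dst_idx]

    # cheap gates: non-degenerate source triangles, compatible edge lengths
    def pairdists(X):
        return np.stack([np.linalg.norm(X[:, 0] - X[:, 1], axis=1),
                         np.linalg.norm(X[:, 0] - X[:, 2], axis=1),
                         np.linalg.norm(X[:, 1] - X[:, 2], axis=1)], axis=1)
    dP, dQ = pairdists(P), pairdists(Q)
    distinct_dst = np.array([len(set(t)) == 3 for t in dst_idx])
    ok = (dP.min(axis=1) > 1e-6) & (np.abs(dP - dQ).max(axis=1) <= 1.5) & \
        distinct_dst
    if not ok.any():
        return None
    R, t = _kabsch_batch(P[ok], Q[ok])
    T_ok = len(R)

    # score every hypothesis at once on a subsample of A (vectorized
    # same-label nearest-neighbour counting), then keep the best transform
    sub = valid if len(valid) <= 24 else rng.choice(valid, 24, replace=False)
    movedS = np.einsum("tij,nj->tni", R, A.points[sub]) + t[:, None, :]
    counts = np.zeros(T_ok, dtype=int)
    sub_labels = A.labels[sub]
    for l, (tree, _) in treesB.items():
        mask = sub_labels == l
        if not mask.any():
            continue
        q = movedS[:, mask, :].reshape(-1, 3)
        d, _ = tree.query(q, distance_upper_bound=config.cavity_match_dist)
        counts += np.isfinite(d).reshape(T_ok, -1).sum(axis=1)
    k = int(np.argmax(counts))
    R0, t0 = R[k], t[k]

    # label-constrained ICP refinement
    for _ in range(config.icp_iterations):
        moved = A.points @ R0.T + t0
        src, dst = [], []
        for l, (tree, idxB) in treesB.items():
            maskA = np.where(A.labels == l)[0]
            if not len(maskA):
                continue
            d, j = tree.query(moved[maskA], distance_upper_bound=3.0)
            hit = np.isfinite(d)
            src.extend(maskA[hit])
            dst.extend(idxB[j[hit]])
        if len(src) < 3:
            break
        Rn, tn = _kabsch(A.points[np.array(src)], B.points[np.array(dst)])
        if np.allclose(Rn, R0, atol=1e-9) and np.allclose(tn, t0, atol=1e-9):
            break
        R0, t0 = Rn, tn

    moved = A.points @ R0.T + t0
    if nA <= nB:
        matched = _count_matched(moved, A.labels, treesB,
                                 config.cavity_match_dist)
    else:
        # count over B, the smaller cloud, against the transformed A
        trees_moved = _label_trees(moved, A.labels)
        matched = _count_matched(B.points, B.labels, trees_moved,
                                 config.cavity_match_dist)
    return R0, t0, matched


def _typed(cloud: LabeledCloud) -> LabeledCloud:
    mask = cloud.labels != "DUMMY"
    return LabeledCloud(cloud.points[mask], cloud.labels[mask],
                        cloud.grid_spacing)


def cavity_similarity(c1: LabeledCloud, c2: LabeledCloud,
                      seed: int = 0,
                      config: PipelineConfig | None = None) -> CavityComparison:
    """Best-of-both-directions registration score in [0, 1].

    Only pharmacophore-typed points take part in matching and in the
    normalization; DUMMY points describe shape but carry no recognizable
    chemistry, so two unrelated pockets never look alike through their
    untyped filler. Identical clouds score 1.0; clouds with disjoint label
    sets score 0.0. Clouds with < 3 typed points fall back to label-bag
    overlap (low confidence).
    """
    config = config or PipelineConfig()
    c1, c2 = _typed(c1), _typed(c2)
    n1, n2 = len(c1), len(c2)
    if n1 == 0 or n2 == 0:
        return CavityComparison(0.0, low_confidence=True)
    smaller = min(n1, n2)
    if n1 < 3 or n2 < 3:
        cnt1, cnt2 = c1.label_counts(), c2.label_counts()
        overlap = sum(min(cnt1.get(l, 0), cnt2.get(l, 0)) for l in cnt1)
        return CavityComparison(overlap / smaller, low_confidence=True)

    rng = np.random.default_rng(seed)
    best = CavityComparison(0.0)
    r12 = _register_direction(c1, c2, rng, config)
    if r12 is not None:
        R, t, m = r12
        best = CavityComparison(m / smaller, R, t, direction=1)
    r21 = _register_direction(c2, c1, rng, config)
    if r21 is not None:
        R, t, m = r21
        if m / smaller > best.score:
            best = CavityComparison(m / smaller, R, t, direction=2)
    best.score = float(min(1.0, best.score))
    return best


def cavity_score_matrix(clouds, seed: int = 0,
                        config: PipelineConfig | None = None) -> np.ndarray:
    n = len(clouds)
    S = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        S[i, j] = S[j, i] = cavity_similarity(
            clouds[i], clouds[j], seed=seed, config=config).score
    return S


def count_cavities(clouds, config: PipelineConfig | None = None,
                   seed: int | None = None) -> int:
    """Distinct binding cavities: DBSCAN on 1 - score, clustering pairs
    with score >= cavity_score_threshold (0.47); singletons count as one
    cavity each."""
    from .modeclust import dbscan, _resolve_noise

    config = config or PipelineConfig()
    if len(clouds) == 0:
        raise ValueError("need at least one cloud")
    if len(clouds) == 1:
        return 1
    if seed is None:
        seed = config.random_seed
    S = cavity_score_matrix(clouds, seed=seed, config=config)
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    eps = (config.cavity_score_threshold if config.literal_eps
           else 1.0 - config.cavity_score_threshold + 1e-9)
    labels = _resolve_noise(dbscan(D, eps=eps,
                                   min_samples=config.cluster_min_samples))
    return int(len(set(labels.tolist())))
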