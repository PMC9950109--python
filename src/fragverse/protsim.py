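"""Sequence relatedness of proteins binding the same fragment.

Local Smith-Waterman alignment (BLOSUM62, affine gaps 10/0.5, emulating
EMBOSS water), identity-based DBSCAN grouping at the >=90% ("same protein
or close homolog") and >=25% ("distant homolog") levels, and least-squares
backbone superposition (Kabsch) for RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .structio import Complex, ProteinSite, THREE_TO_ONE

__all__ = [
    "AlignmentResult", "smith_waterman", "site_chain_sequence",
    "cluster_by_identity", "kabsch_superpose", "identity_matrix",
]


@dataclass
class AlignmentResult:
    aligned_length: int        # alignment columns, gaps included
    identity_fraction: float   # identical pairs / aligned columns
    score: float


_ALIGNER = None


def _aligner():
    global _ALIGNER
    if _ALIGNER is None:
        mat = substitution_matrices.load("BLOSUM62")
        alpha = mat.alphabet
        arr = np.array(mat)
        if "X" in alpha:  # X tolerated, scored 0 against everything
            xi = alpha.index("X")
            arr[xi, :] = 0.0
            arr[:, xi] = 0.0
        mat = substitution_matrices.Array(alphabet=alpha, dims=2, data=arr)
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = mat
        a.open_gap_score = -10.0
        a.extend_gap_score = -0.5
        _ALIGNER = a
    return _ALIGNER


def smith_waterman(s1: str, s2: str) -> AlignmentResult:
    """Optimal local alignment under BLOSUM62 with affine gap penalties
    (open 10, extend 0.5). Identity is counted over aligned columns,
    gap columns included (EMBOSS convention)."""
    s1, s2 = s1.upper(), s2.upper()
    if not s1 or not s2:
        return AlignmentResult(0, 0.0, 0.0)
    aligner = _aligner()
    score = aligner.score(s1, s2)
    if score <= 0:
        return AlignmentResult(0, 0.0, 0.0)
    aln = aligner.align(s1, s2)[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    ident = counts.identities / length if length else 0.0
    return AlignmentResult(int(length), float(ident), float(score))


def site_chain_sequence(cplx: Complex, site: ProteinSite):
    """Sequence of the chain holding the majority of the site residues.

    Returns (sequence, chain_id, flagged); ``flagged`` is True when no
    chain holds more than half of the site and the plurality chain was
    taken (ties broken by chain id).
    """
    if site.is_empty:
        raise ValueError("empty site")
    counts = site.chain_counts()
    total = sum(counts.values())
    best_chain = sorted(counts, key=lambda c: (-counts[c], c))[0]
    flagged = counts[best_chain] * 2 <= total
    seq = []
    for r in sorted((r for r in cplx.protein_residues
                     if r.chain_id == best_chain),
                    key=lambda r: r.seqnum):
        seq.append(THREE_TO_ONE.get(r.name, "X"))
    return "".join(seq), best_chain, flagged


def identity_matrix(sequences) -> tuple:
    """Pairwise identity and aligned-length matrices from local alignments."""
    n = len(sequences)
    ident = np.eye(n)
    alen = np.zeros((n, n), dtype=int)
    for i in range(n):
        alen[i, i] = len(sequences[i])
        for j in range(i + 1, n):
            r = smith_waterman(sequences[i], sequences[j])
            ident[i, j] = ident[j, i] = r.identity_fraction
            alen[i, j] = alen[j, i] = r.aligned_length
    return ident, alen


def cluster_by_identity(identities: np.ndarray, aligned_lengths: np.ndarray,
                        eps: float, min_alignment_len: int = 100,
                        min_samples: int = 2) -> np.ndarray:
    """DBSCAN on distance = 1 - identity; pairs whose alignment is shorter
    than ``min_alignment_len`` columns are forced to distance 1. Noise
    points get their own singleton labels. eps = 0.10 groups >= 90%
    identity, eps = 0.75 groups >= 25%."""
    from .modeclust import dbscan, _resolve_noise

    D = 1.0 - np.asarray(identities, dtype=float)
    short = np.asarray(aligned_lengths) < min_alignment_len
    D[short] = 1.0
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, D.T)  # keep symmetric after the short-alignment mask
    if len(D) == 1:
        return np.array([0])
    return _resolve_noise(dbscan(D, eps=eps, min_samples=min_samples))


def kabsch_superpose(coordsA, coordsB):
    """Least-squares rigid superposition of matched coordinate sets.

    Returns (rotation, translation, rmsd) with ``R @ a + t ~ b``.
    Requires >= 3 matched points.
    """
    A = np.asarray(coordsA, float)
    B = np.asarray(coordsB, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must be matched (N,3) arrays")
    if len(A) < 3:
        raise ValueError("need >= 3 matched points")
    from .cavity import _kabsch

    R, t = _kabsch(A, B)
    moved = A @ R.T + t
    rmsd = float(np.sqrt(np.mean(((moved - B) ** 2).sum(axis=1))))
    return R, t, rmsd


def backbone_coords(cplx: Complex, chain_id: str,
                    atom_names=("N", "CA", "C", "O")) -> dict:
    """Backbone atom coordinates keyed by (seqnum, atom_name) for one chain."""
    out = {}
    for r in cplx.protein_residues:
        if r.chain_id != chain_id:
            continue
        for name in atom_names:
            a = r.get(name)
            if a is not None:
                out[(r.seqnum, name)] = a.coords
    return out
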