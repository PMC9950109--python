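"""Subgraph matching kernel, DBSCAN wrapper, mode counting and merging."""

import itertools

import numpy as np
import pytest

from conftest import make_graph, random_graph
from fragverse.modeclust import (
    ModeClustering, SmkParams, count_binding_modes, dbscan, graph_included,
    merge_included_clusters, similarity_matrix, smk_raw_kernel,
    smk_similarity, symmetry_rmsd)
from fragverse.synthgen import synth_mode_family, complex_to_graph


def smk_oracle(g1, g2, max_nodes=3, dmax=1.0):
    """Independent brute force: recursively enumerate every injective
    label-preserving partial mapping (as an explicit dict, one node at a
    time) and sum the edge-kernel products, without any pruning."""
    lab1, lab2 = g1.labels, g2.labels
    d1, d2 = g1.distance_matrix(), g2.distance_matrix()
    total = 0.0
    for k in range(1, max_nodes + 1):
        for subset in itertools.combinations(range(len(lab1)), k):
            for target in itertools.permutations(range(len(lab2)), k):
                mapping = dict(zip(subset, target))
                if any(lab1[i] != lab2[j] for i, j in mapping.items()):
                    continue
                w = 1.0
                for (i1, j1), (i2, j2) in itertools.combinations(
                        mapping.items(), 2):
                    w *= max(0.0, 1.0 - abs(d1[i1, i2] - d2[j1, j2]) / dmax)
                total += w
    return total


class TestSmk:
    def test_worked_example(self):
        g1 = make_graph(["HYDROPHOBIC"] * 2, [[0, 0, 0], [2, 0, 0]])
        g2 = make_graph(["HYDROPHOBIC"] * 2, [[0, 0, 0], [2.5, 0, 0]])
        assert smk_raw_kernel(g1, g2) == pytest.approx(5.0)
        assert smk_raw_kernel(g1, g1) == pytest.approx(6.0)
        assert smk_similarity(g1, g2) == pytest.approx(5 / 6)

    def test_identical_graphs_score_one(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            g = random_graph(rng, max_nodes=5)
            if g.n_nodes:
                assert smk_similarity(g, g) == pytest.approx(1.0)

    def test_disjoint_labels_zero(self):
        g1 = make_graph(["A", "A"], [[0, 0, 0], [1, 0, 0]])
        g2 = make_graph(["B", "C"], [[0, 0, 0], [1, 0, 0]])
        assert smk_similarity(g1, g2) == 0.0

    def test_empty_graph_zero(self):
        g1 = make_graph([], [])
        g2 = make_graph(["A"], [[0, 0, 0]])
        assert smk_similarity(g1, g2) == 0.0
        assert smk_similarity(g1, g1) == 0.0

    def test_matches_oracle_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            g1, g2 = random_graph(rng), random_graph(rng)
            assert smk_raw_kernel(g1, g2) == pytest.approx(
                smk_oracle(g1, g2), abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            g1, g2 = random_graph(rng), random_graph(rng)
            assert smk_similarity(g1, g2) == pytest.approx(
                smk_similarity(g2, g1), abs=1e-12)

    def test_bounded_unit_interval(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            s = smk_similarity(random_graph(rng), random_graph(rng))
            assert 0.0 <= s <= 1.0

    def test_monotone_under_edge_perturbation(self):
        base = make_graph(["A", "A"], [[0, 0, 0], [2.0, 0, 0]])
        prev = 1.0
        for delta in np.linspace(0, 1.5, 12):
            g = make_graph(["A", "A"], [[0, 0, 0], [2.0 + delta, 0, 0]])
            s = smk_similarity(base, g)
            assert s <= prev + 1e-12
            prev = s
        # once the edge kernel floors, only node terms remain
        far = make_graph(["A", "A"], [[0, 0, 0], [4.0, 0, 0]])
        assert smk_similarity(base, far) == pytest.approx(4 / 6)


class TestDbscan:
    def test_pair_within_eps(self):
        D = np.array([[0, 0.1], [0.1, 0]])
        labels = dbscan(D, eps=0.23, min_samples=2)
        assert labels[0] == labels[1] != -1

    def test_pair_plus_noise(self):
        D = np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        labels = dbscan(D, eps=0.23, min_samples=2)
        assert labels[0] == labels[1] != -1
        assert labels[2] == -1

    def test_all_noise(self):
        D = 1 - np.eye(3)
        assert list(dbscan(D, eps=0.23, min_samples=2)) == [-1, -1, -1]

    def test_asymmetric_rejected(self):
        D = np.array([[0, 0.1], [0.5, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            dbscan(D, eps=0.2, min_samples=2)

    def test_negative_rejected(self):
        D = np.array([[0, -0.1], [-0.1, 0]])
        with pytest.raises(ValueError):
            dbscan(D, eps=0.2, min_samples=2)


class TestCountBindingModes:
    def test_copies_of_one_graph(self):
        g = make_graph(["A", "B"], [[0, 0, 0], [2, 0, 0]])
        mc = count_binding_modes([g] * 5)
        assert mc.n_modes == 1

    def test_two_dissimilar_graphs_two_modes(self):
        # similarity 4/6 between these graphs: distance 1/3 > 0.23
        g1 = make_graph(["A", "A"], [[0, 0, 0], [2.0, 0, 0]])
        g2 = make_graph(["A", "A"], [[0, 0, 0], [4.0, 0, 0]])
        assert smk_similarity(g1, g2) == pytest.approx(4 / 6)
        assert count_binding_modes([g1, g2]).n_modes == 2

    def test_recovers_planted_modes(self):
        cxs, truth = synth_mode_family(3, 4, sigma=0.05, seed=9)
        graphs = [complex_to_graph(c) for c in cxs]
        assert count_binding_modes(graphs).n_modes == 3


class TestGraphIncluded:
    def test_self_inclusion(self):
        g = make_graph(["A", "B", "C"],
                       [[0, 0, 0], [3, 0, 0], [0, 4, 0]])
        assert graph_included(g, g)

    def test_single_node_inclusion(self):
        small = make_graph(["HB"], [[0, 0, 0]])
        big = make_graph(["HB", "X", "Y"],
                         [[5, 5, 5], [8, 5, 5], [5, 9, 5]])
        assert graph_included(small, big)

    def test_edge_tolerance(self):
        small = make_graph(["A", "B"], [[0, 0, 0], [2.0, 0, 0]])
        big = make_graph(["A", "B"], [[0, 0, 0], [3.0, 0, 0]])
        assert not graph_included(small, big, edge_tol=0.5)
        assert graph_included(small, big, edge_tol=1.1)

    def test_label_mismatch(self):
        small = make_graph(["A"], [[0, 0, 0]])
        big = make_graph(["B", "C"], [[0, 0, 0], [2, 0, 0]])
        assert not graph_included(small, big)


class TestMergeIncludedClusters:
    def test_merges_included_singleton(self):
        small = make_graph(["HB"], [[0, 0, 0]])
        big = make_graph(["HB", "X", "Y"], [[0, 0, 0], [4, 0, 0], [0, 5, 0]])
        mc = merge_included_clusters(np.array([0, 1]), [small, big])
        assert mc.n_modes == 1
        assert mc.merged_pairs

    def test_disjoint_labels_unchanged(self):
        a = make_graph(["A"], [[0, 0, 0]])
        b = make_graph(["B"], [[0, 0, 0]])
        mc = merge_included_clusters(np.array([0, 1]), [a, b])
        assert mc.n_modes == 2

    def test_transitive_chain_collapses(self):
        a = make_graph(["A"], [[0, 0, 0]])
        ab = make_graph(["A", "B"], [[0, 0, 0], [3, 0, 0]])
        abc = make_graph(["A", "B", "C"],
                         [[0, 0, 0], [3, 0, 0], [0, 4, 0]])
        mc = merge_included_clusters(np.array([0, 1, 2]), [a, ab, abc])
        assert mc.n_modes == 1

    def test_never_increases_and_idempotent(self):
        rng = np.random.default_rng(21)
        graphs = [random_graph(rng, max_nodes=4) for _ in range(6)]
        graphs = [g for g in graphs if g.n_nodes] or \
            [make_graph(["A"], [[0, 0, 0]])]
        labels = np.arange(len(graphs))
        mc1 = merge_included_clusters(labels, graphs)
        assert mc1.n_modes <= len(graphs)
        mc2 = merge_included_clusters(mc1.labels, graphs)
        assert mc2.n_modes == mc1.n_modes

    def test_empty_graph_does_not_bridge(self):
        empty = make_graph([], [])
        a = make_graph(["A"], [[0, 0, 0]])
        b = make_graph(["B"], [[0, 0, 0]])
        mc = merge_included_clusters(np.array([0, 1, 2]), [empty, a, b])
        assert mc.n_modes == 3


class TestSymmetryRmsd:
    def _benzene(self, rotate_deg=0.0):
        from rdkit import Chem
        from rdkit.Chem import AllChem

        mol = Chem.AddHs(Chem.MolFromSmiles("c1ccccc1"))
        AllChem.EmbedMolecule(mol, randomSeed=7)
        return Chem.RemoveHs(mol)

    def test_identical_conformers_zero(self):
        mol = self._benzene()
        assert symmetry_rmsd(mol, mol) == pytest.approx(0.0, abs=1e-6)

    def test_inplane_rotation_zero_with_symmetry(self):
        from rdkit import Chem
        mol = self._benzene()
        rot = Chem.Mol(mol)
        conf = rot.GetConformer()
        th = np.radians(60)
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        xyz = conf.GetPositions() @ R.T
        for i, p in enumerate(xyz):
            conf.SetAtomPosition(i, p.tolist())
        assert symmetry_rmsd(mol, rot) == pytest.approx(0.0, abs=1e-3)

    def test_translation_removed(self):
        from rdkit import Chem
        mol = self._benzene()
        moved = Chem.Mol(mol)
        conf = moved.GetConformer()
        for i in range(moved.GetNumAtoms()):
            p = conf.GetAtomPosition(i)
            conf.SetAtomPosition(i, (p.x + 5, p.y, p.z))
        assert symmetry_rmsd(mol, moved) == pytest.approx(0.0, abs=1e-6)

    def test_different_species_rejected(self):
        from rdkit import Chem
        from rdkit.Chem import AllChem
        m1 = self._benzene()
        m2 = Chem.AddHs(Chem.MolFromSmiles("c1ccncc1"))
        AllChem.EmbedMolecule(m2, randomSeed=7)
        with pytest.raises(ValueError):
            symmetry_rmsd(m1, Chem.RemoveHs(m2))
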