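"""Cavity cloud generation, registration scoring, cavity counting."""

import numpy as np
import pytest

from fragverse.cavity import (LabeledCloud, cavity_similarity, count_cavities,
                              generate_cavity_cloud)
from fragverse.config import PipelineConfig
from fragverse.structio import (Atom, Complex, LigandInstance, ProteinSite,
                                Residue, ensure_hydrogens, extract_site)
from fragverse.synthgen import (MODE_SIGNATURES, _random_rotation,
                                layout_interactions, synth_cavity_set,
                                synth_complex)


def _fibonacci(n):
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1)


def _enclosed_complex(seed=0):
    spec = layout_interactions(*MODE_SIGNATURES[0])
    return synth_complex(spec, seed=seed, enclose=True)


def _cloud_of(cplx, config):
    prep = ensure_hydrogens(cplx)
    lig = prep.ligand_instances[0]
    env = extract_site(prep, lig, config.cavity_site_radius)
    return generate_cavity_cloud(env, lig, config), prep, lig


class TestGenerateCloud:
    def test_points_near_fragment_and_clash_free(self, config):
        cloud, prep, lig = _cloud_of(_enclosed_complex(), config)
        assert len(cloud) > 0
        lig_xyz = lig.heavy_coords()
        prot_xyz = np.array([a.coords for r in prep.protein_residues
                             for a in r.heavy_atoms()])
        for p in cloud.points:
            assert np.min(np.linalg.norm(lig_xyz - p, axis=1)) <= \
                config.cavity_fragment_dist + 1e-9
            assert np.min(np.linalg.norm(prot_xyz - p, axis=1)) >= \
                config.cavity_clash_dist - 1e-9

    def test_open_solvent_empty(self, config):
        # fragment with no enclosing protein: buriedness fails everywhere
        spec = layout_interactions(*MODE_SIGNATURES[0])
        cplx = synth_complex(spec, enclose=False)
        cloud, _, _ = _cloud_of(cplx, config)
        assert len(cloud) == 0

    def test_carboxylate_site_labels_negative(self, config):
        lig = LigandInstance("LIG", 1, atoms=[
            Atom("C1", "C", [0, 0, 0]), Atom("C2", "C", [1.5, 0, 0])])
        residues = [
            Residue("A", i + 1, "ASP", [Atom("OD1", "O", [0.75, 0, 0] + 5.5 * d)])
            for i, d in enumerate(_fibonacci(200))]
        cplx = Complex("T", protein_residues=residues,
                       ligand_instances=[lig])
        site = ProteinSite(residues, "T", ("LIG", 1))
        cloud = generate_cavity_cloud(site, lig, config)
        assert len(cloud) > 0
        non_dummy = [l for l in cloud.labels if l != "DUMMY"]
        assert non_dummy and all(l == "NEGATIVE" for l in non_dummy)

    def test_equivariant_under_rigid_motion(self, config):
        cplx = _enclosed_complex(seed=4)
        ref, _, _ = _cloud_of(cplx, config)
        rng = np.random.default_rng(12)
        R = _random_rotation(rng)
        t = rng.uniform(-15, 15, 3)
        moved = _enclosed_complex(seed=4)
        for res in moved.protein_residues:
            for a in res.atoms:
                a.coords = R @ a.coords + t
        for a in moved.ligand_instances[0].atoms:
            a.coords = R @ a.coords + t
        got, _, _ = _cloud_of(moved, config)
        assert len(got) == len(ref)
        back = (got.points - t) @ R  # inverse rotation
        order_ref = np.lexsort(ref.points.T)
        order_got = np.lexsort(back.T)
        assert np.allclose(back[order_got], ref.points[order_ref], atol=1e-6)
        assert list(got.labels[order_got]) == list(ref.labels[order_ref])

    def test_lattice_points(self, config):
        cloud, _, _ = _cloud_of(_enclosed_complex(), config)
        # points lie on a regular lattice: pairwise differences along the
        # lattice axes are integer multiples of the spacing
        d = cloud.points - cloud.points[0]
        # recover lattice axes from the 3 shortest nonzero difference vectors
        assert len(cloud) > 10
        # spacing divides all coordinates in the canonical frame; check via
        # distances: the minimum nonzero inter-point distance is the spacing
        from scipy.spatial.distance import pdist
        dists = pdist(cloud.points)
        assert np.min(dists[dists > 1e-6]) == pytest.approx(
            config.cavity_grid_spacing, abs=1e-6)


class TestCavitySimilarity:
    def test_self_score_one(self):
        clouds, _, _ = synth_cavity_set(1, 1, seed=3)
        cmp = cavity_similarity(clouds[0], clouds[0], seed=1)
        assert cmp.score == pytest.approx(1.0)

    def test_rigid_copy_recovers_transform(self):
        clouds, _, tfs = synth_cavity_set(1, 2, seed=11)
        c0, c1 = clouds
        (R0, t0), (R1, t1) = tfs
        cmp = cavity_similarity(c0, c1, seed=2)
        assert cmp.score >= 0.95
        # ground-truth map c0 -> c1
        R_true = R1 @ R0.T
        t_true = t1 - R_true @ t0
        if cmp.direction == 1:
            moved = c0.points @ cmp.rotation.T + cmp.translation
        else:
            moved = np.linalg.solve(
                cmp.rotation, (c0.points - cmp.translation).T).T
        truth = c0.points @ R_true.T + t_true
        rmsd = np.sqrt(np.mean(((moved - truth) ** 2).sum(axis=1)))
        assert rmsd <= 0.5

    def test_disjoint_labels_zero(self):
        a = LabeledCloud(np.random.default_rng(0).uniform(-5, 5, (20, 3)),
                         np.array(["HYDROPHOBIC"] * 20, dtype=object))
        b = LabeledCloud(np.random.default_rng(1).uniform(-5, 5, (20, 3)),
                         np.array(["NEGATIVE"] * 20, dtype=object))
        assert cavity_similarity(a, b, seed=0).score == 0.0

    def test_invariant_under_rigid_motion(self):
        clouds, _, _ = synth_cavity_set(2, 1, seed=21)
        a, b = clouds
        base = cavity_similarity(a, b, seed=3).score
        rng = np.random.default_rng(9)
        for trial in range(3):
            R = _random_rotation(rng)
            t = rng.uniform(-25, 25, 3)
            moved = a.transformed(R, t)
            s = cavity_similarity(moved, b, seed=3).score
            assert abs(s - base) <= 0.02

    def test_score_in_unit_interval(self):
        clouds, _, _ = synth_cavity_set(3, 2, seed=5, label_noise=0.1)
        for i in range(len(clouds)):
            for j in range(i, len(clouds)):
                s = cavity_similarity(clouds[i], clouds[j], seed=0).score
                assert 0.0 <= s <= 1.0

    def test_tiny_cloud_low_confidence(self):
        a = LabeledCloud(np.array([[0., 0, 0], [2, 0, 0]]),
                         np.array(["HYDROPHOBIC", "HB_DONOR"], dtype=object))
        cmp = cavity_similarity(a, a, seed=0)
        assert cmp.low_confidence
        assert cmp.score == pytest.approx(1.0)


class TestCountCavities:
    def test_duplicated_cloud_one_cavity(self):
        clouds, _, _ = synth_cavity_set(1, 1, seed=2)
        assert count_cavities(clouds * 3, seed=1) == 1

    def test_planted_environments_recovered(self):
        clouds, truth, _ = synth_cavity_set(3, 2, seed=13)
        assert count_cavities(clouds, seed=1) == 3

    def test_overlapping_subsets_cluster_together(self):
        # two half-overlapping views of one environment behave like
        # overlapping sub-sites of a pocket: they stay in one cluster
        clouds, _, _ = synth_cavity_set(1, 1, seed=17, n_points=60)
        base = clouds[0]
        order = np.argsort(base.points[:, 0])
        n = len(order)
        a_idx = order[: int(0.7 * n)]
        b_idx = order[int(0.3 * n):]
        a = LabeledCloud(base.points[a_idx], base.labels[a_idx])
        b = LabeledCloud(base.points[b_idx], base.labels[b_idx])
        assert cavity_similarity(a, b, seed=0).score >= 0.47
        assert count_cavities([a, b], seed=0) == 1
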