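"""Structure reading/writing, site extraction, protonation and RSCC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fragverse.structio import (
    Atom, Residue, Complex, LigandInstance, classify_rscc, ensure_hydrogens,
    extract_site, parse_validation_rscc, read_mol2, read_structure,
    write_mol2, StructureError)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
HETATM    4  C1  LIG L   1       5.000   0.000   0.000  1.00  0.00           C
HETATM    5  O1  LIG L   1       6.400   0.000   0.000  1.00  0.00           O
END
"""


def _residue(chain, num, name, coords_by_atom):
    return Residue(chain, num, name,
                   [Atom(n, n[0], c) for n, c in coords_by_atom.items()])


class TestReadStructure:
    def test_minimal_pdb_counts(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        cplx = read_structure(p)
        assert len(cplx.protein_residues) == 1
        lig = cplx.ligand_instances
        assert len(lig) == 1
        assert lig[0].het_code == "LIG"
        assert len(lig[0].heavy_atoms()) == 2

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(StructureError):
            read_structure(tmp_path / "nope.pdb")

    def test_no_protein_raises(self, tmp_path):
        p = tmp_path / "ligonly.pdb"
        p.write_text("\n".join(MINIMAL_PDB.splitlines()[3:]) + "\n")
        with pytest.raises(StructureError, match="no protein"):
            read_structure(p)

    def test_waters_excluded(self, tmp_path):
        text = MINIMAL_PDB.replace(
            "END",
            "HETATM    6  O   HOH W   1       9.000   0.000   0.000"
            "  1.00  0.00           O\nEND")
        p = tmp_path / "wat.pdb"
        p.write_text(text)
        cplx = read_structure(p)
        assert all(r.name != "HOH" for r in cplx.protein_residues)
        assert all(l.het_code != "HOH" for l in cplx.ligand_instances)


class TestMol2RoundTrip:
    def test_roundtrip_preserves_atoms(self, tmp_path):
        atoms = [Atom("C1", "C", [0.1234, -1.5, 2.25]),
                 Atom("N1", "N", [1.5, 0.0, -3.75], formal_charge=1),
                 Atom("O1", "O", [-2.0, 4.125, 0.5])]
        bonds = [(0, 1, 1), (1, 2, 1)]
        path = tmp_path / "frag.mol2"
        write_mol2(path, atoms, bonds, mol_name="FRG")
        back = read_mol2(path)
        lig = back.ligand_instances[0]
        assert len(lig.atoms) == 3
        assert [a.element for a in lig.atoms] == ["C", "N", "O"]
        got = np.array([a.coords for a in lig.atoms])
        want = np.array([a.coords for a in atoms])
        assert np.allclose(got, want, atol=1e-3)
        assert lig.atoms[1].formal_charge == 1
        assert len(lig.bonds) == 2

    def test_site_roundtrip(self, tmp_path):
        res = _residue("A", 7, "SER",
                       {"N": [0, 0, 0], "CA": [1.4, 0, 0], "OG": [2, 1, 0]})
        atoms = list(res.atoms)
        subst = {i: (7, "SER7") for i in range(len(atoms))}
        path = tmp_path / "site.mol2"
        write_mol2(path, atoms, substructures=subst, mol_name="SITE")
        back = read_mol2(path)
        assert len(back.protein_residues) == 1
        r = back.protein_residues[0]
        assert r.name == "SER" and r.seqnum == 7
        assert len(r.atoms) == 3


class TestExtractSite:
    def _complex(self, positions):
        residues = [_residue("A", i + 1, "ALA", {"CA": p})
                    for i, p in enumerate(positions)]
        lig = LigandInstance("LIG", 1,
                             atoms=[Atom("C1", "C", [0, 0, 0]),
                                    Atom("C2", "C", [1.5, 0, 0])])
        cplx = Complex("T", protein_residues=residues,
                       ligand_instances=[lig])
        return cplx, lig

    def test_distance_threshold(self):
        cplx, lig = self._complex([[5.0, 0, 0], [-8.0, 0, 0]])
        site = extract_site(cplx, lig, 6.5)
        assert [r.seqnum for r in site.residues] == [1]

    def test_degenerate_radius_flags_empty(self):
        cplx, lig = self._complex([[5.0, 0, 0]])
        site = extract_site(cplx, lig, 0.1)
        assert site.is_empty

    def test_planted_count(self):
        inside = [[3, 0, 0], [0, 4, 0], [0, 0, 5], [-6, 0, 0]]
        outside = [[10, 0, 0], [0, -12, 0]]
        cplx, lig = self._complex(inside + outside)
        site = extract_site(cplx, lig, 6.5)
        assert len(site.residues) == 4

    @given(st.lists(st.floats(0.5, 15), min_size=1, max_size=8),
           st.floats(0.5, 12), st.floats(0.5, 12))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_radius(self, dists, r1, r2):
        r1, r2 = min(r1, r2), max(r1, r2)
        cplx, lig = self._complex([[d, 0, 0] for d in dists])
        small = {r.seqnum for r in extract_site(cplx, lig, r1).residues}
        large = {r.seqnum for r in extract_site(cplx, lig, r2).residues}
        assert small <= large


class TestRscc:
    @pytest.mark.parametrize("value,expected", [
        (0.95, "FIT"), (0.901, "FIT"),
        (0.90, "PARTIAL"), (0.80, "PARTIAL"), (0.85, "PARTIAL"),
        (0.79, "POOR"), (-0.5, "POOR"),
    ])
    def test_classes(self, value, expected):
        assert classify_rscc(value) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_rscc(1.2)

    @given(st.floats(-1, 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_partition_no_gaps(self, x):
        assert classify_rscc(x) in {"FIT", "PARTIAL", "POOR"}

    def _xml(self, tmp_path, rows, lig_row=None):
        body = "".join(
            f'<ModelledSubgroup chain="{c}" resnum="{n}" resname="{r}" '
            f'rscc="{v}"/>' for c, n, r, v in rows)
        if lig_row:
            c, n, r, v = lig_row
            body += (f'<ModelledSubgroup chain="{c}" resnum="{n}" '
                     f'resname="{r}" rscc="{v}"/>')
        path = tmp_path / "val.xml"
        path.write_text(f"<wwPDB-validation-information><Entry>{body}"
                        "</Entry></wwPDB-validation-information>")
        return path

    def _site(self, keys):
        residues = [_residue(c, n, r, {"CA": [0, 0, 0]}) for c, n, r in keys]
        from fragverse.structio import ProteinSite
        return ProteinSite(residues, "T", ("LIG", 1))

    def test_site_mean(self, tmp_path):
        keys = [("A", 1, "ALA"), ("A", 2, "GLY"), ("A", 3, "SER")]
        xml = self._xml(tmp_path, [(c, n, r, v) for (c, n, r), v in
                                   zip(keys, [0.8, 0.9, 1.0])])
        lig = LigandInstance("LIG", 1, atoms=[Atom("C1", "C", [0, 0, 0]),
                                              Atom("C2", "C", [1, 0, 0])])
        rep = parse_validation_rscc(xml, self._site(keys), lig)
        assert rep.site_mean_rscc == pytest.approx(0.9)

    def test_ligand_passthrough_and_class(self, tmp_path):
        keys = [("A", 1, "ALA")]
        xml = self._xml(tmp_path, [("A", 1, "ALA", 0.95)],
                        lig_row=("L", 1, "LIG", 0.85))
        lig = LigandInstance("LIG", 1, chain_id="L", seqnum=1,
                             atoms=[Atom("C1", "C", [0, 0, 0]),
                                    Atom("C2", "C", [1, 0, 0])])
        rep = parse_validation_rscc(xml, self._site(keys), lig)
        assert rep.ligand_rscc == pytest.approx(0.85)
        assert rep.quality_class == "PARTIAL"

    def test_missing_residue_excluded_from_mean(self, tmp_path):
        keys = [("A", 1, "ALA"), ("A", 2, "GLY"), ("A", 9, "SER")]
        xml = self._xml(tmp_path, [("A", 1, "ALA", 0.8), ("A", 2, "GLY", 1.0)])
        lig = LigandInstance("LIG", 1, atoms=[Atom("C1", "C", [0, 0, 0]),
                                              Atom("C2", "C", [1, 0, 0])])
        rep = parse_validation_rscc(xml, self._site(keys), lig)
        assert rep.site_mean_rscc == pytest.approx(0.9)  # n-1 denominator
        assert rep.ligand_rscc is None  # absent, not 0


class TestEnsureHydrogens:
    def test_hydroxyl_gets_one_h(self):
        lig = LigandInstance("LIG", 1, atoms=[
            Atom("C1", "C", [0, 0, 0]), Atom("O1", "O", [1.43, 0, 0])],
            bonds=[(0, 1, 1)])
        cplx = Complex("T", protein_residues=[
            _residue("A", 1, "ALA", {"CA": [9, 9, 9]})],
            ligand_instances=[lig])
        out = ensure_hydrogens(cplx)
        olig = out.ligand_instances[0]
        hs = [a for a in olig.atoms if a.is_hydrogen]
        assert len(hs) == 1
        d = np.linalg.norm(hs[0].coords - olig.atoms[1].coords)
        assert d == pytest.approx(0.96, abs=1e-6)

    def test_carbonyl_stays_bare(self):
        lig = LigandInstance("LIG", 1, atoms=[
            Atom("C1", "C", [0, 0, 0]), Atom("O1", "O", [1.23, 0, 0])],
            bonds=[(0, 1, 2)])
        cplx = Complex("T", protein_residues=[
            _residue("A", 1, "ALA", {"CA": [9, 9, 9]})],
            ligand_instances=[lig])
        out = ensure_hydrogens(cplx)
        assert not any(a.is_hydrogen for a in out.ligand_instances[0].atoms)

    def test_backbone_amide_h(self):
        r1 = _residue("A", 1, "GLY",
                      {"N": [0, 0, 0], "CA": [1.46, 0, 0], "C": [2.0, 1.4, 0],
                       "O": [1.5, 2.4, 0]})
        r2 = _residue("A", 2, "GLY",
                      {"N": [3.3, 1.5, 0], "CA": [4.2, 2.6, 0],
                       "C": [5.6, 2.2, 0]})
        lig = LigandInstance("LIG", 1, atoms=[Atom("C1", "C", [0, 5, 5]),
                                              Atom("C2", "C", [1, 5, 5])])
        cplx = Complex("T", protein_residues=[r1, r2],
                       ligand_instances=[lig])
        out = ensure_hydrogens(cplx)
        res2 = [r for r in out.protein_residues if r.seqnum == 2][0]
        hs = [a for a in res2.atoms if a.is_hydrogen]
        assert len(hs) == 1
        assert np.linalg.norm(hs[0].coords - res2.get("N").coords) == \
            pytest.approx(1.01, abs=1e-6)

    def test_idempotent(self):
        lig = LigandInstance("LIG", 1, atoms=[
            Atom("C1", "C", [0, 0, 0]), Atom("O1", "O", [1.43, 0, 0])],
            bonds=[(0, 1, 1)])
        cplx = Complex("T", protein_residues=[
            _residue("A", 1, "ALA", {"CA": [9, 9, 9]})],
            ligand_instances=[lig])
        once = ensure_hydrogens(cplx)
        twice = ensure_hydrogens(once)
        assert len(twice.ligand_instances[0].atoms) == \
            len(once.ligand_instances[0].atoms)
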