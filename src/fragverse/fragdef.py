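"""Fragment definition, filtering and chemistry characterization.

Implements the fragment definition filter (MW < 300 Da, 2-18 heavy atoms,
no monosaccharides / organometallics / prosthetic groups / additives /
polyatomic ions / polyhalogenated or linear aliphatic compounds), the
multi-entry occurrence filter, PAINS flagging, and the descriptor block
used to characterize versatile fragments (rule of three, plane of best
fit, Murcko scaffolds, substructure contribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, Crippen, rdMolDescriptors, FilterCatalog
from rdkit.Chem.Scaffolds import MurckoScaffold
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Molecule", "FragmentVerdict", "DescriptorBlock", "classify_ligand",
    "filter_multi_entry", "pains_flags", "ro3_violations", "compute_pbf",
    "murcko_scaffold", "substructure_contribution", "compute_descriptors",
    "NO_MATCH", "HET_BLOCKLIST",
]

NO_MATCH = None  # sentinel returned by substructure_contribution

REJECT_REASONS = (
    "MW>=300", "heavy_atoms_out_of_range", "monosaccharide",
    "organometallic", "prosthetic_group", "crystallization_additive",
    "polyatomic_ion", "polyhalogenated", "linear_aliphatic",
)

# HET-code blocklist reconstructing the published exclusion curation
# (crystallization additives / buffers / prosthetic groups); configurable.
HET_BLOCKLIST = {
    # solvents / cryoprotectants / buffers / detergents / polyalcohols
    "GOL": "crystallization_additive", "EDO": "crystallization_additive",
    "PEG": "crystallization_additive", "PGE": "crystallization_additive",
    "PG4": "crystallization_additive", "MPD": "crystallization_additive",
    "DMS": "crystallization_additive", "ACT": "crystallization_additive",
    "ACY": "crystallization_additive", "TRS": "crystallization_additive",
    "EPE": "crystallization_additive", "MES": "crystallization_additive",
    "BME": "crystallization_additive", "DTT": "crystallization_additive",
    "IMD": "crystallization_additive", "FMT": "crystallization_additive",
    "CIT": "crystallization_additive", "TLA": "crystallization_additive",
    "CAC": "crystallization_additive", "NO3": "crystallization_additive",
    # prosthetic groups / cofactor cores
    "HEM": "prosthetic_group", "HEC": "prosthetic_group",
    "FAD": "prosthetic_group", "FMN": "prosthetic_group",
    "PLP": "prosthetic_group", "B12": "prosthetic_group",
    "CLA": "prosthetic_group", "BCL": "prosthetic_group",
    # common monosaccharides
    "GLC": "monosaccharide", "BGC": "monosaccharide", "GAL": "monosaccharide",
    "MAN": "monosaccharide", "BMA": "monosaccharide", "FUC": "monosaccharide",
    "XYS": "monosaccharide", "NAG": "monosaccharide", "NDG": "monosaccharide",
    "FRU": "monosaccharide", "RIB": "monosaccharide", "ARA": "monosaccharide",
    # simple polyatomic ions
    "SO4": "polyatomic_ion", "PO4": "polyatomic_ion", "SO3": "polyatomic_ion",
    "CO3": "polyatomic_ion", "NH4": "polyatomic_ion", "AZI": "polyatomic_ion",
}

_METAL_Z = {3, 4, 11, 12, 13, 19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29,
            30, 31, 37, 38, 39, 40, 41, 42, 44, 45, 46, 47, 48, 49, 50, 55,
            56, 57, 72, 73, 74, 75, 76, 77, 78, 79, 80, 81, 82, 83}

_HALOGENS = {9, 17, 35, 53}

# pyranose / furanose ring decorated with hydroxyls
_SUGAR_SMARTS = Chem.MolFromSmarts(
    "[OX2r5,OX2r6]1[CX4][CX4]([OX2H1,OX2H0&!$(O=*)])[CX4]([OX2H1])[CX4]1")
_SUGAR_SMARTS2 = Chem.MolFromSmarts(
    "[C;r6]1[C;r6][C;r6][C;r6][C;r6][O;r6]1")

# simple ion heuristics: sulfate/phosphate/carbonate cores, bare carboxylic
# acids or carboxylates with nothing but the acid group
_ION_SMARTS = [
    Chem.MolFromSmarts("[SX4](=O)(=O)([OX1,OX2H])[OX1,OX2H]"),
    Chem.MolFromSmarts("[PX4](=O)([OX1,OX2H])([OX1,OX2H])[OX1,OX2H]"),
    Chem.MolFromSmarts("[CX3](=O)([OX1,OX2H])[OX1,OX2H]"),
]


@dataclass
class Molecule:
    """Thin wrapper pairing an RDKit molecule with its PDB HET code."""

    rdmol: Chem.Mol
    het_code: str | None = None

    @classmethod
    def from_smiles(cls, smiles: str, het_code: str | None = None) -> "Molecule":
        m = Chem.MolFromSmiles(smiles)
        if m is None:
            raise ValueError(f"unparsable SMILES: {smiles!r}")
        return cls(rdmol=m, het_code=het_code)

    @classmethod
    def from_mol2(cls, path, het_code: str | None = None) -> "Molecule":
        m = Chem.MolFromMol2File(str(path), removeHs=False)
        if m is None:
            raise ValueError(f"unparsable MOL2: {path}")
        return cls(rdmol=m, het_code=het_code)

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.rdmol)

    @property
    def n_heavy(self) -> int:
        return self.rdmol.GetNumHeavyAtoms()

    @property
    def mw(self) -> float:
        return Descriptors.MolWt(self.rdmol)


@dataclass
class FragmentVerdict:
    reject_reasons: list = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return not self.reject_reasons


@dataclass
class DescriptorBlock:
    mw: float
    alogp: float
    tpsa: float
    hbd: int
    hba: int
    pos_atoms: int
    neg_atoms: int
    rot_bonds: int
    rings: int
    stereocenters: int
    heavy_atoms: int
    pbf: float | None = None


def _is_linear_aliphatic(mol: Chem.Mol) -> bool:
    """Acyclic, carbon-only heavy skeleton, unbranched."""
    if rdMolDescriptors.CalcNumRings(mol) > 0:
        return False
    if any(a.GetAtomicNum() != 6 for a in mol.GetAtoms()
           if a.GetAtomicNum() > 1):
        return False
    return all(sum(1 for n in a.GetNeighbors() if n.GetAtomicNum() > 1) <= 2
               for a in mol.GetAtoms())


def _is_polyhalogenated(mol: Chem.Mol) -> bool:
    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    nhal = sum(1 for a in heavy if a.GetAtomicNum() in _HALOGENS)
    return len(heavy) <= 6 and nhal >= max(1, len(heavy) / 2)


def _is_monosaccharide(mol: Chem.Mol) -> bool:
    if mol.HasSubstructMatch(_SUGAR_SMARTS):
        return True
    # ring of 5-6 with ring O and >=3 exocyclic hydroxyls
    ri = mol.GetRingInfo()
    if ri.NumRings() != 1:
        return False
    ring = ri.AtomRings()[0]
    if len(ring) not in (5, 6):
        return False
    ring_elems = [mol.GetAtomWithIdx(i).GetAtomicNum() for i in ring]
    if ring_elems.count(8) != 1 or any(z not in (6, 8) for z in ring_elems):
        return False
    n_oh = sum(1 for a in mol.GetAtoms()
               if a.GetAtomicNum() == 8 and a.GetTotalNumHs() >= 1
               and not a.IsInRing())
    return n_oh >= 3


def _is_simple_ion(mol: Chem.Mol) -> bool:
    """Phosphate / sulfate / bare carboxylic acid with no carbon skeleton."""
    heavy = mol.GetNumHeavyAtoms()
    for patt in _ION_SMARTS:
        match = mol.GetSubstructMatch(patt)
        if match and heavy <= len(match) + 1:
            return True
    return False


def classify_ligand(mol: Molecule, blocklist: dict | None = None) -> FragmentVerdict:
    """Apply the fragment definition; every violated rule is reported."""
    blocklist = HET_BLOCKLIST if blocklist is None else blocklist
    m = mol.rdmol
    reasons = []
    if mol.mw >= 300.0:
        reasons.append("MW>=300")
    if not 2 <= mol.n_heavy <= 18:
        reasons.append("heavy_atoms_out_of_range")
    if any(a.GetAtomicNum() in _METAL_Z for a in m.GetAtoms()):
        reasons.append("organometallic")
    if mol.het_code and mol.het_code.upper() in blocklist:
        reasons.append(blocklist[mol.het_code.upper()])
    if _is_monosaccharide(m) and "monosaccharide" not in reasons:
        reasons.append("monosaccharide")
    if _is_simple_ion(m) and "polyatomic_ion" not in reasons:
        reasons.append("polyatomic_ion")
    if _is_polyhalogenated(m):
        reasons.append("polyhalogenated")
    if _is_linear_aliphatic(m):
        reasons.append("linear_aliphatic")
    return FragmentVerdict(reject_reasons=reasons)


def filter_multi_entry(corpus) -> set:
    """HET codes seen in >= 2 distinct entry ids.

    ``corpus`` is an iterable of (entry_id, het_code) pairs; multiple
    copies within one entry count once.
    """
    entries: dict = {}
    for entry_id, het in corpus:
        entries.setdefault(het, set()).add(entry_id)
    return {het for het, ids in entries.items() if len(ids) >= 2}


_PAINS_CATALOG = None


def _pains_catalog():
    global _PAINS_CATALOG
    if _PAINS_CATALOG is None:
        params = FilterCatalog.FilterCatalogParams()
        params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS)
        _PAINS_CATALOG = FilterCatalog.FilterCatalog(params)
    return _PAINS_CATALOG


def pains_flags(mol: Molecule) -> list:
    """Matched PAINS rule identifiers (families A+B+C); empty list = clean."""
    cat = _pains_catalog()
    return sorted({e.GetDescription()
                   for e in cat.GetMatches(mol.rdmol)})


def compute_descriptors(mol: Molecule, conformer_xyz=None) -> DescriptorBlock:
    m = mol.rdmol
    pbf = None
    if conformer_xyz is not None:
        pbf = compute_pbf(conformer_xyz)
    elif m.GetNumConformers():
        pbf = compute_pbf(m.GetConformer().GetPositions())
    return DescriptorBlock(
        mw=Descriptors.MolWt(m),
        alogp=Crippen.MolLogP(m),
        tpsa=rdMolDescriptors.CalcTPSA(m),
        hbd=rdMolDescriptors.CalcNumHBD(m),
        hba=rdMolDescriptors.CalcNumHBA(m),
        pos_atoms=sum(1 for a in m.GetAtoms() if a.GetFormalCharge() > 0),
        neg_atoms=sum(1 for a in m.GetAtoms() if a.GetFormalCharge() < 0),
        rot_bonds=rdMolDescriptors.CalcNumRotatableBonds(m),
        rings=rdMolDescriptors.CalcNumRings(m),
        stereocenters=rdMolDescriptors.CalcNumAtomStereoCenters(m),
        heavy_atoms=m.GetNumHeavyAtoms(),
        pbf=pbf,
    )


def ro3_violations(d: DescriptorBlock,
                   mw=300.0, hbd=3, hba=3, logp=3.0, rotb=3) -> int:
    """Count of rule-of-three limits violated (0-5)."""
    return sum([d.mw > mw, d.hbd > hbd, d.hba > hba,
                d.alogp > logp, d.rot_bonds > rotb])


def compute_pbf(coords) -> float | None:
    """Plane of best fit: mean |distance| of heavy atoms to their
    least-squares plane. Zero for planar conformers; rigid-motion invariant.
    Returns None for < 3 atoms or collinear input."""
    xyz = np.asarray(coords, dtype=float)
    if xyz.ndim != 2 or xyz.shape[0] < 3:
        return None
    centered = xyz - xyz.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8:  # collinear: plane undefined
        return None
    normal = vt[2]
    return float(np.mean(np.abs(centered @ normal)))


def murcko_scaffold(mol: Molecule) -> Molecule:
    """Bemis-Murcko framework: ring systems plus linkers, side chains
    removed; acyclic molecules give an empty scaffold."""
    scaf = MurckoScaffold.GetScaffoldForMol(mol.rdmol)
    return Molecule(rdmol=scaf, het_code=mol.het_code)


def _standardize(m: Chem.Mol) -> Chem.Mol:
    m = rdMolStandardize.Cleanup(m)
    m = rdMolStandardize.Uncharger().uncharge(m)
    return rdMolStandardize.TautomerEnumerator().Canonicalize(m)


def substructure_contribution(query: Molecule, target: Molecule,
                              use_chirality: bool = True,
                              standardize: bool = True):
    """If ``query`` embeds in ``target``, the fraction of target bonds it
    covers: bonds(query)/bonds(target). 1.0 means exact match; no embedding
    returns the NO_MATCH sentinel (None)."""
    q = _standardize(query.rdmol) if standardize else query.rdmol
    t = _standardize(target.rdmol) if standardize else target.rdmol
    if not t.HasSubstructMatch(q, useChirality=use_chirality):
        return NO_MATCH
    nb_t = t.GetNumBonds()
    if nb_t == 0:
        return 1.0 if q.GetNumAtoms() == t.GetNumAtoms() else NO_MATCH
    return q.GetNumBonds() / nb_t
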