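"""Structure input/output and site extraction.

Reads protein-fragment complexes from mmCIF/PDB (via gemmi) or MOL2 (own
parser: no installed library both reads and writes MOL2), assembles
:class:`Complex` objects, extracts amino-acid-only binding sites around a
bound fragment, places missing polar hydrogens, and parses real-space
correlation coefficients (RSCC) from wwPDB validation XML.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree
from scipy.spatial import cKDTree

__all__ = [
    "Atom", "Residue", "LigandInstance", "Complex", "ProteinSite",
    "RsccReport", "read_structure", "write_mol2", "read_mol2",
    "ensure_hydrogens", "extract_site", "classify_rscc",
    "parse_validation_rscc", "infer_bonds", "STANDARD_AA",
]

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

METALS = {
    "LI", "NA", "K", "RB", "CS", "MG", "CA", "SR", "BA", "MN", "FE", "CO",
    "NI", "CU", "ZN", "CD", "HG", "AL", "GA", "PT", "PD", "AG", "AU", "MO",
    "W", "V", "CR", "TI",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class StructureError(ValueError):
    """Raised for unreadable or chemically unusable structure input."""


@dataclass
class Atom:
    """A single atom: element symbol, coordinates (A), charge and flags."""

    name: str
    element: str
    coords: np.ndarray
    formal_charge: int = 0
    is_aromatic: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coords must be a finite 3-vector")
        self.element = self.element.strip().capitalize()

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seqnum: int
    name: str
    atoms: list = field(default_factory=list)

    def heavy_atoms(self):
        return [a for a in self.atoms if not a.is_hydrogen]

    def get(self, atom_name):
        for a in self.atoms:
            if a.name == atom_name:
                return a
        return None

    @property
    def key(self):
        return (self.chain_id, self.seqnum, self.name)


@dataclass
class LigandInstance:
    """One crystallographic copy of a chemical component (HET code)."""

    het_code: str
    copy_index: int
    atoms: list = field(default_factory=list)
    bonds: list = field(default_factory=list)   # (i, j, order) on self.atoms
    chain_id: str = ""
    seqnum: int = 0
    smiles: str | None = None

    def __post_init__(self):
        self.het_code = self.het_code.upper()
        if self.copy_index < 1:
            raise StructureError("copy_index must be >= 1")

    def heavy_atoms(self):
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        hv = self.heavy_atoms()
        return np.array([a.coords for a in hv]) if hv else np.empty((0, 3))


@dataclass
class Complex:
    """A structure entry: protein residues plus bound ligand instances."""

    entry_id: str
    protein_residues: list = field(default_factory=list)
    ligand_instances: list = field(default_factory=list)
    resolution: float | None = None
    deposition_date: str | None = None

    def protein_heavy_coords(self) -> np.ndarray:
        pts = [a.coords for r in self.protein_residues for a in r.heavy_atoms()]
        return np.array(pts) if pts else np.empty((0, 3))

    def get_ligand(self, het_code: str, copy_index: int = 1) -> LigandInstance:
        for lig in self.ligand_instances:
            if lig.het_code == het_code.upper() and lig.copy_index == copy_index:
                return lig
        raise KeyError(f"no ligand {het_code}/{copy_index} in {self.entry_id}")


@dataclass
class ProteinSite:
    """Amino-acid residues lining a fragment's binding site."""

    residues: list
    source_entry: str
    fragment_ref: tuple  # (het_code, copy_index)

    @property
    def is_empty(self) -> bool:
        return len(self.residues) == 0

    def heavy_atoms(self):
        return [(r, a) for r in self.residues for a in r.heavy_atoms()]

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coords for r in self.residues for a in r.heavy_atoms()]
        return np.array(pts) if pts else np.empty((0, 3))

    def chain_counts(self) -> dict:
        counts: dict = {}
        for r in self.residues:
            counts[r.chain_id] = counts.get(r.chain_id, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# RSCC classification (Twilight-style classes)

@dataclass
class RsccReport:
    ligand_rscc: float | None
    site_mean_rscc: float | None
    quality_class: str | None


def classify_rscc(rscc: float) -> str:
    """Map an RSCC value to FIT (>0.9), PARTIAL (0.8-0.9, closed) or POOR (<0.8)."""
    if not -1.0 <= rscc <= 1.0:
        raise ValueError(f"RSCC must be in [-1,1], got {rscc}")
    if rscc > 0.9:
        return "FIT"
    if rscc >= 0.8:
        return "PARTIAL"
    return "POOR"


def parse_validation_rscc(xml_path, site: ProteinSite, ligand: LigandInstance) -> RsccReport:
    """Read ligand and site-residue RSCC values from a wwPDB validation XML.

    The site mean is the arithmetic mean over site residues present in the
    file; residues absent from the XML are excluded from the denominator.
    A ligand absent from the file yields ``ligand_rscc=None``, never 0.
    """
    tree = etree.parse(str(xml_path))
    by_key = {}
    lig_rscc = None
    for sub in tree.iter("ModelledSubgroup"):
        rscc = sub.get("rscc")
        if rscc is None:
            continue
        rscc = float(rscc)
        chain = sub.get("chain", "")
        resname = (sub.get("resname") or "").upper()
        try:
            resnum = int(sub.get("resnum"))
        except (TypeError, ValueError):
            continue
        by_key[(chain, resnum, resname)] = rscc
        if resname == ligand.het_code:
            if (not ligand.chain_id or chain == ligand.chain_id) and \
               (not ligand.seqnum or resnum == ligand.seqnum):
                lig_rscc = rscc
    vals = [by_key[r.key] for r in site.residues if r.key in by_key]
    site_mean = float(np.mean(vals)) if vals else None
    qclass = classify_rscc(lig_rscc) if lig_rscc is not None else None
    return RsccReport(lig_rscc, site_mean, qclass)


# ---------------------------------------------------------------------------
# Bond inference (distance-based, for ligands read from coordinate-only files)

_BOND_MARGIN = 0.45
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39, "B": 0.84, "Se": 1.20,
}


def infer_bonds(atoms) -> list:
    """Distance-based single bonds between atoms (covalent radii + 0.45 A)."""
    bonds = []
    n = len(atoms)
    for i in range(n):
        ri = _COVALENT_RADII.get(atoms[i].element, 1.5)
        for j in range(i + 1, n):
            rj = _COVALENT_RADII.get(atoms[j].element, 1.5)
            cut = ri + rj + _BOND_MARGIN
            if atoms[i].is_hydrogen and atoms[j].is_hydrogen:
                continue
            d = float(np.linalg.norm(atoms[i].coords - atoms[j].coords))
            if 0.4 < d <= cut:
                bonds.append((i, j, 1))
    return bonds


# ---------------------------------------------------------------------------
# Readers

def read_structure(path, fmt: str | None = None) -> Complex:
    """Read a structure file (mmCIF, PDB or MOL2) into a :class:`Complex`.

    Waters are dropped; standard amino acids become protein residues; every
    other chemical component with >= 2 heavy atoms becomes a ligand
    instance (copies of the same HET code get increasing ``copy_index``).
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    if fmt is None:
        fmt = {".cif": "mmcif", ".mmcif": "mmcif", ".pdb": "pdb",
               ".ent": "pdb", ".mol2": "mol2"}.get(path.suffix.lower())
        if fmt is None:
            raise StructureError(f"cannot guess format of {path}")
    fmt = fmt.lower()
    if fmt == "mol2":
        return read_mol2(path)

    import gemmi
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    entry_id = st.name or path.stem
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    date = None
    for key in ("_pdbx_database_status.recvd_initial_deposition_date",
                "_database_PDB_rev.date_original"):
        if key in st.info:
            date = st.info[key]
            break

    cplx = Complex(entry_id=entry_id, resolution=resolution, deposition_date=date)
    het_counts: dict = {}
    if len(st) == 0:
        raise StructureError(f"{path}: no model")
    model = st[0]
    for chain in model:
        for res in chain:
            rname = res.name.upper()
            if rname in WATER_NAMES:
                continue
            atoms = [
                Atom(name=a.name, element=a.element.name,
                     coords=[a.pos.x, a.pos.y, a.pos.z],
                     formal_charge=int(a.charge))
                for a in res
            ]
            if rname in STANDARD_AA:
                cplx.protein_residues.append(
                    Residue(chain.name, res.seqid.num, rname, atoms))
            else:
                heavy = [a for a in atoms if not a.is_hydrogen]
                if len(heavy) < 2:
                    continue  # monoatomic species (ions) are never fragments
                het_counts[rname] = het_counts.get(rname, 0) + 1
                lig = LigandInstance(
                    het_code=rname, copy_index=het_counts[rname],
                    atoms=atoms, chain_id=chain.name, seqnum=res.seqid.num)
                lig.bonds = infer_bonds(lig.atoms)
                cplx.ligand_instances.append(lig)
    if not cplx.protein_residues:
        raise StructureError(f"{path}: structure has no protein chain")
    return cplx


# ---------------------------------------------------------------------------
# MOL2 (hand-rolled: RDKit reads but does not write MOL2; gemmi has none)

def write_mol2(path, atoms, bonds=(), mol_name="MOL",
               substructures=None) -> None:
    """Write atoms/bonds as a TRIPOS MOL2 file.

    ``substructures`` optionally maps atom index -> (subst_id, subst_name)
    so protein sites keep their residue annotation.
    """
    lines = ["@<TRIPOS>MOLECULE", mol_name,
             f"{len(atoms)} {len(bonds)} 0 0 0", "SMALL", "USER_CHARGES",
             "@<TRIPOS>ATOM"]
    for i, a in enumerate(atoms):
        sid, sname = (1, mol_name)
        if substructures is not None:
            sid, sname = substructures[i]
        x, y, z = a.coords
        lines.append(
            f"{i + 1:>6} {a.name:<6} {x:>12.4f} {y:>12.4f} {z:>12.4f} "
            f"{a.element:<5} {sid:>4} {sname:<8} {float(a.formal_charge):>8.4f}")
    lines.append("@<TRIPOS>BOND")
    for bi, (i, j, order) in enumerate(bonds):
        o = {1: "1", 2: "2", 3: "3"}.get(order, "1")
        lines.append(f"{bi + 1:>6} {i + 1:>6} {j + 1:>6} {o:>4}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_mol2(path) -> Complex:
    """Read a MOL2 file written by :func:`write_mol2` into a Complex.

    Substructure names starting with a standard amino-acid code become
    protein residues; everything else is collected into one ligand.
    """
    text = Path(path).read_text()
    section = None
    atoms, bonds, substs, name = [], [], [], "MOL"
    mol_lines = 0
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("@<TRIPOS>"):
            section = line[9:].upper()
            mol_lines = 0
            continue
        if not line or line.startswith("#"):
            continue
        if section == "MOLECULE":
            if mol_lines == 0:
                name = line
            mol_lines += 1
        elif section == "ATOM":
            parts = line.split()
            if len(parts) < 6:
                raise StructureError(f"{path}: bad ATOM record: {line}")
            aname = parts[1]
            x, y, z = map(float, parts[2:5])
            element = parts[5].split(".")[0]
            sid = int(parts[6]) if len(parts) > 6 else 1
            sname = parts[7] if len(parts) > 7 else name
            charge = float(parts[8]) if len(parts) > 8 else 0.0
            atoms.append(Atom(aname, element, [x, y, z],
                              formal_charge=int(round(charge))))
            substs.append((sid, sname))
        elif section == "BOND":
            parts = line.split()
            i, j = int(parts[1]) - 1, int(parts[2]) - 1
            order = {"1": 1, "2": 2, "3": 3, "am": 1, "ar": 1}.get(parts[3], 1)
            bonds.append((i, j, order))

    cplx = Complex(entry_id=name)
    groups: dict = {}
    order_seen = []
    for idx, (sid, sname) in enumerate(substs):
        if (sid, sname) not in groups:
            groups[(sid, sname)] = []
            order_seen.append((sid, sname))
        groups[(sid, sname)].append(idx)

    lig_atoms, lig_map = [], {}
    for sid, sname in order_seen:
        idxs = groups[(sid, sname)]
        res3 = sname[:3].upper()
        if res3 in STANDARD_AA:
            num = sid
            tail = sname[3:]
            if tail and tail.lstrip("-").isdigit():
                num = int(tail)
            cplx.protein_residues.append(
                Residue("A", num, res3, [atoms[i] for i in idxs]))
        else:
            for i in idxs:
                lig_map[i] = len(lig_atoms)
                lig_atoms.append(atoms[i])
    if lig_atoms:
        lig_bonds = [(lig_map[i], lig_map[j], o) for i, j, o in bonds
                     if i in lig_map and j in lig_map]
        het = name[:3].upper() if name[:3].isalnum() else "LIG"
        cplx.ligand_instances.append(
            LigandInstance(het_code=het, copy_index=1,
                           atoms=lig_atoms, bonds=lig_bonds))
    return cplx


# ---------------------------------------------------------------------------
# Hydrogen placement

_OH_LEN = 0.96
_NH_LEN = 1.01
_H_ATTACH = 1.25  # existing H within this distance counts as bonded


def _attached_h(atoms, i, bonds_by_atom):
    out = []
    for j in bonds_by_atom.get(i, ()):
        if atoms[j].is_hydrogen:
            out.append(j)
    # distance fallback for bondless inputs
    for j, a in enumerate(atoms):
        if a.is_hydrogen and j not in out and \
           np.linalg.norm(a.coords - atoms[i].coords) <= _H_ATTACH:
            out.append(j)
    return out


def _bonds_by_atom(n, bonds):
    nbrs: dict = {i: [] for i in range(n)}
    for i, j, _ in bonds:
        nbrs[i].append(j)
        nbrs[j].append(i)
    return nbrs


def _place_h(pos, direction, length):
    d = np.asarray(direction, float)
    nrm = np.linalg.norm(d)
    if nrm < 1e-9:
        d = np.array([0.0, 0.0, 1.0])
        nrm = 1.0
    return pos + d / nrm * length


def ensure_hydrogens(cplx: Complex) -> Complex:
    """Add missing polar hydrogens; idempotent on protonated input.

    Ligands: hydroxyl oxygens (one heavy neighbour, single-bond length)
    get one H at 0.96 A anti to the neighbour; trivalent nitrogens are
    filled to valence 3 (+1 per positive charge) at 1.01 A, except
    two-coordinate aromatic N (pyridine-like), which stays bare.
    Protein: backbone amide H is rebuilt from N, CA and the preceding
    carbonyl C. Side-chain protein hydrogens are not placed; interaction
    detection falls back to distance-only rules on the protein side.
    """
    out = copy.deepcopy(cplx)

    for lig in out.ligand_instances:
        atoms = lig.atoms
        bonds = lig.bonds or infer_bonds(atoms)
        nbrs = _bonds_by_atom(len(atoms), bonds)
        new_atoms = []
        for i, a in enumerate(atoms):
            if a.is_hydrogen:
                continue
            heavies = [j for j in nbrs.get(i, ()) if not atoms[j].is_hydrogen]
            hs = _attached_h(atoms, i, nbrs)
            n_add = 0
            if a.element == "O" and a.formal_charge == 0 and not hs:
                if len(heavies) == 1:
                    d = np.linalg.norm(atoms[heavies[0]].coords - a.coords)
                    if d > 1.30:  # single bond -> hydroxyl, C=O stays bare
                        n_add = 1
                elif len(heavies) == 0:
                    n_add = 2  # isolated water-like O
            elif a.element == "N" and a.formal_charge >= 0:
                if a.is_aromatic and len(heavies) == 2 and not hs:
                    n_add = 0  # pyridine-type ring nitrogen
                else:
                    target = 3 + max(a.formal_charge, 0)
                    n_add = max(0, target - len(heavies) - len(hs))
            if n_add == 0:
                continue
            anti = -sum((atoms[j].coords - a.coords) /
                        max(np.linalg.norm(atoms[j].coords - a.coords), 1e-9)
                        for j in heavies) if heavies else np.array([0., 0., 1.])
            length = _OH_LEN if a.element == "O" else _NH_LEN
            base = _place_h(a.coords, anti, length)
            for k in range(n_add):
                if k == 0:
                    hpos = base
                else:  # fan additional hydrogens around the anti direction
                    perp = np.cross(anti, [1.0, 0.3, 0.2])
                    if np.linalg.norm(perp) < 1e-6:
                        perp = np.cross(anti, [0.0, 1.0, 0.0])
                    perp = perp / np.linalg.norm(perp)
                    hpos = _place_h(a.coords, anti + 1.2 * perp * k, length)
                hname = f"H{a.name}{k if n_add > 1 else ''}"
                new_atoms.append((i, Atom(hname, "H", hpos)))
        for parent, h in new_atoms:
            lig.atoms.append(h)
            lig.bonds.append((parent, len(lig.atoms) - 1, 1))

    # backbone amide H
    chains: dict = {}
    for r in out.protein_residues:
        chains.setdefault(r.chain_id, []).append(r)
    for chain_res in chains.values():
        chain_res.sort(key=lambda r: r.seqnum)
        for k, res in enumerate(chain_res):
            if res.name == "PRO":
                continue
            n_at, ca = res.get("N"), res.get("CA")
            if n_at is None or ca is None:
                continue
            if any(a.is_hydrogen and
                   np.linalg.norm(a.coords - n_at.coords) <= _H_ATTACH
                   for a in res.atoms):
                continue
            c_prev = None
            for prev in chain_res[max(0, k - 1):k]:
                c = prev.get("C")
                if c is not None and \
                   np.linalg.norm(c.coords - n_at.coords) < 1.6:
                    c_prev = c
            if c_prev is None:
                continue  # chain start or break: leave unprotonated
            u1 = n_at.coords - c_prev.coords
            u2 = n_at.coords - ca.coords
            u1 /= max(np.linalg.norm(u1), 1e-9)
            u2 /= max(np.linalg.norm(u2), 1e-9)
            res.atoms.append(Atom("H", "H", _place_h(n_at.coords, u1 + u2, _NH_LEN)))
    return out


# ---------------------------------------------------------------------------
# Site extraction

def extract_site(cplx: Complex, ligand: LigandInstance,
                 site_radius: float = 6.5) -> ProteinSite:
    """Amino-acid residues with >= 1 heavy atom within ``site_radius`` of
    any ligand heavy atom."""
    if site_radius <= 0:
        raise ValueError("site_radius must be positive")
    lig_xyz = ligand.heavy_coords()
    if len(lig_xyz) == 0:
        raise StructureError("ligand has no heavy atoms")
    tree = cKDTree(lig_xyz)
    residues = []
    for res in cplx.protein_residues:
        if res.name not in STANDARD_AA:
            continue
        pts = np.array([a.coords for a in res.heavy_atoms()])
        if len(pts) and np.any(tree.query(pts)[0] <= site_radius):
            residues.append(res)
    return ProteinSite(residues=residues, source_entry=cplx.entry_id,
                       fragment_ref=(ligand.het_code, ligand.copy_index))
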