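"""Geometric protein-fragment interaction typing and interaction graphs.

Each detected non-covalent contact (hydrogen bond, ionic bond, aromatic
stacking, hydrophobic contact) places a typed pseudo-atom on the ligand
interacting atom (ring centroid for aromatic stacking); hydrogen bonds add
a second pseudo-atom halfway to the protein partner to encode bond
directionality. The pseudo-atoms are the nodes of a complete graph whose
edges carry Euclidean distances - the binding-mode fingerprint compared by
the subgraph matching kernel in :mod:`fragverse.modeclust`.

Protein atoms are typed from residue-name templates; angle criteria apply
only where an explicit hydrogen exists (ligand donors, backbone amide H).
Water-mediated and weak hydrogen bonds are ignored.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .config import GeomRules
from .structio import LigandInstance, ProteinSite, infer_bonds

logger = logging.getLogger(__name__)

__all__ = [
    "Interaction", "PseudoAtom", "InteractionGraph",
    "detect_interactions", "build_interaction_graph",
    "HB_DONOR", "HB_ACCEPTOR", "IONIC_POS", "IONIC_NEG",
    "AROMATIC", "HYDROPHOBIC", "MID_SUFFIX",
]

HB_DONOR = "HB_DONOR"        # ligand donates
HB_ACCEPTOR = "HB_ACCEPTOR"  # ligand accepts
IONIC_POS = "IONIC_POS"      # ligand cation
IONIC_NEG = "IONIC_NEG"      # ligand anion
AROMATIC = "AROMATIC"
HYDROPHOBIC = "HYDROPHOBIC"
MID_SUFFIX = "|MID"          # midpoint marker on H-bond second nodes

# ---------------------------------------------------------------------------
# Protein atom typing templates (side chains by atom name, backbone shared)

_BB_DONOR = {"N"}       # except PRO
_BB_ACCEPTOR = {"O", "OXT"}

_SC_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"}, "LYS": {"NZ"}, "SER": {"OG"}, "THR": {"OG1"},
    "TRP": {"NE1"}, "TYR": {"OH"}, "CYS": {"SG"},
}
_SC_ACCEPTORS = {
    "ASN": {"OD1"}, "ASP": {"OD1", "OD2"}, "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"}, "HIS": {"ND1", "NE2"}, "SER": {"OG"},
    "THR": {"OG1"}, "TYR": {"OH"}, "MET": {"SD"},
}
_SC_POSITIVE = {"ARG": {"NH1", "NH2", "NE"}, "LYS": {"NZ"}}
_SC_NEGATIVE = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}

_RING_ATOMS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [("CG", "CD1", "CD2", "NE1", "CE2"),
            ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")],
}

_HYDROPHOBIC_SC = {
    "ALA": {"CB"}, "VAL": {"CB", "CG1", "CG2"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "ILE": {"CB", "CG1", "CG2", "CD1"},
    "MET": {"CB", "CG", "CE", "SD"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CB", "CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "PRO": {"CB", "CG", "CD"},
    "LYS": {"CB", "CG", "CD"}, "ARG": {"CB", "CG"},
    "GLU": {"CB", "CG"}, "GLN": {"CB", "CG"},
    "ASP": {"CB"}, "ASN": {"CB"}, "HIS": {"CB"}, "THR": {"CG2"},
    "CYS": {"CB"}, "ILE2": set(),
}


@dataclass
class Interaction:
    itype: str
    ligand_pos: np.ndarray          # ligand interacting atom / ring centroid
    protein_pos: np.ndarray         # protein partner atom / ring centroid
    distance: float
    ligand_atom: int | None = None  # index into ligand.atoms; None = centroid
    protein_residue: tuple | None = None  # (chain, seqnum, resname)
    angle: float | None = None      # degrees, where applicable

    def __post_init__(self):
        self.ligand_pos = np.asarray(self.ligand_pos, float)
        self.protein_pos = np.asarray(self.protein_pos, float)
        if self.distance <= 0:
            raise ValueError("interaction distance must be positive")


@dataclass
class PseudoAtom:
    position: np.ndarray
    label: str

    def __post_init__(self):
        self.position = np.asarray(self.position, float)


@dataclass
class InteractionGraph:
    """Complete graph of typed pseudo-atoms with Euclidean edge lengths."""

    nodes: list = field(default_factory=list)   # list[PseudoAtom]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def labels(self) -> list:
        return [n.label for n in self.nodes]

    def positions(self) -> np.ndarray:
        if not self.nodes:
            return np.empty((0, 3))
        return np.array([n.position for n in self.nodes])

    def distance_matrix(self) -> np.ndarray:
        xyz = self.positions()
        diff = xyz[:, None, :] - xyz[None, :, :]
        return np.sqrt((diff ** 2).sum(-1))

    def edges(self):
        dm = self.distance_matrix()
        return [(i, j, float(dm[i, j]))
                for i, j in itertools.combinations(range(self.n_nodes), 2)]

    def to_json(self) -> str:
        return json.dumps({
            "nodes": [{"label": n.label, "position": n.position.tolist()}
                      for n in self.nodes],
            "edges": [{"i": i, "j": j, "length": d} for i, j, d in self.edges()],
        })

    @classmethod
    def from_json(cls, text: str) -> "InteractionGraph":
        data = json.loads(text)
        return cls(nodes=[PseudoAtom(n["position"], n["label"])
                          for n in data["nodes"]])


# ---------------------------------------------------------------------------
# Ligand atom typing (geometry + explicit flags; no chemistry toolkit needed)

def _ligand_typing(ligand: LigandInstance):
    atoms = ligand.atoms
    bonds = ligand.bonds or infer_bonds(atoms)
    nbrs = {i: set() for i in range(len(atoms))}
    for i, j, _ in bonds:
        nbrs[i].add(j)
        nbrs[j].add(i)

    def attached_h(i):
        out = [j for j in nbrs[i] if atoms[j].is_hydrogen]
        for j, a in enumerate(atoms):
            if a.is_hydrogen and j not in out and \
               np.linalg.norm(a.coords - atoms[i].coords) <= 1.25:
                out.append(j)
        return out

    info = {}
    for i, a in enumerate(atoms):
        if a.is_hydrogen:
            continue
        heavies = [j for j in nbrs[i] if not atoms[j].is_hydrogen]
        hs = attached_h(i)
        polar_nbr = any(atoms[j].element in ("N", "O", "F") for j in heavies)
        info[i] = {
            "donor": a.element in ("N", "O") and len(hs) > 0,
            "acceptor": a.element in ("N", "O") and a.formal_charge <= 0,
            "cation": a.formal_charge > 0,
            "anion": a.formal_charge < 0,
            "hydrophobic": (a.element in ("C", "S") and a.formal_charge == 0
                            and not polar_nbr),
            "h_idx": hs,
            "heavies": heavies,
        }

    rings = _perceive_rings(atoms, bonds)
    return info, rings, nbrs


def _perceive_rings(atoms, bonds, planar_tol=0.15):
    """5/6-membered near-planar rings, treated as aromatic.

    Planarity is an RMS criterion: aromatic rings fit their plane to
    ~0.01 A (well under the tolerance even with coordinate noise) while
    chair/envelope saturated rings deviate by ~0.25 A RMS.
    """
    g = nx.Graph()
    heavy_idx = [i for i, a in enumerate(atoms) if not a.is_hydrogen]
    g.add_nodes_from(heavy_idx)
    for i, j, _ in bonds:
        if not atoms[i].is_hydrogen and not atoms[j].is_hydrogen:
            g.add_edge(i, j)
    rings = []
    for cyc in nx.cycle_basis(g):
        if len(cyc) not in (5, 6):
            continue
        if any(atoms[i].element not in ("C", "N", "O", "S") for i in cyc):
            continue
        xyz = np.array([atoms[i].coords for i in cyc])
        centered = xyz - xyz.mean(axis=0)
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        if np.sqrt(np.mean((centered @ vt[2]) ** 2)) > planar_tol:
            continue
        flagged = any(atoms[i].is_aromatic for i in cyc)
        all_sp2_like = True  # geometric planarity is the operative test
        if flagged or all_sp2_like:
            rings.append({"atoms": tuple(cyc), "centroid": xyz.mean(axis=0),
                          "normal": vt[2]})
    return rings


def _protein_rings(residue):
    rings = []
    for names in _RING_ATOMS.get(residue.name, ()):
        ats = [residue.get(n) for n in names]
        ats = [a for a in ats if a is not None]
        if len(ats) < 5:
            continue
        xyz = np.array([a.coords for a in ats])
        centered = xyz - xyz.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        rings.append({"names": names, "centroid": xyz.mean(axis=0),
                      "normal": vt[2], "residue": residue})
    return rings


def protein_atom_types(residue, atom) -> set:
    """Pharmacophoric types of one protein heavy atom (template-based)."""
    types = set()
    name, res = atom.name, residue.name
    if name in _BB_DONOR and res != "PRO":
        types.add("donor")
    if name in _BB_ACCEPTOR:
        types.add("acceptor")
    if name in _SC_DONORS.get(res, ()):
        types.add("donor")
    if name in _SC_ACCEPTORS.get(res, ()):
        types.add("acceptor")
    if name in _SC_POSITIVE.get(res, ()):
        types.add("positive")
    if name in _SC_NEGATIVE.get(res, ()) or name == "OXT":
        types.add("negative")
    for ringnames in _RING_ATOMS.get(res, ()):
        if name in ringnames:
            types.add("aromatic")
    if name in _HYDROPHOBIC_SC.get(res, ()):
        types.add("hydrophobic")
    return types


def _angle(a, b, c):
    """Angle a-b-c in degrees."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / max(np.linalg.norm(u) * np.linalg.norm(v), 1e-12)
    return float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))


def detect_interactions(ligand: LigandInstance, site: ProteinSite,
                        rules: GeomRules | None = None) -> list:
    """Detect H-bond / ionic / aromatic / hydrophobic contacts.

    Deterministic in the coordinates and rules. Missing ligand hydrogens
    downgrade donor detection to heavy-atom distance only (logged).
    Atom pairs qualifying as ionic are not double-reported as H-bonds, and
    ring atoms engaged in a detected aromatic stacking are excluded from
    hydrophobic contacts with the partner ring's residue.
    """
    rules = rules or GeomRules()
    lig_info, lig_rings, _ = _ligand_typing(ligand)
    atoms = ligand.atoms
    interactions: list[Interaction] = []
    ionic_pairs = set()      # (lig_atom, residue_key, protein_atom_name)
    aromatic_excl = set()    # (lig_atom_idx, residue_key) hydrophobic vetoes

    prot_atoms = []  # (residue, atom)
    for res in site.residues:
        for a in res.heavy_atoms():
            prot_atoms.append((res, a))

    # --- ionic (takes precedence over H-bonds on the same pair)
    for i, inf in lig_info.items():
        if not (inf["cation"] or inf["anion"]):
            continue
        for res, pa in prot_atoms:
            ptypes = protein_atom_types(res, pa)
            d = float(np.linalg.norm(atoms[i].coords - pa.coords))
            if d > rules.ionic_dist:
                continue
            if inf["cation"] and "negative" in ptypes:
                itype = IONIC_POS
            elif inf["anion"] and "positive" in ptypes:
                itype = IONIC_NEG
            else:
                continue
            interactions.append(Interaction(
                itype, atoms[i].coords, pa.coords, d,
                ligand_atom=i, protein_residue=res.key))
            ionic_pairs.add((i, res.key, pa.name))

    # --- hydrogen bonds
    no_h_warned = False
    for i, inf in lig_info.items():
        for res, pa in prot_atoms:
            if (i, res.key, pa.name) in ionic_pairs:
                continue
            d = float(np.linalg.norm(atoms[i].coords - pa.coords))
            if d > rules.hbond_dist:
                continue
            ptypes = protein_atom_types(res, pa)
            # ligand donates
            if inf["donor"] and "acceptor" in ptypes:
                ok = False
                if inf["h_idx"]:
                    for h in inf["h_idx"]:
                        ang = _angle(atoms[i].coords, atoms[h].coords, pa.coords)
                        if ang >= rules.hbond_angle:
                            ok, best_ang = True, ang
                            break
                else:
                    ok, best_ang = True, None
                    if not no_h_warned:
                        logger.warning(
                            "%s: ligand donor without explicit H; "
                            "distance-only H-bond detection", ligand.het_code)
                        no_h_warned = True
                if ok:
                    interactions.append(Interaction(
                        HB_DONOR, atoms[i].coords, pa.coords, d,
                        ligand_atom=i, protein_residue=res.key,
                        angle=best_ang))
                    continue
            # ligand accepts (protein-side H not placed: distance-only)
            if inf["acceptor"] and "donor" in ptypes:
                h_prot = [a for a in res.atoms if a.is_hydrogen and
                          np.linalg.norm(a.coords - pa.coords) <= 1.25]
                ok = True
                ang = None
                if h_prot:
                    ok = any(_angle(pa.coords, h.coords, atoms[i].coords)
                             >= rules.hbond_angle for h in h_prot)
                if ok:
                    interactions.append(Interaction(
                        HB_ACCEPTOR, atoms[i].coords, pa.coords, d,
                        ligand_atom=i, protein_residue=res.key, angle=ang))

    # --- aromatic stacking (ring centroid pairs)
    prot_rings = []
    for res in site.residues:
        prot_rings.extend(_protein_rings(res))
    for lr in lig_rings:
        for pr in prot_rings:
            d = float(np.linalg.norm(lr["centroid"] - pr["centroid"]))
            if d > rules.aromatic_dist or d < 1e-6:
                continue
            cosang = abs(float(np.dot(lr["normal"], pr["normal"])))
            ang = float(np.degrees(np.arccos(np.clip(cosang, 0, 1))))
            parallel = ang <= rules.aromatic_parallel_angle
            tshaped = rules.aromatic_tshape_lo <= ang <= rules.aromatic_tshape_hi
            if parallel or tshaped:
                interactions.append(Interaction(
                    AROMATIC, lr["centroid"], pr["centroid"], d,
                    ligand_atom=None, protein_residue=pr["residue"].key,
                    angle=ang))
                for li in lr["atoms"]:
                    aromatic_excl.add((li, pr["residue"].key))

    # --- hydrophobic contacts, collapsed per (adjacency patch, residue)
    contacts: dict = {}
    for i, inf in lig_info.items():
        if not inf["hydrophobic"]:
            continue
        for res, pa in prot_atoms:
            if (i, res.key) in aromatic_excl and \
               any(pa.name in names for names in _RING_ATOMS.get(res.name, ())):
                continue
            if "hydrophobic" not in protein_atom_types(res, pa):
                continue
            d = float(np.linalg.norm(atoms[i].coords - pa.coords))
            if d <= rules.hydrophobic_dist:
                contacts.setdefault(res.key, []).append((d, i, pa))
    if contacts:
        # group ligand atoms bonded to each other contacting the same residue
        bonds = ligand.bonds or infer_bonds(atoms)
        adj = nx.Graph()
        adj.add_nodes_from(lig_info)
        for bi, bj, _ in bonds:
            if bi in lig_info and bj in lig_info:
                adj.add_edge(bi, bj)
        for rkey, lst in contacts.items():
            involved = {i for _, i, _ in lst}
            sub = adj.subgraph(involved)
            for comp in nx.connected_components(sub):
                best = min((c for c in lst if c[1] in comp), key=lambda c: c[0])
                d, i, pa = best
                interactions.append(Interaction(
                    HYDROPHOBIC, atoms[i].coords, pa.coords, d,
                    ligand_atom=i, protein_residue=rkey))

    return interactions


def build_interaction_graph(interactions) -> InteractionGraph:
    """Pseudo-atom graph: one node per interaction on the ligand side, plus
    one midpoint node per hydrogen bond. The graph is complete; edges carry
    Euclidean distances (implicit, from node positions)."""
    nodes = []
    for it in interactions:
        nodes.append(PseudoAtom(it.ligand_pos, it.itype))
        if it.itype in (HB_DONOR, HB_ACCEPTOR):
            mid = (it.ligand_pos + it.protein_pos) / 2.0
            nodes.append(PseudoAtom(mid, it.itype + MID_SUFFIX))
    return InteractionGraph(nodes=nodes)


def write_pseudoatoms_mol2(path, graph: InteractionGraph, name="PSEUDO"):
    """Pseudo-atoms as MOL2 with label-encoded atom names."""
    from .structio import Atom, write_mol2
    short = {HB_DONOR: "DON", HB_ACCEPTOR: "ACC", IONIC_POS: "POS",
             IONIC_NEG: "NEG", AROMATIC: "ARO", HYDROPHOBIC: "HYD"}
    atoms = []
    for n in graph.nodes:
        base = n.label.replace(MID_SUFFIX, "")
        lab = short.get(base, "UNK") + ("M" if n.label.endswith(MID_SUFFIX) else "")
        atoms.append(Atom(lab, "C", n.position))
    write_mol2(path, atoms, bonds=(), mol_name=name)
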