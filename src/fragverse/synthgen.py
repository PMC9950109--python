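"""Synthetic complexes, graph families, cavity clouds and mini-corpora.

Every pipeline stage is testable without downloads: this module plants
known numbers of binding modes (controlled interaction patterns plus
coordinate jitter) and known numbers of distinct cavities (labeled point
environments related or unrelated by rigid motion), wrapped in minimal
protein "complexes" made of single-residue probes, typed decoration atoms
and an enclosing shell of untyped carbon atoms that provides buriedness.
Probes are positioned so that geometric interaction detection recovers the
planted interaction list exactly; construction margins keep within-mode
similarities well above and between-mode similarities well below the
clustering thresholds, so recovery tests are robust rather than
knife-edge.

Synthetic proteins are geometric probes, not folded chains: every
downstream computation consumes geometry, not fold.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import PipelineConfig, GeomRules
from .structio import (Atom, Residue, Complex, LigandInstance, ProteinSite,
                       ensure_hydrogens, extract_site)
from .interact import (detect_interactions, build_interaction_graph,
                       HB_DONOR, HB_ACCEPTOR, IONIC_POS, IONIC_NEG,
                       AROMATIC, HYDROPHOBIC)
from .cavity import LabeledCloud

__all__ = [
    "SyntheticSpec", "FragmentPlan", "GroundTruth", "ConstructionError",
    "synth_complex", "synth_mode_family", "synth_cavity_set", "synth_corpus",
    "layout_interactions", "MODE_SIGNATURES", "DEFAULT_CORPUS_PLAN",
    "complex_to_graph", "write_complex_pdb",
]


class ConstructionError(RuntimeError):
    """Requested geometry cannot realize the planted interactions."""


# interaction anchor distances (A): chosen inside the rule cutoffs with
# margin, so small jitter never crosses a threshold
_DIST = {HB_DONOR: 3.0, HB_ACCEPTOR: 3.0, IONIC_POS: 3.6, IONIC_NEG: 3.6,
         AROMATIC: 3.8, HYDROPHOBIC: 4.0}

# planted binding-mode signatures: (interaction types, ligand layout
# radius). Signatures that share interaction labels differ in radius
# and/or anchor count so that their inter-anchor chord lengths differ by
# more than the edge-kernel tolerance (1 A): between-mode kernel terms
# floor at zero and no signature graph embeds in another. Radii stay
# within a 3.2 A band so the clouds of different modes of one fragment
# occupy overlapping regions of the same synthetic pocket.
MODE_SIGNATURES = [
    ((HB_DONOR, HYDROPHOBIC), 4.0),
    ((HB_ACCEPTOR, AROMATIC), 4.8),
    ((IONIC_NEG, HYDROPHOBIC, HB_DONOR), 5.6),
    ((IONIC_POS, AROMATIC, HB_ACCEPTOR), 6.4),
    ((HB_DONOR, HB_ACCEPTOR, HYDROPHOBIC, AROMATIC), 7.2),
]

# cavity environment label compositions: pairwise overlap of the label
# frequency vectors stays below 0.3
ENV_COMPOSITIONS = [
    {"HYDROPHOBIC": 0.8, "HB_ACCEPTOR": 0.2},
    {"AROMATIC": 0.8, "POSITIVE": 0.2},
    {"NEGATIVE": 0.8, "HB_DONOR": 0.2},
    {"HB_DONOR": 0.8, "HYDROPHOBIC": 0.2},
    {"HB_ACCEPTOR": 0.8, "NEGATIVE": 0.2},
]

# decoration atoms carrying one pharmacophoric label each (single-atom
# residues; template typing in fragverse.interact gives the stated label)
_DECOR_TEMPLATES = {
    "NEGATIVE": ("ASP", "OD1", "O"),
    "POSITIVE": ("LYS", "NZ", "N"),
    "HB_DONOR": ("TRP", "NE1", "N"),
    "HB_ACCEPTOR": ("GLY", "O", "O"),
    "HYDROPHOBIC": ("LEU", "CD1", "C"),
    "AROMATIC": ("PHE", "CG", "C"),
}


@dataclass
class FragmentPlan:
    het: str
    smiles: str
    mode_ids: list          # signature index per observation
    env_ids: list           # environment id per observation
    expected_reject_step: int | None   # None = versatile
    k_expected: int | None = None      # modes after merge correction


@dataclass
class SyntheticSpec:
    fragments: list
    sigma: float = 0.05          # A coordinate jitter
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class GroundTruth:
    observations: list = field(default_factory=list)  # dicts per complex
    fragments: dict = field(default_factory=dict)     # het -> truth dict


# ---------------------------------------------------------------------------
# geometry helpers

def _unit(v):
    v = np.asarray(v, float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ConstructionError("zero-length direction")
    return v / n


def _perp(u):
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, ref)) > 0.95:
        ref = np.array([1.0, 0.0, 0.0])
    return _unit(np.cross(u, ref))


def _ring(center, normal, radius=1.39, n=6, phase=0.0):
    e1 = _perp(normal)
    e2 = np.cross(normal, e1)
    return [center + radius * (math.cos(2 * math.pi * k / n + phase) * e1 +
                               math.sin(2 * math.pi * k / n + phase) * e2)
            for k in range(n)]


def _fibonacci_sphere(n):
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = math.pi * (1 + 5 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def layout_interactions(signature, radius, phase=0.0):
    """Place interaction anchors on a circle (z = 0) of the given radius;
    protein partners sit radially outward at the type's anchor distance."""
    n = max(len(signature), 1)
    spec = []
    for k, itype in enumerate(signature):
        ang = 2 * math.pi * k / n + phase
        u = np.array([math.cos(ang), math.sin(ang), 0.0])
        lig = radius * u
        prot = (radius + _DIST[itype]) * u
        spec.append((itype, lig, prot))
    return spec


# ---------------------------------------------------------------------------
# probe construction

def _probe_residue(itype, lig_pos, prot_pos, resnum):
    """Single-residue probe realizing one interaction.

    Only the anchor atom (and the phenyl ring of the aromatic probe)
    carries a pharmacophoric type; the scaffold atoms behind it use
    template-untyped names so probes do not flood the cavity cloud with
    interaction-specific labels.
    """
    u = _unit(prot_pos - lig_pos)
    p = np.asarray(prot_pos, float)
    if itype == HB_DONOR:  # pure-acceptor probe: backbone carbonyl
        atoms = [Atom("O", "O", p), Atom("C", "C", p + 1.23 * u),
                 Atom("CA", "C", p + 2.45 * u + 0.5 * _perp(u))]
        return Residue("A", resnum, "GLY", atoms)
    if itype == HB_ACCEPTOR:  # pure-donor probe: indole NH (partial TRP)
        w = _perp(u)
        atoms = [Atom("NE1", "N", p),
                 Atom("CA", "C", p + 1.30 * u + 0.55 * w),
                 Atom("C", "C", p + 1.30 * u - 0.55 * w)]
        return Residue("A", resnum, "TRP", atoms)
    if itype == IONIC_POS:  # carboxylate oxygen
        atoms = [Atom("OD1", "O", p, formal_charge=-1),
                 Atom("CG", "C", p + 1.25 * u),
                 Atom("CA", "C", p + 2.7 * u)]
        return Residue("A", resnum, "ASP", atoms)
    if itype == IONIC_NEG:  # guanidinium nitrogen
        atoms = [Atom("NH1", "N", p, formal_charge=1),
                 Atom("CZ", "C", p + 1.33 * u),
                 Atom("CA", "C", p + 2.6 * u)]
        return Residue("A", resnum, "ARG", atoms)
    if itype == AROMATIC:  # bare phenyl ring, stacked parallel
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        atoms = [Atom(nm, "C", pos) for nm, pos in
                 zip(names, _ring(p, u))]
        return Residue("A", resnum, "PHE", atoms)
    if itype == HYDROPHOBIC:  # leucine tip
        atoms = [Atom("CD1", "C", p), Atom("C", "C", p + 1.54 * u),
                 Atom("CA", "C", p + 2.9 * u)]
        return Residue("A", resnum, "LEU", atoms)
    raise ConstructionError(f"unknown interaction type {itype}")


def _ligand_atoms(interaction_spec):
    """Ligand atoms + bonds realizing the planted interaction anchors."""
    atoms, bonds = [], []
    anchor_of = []  # index of the anchor atom per spec entry
    for itype, lig_pos, prot_pos in interaction_spec:
        u = _unit(np.asarray(prot_pos) - np.asarray(lig_pos))
        L = np.asarray(lig_pos, float)
        if itype == HB_DONOR:
            i = len(atoms)
            atoms.append(Atom(f"N{i}", "N", L))
            atoms.append(Atom(f"H{i}", "H", L + 1.01 * u))
            bonds.append((i, i + 1, 1))
            anchor_of.append(i)
        elif itype == HB_ACCEPTOR:
            anchor_of.append(len(atoms))
            atoms.append(Atom(f"O{len(atoms)}", "O", L))
        elif itype == IONIC_POS:
            anchor_of.append(len(atoms))
            atoms.append(Atom(f"N{len(atoms)}", "N", L, formal_charge=1))
        elif itype == IONIC_NEG:
            anchor_of.append(len(atoms))
            atoms.append(Atom(f"O{len(atoms)}", "O", L, formal_charge=-1))
        elif itype == AROMATIC:
            start = len(atoms)
            ring = _ring(L, u)
            for k, pos in enumerate(ring):
                atoms.append(Atom(f"C{start + k}", "C", pos, is_aromatic=True))
            for k in range(6):
                bonds.append((start + k, start + (k + 1) % 6, 1))
            anchor_of.append(start)
        elif itype == HYDROPHOBIC:
            anchor_of.append(len(atoms))
            atoms.append(Atom(f"C{len(atoms)}", "C", L))
        else:
            raise ConstructionError(f"unknown interaction type {itype}")
    # central carbon keeps the ligand connected and >= 2 heavy atoms
    if interaction_spec:
        anchors = np.array([np.asarray(s[1], float) for s in interaction_spec])
        center = anchors.mean(axis=0)
        if np.min(np.linalg.norm(anchors - center, axis=1)) < 2.0:
            itype, L, P = interaction_spec[0]
            center = np.asarray(L, float) - 4.0 * _unit(
                np.asarray(P, float) - np.asarray(L, float))
        ci = len(atoms)
        atoms.append(Atom(f"C{ci}", "C", center))
        for a in anchor_of:
            bonds.append((a, ci, 1))
    else:
        atoms = [Atom("C0", "C", np.zeros(3)), Atom("C1", "C", [1.5, 0, 0])]
        bonds = [(0, 1, 1)]
    return atoms, bonds


def synth_complex(interaction_spec, seed: int = 0, jitter: float = 0.0,
                  het_code: str = "SYN", entry_id: str = "SYN1",
                  enclose: bool = True, wall_offset: float = 0.0,
                  wall_radius: float | None = None,
                  decorations=(), validate: bool = True,
                  rules: GeomRules | None = None) -> Complex:
    """Minimal complex whose detected interactions equal ``interaction_spec``.

    ``interaction_spec`` is a list of (itype, ligand_pos, protein_pos).
    ``decorations`` is a list of (pharmacophore label, position) adding
    typed single-atom residues that shape the cavity labeling without
    creating interactions (the caller guarantees clearance). ``enclose``
    adds an untyped carbon shell so cavity points are buried.
    """
    rng = np.random.default_rng(seed)
    rules = rules or GeomRules()
    lig_atoms, lig_bonds = _ligand_atoms(interaction_spec)
    residues = [_probe_residue(itype, lig, prot, num + 1)
                for num, (itype, lig, prot) in enumerate(interaction_spec)]

    for k, (label, pos) in enumerate(decorations):
        resname, aname, elem = _DECOR_TEMPLATES[label]
        residues.append(Residue("A", 100 + k, resname,
                                [Atom(aname, elem, np.asarray(pos, float))]))

    if enclose:
        lig_xyz = np.array([a.coords for a in lig_atoms if not a.is_hydrogen])
        center = np.zeros(3)  # anchor layout is centered at the origin
        if wall_radius is None:
            wall_radius = float(
                np.max(np.linalg.norm(lig_xyz - center, axis=1))) + 4.5
        R = wall_radius + wall_offset
        n_wall = max(80, int(4 * math.pi * R * R / 1.3))
        shell = center + R * _fibonacci_sphere(n_wall)
        occupied = [a.coords for r in residues for a in r.atoms]
        occupied = np.array(occupied) if occupied else np.empty((0, 3))
        for k, pos in enumerate(shell):
            if len(occupied) and \
               np.min(np.linalg.norm(occupied - pos, axis=1)) < 2.5:
                continue
            if np.min(np.linalg.norm(lig_xyz - pos, axis=1)) < 4.6:
                continue
            residues.append(Residue("W", 1000 + k, "GLY",
                                    [Atom("CA", "C", pos)]))

    cplx = Complex(entry_id=entry_id)
    cplx.protein_residues = residues
    lig = LigandInstance(het_code=het_code, copy_index=1, atoms=lig_atoms,
                         bonds=lig_bonds, chain_id="L", seqnum=1)
    cplx.ligand_instances = [lig]

    if jitter > 0:
        for res in cplx.protein_residues:
            for a in res.atoms:
                a.coords = a.coords + rng.normal(0, jitter, 3)
        for a in lig.atoms:
            a.coords = a.coords + rng.normal(0, jitter, 3)

    if validate:
        prepared = ensure_hydrogens(cplx)
        plig = prepared.ligand_instances[0]
        site = extract_site(prepared, plig, 6.5)
        found = sorted(i.itype for i in detect_interactions(plig, site, rules))
        wanted = sorted(s[0] for s in interaction_spec)
        if found != wanted:
            raise ConstructionError(
                f"planted {wanted} but detected {found}")
    return cplx


def complex_to_graph(cplx: Complex, config: PipelineConfig | None = None,
                     het_code: str | None = None, copy_index: int = 1):
    """Prepare hydrogens, extract the site and build the interaction graph
    for one ligand instance (the first one by default)."""
    config = config or PipelineConfig()
    prepared = ensure_hydrogens(cplx)
    if het_code is None:
        lig = prepared.ligand_instances[0]
    else:
        lig = prepared.get_ligand(het_code, copy_index)
    site = extract_site(prepared, lig, config.site_radius)
    inter = detect_interactions(lig, site, config.geom_rules)
    return build_interaction_graph(inter)


# ---------------------------------------------------------------------------
# mode families

def synth_mode_family(K: int, n_per_mode: int, sigma: float = 0.05,
                      seed: int = 0, enclose: bool = False):
    """``K`` planted binding modes, ``n_per_mode`` jittered observations
    each. Returns (complexes, GroundTruth)."""
    if not 1 <= K <= len(MODE_SIGNATURES):
        raise ValueError(f"K must be in 1..{len(MODE_SIGNATURES)}")
    rng = np.random.default_rng(seed)
    complexes, truth = [], GroundTruth()
    for m in range(K):
        signature, radius = MODE_SIGNATURES[m]
        spec = layout_interactions(signature, radius)
        for r in range(n_per_mode):
            sub = int(rng.integers(0, 2 ** 31 - 1))
            cplx = synth_complex(spec, seed=sub, jitter=sigma,
                                 entry_id=f"M{m}R{r}", enclose=enclose)
            complexes.append(cplx)
            truth.observations.append(
                {"entry": cplx.entry_id, "mode_id": m, "cavity_id": 0})
    truth.fragments["SYN"] = {"K": K, "M": 1, "versatile": False}
    return complexes, truth


# ---------------------------------------------------------------------------
# cavity environments (direct cloud construction)

def _env_base_cloud(env: int, rng, n_points: int = 40) -> LabeledCloud:
    """One environment: a lattice blob with a spatially coherent,
    environment-specific label composition."""
    comp = ENV_COMPOSITIONS[env % len(ENV_COMPOSITIONS)]
    a, b, c = 7.0 + env, 5.0 + 0.7 * env, 3.5 + 0.5 * env
    h = 1.5
    grid = np.stack(np.meshgrid(
        np.arange(-a, a + h, h), np.arange(-b, b + h, h),
        np.arange(-c, c + h, h), indexing="ij"), axis=-1).reshape(-1, 3)
    inside = ((grid[:, 0] / a) ** 2 + (grid[:, 1] / b) ** 2 +
              (grid[:, 2] / c) ** 2) <= 1.0
    pts = grid[inside]
    if len(pts) > n_points:
        idx = rng.choice(len(pts), n_points, replace=False)
        pts = pts[np.sort(idx)]
    labels = np.empty(len(pts), dtype=object)
    (l1, f1), (l2, _) = sorted(comp.items(), key=lambda kv: -kv[1])
    cut = np.quantile(pts[:, 0], f1)
    labels[pts[:, 0] <= cut] = l1
    labels[pts[:, 0] > cut] = l2
    return LabeledCloud(pts, labels, h)


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def synth_cavity_set(M: int, n_obs: int, transform_magnitude: float = 20.0,
                     label_noise: float = 0.0, seed: int = 0,
                     n_points: int = 40):
    """``M`` distinct environments observed ``n_obs`` times each as rigid
    copies (random rotation + translation) with optional label noise.
    Returns (clouds, GroundTruth, transforms) where transforms[i] is the
    (R, t) that produced observation i from its environment base cloud."""
    if not 1 <= M <= len(ENV_COMPOSITIONS):
        raise ValueError(f"M must be in 1..{len(ENV_COMPOSITIONS)}")
    rng = np.random.default_rng(seed)
    clouds, transforms, truth = [], [], GroundTruth()
    all_labels = list(_DECOR_TEMPLATES)
    for env in range(M):
        base = _env_base_cloud(env, rng, n_points)
        for r in range(n_obs):
            R = _random_rotation(rng)
            t = rng.uniform(-transform_magnitude, transform_magnitude, 3)
            obs = base.transformed(R, t)
            if label_noise > 0:
                flip = rng.random(len(obs)) < label_noise
                for i in np.where(flip)[0]:
                    obs.labels[i] = all_labels[rng.integers(len(all_labels))]
            clouds.append(obs)
            transforms.append((R, t))
            truth.observations.append(
                {"entry": f"C{env}R{r}", "mode_id": 0, "cavity_id": env})
    truth.fragments["SYN"] = {"K": 1, "M": M, "versatile": False}
    return clouds, truth, transforms


# ---------------------------------------------------------------------------
# full corpus

DEFAULT_CORPUS_PLAN = [
    FragmentPlan("VF1", "Cc1ccc(O)cc1", [0, 1, 0, 1], [0, 0, 1, 1], None, 2),
    FragmentPlan("VF2", "c1ccc2[nH]ccc2c1", [0, 1, 2, 0, 1], [0, 0, 0, 1, 1],
                 None, 3),
    FragmentPlan("VF3", "Nc1ncnc2[nH]cnc12", [3, 4, 3, 4], [0, 0, 1, 1],
                 None, 2),
    FragmentPlan("SE1", "c1ccncc1", [0], [0], 2, 1),
    FragmentPlan("GOL", "OCC(O)CO", [0, 0], [0, 0], 1, 1),
    FragmentPlan("SO4", "O=S(=O)(O)O", [0, 0], [0, 0], 1, 1),
    FragmentPlan("SC1", "Oc1ccccn1", [0, 2, 0, 2], [0, 0, 0, 0], 4, 2),
    FragmentPlan("CAT", "Oc1ccccc1O", [0, 1, 0, 1], [0, 0, 1, 1], 5, 2),
    FragmentPlan("SM1", "CC(N)=O", [1, 1], [0, 0], 3, 1),
    # inclusion pair: a lone H-bond mode embeds in the richer mode -> merged
    FragmentPlan("INC", "c1ccsc1", [-1, -1, -2, -2], [0, 0, 0, 0], 3, 1),
]

# special signatures for the inclusion-merge fragment: the shared H-bond
# sits at the same anchor so the small graph embeds in the large one
_INC_SIG_SMALL = ((HB_DONOR,), 4.5)
_INC_SIG_BIG = ((HB_DONOR, HYDROPHOBIC, HB_ACCEPTOR), 4.5)


def _fragment_mode_spec(mode_id: int):
    if mode_id == -1:
        sig, radius = _INC_SIG_SMALL
    elif mode_id == -2:
        sig, radius = _INC_SIG_BIG
    else:
        sig, radius = MODE_SIGNATURES[mode_id]
    return layout_interactions(sig, radius)


def _typed_shell(frag_specs, env: int, rng, clearance: float = 4.9):
    """A pharmacophore-typed pocket lining for one environment.

    Single-atom residues are placed on the offset surface at ``clearance``
    from the nearest ligand atom (over every mode of the fragment), so the
    lining hugs the pocket and its labels reach most cavity points. Each
    lining atom carries a pharmacophoric label drawn from the
    environment's composition, assigned per angular octant so labels form
    coherent patches. The lining provides buriedness AND the
    environment-specific cavity labeling; at ~4.9 A from every ligand atom
    it sits outside all interaction cutoffs.
    """
    comp = ENV_COMPOSITIONS[env % len(ENV_COMPOSITIONS)]
    lig_pts, prot_pts = [], []
    for spec in frag_specs:
        atoms, _ = _ligand_atoms(spec)  # full atoms: ring carbons included
        lig_pts.extend(a.coords for a in atoms if not a.is_hydrogen)
        res = [_probe_residue(it, l, p, 1) for it, l, p in spec]
        for r in res:
            prot_pts.extend(a.coords for a in r.atoms)
    lig_pts = np.array(lig_pts) if lig_pts else np.zeros((1, 3))
    prot_pts = np.array(prot_pts) if prot_pts else np.zeros((1, 3))
    labels = list(comp)
    weights = np.array([comp[l] for l in labels], dtype=float)
    weights /= weights.sum()
    # one label per angular octant, drawn from the composition
    sector_labels = [labels[int(rng.choice(len(labels), p=weights))]
                     for _ in range(8)]
    # make sure the secondary label appears at least once
    if len(set(sector_labels)) == 1 and len(labels) > 1:
        sector_labels[int(rng.integers(8))] = labels[1]

    def _dist_to_ligand(pos):
        return float(np.min(np.linalg.norm(lig_pts - pos, axis=1)))

    rmax = float(np.max(np.linalg.norm(lig_pts, axis=1)))
    out = []
    n_dirs = max(300, int(4 * math.pi * (rmax + clearance) ** 2 / 1.2))
    for d in _fibonacci_sphere(n_dirs):
        # offset surface: walk outward until clearance from the ligand
        lo, hi = 0.0, rmax + clearance + 1.0
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            if _dist_to_ligand(mid * d) < clearance:
                lo = mid
            else:
                hi = mid
        pos = hi * d
        if len(prot_pts) and \
           np.min(np.linalg.norm(prot_pts - pos, axis=1)) < 2.2:
            continue
        octant = (int(pos[0] > 0) + 2 * int(pos[1] > 0) + 4 * int(pos[2] > 0))
        out.append((sector_labels[octant], pos))
    return out


def write_complex_pdb(cplx: Complex, path) -> None:
    """Write a complex as PDB via gemmi (charges kept in columns 79-80)."""
    import gemmi

    st = gemmi.Structure()
    st.name = cplx.entry_id
    model = gemmi.Model("1")
    chains: dict = {}

    def _add(chain_id, seqnum, resname, atoms, het):
        if chain_id not in chains:
            chains[chain_id] = gemmi.Chain(chain_id)
        res = gemmi.Residue()
        res.name = resname
        res.seqid = gemmi.SeqId(seqnum, " ")
        res.het_flag = "H" if het else "A"
        for a in atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.coords)
            ga.charge = int(a.formal_charge)
            ga.occ = 1.0
            res.add_atom(ga)
        chains[chain_id].add_residue(res)

    for r in cplx.protein_residues:
        _add(r.chain_id, r.seqnum, r.name, r.atoms, het=False)
    for lig in cplx.ligand_instances:
        _add(lig.chain_id or "L", lig.seqnum or lig.copy_index,
             lig.het_code, lig.atoms, het=True)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def synth_corpus(spec: SyntheticSpec, out_dir):
    """Write a corpus of PDB entries + components.csv + truth.csv.

    Deterministic under a fixed seed. Returns (corpus path, GroundTruth).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    truth = GroundTruth()
    entry_counter = 0

    for plan in spec.fragments:
        mode_set = sorted(set(plan.mode_ids))
        frag_specs = [_fragment_mode_spec(m) for m in mode_set]
        env_shell = {}
        het_key = sum(ord(c) * 31 ** i for i, c in enumerate(plan.het))
        env_rng = np.random.default_rng(
            (spec.seed * 1000003 + het_key) % (2 ** 31 - 1))
        for env in sorted(set(plan.env_ids)):
            env_shell[env] = _typed_shell(frag_specs, env, env_rng)
        for mode_id, env_id in zip(plan.mode_ids, plan.env_ids):
            entry_counter += 1
            entry = f"E{entry_counter:04d}"
            ispec = _fragment_mode_spec(mode_id)
            cplx = synth_complex(
                ispec, seed=int(rng.integers(0, 2 ** 31 - 1)),
                jitter=spec.sigma, het_code=plan.het, entry_id=entry,
                enclose=False, decorations=env_shell[env_id], validate=True)
            write_complex_pdb(cplx, out / f"{entry}.pdb")
            truth.observations.append(
                {"entry": entry, "het": plan.het,
                 "mode_id": mode_id, "cavity_id": env_id})
        truth.fragments[plan.het] = {
            "K": plan.k_expected,
            "M": len(set(plan.env_ids)),
            "versatile": plan.expected_reject_step is None,
            "expected_reject_step": plan.expected_reject_step,
        }

    with open(out / "components.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["het_code", "smiles"])
        for plan in spec.fragments:
            w.writerow([plan.het, plan.smiles])
    with open(out / "truth.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["entry", "het_code", "mode_id", "cavity_id",
                    "versatile", "expected_reject_step"])
        for obs in truth.observations:
            frag = truth.fragments[obs["het"]]
            w.writerow([obs["entry"], obs["het"], obs["mode_id"],
                        obs["cavity_id"], frag["versatile"],
                        frag["expected_reject_step"] or ""])
    return out, truth


def default_corpus_spec(seed: int = 0, sigma: float = 0.05) -> SyntheticSpec:
    """The standard 10-fragment study corpus: 3 planted versatile fragments
    plus decoys covering every rejection step."""
    return SyntheticSpec(fragments=list(DEFAULT_CORPUS_PLAN),
                         sigma=sigma, seed=seed)
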