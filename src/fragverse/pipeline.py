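"""The five-step versatile-fragment funnel.

1. Remove molecules that do not meet the fragment definition.
2. Keep only fragments present in more than one entry.
3. Keep fragments with two or more binding modes (interaction-graph
   clustering with the inclusion-merge correction).
4. Keep fragments bound in two or more dissimilar cavities (labeled
   point-cloud registration and clustering).
5. Remove PAINS.

Steps run lazily per fragment: a fragment failing step 3 never enters the
cavity computation. Entry metadata filters (deposition year >= 2000,
resolution < 3 A) apply at ingestion when the metadata is present; absent
metadata passes with a warning.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .config import PipelineConfig
from .fragdef import (Molecule, classify_ligand, filter_multi_entry,
                      pains_flags, compute_descriptors, ro3_violations,
                      murcko_scaffold)
from .structio import read_structure, ensure_hydrogens, extract_site
from .interact import detect_interactions, build_interaction_graph
from .modeclust import count_binding_modes
from .cavity import generate_cavity_cloud, count_cavities

logger = logging.getLogger(__name__)

__all__ = ["FragmentRecord", "PipelineReport", "run_pipeline", "export_deposit"]


@dataclass
class FragmentRecord:
    het_code: str
    smiles: str | None = None
    n_entries: int = 0
    n_instances: int = 0
    n_binding_modes: int | None = None
    n_cavities: int | None = None
    pains: list = field(default_factory=list)
    descriptors: object = None
    ro3: int | None = None
    scaffold_smiles: str | None = None
    step_rejected_at: int | None = None
    reject_reasons: list = field(default_factory=list)

    @property
    def versatile(self) -> bool:
        return (self.step_rejected_at is None
                and (self.n_binding_modes or 0) >= 2
                and (self.n_cavities or 0) >= 2
                and not self.pains)


@dataclass
class PipelineReport:
    step_counts: dict = field(default_factory=dict)  # step -> survivors
    records: list = field(default_factory=list)
    quarantined: list = field(default_factory=list)  # (path, reason)
    provenance: dict = field(default_factory=dict)

    @property
    def versatile(self) -> list:
        return sorted(r.het_code for r in self.records if r.versatile)

    def record(self, het: str) -> FragmentRecord:
        for r in self.records:
            if r.het_code == het:
                return r
        raise KeyError(het)


def _load_components(corpus_dir: Path) -> dict:
    path = corpus_dir / "components.csv"
    if not path.exists():
        return {}
    out = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["het_code"].upper()] = row["smiles"]
    return out


def _passes_metadata(cplx, config) -> bool:
    if cplx.resolution is not None and cplx.resolution >= config.max_resolution:
        return False
    if cplx.deposition_date:
        try:
            year = int(str(cplx.deposition_date)[:4])
            if year < config.min_deposition_year:
                return False
        except ValueError:
            pass
    else:
        logger.warning("%s: no deposition date; entry kept", cplx.entry_id)
    return True


def run_pipeline(corpus_dir, config: PipelineConfig | None = None,
                 seed: int | None = None) -> PipelineReport:
    """Run the funnel over every structure file in ``corpus_dir``."""
    config = config or PipelineConfig()
    config.validate()
    if seed is None:
        seed = config.random_seed
    corpus_dir = Path(corpus_dir)
    report = PipelineReport(provenance={
        "seed": seed, "config": config.to_dict(), "tool": "fragverse"})

    smiles_map = _load_components(corpus_dir)
    complexes = []
    paths = sorted(list(corpus_dir.glob("*.pdb")) +
                   list(corpus_dir.glob("*.cif")) +
                   list(corpus_dir.glob("*.mmcif")))
    for path in paths:
        try:
            cplx = read_structure(path)
        except Exception as exc:  # quarantined, never silently dropped
            logger.error("quarantined %s: %s", path.name, exc)
            report.quarantined.append((str(path), str(exc)))
            continue
        if _passes_metadata(cplx, config):
            complexes.append(cplx)

    # group ligand instances by HET code
    instances: dict = {}
    for cplx in complexes:
        for lig in cplx.ligand_instances:
            instances.setdefault(lig.het_code, []).append((cplx, lig))

    for het in sorted(instances):
        pairs = instances[het]
        rec = FragmentRecord(
            het_code=het, smiles=smiles_map.get(het),
            n_entries=len({c.entry_id for c, _ in pairs}),
            n_instances=len(pairs))
        report.records.append(rec)
        if rec.smiles:
            try:
                mol = Molecule.from_smiles(rec.smiles, het_code=het)
                verdict = classify_ligand(mol)
                rec.descriptors = compute_descriptors(mol)
                rec.ro3 = ro3_violations(
                    rec.descriptors, config.ro3_mw, config.ro3_hbd,
                    config.ro3_hba, config.ro3_logp, config.ro3_rotb)
                rec.scaffold_smiles = murcko_scaffold(mol).smiles
            except ValueError as exc:
                rec.step_rejected_at = 1
                rec.reject_reasons = [f"unparsable: {exc}"]
                continue
            if not verdict.accepted:
                rec.step_rejected_at = 1
                rec.reject_reasons = verdict.reject_reasons
        else:
            logger.warning("%s: no SMILES in components.csv; "
                           "definition/PAINS checks skipped", het)
            mol = None

    survivors = [r for r in report.records if r.step_rejected_at is None]
    report.step_counts[1] = len(survivors)

    multi = filter_multi_entry(
        [(c.entry_id, lig.het_code) for c, lig in
         (p for het in instances for p in instances[het])])
    for rec in survivors:
        if rec.het_code not in multi:
            rec.step_rejected_at = 2
    survivors = [r for r in survivors if r.step_rejected_at is None]
    report.step_counts[2] = len(survivors)

    prepared_cache: dict = {}

    def _prepared(cplx):
        if cplx.entry_id not in prepared_cache:
            prepared_cache[cplx.entry_id] = ensure_hydrogens(cplx)
        return prepared_cache[cplx.entry_id]

    for rec in survivors:
        graphs = []
        for cplx, lig in instances[rec.het_code]:
            prep = _prepared(cplx)
            plig = prep.get_ligand(lig.het_code, lig.copy_index)
            site = extract_site(prep, plig, config.site_radius)
            if site.is_empty:
                logger.warning("%s/%s: empty site", cplx.entry_id, rec.het_code)
            inter = detect_interactions(plig, site, config.geom_rules)
            graphs.append(build_interaction_graph(inter))
        clustering = count_binding_modes(graphs, config)
        rec.n_binding_modes = clustering.n_modes
        if clustering.n_modes < 2:
            rec.step_rejected_at = 3
    survivors = [r for r in survivors if r.step_rejected_at is None]
    report.step_counts[3] = len(survivors)

    for rec in survivors:
        clouds = []
        for cplx, lig in instances[rec.het_code]:
            prep = _prepared(cplx)
            plig = prep.get_ligand(lig.het_code, lig.copy_index)
            env = extract_site(prep, plig, config.cavity_site_radius)
            clouds.append(generate_cavity_cloud(env, plig, config))
        empty = [i for i, c in enumerate(clouds) if len(c) == 0]
        if empty:
            logger.warning("%s: %d empty cavity clouds", rec.het_code, len(empty))
        clouds = [c for c in clouds if len(c)]
        rec.n_cavities = count_cavities(clouds, config, seed=seed) if clouds else 0
        if rec.n_cavities < 2:
            rec.step_rejected_at = 4
    survivors = [r for r in survivors if r.step_rejected_at is None]
    report.step_counts[4] = len(survivors)

    for rec in survivors:
        if rec.smiles:
            rec.pains = pains_flags(Molecule.from_smiles(rec.smiles))
            if rec.pains:
                rec.step_rejected_at = 5
    survivors = [r for r in survivors if r.step_rejected_at is None]
    report.step_counts[5] = len(survivors)
    return report


def export_deposit(report: PipelineReport, out_dir) -> Path:
    """Write the deposit-style CSV bundle (versatile fragments, post-step-2
    fragments, entry info, RSCC placeholders, substructure-search results)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _write(name, header, rows):
        with open(out / name, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(header)
            w.writerows(rows)

    _write("versatile_fragments.csv",
           ["het_code", "smiles", "n_binding_modes", "n_cavities",
            "ro3_violations", "scaffold"],
           [[r.het_code, r.smiles or "", r.n_binding_modes, r.n_cavities,
             r.ro3 if r.ro3 is not None else "", r.scaffold_smiles or ""]
            for r in report.records if r.versatile])
    _write("post_step2_fragments.csv",
           ["het_code", "smiles"],
           [[r.het_code, r.smiles or ""] for r in report.records
            if r.step_rejected_at is None or r.step_rejected_at > 2])
    _write("entries.csv",
           ["het_code", "n_entries", "n_instances", "step_rejected_at"],
           [[r.het_code, r.n_entries, r.n_instances,
             r.step_rejected_at if r.step_rejected_at else ""]
            for r in report.records])
    _write("rscc_scores.csv",
           ["het_code", "entry", "ligand_rscc", "site_mean_rscc", "class"], [])
    _write("substructure_search.csv",
           ["query_het", "target_id", "bond_fraction", "exact_match"], [])
    with open(out / "report.json", "w") as fh:
        json.dump({"step_counts": report.step_counts,
                   "versatile": report.versatile,
                   "quarantined": report.quarantined,
                   "provenance": report.provenance}, fh, indent=2, sort_keys=True)
    return out
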