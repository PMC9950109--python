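"""Pipeline-wide configuration.

All tunable constants of the versatile-fragment workflow live here: the
fragment definition limits, the clustering radii for binding modes and
cavities, the subgraph-matching-kernel parameters, the cavity-cloud
geometry, and the sequence-alignment settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class GeomRules:
    """Geometric cutoffs for protein-ligand interaction typing.

    Distances are donor/acceptor heavy-atom distances in Angstrom, angles
    in degrees. Defaults follow the consensus values of geometric-rule
    interaction fingerprinting tools.
    """

    hbond_dist: float = 3.5          # donor-acceptor heavy-atom distance
    hbond_angle: float = 120.0       # D-H...A angle, applied when H is present
    ionic_dist: float = 4.0          # opposite formal charges
    aromatic_dist: float = 5.0       # ring centroid - ring centroid
    aromatic_parallel_angle: float = 30.0   # interplanar angle for stacking
    aromatic_tshape_lo: float = 60.0        # interplanar band for T-shaped
    aromatic_tshape_hi: float = 90.0
    hydrophobic_dist: float = 4.5    # apolar C/S pair distance


@dataclass
class PipelineConfig:
    """All thresholds of the five-step versatile-fragment funnel."""

    # step 1 - fragment definition
    mw_max: float = 300.0
    heavy_min: int = 2
    heavy_max: int = 18

    # rule of three (characterization, not a funnel step)
    ro3_mw: float = 300.0
    ro3_hbd: int = 3
    ro3_hba: int = 3
    ro3_logp: float = 3.0
    ro3_rotb: int = 3

    # step 3 - binding-mode clustering
    mode_eps: float = 0.23
    cluster_min_samples: int = 2
    smk_max_nodes: int = 3
    smk_edge_dmax: float = 1.0       # A, edge-kernel tolerance
    merge_edge_tol: float = 0.5      # A, inclusion-merge embedding tolerance

    # step 4 - cavity clustering
    cavity_score_threshold: float = 0.47
    literal_eps: bool = False        # if True, DBSCAN eps = 0.47 on 1 - score
    cavity_fragment_dist: float = 4.0    # A, cloud point to fragment
    cavity_grid_spacing: float = 1.5
    cavity_clash_dist: float = 2.0
    cavity_burial_range: float = 8.0
    cavity_burial_min_rays: int = 7      # out of 14 lattice directions
    cavity_match_dist: float = 1.5       # A, same-label inlier distance
    ransac_iterations: int = 1000
    icp_iterations: int = 10

    # sequence comparison
    identity_eps_close: float = 0.10
    identity_eps_distant: float = 0.75
    sw_gap_open: float = 10.0
    sw_gap_extend: float = 0.5
    min_alignment_len: int = 100

    # site extraction (interactions) and the wider environment used for
    # cavity buriedness testing
    site_radius: float = 6.5
    cavity_site_radius: float = 12.0

    # ingestion metadata filters
    min_deposition_year: int = 2000
    max_resolution: float = 3.0

    random_seed: int = 0
    geom_rules: GeomRules = field(default_factory=GeomRules)

    def to_dict(self) -> dict:
        return asdict(self)

    def validate(self) -> None:
        if not (0 < self.mode_eps < 1):
            raise ValueError("mode_eps must be in (0,1)")
        if not (0 < self.cavity_score_threshold < 1):
            raise ValueError("cavity_score_threshold must be in (0,1)")
        for name in ("mw_max", "smk_edge_dmax", "cavity_fragment_dist",
                     "cavity_grid_spacing", "site_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_CONFIG = PipelineConfig()
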