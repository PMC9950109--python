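# Methods

This note records the models, parameter choices and numerical decisions
behind fragverse, and what the synthetic-data suite does and does not
demonstrate.

## Interaction model

Protein–ligand contacts are typed by geometric rules. The exact
thresholds used by the established interaction-fingerprinting tools are
not published in full, so the defaults here are reconstructions chosen to
sit at the community's consensus values; all are configurable
(`GeomRules`):

| interaction | rule | default |
|---|---|---|
| hydrogen bond | donor–acceptor heavy-atom distance; D–H···A angle where an explicit H exists | ≤ 3.5 Å, ≥ 120° |
| ionic | opposite formal charges | ≤ 4.0 Å |
| aromatic stacking | ring-centroid distance; interplanar angle parallel or T-shaped | ≤ 5.0 Å; ≤ 30° or 60–90° |
| hydrophobic | apolar C/S pair | ≤ 4.5 Å |

Protein atoms are typed from residue-name templates (backbone N/O plus
the canonical side-chain donors, acceptors, charges, rings and apolar
carbons). Histidine is treated as neutral; metal coordination, halogen
bonds, cation–π, water-mediated and weak hydrogen bonds are outside the
four interaction classes and are ignored.

Three tie-break decisions matter and are deliberate:

- **Ionic precedence.** An atom pair that satisfies the ionic rule is
  reported as ionic only, never additionally as a hydrogen bond — a
  charged-pair contact is one physical interaction.
- **Stacked rings are not hydrophobic contacts.** Ring-atom pairs of two
  rings engaged in a detected aromatic stacking are excluded from the
  hydrophobic rule; parallel rings at ~3.8 Å would otherwise always add
  spurious hydrophobic nodes and double-count the same contact.
- **Hydrophobic collapse.** Bonded ligand apolar atoms contacting the
  same residue are collapsed to the closest pair, preventing node
  inflation along aliphatic chains.

Hydrogen placement is template/valence-based: hydroxyl oxygens (one
heavy neighbour at single-bond length) receive one H at 0.96 Å anti to
the neighbour; trivalent nitrogens are filled at 1.01 Å (two-coordinate
aromatic N stays bare, the pyridine default); backbone amide H is rebuilt
from N, CA and the preceding carbonyl carbon. Side-chain protein
hydrogens are rotamer-ambiguous and are not placed; the angle criterion
applies only where an H exists. Protonation-sensitive cases (a fragment
whose charge state differs between sites) can be handled by overriding
ligand formal charges per entry before detection.

## Binding-mode clustering

The subgraph matching kernel sums over unordered node subsets S of the
first graph (1 ≤ |S| ≤ 3) and injective label-preserving maps into the
second, weighting each mapping by the product of pairwise edge kernels
k_e(a,b) = max(0, 1 − |a−b| / 1 Å); node compatibility is label equality
(hydrogen-bond midpoint nodes carry a distinct midpoint label). This
counting convention is fixed by a worked identity: two 2-node
HYDROPHOBIC graphs with edges 2.0 and 2.5 Å give raw k₁₂ = 4 + 2·0.5 = 5
and self-kernels 6, hence similarity 5/6. The implementation is verified
against a brute-force enumeration oracle at every build.

Clustering uses DBSCAN (scikit-learn, precomputed distances,
eps = 0.23, min_samples = 2) on 1 − normalized similarity. With
min_samples = 2 this is exactly connected components of the
eps-threshold graph; isolated graphs (noise) count as singleton binding
modes — a fragment observed twice with unrelated interaction patterns
has two modes. The eps value is taken as a constant of the method; its
original derivation from a score-distribution inflection is
dataset-dependent and is not recomputed here.

**Inclusion merge.** Clusters A and B merge when every graph of A embeds
(injective, label-preserving, all edge-length differences ≤ 0.5 Å) into
some graph of B, with transitive closure. This replaces a proprietary
3D-shape criterion with the relation it was described as capturing:
one binding mode being a sub-pattern of another. Interaction-free graphs
embed vacuously and are therefore barred from merging, otherwise a
single empty observation would bridge unrelated modes.

## Cavity clouds and comparison

Cloud generation emulates a grid-based pocket descriptor: lattice
spacing 1.5 Å, clash distance 2.0 Å, points within 4.0 Å of a fragment
heavy atom, buriedness = at least 7 of 14 lattice ray directions hit a
protein heavy atom within 8 Å. The lattice is anchored to a canonical
frame derived from the ligand + site heavy atoms (PCA axes, sign-fixed
by third moments with a first-moment fallback, right-handed) so that
cloud generation is exactly equivariant under rigid motion of the
complex — a world-aligned lattice would not be. The buriedness test uses
the protein environment within 12 Å of the ligand (`cavity_site_radius`),
wider than the 6.5 Å interaction site, because pocket enclosure is a
property of the surroundings, not just the first shell.

Each point takes the pharmacophoric type of the nearest protein heavy
atom within 4 Å with precedence charged > H-bond > aromatic >
hydrophobic, else DUMMY.

Registration is seeded and deterministic: per-point descriptors
(neighbour-label histograms in two distance bins ≤ 4 Å) propose
same-label candidate correspondences; RANSAC (1000 iterations, batched
3-point Kabsch, edge-length-compatibility gating) scores hypotheses by
same-label inliers on a subsample; the best transform is refined by
label-constrained ICP. The score is the fraction of the smaller cloud's
**typed** points with a same-label counterpart within 1.5 Å after
alignment, computed in both directions with the best kept. DUMMY points
shape the cloud but are excluded from matching and normalization: untyped
filler is chemically anonymous, and counting DUMMY–DUMMY coincidences
would make unrelated pockets of similar size look alike. Calibration:
identical clouds score 1.0, disjoint label sets 0.0. Clouds with fewer
than three typed points fall back to label-bag overlap and are flagged
low-confidence.

The similarity threshold 0.47 is read as "pairs cluster when score
≥ 0.47", i.e. DBSCAN eps = 0.53 on 1 − score. The alternative literal
reading (eps = 0.47 on the distance) is available via
`PipelineConfig.literal_eps`; the two differ only for scores in
(0.47, 0.53).

## Sequence and structure comparison

Local alignment is Biopython's PairwiseAligner in local mode with
BLOSUM62, gap open 10 and extension 0.5 (the EMBOSS-water setup); X is
rescored to 0. Identity is identical pairs over aligned columns, gap
columns included. Alignments shorter than 100 columns are forced to
distance 1 before clustering. The 3/2-chain site split selects the
majority chain unflagged (3 of 5 is more than half); the plurality flag
fires only when no chain exceeds half, with ties broken by chain id.
Backbone RMSD uses Kabsch superposition on residue correspondences from
the sequence alignment (N/CA/C/O); a dedicated structural-alignment
algorithm is out of scope, so RMSD values on remote homologs are
indicative. Under isotropic coordinate noise σ the expected
post-superposition RMSD is σ√(3(1−2/N)) (six rigid degrees of freedom
removed from 3N), verified by Monte-Carlo.

## Synthetic data: what it emulates, what it does not

The generator builds minimal complexes, not folded proteins: each
planted interaction is realized by a single-residue probe whose anchor
atom satisfies the corresponding geometric rule with margin (H-bond
anchors at 3.0 Å, ionic at 3.6 Å, stacking at 3.8 Å, hydrophobic at
4.0 Å), and `synth_complex` verifies by construction that detection
returns exactly the planted list. Binding modes are interaction-type
signatures laid out on circles; signatures sharing labels use different
radii/anchor counts so their inter-anchor chords differ by more than the
1 Å edge tolerance — between-mode kernel terms floor at zero while
within-mode jitter (σ = 0.05 Å by default, up to 0.1 Å in the recovery
suites) keeps similarities high. Margins are construction constants, so
recovery tests probe correctness, not threshold luck.

Cavity environments are pharmacophore-typed pocket linings: an offset
surface at 4.9 Å from the ligand (outside every interaction cutoff),
labeled in coherent octant patches from environment-specific label
compositions whose pairwise overlap is below 0.3. All observations in
one environment share the lining; observations in different environments
share only the fragment-contacting probe labels. Archive-scale corpus
statistics (hundreds of fragments from a full structure-database
snapshot) are deliberately out of reach of this generator, and passing the
recovery suites does not show that the reconstructed geometric
thresholds match any particular published tool on real structures — the
two literature worked examples serve that purpose and require locally
fetched mmCIF files (see README).

The standard corpus plants 3 versatile fragments and 7 decoys covering
every rejection step, including an inclusion-merge pair (a lone H-bond
mode embedded in a richer mode) and a two-modes-one-pocket fragment.
Entries are written as PDB files with formal charges in the charge
column plus a `components.csv` with HET → SMILES, standing in for the
chemical component dictionary a real run would consult.

## Numerical and degenerate-input choices

- Aromatic ring perception for coordinate-only ligands: 5/6-membered
  C/N/O/S cycles with RMS plane deviation ≤ 0.15 Å (aromatic rings fit
  to ~0.01 Å even with noise; chair/envelope saturated rings deviate by
  ~0.25 Å).
- Plane of best fit: least-squares plane by SVD; undefined (None) for
  fewer than 3 atoms or collinear conformers.
- RSCC classes close the PARTIAL interval at both 0.8 and 0.9; site
  means exclude residues absent from the validation file (n−1
  denominator); an absent ligand yields a missing value, never 0.
- Multi-entry filtering counts distinct entry ids, not ligand copies.
- Empty interaction-graph observations and empty clouds are flagged and
  kept out of merging/scoring rather than silently dropped.
- All randomness (RANSAC, generators) flows from explicit seeds;
  pipeline reruns are byte-identical.

## Known limitations

- PAINS filtering ships the public SMARTS families A+B+C (480 rules);
  the commercial filter referenced in the literature uses 652 rules, so
  flag counts differ at the margins.
- Descriptors (AlogP, TPSA, rotatable bonds) use RDKit's published
  atomic-contribution schemes; vendor descriptor packages differ in the
  second decimal.
- Protein side-chain protonation is not modeled; protein-side H-bond
  geometry is distance-only.
- Nucleic-acid sites are out of scope (amino-acid residues only), as are
  halogen bonds, metal coordination and water-mediated contacts.
- The cavity registration assumes rigid pockets; flexible or partial
  matches beyond the overlap the ICP tolerates are not modeled.
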