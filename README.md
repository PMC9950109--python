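# fragverse

Mining protein–fragment complexes for **versatile fragments**: low
molecular weight compounds (MW < 300 Da, 2–18 heavy atoms) that are
observed with **two or more distinct binding modes** in **two or more
dissimilar binding cavities** across crystal structures. Such fragments
adapt their interaction pattern to the protein context, which makes them
attractive starting points for fragment-based drug discovery: they are
more likely to give hits against new targets than fragments that always
bind one way.

The package is aimed at structural bioinformaticians and fragment-library
designers who have a directory of protein–fragment complexes (mmCIF/PDB)
and want to classify the fragments by binding-mode and binding-site
diversity, then characterize the survivors chemically.

## Method

A five-step funnel is applied per chemical component (HET code):

1. **Fragment definition** — reject molecules with MW ≥ 300 Da or heavy
   atom count outside [2, 18], monosaccharides, organometallics,
   prosthetic groups, crystallization additives, simple polyatomic ions,
   polyhalogenated and linear aliphatic compounds.
2. **Occurrence** — keep fragments present in more than one entry.
3. **Binding modes** — each complex is encoded as an *interaction graph*:
   geometric rules detect hydrogen bonds, ionic bonds, aromatic stacking
   and hydrophobic contacts; every interaction places a typed pseudo-atom
   on the ligand interacting atom, and each hydrogen bond adds a second
   pseudo-atom halfway to the protein partner. The complete graph over
   the pseudo-atoms carries Euclidean edge lengths. Graphs of the same
   fragment are compared with a **subgraph matching kernel**

   &nbsp;&nbsp;&nbsp;&nbsp;k(G₁,G₂) = Σ_{S⊆V₁, |S|≤3} Σ_{f:S↪V₂ label-preserving} Π_{u<v∈S} k_e(d₁(u,v), d₂(f(u),f(v)))

   with edge kernel k_e(a,b) = max(0, 1 − |a−b|/1 Å), normalized as
   k₁₂/√(k₁₁k₂₂). Binding modes are DBSCAN clusters (eps = 0.23,
   min_samples = 2) of the 1 − similarity matrix; clusters whose graphs
   all embed into graphs of another cluster are merged (a sub-pattern of
   a mode is not a new mode). Fragments need ≥ 2 modes to survive.
4. **Binding cavities** — the pocket around each bound fragment is a
   lattice cloud (1.5 Å spacing) of clash-free, buried points within 4 Å
   of the fragment's heavy atoms, each labeled with the pharmacophoric
   type of the nearest protein atom (charged > H-bonding > aromatic >
   hydrophobic, else DUMMY). Clouds are compared by label-aware rigid
   registration (descriptor-matched RANSAC + label-constrained ICP); the
   score is the fraction of the smaller cloud's typed points with a
   same-label counterpart within 1.5 Å, best of both directions. Two
   cavities are similar when the score reaches 0.47; fragments need ≥ 2
   dissimilar cavities (DBSCAN as above).
5. **PAINS** — remove pan-assay interference compounds by SMARTS
   substructure matching.

Survivors are characterized: descriptor block (MW, AlogP, TPSA, HBD/HBA,
charges, rotatable bonds, rings, stereocenters), rule-of-three violations,
plane of best fit (mean distance of heavy atoms to their least-squares
plane — 0 for flat fragments), Bemis–Murcko scaffolds, symmetry-aware
conformer RMSD, Smith–Waterman sequence relatedness of the host proteins
(BLOSUM62, gaps 10/0.5, ≥ 100 aligned residues; ≥ 90% identity = same
protein or close homolog, ≥ 25% = distant homolog), backbone Kabsch RMSD,
and substructure contribution to larger molecules (bond-count ratio).

## Worked example

Generate a synthetic corpus with known ground truth (three planted
versatile fragments among seven decoys) and run the funnel:

```text
$ fragverse synth --seed 3 --out corpus/
corpus written to corpus (32 entries, planted versatile: VF1, VF2, VF3)

$ fragverse run --corpus corpus/ --out results/ --seed 3
step 1: 8 fragments remain
step 2: 7 fragments remain
step 3: 5 fragments remain
step 4: 4 fragments remain
step 5: 3 fragments remain
versatile: VF1, VF2, VF3
```

Reading: 10 HET codes enter; the glycerol-like additive and the sulfate
ion fail the fragment definition (step 1 leaves 8); the single-entry
fragment falls at step 2; the single-mode fragment and the
inclusion-merge pair (whose lone H-bond pattern embeds in the richer
pattern and is merged back) fall at step 3; the fragment seen only in one
pocket falls at step 4; the catechol falls to the PAINS filter at step 5.
Exactly the three planted versatile fragments remain. `results/`
contains the deposit-style CSVs (versatile fragments with SMILES, mode
and cavity counts; post-step-2 fragments; per-entry info) and
`report.json` with the funnel counts and provenance.

The same funnel runs on real structures: point `--corpus` at a directory
of mmCIF/PDB files (plus an optional `components.csv` mapping HET codes
to SMILES for the chemistry steps).

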