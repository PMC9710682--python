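# molpatch

Structure-based measures of protein surface hydrophobicity, with a
largest-hydrophobic-patch detector.

Proteins bury most hydrophobic residues in their core, but the ones left
exposed drive protein–protein and membrane interactions, aggregation and
chromatographic behaviour. This package quantifies how "sticky" a protein
surface is with three measures:

- **THSA** — total hydrophobic surface area: the summed accessible surface
  area (ASA) of the hydrophobic residues r ∈ {A, C, F, I, L, M, V, W, Y}, in Å².
- **RHSA** — relative hydrophobic surface area: THSA / TASA, where TASA is
  the total accessible surface area of all residues.
- **LHP** — largest hydrophobic patch: the area of the largest *connected*
  hydrophobic region of the surface, so LHP ≤ THSA ≤ TASA always.

The patch detector works on a surface point cloud. Each heavy atom
contributes a deterministic quasi-uniform lattice of points on its
probe-inflated sphere (probe 1.5 Å, density 1.5 points/Å²); points buried
inside neighbouring atoms are discarded and each survivor carries an equal
share of its sphere's analytic area. Points are labelled hydrophobic or
hydrophilic by the residue that owns their atom, points within 1.25 Å of
each other are connected (KD-tree search), edges with a hydrophilic
endpoint are dropped, and the connected components of what remains are the
hydrophobic patches, ranked by area:

    LHP = max over components C of Σ_{points p ∈ C} w_p

The package also provides the surrounding analysis stack: per-residue ASA
tables from sequence-based accessibility predictors can be aggregated into
THSA/RHSA; predictions are scored with relative errors
δ_i = |pred_i − ref_i| / ref_i and the threshold curve
F(t) = 100 · |{i : δ_i < t}| / |{i}|; sequence feature extraction and a
seeded train/validation harness support regression models (three-feature,
31-global-feature, and accessibility-derived feature sets); and
proteome-level tools give curation filters, expression deciles, preranked
gene lists, and the tissue-specific average surface hydrophobicity
TASH_t = Σ_g NX_{g,t}·h_g / Σ_g NX_{g,t} for expression table NX and any
per-gene hydrophobicity value h.

Intended users: structural bioinformaticians quantifying surface
hydrophobicity from PDB structures, and computational biologists relating
predicted hydrophobicity to expression data at proteome scale.

## Worked example

```bash
molpatch fixtures --kind pseudo_chain --pattern HPH --spacing 20 -o toy.pdb
molpatch measure toy.pdb --percent
```

prints

```json
{
  "tool": "molpatch",
  "version": "0.1.0",
  "params": {"probe_radius": 1.5, "density": 1.5, "edge_cutoff": 1.25},
  "structure_id": "toy",
  "chains": ["A"],
  "tasa": 371.97,
  "thsa": 257.36,
  "rhsa": 69.19,
  "rhsa_units": "percent",
  "lhp": 128.68
}
```

The toy chain has two hydrophobic pseudo-residues 40 Å apart separated by
a hydrophilic one: each hydrophobic sphere is fully exposed (THSA is two
sphere areas, 257.4 Å²), the surface is 69.2% hydrophobic, and because the
two hydrophobic clouds are disconnected the LHP is exactly half the THSA —
one sphere, 128.7 Å². `molpatch patches toy.pdb` lists both patches with
their residue membership. The same pipeline runs on real structures:
`molpatch measure 4O5J.pdb --chain A --percent`.

Further narrative scripts live in `examples/` (patch detection, ASA-table
aggregation, threshold-curve evaluation, proteome TASH).

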