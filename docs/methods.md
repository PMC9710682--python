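# Methods

## Surface model

The package computes accessible-surface areas and hydrophobic patches from
one shared geometry: a solvent-accessible surface (SAS) point cloud. Every
heavy atom is inflated by the probe radius (default 1.5 Å, a slightly
generous water probe) and sampled with a golden-spiral (Fibonacci)
lattice of `n = ceil(density · 4π(r + probe)²)` points at the default
density of 1.5 points/Å². A point is kept iff it is not strictly inside
any other atom's inflated sphere (tolerance 1e-9 Å; boundary points are
kept, which is deterministic and conservative). Each surviving point
carries weight `4π(r + probe)²/n`, so the weights of an isolated atom sum
to the analytic sphere area *exactly*, and per-residue ASA, TASA and patch
areas are all sums over the same weights. Occlusion candidates are found
with a KD-tree over atom centres (query radius = own inflated radius +
the largest inflated radius), which is exhaustive — it returns the same
survivors as the all-pairs test.

This is a Shrake–Rupley-style accessible surface with a deterministic
lattice instead of random sampling: there is no RNG anywhere in the
geometry path, so all surface outputs are bit-reproducible for fixed input
and parameters. It is *not* a solvent-excluded surface (SES): reentrant
area between atoms is not modelled, and absolute areas run systematically
larger than SES-based tools (DSSP, MSMS). Patch *topology* — which exposed
hydrophobic residues are surface-adjacent — is what the patch measures
need, and that is preserved; users comparing absolute areas against
SES-based references should expect a systematic offset and use relative
tolerances.

## Hydrophobicity and patches

Residues are hydrophobic iff their one-letter code is in
{A, C, F, I, L, M, V, W, Y}; every surface point inherits the flag of the
residue owning its generating atom (which is the nearest surface residue
by construction). Points within the edge cutoff (1.25 Å) of each other
are linked, edges with a hydrophilic endpoint are discarded, and connected
components of the remainder are the patches. Numerical choices:

- **Cutoff/density coupling.** 1.25 Å is calibrated to the default
  density (mean lattice spacing ≈ 0.8 Å). If the density is changed, the
  effective cutoff is scaled by `sqrt(1.5/density)` so that graph
  connectivity behaviour is preserved; the raw cutoff remains overridable.
- **Singletons.** Isolated hydrophobic points are singleton components, so
  patch areas always partition THSA exactly.
- **Ranking ties.** Equal-area patches are ordered by smallest member
  residue index, then smallest point index — determinism, nothing more.
- **Interior cavities.** All surviving surface points participate in the
  patch search, including points lining interior voids large enough to
  survive the occlusion test; they are part of the reported areas.

THSA/RHSA can also be aggregated from per-residue ASA tables produced by
sequence-based accessibility predictors (NetSurfP-style input). LHP
cannot: per-residue predictions carry no surface adjacency, so
table-derived measures report LHP as undefined and the regression harness
below exists to predict it instead.

## Structure input

PDB files are parsed with Biopython; waters and hetero records are
removed, hydrogens dropped by default (crystal structures rarely resolve
them), alternate locations resolved to the highest-occupancy conformer
(ties keep the first encountered), and only the first model of multi-model
files is used. A small built-in table maps common modified residues (MSE,
SEP, PTR, …) to their parent amino acid; unmapped residues are dropped
with a logged warning. Van der Waals radii are Bondi-style (C 1.70,
N 1.55, O 1.52, S 1.80 Å, default 1.70 Å) and overridable via a
two-column text file; the choice shifts absolute areas by a few percent
but barely moves RHSA, which is a ratio.

## Evaluation statistics

Relative errors are δ = |pred − ref|/ref; chains with zero reference are
excluded and counted separately (a zero-area reference has no meaningful
relative error). The threshold curve F(t) uses a *strict* inequality
δ < t and a default grid of t from 0 to 1 in steps of 0.01; it need not
reach 100% at t = 1 because relative errors can exceed 100%. R² defaults
to the squared Pearson correlation, with the coefficient-of-determination
variant behind a flag — the two differ whenever predictions are biased,
and both are useful diagnostics.

## Sequence features and regression harness

The 31 global features are: the 20 amino-acid counts, length, Shannon
entropy (bits, over the 20-letter frequency distribution), hydrophobic
count, polar count (= length − hydrophobic count), molecular weight,
aromaticity (frequency of F+W+Y), instability index (Guruprasad dipeptide
method), gravy (mean Kyte–Doolittle), buried fraction, isoelectric point
(Henderson–Hasselbalch bisection), and molar extinction coefficient
(Gill–von Hippel: 5500·W + 1490·Y + 125·cystine, all cysteines assumed
paired). Standard physicochemical values come from Biopython's ProtParam.
The "buried" feature has no canonical definition; here it is the fraction
of residues in {A, C, F, I, L, M, V} — the aliphatic/sulfur hydrophobics,
excluding the surface-active aromatics W and Y. `X` is tolerated in input
sequences: it counts toward length but is excluded from scale-based
features. Note two features are genuinely order-dependent (instability
index via dipeptides, pI via terminal pKa values); all others are
composition statistics.

Three feature sets feed pluggable scikit-learn regressors: the
three-feature set (length, hydrophobic count, hydrophilic count; default
linear model), the 31-feature global set (default gradient-boosted
trees), and the accessibility-derived set (predicted THSA and RHSA;
default random forest) used for LHP. The estimator brand is deliberately
pluggable — the fixed parts are the feature/target contracts, the seeded
80/20 train/test split, the inner split of the training part into a 2/3
cross-validation pool (k-fold grid search on R², default 5 folds,
parameterizable because both 3- and 5-fold schemes are defensible) and a
1/3 validation set.

## Proteome aggregation

Curation drops proteins with more than half their residues predicted
disordered, proteins longer than 800 residues, and duplicate gene ids
(keeping the highest-THSA entry, first on ties); the filter is
idempotent. Per-gene expression is the maximum NX over tissues (median
variant behind a flag), deciles are equal-count bins with stable-order
tie-breaking, and TASH_t is the NX-weighted mean of a hydrophobicity
value over the genes expressed in tissue t, optionally excluding e.g.
transmembrane-annotated genes. Ranked lists for preranked gene-set
enrichment are (value − center)/scale sorted descending; the center
defaults to the median but is user-overridable because the natural split
point of a bimodal measure distribution is dataset-dependent. Enrichment
itself (permutations, ES statistics) is out of scope — the module emits
standard 2-column `.rnk` input instead.

## Synthetic fixtures and what they show

Test structures use single-atom pseudo-residues (united-atom radius
1.9 Å) so every expected value has a closed form: a lone atom's area is
4π(r + probe)², far-apart atoms give disjoint clouds, a tight shell
around a central atom buries it completely, and linear H/P chains make
patch counts enumerable. Synthetic prediction tables draw references from
a lognormal (median 3000 Å², σ = 0.5 — the scale and spread typical of
per-chain surface areas) and apply bounded multiplicative uniform noise,
so F(t) has closed-form expectations (e.g. F(0.1) = 50% under ±20%
noise). Synthetic regression tables generate targets as fixed functions
of the feature set with optional 20% multiplicative noise; with n = 500
and an 80/20 split this puts held-out R² near 1 (noiseless) and in the
0.9 range (noisy) by the signal-to-noise closed form.

What passing these tests does *not* show: fixtures have no reentrant
geometry, no realistic packing density, and no correlation structure
between features, so agreement with SES-based areas on real proteins, and
real-data regression performance, are not certified by the suite. A
full-pipeline check against published values for two crystal structures
(4O5J, 1LML: residue counts, THSA within ±15%, RHSA within ±3 points, LHP
within ±15%) is included but requires the user to download those PDB
entries into `tests/data/`; the tolerances budget the SAS-vs-SES offset
and the unknown radii used by the reference computation.

## Known limitations

- SAS areas exceed SES areas systematically; absolute comparisons against
  DSSP/MSMS need a tolerance or a cross-calibration.
- Per-chain analysis is the default (`--all-chains` computes on the chain
  union); biological-assembly expansion and mmCIF input are not supported.
- The atom-based hydrophobicity labelling variant is deliberately not
  implemented; labelling is residue-based only.
- Problem sizes in the shipped tests and the acceptance script (fixtures
  of ≤ 6 residues, n = 500 regression tables, 10⁴-row prediction tables)
  were chosen so the full suite completes in well under a minute while
  keeping all closed-form checks tight.
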