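# Methods

## Data model and alignment

The evaluation unit is an aligned list of *(native residue, predicted
probability vector)* pairs with stratification labels. Structures are read
from PDB files (first model only; altlocs resolved to the highest-occupancy
conformer, ties to the first encountered; waters and unmappable
HETATM-only ligands dropped). Residue identities are canonicalized through
a shipped substitution table: the 20 standard residues map to their letter,
common non-canonicals map to their chemical parent (MSE→M, SEC→C, PYL→K,
HSD/HSE/HIE/HID→H, phospho-Ser/Thr/Tyr→S/T/Y, …), anything else becomes the
unknown marker `X`. Unknown residues carry no ground truth; they are
excluded from all metrics and reported per chain in an exclusion count.

Prediction CSVs (`chain_key,position,A,…,Y`) align to the canonicalized
residues **by row order** within each chain; `position` is bookkeeping
only. A row-count mismatch is a hard error — silent truncation or
intersection would quietly change the evaluated set. Probability vectors
must be non-negative; sums within 1 ± 0.01 are renormalized exactly to 1
(absorbing float truncation in exported files), sums outside that window
are an error naming the row.

## Metric definitions and conventions

All argmax and top-k operations break ties by alphabet order
(`ACDEFGHIKLMNPQRSTVWY`), making every reported number deterministic.

- **Recall / precision / F1** from the 20×20 confusion matrix; macro
  averages skip classes with a zero denominator (recall needs ≥1
  occurrence, precision ≥1 occurrence and ≥1 prediction) rather than
  imputing 0, so a short chain is not penalized for lacking rare residues.
- **AUC**: one-vs-rest, computed from midranks (Mann–Whitney), pooling all
  residues of the evaluation unit rather than averaging per chain. It
  equals the pairwise concordance count `(#concordant + ½·#ties)/#pairs`,
  which the tests verify against a brute-force double loop.
- **Entropy** is computed on the row-normalized confusion distribution of
  each true class (argmax-based), not on averaged probability vectors:
  this keeps it well defined for one-hot inputs and reads directly as "how
  spread out are this class's predictions" (0 bits = always the same
  letter, log₂ 20 = uniform). The alternative (entropy of mean predicted
  probabilities) is deliberately not mixed in; it would measure softness,
  not dispersion.
- **Prediction bias** `(n_predicted − n_true)/n_true` is dimensionless and
  signed; −1 means the class is never predicted, 0 that prediction
  frequency matches natural abundance. The denominator makes
  over-prediction of rare classes stand out.
- **Similarity** counts a substitution as correct when its BLOSUM62
  log-odds score is positive, i.e. the pair substitutes more often than
  chance in nature. Score-0 pairs do not count; the diagonal always does.
- **Resolution correlation**: Pearson r of per-chain accuracy vs crystal
  resolution, requiring ≥3 chains with a recorded resolution and non-zero
  variance in both variables; otherwise it is reported absent, never 0.

## Secondary structure

The built-in assigner reconstructs amide hydrogens (1.01 Å from N along the
normalized sum of the unit vectors N−C(prev) and N−CA — an approximation of
the DSSP convention), scores every donor/acceptor pair with the
Kabsch–Sander electrostatic model `E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH −
1/r_CN)·332` kcal/mol, and keeps bonds with `E < −0.5` kcal/mol and
sequence separation ≥ 2 (constants from the published method). Patterns:

- α-helix: residues `i…i+3` wherever 4-turns start at both `i−1` and `i`;
  runs are therefore always ≥ 4 residues.
- strand: any residue in a parallel or antiparallel bridge via the classic
  two-bond patterns; no singleton E is possible.
- ties (helix and bridge): helix wins — fixed precedence, deterministic.
- everything else, including residues with missing backbone atoms, is coil
  (missing-atom residues are flagged as excluded).

Prolines donate no hydrogen, and the first residue has no preceding
carbonyl to define one. The assigner emits 3 states only; 8-state codes
(G, I, T, S, B…) appear when labels are imported from DSSP files and are
reduced H,G,I→H / E,B→E / rest→C. It deliberately omits 3-10/π helices,
bends, β-bulges and polyproline II; on regular elements it matches DSSP,
on irregular structure it is coarser.

## Geometry

Dihedrals use the standard atan2 formulation, signed, right-handed, in
(−180°, 180°]; colinear triples raise an explicit undefined-torsion error.
φ(i) = C(i−1)–N(i)–CA(i)–C(i), ψ(i) = N(i)–CA(i)–C(i)–N(i+1); termini and
missing neighbour atoms yield absent angles. Ramachandran comparison
tables bin (φ, ψ) on a fixed 36×36 grid (10° bins, interval convention
(lo, hi]) per amino-acid label under two labelings — where the type is
native vs where it is predicted — and positions lacking either angle
contribute to neither, so each histogram's total equals its contributing
position count exactly.

## Synthetic fixtures

`build_chain_from_torsions` places backbone atoms by NeRF-style internal
coordinates with fixed ideal geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N
1.329 Å, C=O 1.231 Å; angles N-CA-C 111.2°, CA-C-N 116.2°, C-N-CA 121.7°,
CA-C-O 120.5°; ω fixed trans). Torsion round-trips through `phi_psi` are
exact to well below 1e−6°, which the tests assert. The ideal helix uses
(φ, ψ) = (−57°, −47°); extended strands (−139°, 135°).

The antiparallel sheet is the strand plus a copy rotated 180° about the
in-plane axis perpendicular to the strand direction and offset 4.8 Å along
the sheet normal. Registration of carbonyls against amide protons needs an
additional shift along the strand axis; this constant (−2.8 Å, plus half a
residue rise for odd strand lengths, whose pleat parity moves the C2
centre) was calibrated once against the ideal-strand geometry and is part
of the fixture definition.

Synthetic predictors (perfect, uniform, constant, biased, softmax-noise)
are seed-deterministic and have analytically known expected metrics; the
*biased(x, s)* predictor emits, per residue, a one-hot at `x` with
probability `s` and a one-hot at the native residue otherwise, so its
expected accuracy is `1 − s + s·f_x` and measured accuracy is binomial
around it — the planted-parameter recovery tests check a 3σ window at
n = 2000. The toy benchmark writes ≥ 8 chains spanning all four fold
classes (default 2 chains × 18 residues per class, sizes chosen to keep
the whole suite desk-scale while every stratum stays populated), with
resolutions drawn in (1 Å, 3 Å], plus DSSP-style label files and a sidecar
manifest of the planted composition. The packaged static composition table
(70/282/196/47 chains per fold class, 595 total) ships for bookkeeping
checks only; no real structures are bundled.

What the fixtures do **not** emulate: side chains, crystallographic noise
and missing density, non-ideal bond geometry, chain breaks inside a
segment, multi-chain PDB entries, and real DSSP output (the packaged
`.dssp` files are written from the built-in assigner's labels, so the
import-agreement test validates the format round-trip and the 8→3
reduction, not agreement with the external DSSP program). Passing tests
therefore demonstrate correctness of the metrics and plumbing, not
robustness to experimental-structure pathology.

## Numerical and design choices

- Comparisons across models require an *identical* residue set (same
  chains, same native sequences); a mismatch is an error, never a silent
  intersection.
- Renormalization tolerance ±0.01; validated vectors sum to 1 within
  1e−6. Metric-oracle agreement is asserted at 1e−9; torsion round-trips
  at 1e−6°; stratification conservation at 1e−12.
- Undefined metrics are absent (NaN/None), never imputed.
- All generator and test randomness flows through explicit
  `numpy.random.default_rng` seeds; two runs on the same inputs produce
  byte-identical CSV outputs.
- Plots are a thin matplotlib layer over their CSV twins; nothing asserts
  on pixels.

## Limitations / future work

No significance tests or bootstrap intervals on metric differences between
models; no mmCIF input; NMR ensembles use the first model only; CATH codes
are taken from the dataset map, never fetched.
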