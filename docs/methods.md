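# Methods

## The dissimilarity

Two frames A and B with the same element composition are compared by the
weighted RMSD after minimization over (i) a species-preserving
relabeling of B's atoms and (ii) rigid rotations, with the translation
fixed by centering both frames on their solute centroid.  Weights follow
the solute/solvent split: a total solute weight W ∈ [0, 1] is spread
uniformly over the first N_solute atoms and 1 − W uniformly over the
rest; W = N_solute/N reproduces uniform weights, which are the default.
The same weight vector is used for the rotation fits and for the
reported RMSD.

### Staged minimization

The search is staged rather than joint, because assignment-based
relabeling depends on the current Euclidean distances: relabeling a
badly oriented frame pairs the wrong atoms, and a rotation fitted to a
bad pairing is itself bad.  Anchoring on the solute breaks the cycle:

1. translate both frames so the (uniform) solute centroid is at the
   origin — this fixes the translation once; all later stages are
   rotations and relabelings only;
2. Kabsch rotation fitted on solute atoms only;
3. solute relabeling (skipped when no solute element repeats, or when
   solute reordering is disabled);
4. solute Kabsch again, now with a sensible pairing;
5. solvent relabeling — by now solvent atoms of the two frames occupy
   comparable regions, which is where assignment heuristics work well;
6. optional (default on) all-atom Kabsch rotation, fitted *about the
   fixed origin* — i.e. the rotation-only optimum given the step-1
   translation, computed from the uncentered weighted covariance.

Because the translation convention is part of the definition, the
"global minimum" reference used in tests is the exhaustive minimum over
all species-preserving permutations with, for each, the optimal
rotation about the same solute-centroid origin.  The staged brute-force
variant reproduces that reference exactly on small systems; the
Hungarian variant matches it in ≈99% of random 1-solute + 2-water
systems and can never beat it.

Relabeling acts per atom, per element, not per molecule: the assignment
problem is solved independently for each element species, so atoms of
one solvent molecule may in principle map to different molecules.  The
synthetic generators deliberately permute *whole* molecules while the
solver relabels per atom; the congruence tests confirm the per-atom
formulation still recovers exact congruences.

### Relabeling algorithms

* **brute** — enumerate every species-respecting permutation (product of
  per-element factorials) of the block being relabeled and keep the one
  minimizing the final weighted RMSD (after the optional all-atom
  rotation, i.e. exactly the reported objective).  Global optimum by
  construction; refuses blocks with more than 10⁶ permutations and
  advises the Hungarian algorithm instead.
* **hungarian** — per element, a linear assignment problem with cost
  ‖aᵢ − bⱼ‖² solved exactly in O(K³).  The squared Euclidean cost is
  chosen because its weighted sum is the quantity inside the RMSD.
  Exact for the assignment objective, not necessarily for the
  post-rotation RMSD.
* **hungarian_inertia** — the staged pipeline is evaluated for five
  initial orientations of B: the identity plus the four proper-rotation
  sign combinations aligning B's principal inertia axes (unit masses —
  the clustering is geometric, masses are irrelevant to label bookkeeping)
  onto A's; the best final RMSD wins.  Including the identity baseline
  makes the variant never worse than plain Hungarian.  Degenerate
  (symmetric-top) spectra are logged; all candidates are still evaluated.
* **distance** — per element, sort atoms of each frame by distance to
  the block centroid and match by rank, O(K log K); ties broken by
  original index.  Exact only when, within each element, the
  centroid-distance gaps dominate the coordinate noise.  Water
  hydrogens are intrinsically near-degenerate in this coordinate
  (empirically ≲0.2 Å gaps), so rank flips — and the resulting inflated
  intra-cluster RMSDs — are expected at realistic noise; this is the
  documented weakness of the approximate method, and the recovery test
  for it asserts its validity precondition explicitly.
* **none** — superposition only, no relabeling.

The assignment-cost ordering distance ≥ hungarian is a theorem; the
final-RMSD orderings brute ≤ hungarian ≤ distance are checked
empirically on pre-aligned fixtures.

### Kabsch details

SVD of the (weighted) covariance with the determinant sign correction,
so reflections are never returned even for chiral/mirror inputs;
degenerate spectra fall back to the SVD's deterministic convention.
Double precision throughout; test equality tolerance 1e-8 Å.

## The RMSD matrix

All M(M−1)/2 pairs with frame i as reference for pair (i, j), i < j.
Approximate relabeling is not exactly symmetric; only the brute variant
is (tested to 1e-8).  Pairs are partitioned into fixed index blocks and
written back by position, so the condensed vector is bitwise identical
for any worker count.  The matrix is cached (NumPy archive: condensed
vector, M, SHA-256 fingerprint of all options that determine the
entries); a cache whose fingerprint mismatches is refused unless forced.

## Clustering

SciPy agglomerative linkage on the condensed matrix; the seven standard
schemes are accepted, ward is the default.  Ward/centroid/median
formally assume Euclidean distances — applying them to a generic RMSD
matrix is a widely used heuristic and is allowed with a logged warning.

Cutting at threshold t yields flat clusters; ids are renumbered by order
of first appearance along the trajectory, so frame 1 is always in
cluster 1 and time-evolution plots are reproducible.

Quality metrics: silhouette score evaluated on the precomputed distance
matrix; Calinski–Harabasz and Davies–Bouldin need point coordinates, so
each frame is represented by its row of the squareform RMSD matrix (an
implementation convention, stated here because no canonical choice
exists for precomputed distances); cophenetic correlation between the
condensed and tree-implied distances.  Scores are refused (ValueError)
for partitions where any of them is undefined — e.g. coincident
clusters or an all-zero matrix.

### Automatic threshold

Candidates are every distinct merge height ± ε (ε = 10⁻⁹ relative) plus
midpoints between consecutive heights; each candidate cut with
2 ≤ k ≤ M−1 clusters is scored by silhouette and the maximizer is
returned, ties resolved toward the smallest threshold.  Scanning the
merge heights exhaustively dominates any fixed grid.  When tied merge
heights make some cluster count unreachable by a distance cut (e.g.
three equidistant points), partitions obtained by truncating the merge
sequence are added as candidates, with the threshold reported just
below the tied height; for untied trees this adds nothing.

## Outputs

Per-cluster medoid = argmin over members of the summed RMSD to the other
members, ties to the lowest frame index.  Artifacts: two-column
assignments file; per-cluster multi-frame trajectory with the medoid
first and every member relabeled+superposed onto it; dendrogram image
plus its merge table as text; 2-D projection by classical (Torgerson)
metric MDS of the RMSD matrix — chosen over iterative embeddings for
determinism — with the coordinates also written as text; JSON summary.

## File formats

Multi-frame XYZ and fixed-column GRO are parsed natively (streaming one
frame at a time; GRO nm → Å; element symbols inferred from atom names
with a two-letter-symbol table; "D" counts as hydrogen for the
hydrogen-exclusion option); PDB goes through MDAnalysis (MODEL/ENDMDL
frames).  A frame that cannot be parsed raises an error naming its
index; frames disagreeing in composition raise "inconsistent
composition".  Exclusion ranges are 1-based inclusive, chemistry
convention; the solute count supplied by the user refers to the
original frames and is recomputed after exclusions.  Weights are
renormalized over the retained atoms.

## Synthetic data

The generators emulate solvation-shell snapshots: a rigid 5-atom,
five-element chiral solute; rigid 3-site waters dropped with random
orientation on 3–7 Å shells with a 1.5 Å center–center overlap
rejection; per-frame nuisances of whole-molecule solvent permutation,
Haar-random rigid motion, and isotropic Gaussian noise (default
σ = 0.05 Å, far below the ≳3 Å separation of independently drawn
conformer layouts, so ground-truth labels are unambiguous).  Defaults:
5 solvent molecules, 20 frames, 2 conformers.  All randomness flows
through one explicitly passed seeded generator.

What the generators do *not* emulate: force-field energetics and
realistic thermal ensembles, solvent exchange between shells,
flexible/intramolecular motion, and box periodicity.  Passing tests
therefore demonstrate the label/rotation bookkeeping and the clustering
machinery — not that any particular physical system clusters well.

## Problem sizes and numerical choices

Test and acceptance fixtures use 2–5 solvent molecules, 6–100 frames,
and exhaustive oracles up to a few thousand permutations — small enough
that every oracle is exact and the whole suite stays fast, large enough
to exercise every code path including parallel workers.  Brute-force
enumeration is capped at 10⁶ permutations (refusal, not silent
degradation).  Degenerate inputs: single-atom solutes skip the solute
rotation; blocks with no repeated element skip relabeling; all-zero
distance matrices refuse scoring.

## Known limitations

* Approximate relabelings make d(i, j) mildly reference-dependent; the
  matrix is defined with i < j as reference.
* Per-atom relabeling can split molecules across a pairing; a
  whole-molecule assignment mode is out of scope.
* Descriptor-based (FCHL19/QML) relabeling is not implemented; the CLI
  rejects it explicitly.
* Binary trajectory formats (XTC/DCD) are not read; convert to
  XYZ/PDB/GRO first.
* Ward on non-Euclidean RMSD matrices is heuristic (see above); results
  for centroid/median linkage may show height inversions, which are not
  flagged.
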