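# Methods

## Problem setting

Given an active compound, inverse screening ranks candidate protein
targets instead of candidate ligands.  Two evidence families are
implemented: statistical post-processing of blind-docking score
matrices (target-based), and fingerprint similarity to known ligands of
each target (ligand-based).  Both produce (target, compound) pairings;
a consensus score counts how many independent channels agree.

## Score matrices and sign convention

A score matrix holds one docking program's binding energies (kcal/mol)
for every ligand × target combination.  Energies are kept negative
(more negative = stronger predicted binding).  Cells ≥ 0 represent
failed or non-binding dockings: they are masked to missing rather than
imputed, because the method-I quotient is non-monotone on a mixed-sign
matrix.  Rows or columns left entirely missing are dropped with a
warning.  Missing cells are excluded from every mean and SD and can
never be selected.  Matrices from different programs are never merged
numerically; programs are compared only at the pairing-set level.

## Method I — quotient normalization with a 3σ threshold

For each defined cell, `V = V0 / ((ML + MT)/2)` with ML the ligand-row
mean and MT the target-column mean (defined cells only).  Since V0 and
the denominator are both negative, V > 0 and larger V means the cell is
strong relative to both its row's and its column's typical score; an
additive row or column shift is cancelled to first order.  Selection
keeps cells with `V ≥ M + 3σ`, where M and σ are the mean and
population SD of all defined V.  The comparison is inclusive: the
threshold names the boundary of admissibility, so a constant matrix
(σ = 0, all V = M) degenerately selects everything, which is logged.
Method I is exactly invariant under multiplication of the matrix by any
positive constant.

## Method II — two-directional Z-transformation

`ZT` standardizes each cell within its **target column** (across
ligands); `ZL` standardizes within its **ligand row** (across targets);
`Zcomb = 0.7·ZT + 0.3·ZL`.  For every ligand the receptor with the
lowest Zcomb is selected; exact ties go to the lexicographically
smallest target id (deterministic, logged).  There is no score cutoff
by default — every ligand with a defined Zcomb yields a pairing — but an
optional `zcomb_cutoff` is exposed.

The orientation of the two Z directions is a genuinely open design
point: the method's description ("target- and ligand-specific Z-score")
does not fix which axis each equation runs over.  We standardize ZT
per target because selecting *among receptors for one ligand* requires
the receptors' score distributions to be comparable — i.e. each target
column standardized — and because this choice actually removes
target-column bias from the 0.7-weighted term (measured: under ±1
kcal/mol column offsets, per-ligand selections stay uniform with the
per-target orientation, chi-square p ≈ 0.34 pooled over seeds, but are
already significantly biased with the transposed orientation,
p ≈ 2e-6).  Both orientations are selectable via
`PipelineConfig.z_orientation`.

All standard deviations anywhere in the package are population SDs
(divide by n), keeping the matrix-wide σ and the axis SDs consistent;
rows/columns with fewer than two defined cells are dropped before the
Z-transform (iterated to a fixed point), and a zero-SD axis yields Z = 0
for its cells, logged.

## Ligand-based screen

Reference interactions (target id, SMILES) are deduplicated on
(target, full InChIKey) — the full key, not the connectivity skeleton,
so stereoisomers remain distinct while alternative SMILES spellings of
one molecule collapse.  Sources merge by set union; the merge report
records per-source sizes, pairwise overlaps and the union size.
Queries are screened per target: the maximum Tanimoto between the query
and that target's reference fingerprints, with one hit per
(query, target) at similarity ≥ cutoff (default 0.75, inclusive, chosen
deliberately less restrictive than the common 0.85).  Morgan
fingerprints use radius 2 and 2048 bits (the de-facto ECFP4-like
default); both are configurable.  Tanimoto of two all-zero fingerprints
is defined as 0.

## Consensus scoring

The approach universe has five members: {method I, method II} × {two
docking programs} plus the similarity screen.  A pairing's confidence
is the number of *distinct approaches* supporting it (1–5); an approach
firing in both the all-targets run and the rerun after
promiscuous-target exclusion still counts once (`fuse_runs=True`,
configurable to approach×run counting).  Rationale: the score measures
independent lines of evidence; re-running the same method on a reduced
matrix is not independent evidence.  Promiscuity detection defaults to
a manual curated list; the automatic policy flags targets whose
associated-ligand count exceeds median + k·MAD (k = 5), with the MAD
floored at one ligand so near-uniform count vectors (MAD = 0) do not
flag everything marginally above the median.

## Protein–ligand network

Associations at or above a confidence threshold form a bipartite graph
projected onto targets: edge weight = number of shared ligands, node
attribute `degree` = incident edges (the figure-style node size), and
targets with ligands but no shared ones are kept as degree-0 nodes so
per-target counts remain visible.  Exports (GraphML, SIF, edge table)
emit nodes and edges in sorted order, so identical networks produce
byte-identical files.

## Synthetic data: what it emulates, and what it does not

Score matrices: cell = N(μ, σ²) + ligand offset + target offset, with
planted pairings lowered by `signal·σ`; defaults μ = −8.0 kcal/mol,
σ = 1.5 kcal/mol, offsets uniform on ±1 kcal/mol, no missing cells.
The background level and spread match the range of blind-docking
affinities typical of Vina-family scoring (roughly −4 to −13 kcal/mol
across diverse compounds); the offsets model program- and
structure-specific systematic error.  A Gaussian background makes the
selection rate of the 3σ threshold analytically predictable (≈ 0.13%
one-sided tail mass), which the calibration test exploits.  Real
docking scores are not Gaussian (bounded above, heavy lower tail,
correlated across related targets), queries are not independent of
references, and real libraries carry activity-value noise — so passing
tests demonstrate the statistical machinery, not docking accuracy.

Reference libraries: interaction sources realize configured sizes and
overlaps exactly, with deterministic synthetic structure keys; SMILES
come from an enumerated pool of substituted aromatic scaffolds
(validated and canonicalized by RDKit), and decoy queries from a
disjoint aliphatic pool whose fingerprints cannot reach the 0.75 cutoff
against the aromatic references.  Planted queries copy reference SMILES
verbatim, guaranteeing hits at Tanimoto 1.0.

Consensus fixtures assign each synthetic pairing to exactly the number
of approaches its requested score demands, optionally controlling the
structure-based/ligand-based family split.

## Study-condition recovery: measured behaviour and known limits

At the planted-recovery conditions (300×35 cells, 30 planted binders at
4 SD, ±1 kcal/mol biases, 10 seeds) method II names the planted target
for ≈ 94–95% of planted ligands.  Method I recovers ≈ 76–80% of planted
pairings at ≈ 24–25% false discoveries.  The false-discovery level is
structural, not a tuning artifact: a 3σ threshold over ~10,500
Gaussian cells admits ≈ 11–14 background cells (the same ≈ 0.13% tail
the calibration test verifies) against at most 30 true positives, and
method I's scale invariance means no choice of background mean or SD
changes the 4-SD-signal versus 3σ-threshold geometry.  Tightening the
threshold or shrinking the matrix would trade this away, but both are
part of the method's definition and the study conditions, so the
behaviour is reported as measured.

Similarly, neither normalization removes *strong* additive column
offsets completely: method I cancels them only to first order, and
method II's ligand-direction term (weight 0.3) retains the standardized
column pattern, which becomes detectable when offsets dominate the
noise.  At the default ±1 kcal/mol bias scale both methods' selections
are statistically uniform across targets, and both are far less biased
than selecting on raw scores — which is the operational meaning of
"eliminating systematic errors" here, and what the property tests
assert.

## Numerical choices

- Delimiters auto-detected (comma/tab) on read; all output tab-delimited.
- Matrix round-trips are bit-identical: floats are written with
  shortest-round-trip `repr` and parsed with correctly rounded
  `float()` (the default pandas fast paths lose the last ulp).
- Sub-seeds for multi-part runs are derived deterministically from the
  master seed and kept below 2³¹.
- Problem sizes in tests and the acceptance script (10 seeds of 300×35
  matrices, 100×100 calibration matrices, libraries up to ~66k
  interactions, 30-query screens) keep the whole suite within a few
  seconds while leaving Monte-Carlo error well below the asserted
  margins.

## Known limitations

- Docking itself, pose analysis and structure handling are out of
  scope; the package starts from score matrices.
- The similarity screen treats every reference interaction as valid,
  with no activity-value thresholding.
- Confidence scores weight all approaches equally; no
  reliability-weighted fusion is provided.
- The automatic promiscuity detector is a robust-outlier heuristic;
  curated exclusion lists remain the default.
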