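# Methods

## Model

A pair of proteins (x, y) is scored by a likelihood ratio for the
hypothesis that they interact through a domain-motif interface.  Every
candidate interface carries categorical clues; for clue value c the
likelihood ratio is estimated by exhaustive counting over curated
true-positive (TP) and true-negative (TN) pair lists:

    LR(c) = (n_TP / N_TP) / (n_TN / N_TN)

where n is the number of pairs in the respective list carrying c.  A pair
contributes at most once to each (clue, value) count, even when it has
several candidate interfaces.  Clues are treated as conditionally
independent given the match clue; because class/PSD/SIM/disorder/
conservation clues can only be observed when a match exists, their LRs
are divided by LR(match) before multiplication (the formulas in the
README).  The implementation evaluates the normalized-product form
literally; tests verify the algebraic reductions
LR(class)·LR(diso)·LR(consv)/LR(match)² and
LR(PSD)·LR(SIM)·LR(diso)·LR(consv)/LR(match)³ to 1e-12 relative
tolerance.

Per-pair aggregation over candidate interfaces — including across the two
discovery routes — takes the **maximum** interface LR.  The two routes
frequently describe the same physical interface, so a product would
double-count correlated evidence; the maximum also mirrors the established
rule of keeping the larger of two structural scores when merging with an
existing domain-domain predictor.  A product policy is available
(`policy="product"`) for sensitivity analysis.

The final score multiplies the aggregated interface LR by a pre-computed
non-structural LR; pairs missing from the NS table use LR 1, the
multiplicative identity, so absence of data neither rewards nor penalizes.
A final LR above 600 (strict) flags a strong prediction; with prior odds
of 1/600, posterior = odds/(1+odds) gives exactly 0.5 at LR 600.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| interface distance cutoff | 4.5 Å (inclusive) | PRD residue is interfacial if any atom is within this distance of the peptide |
| ASA threshold | 10 Å² (inclusive) | residue counts as surface |
| probe radius / sphere points | 1.4 Å / 960 | Shrake–Rupley sampling |
| vdW radii | C 1.7, N 1.55, O 1.52, S 1.8, else 1.8 Å | solvent-sphere radii |
| interface coverage | 0.75 (inclusive) | fraction of template interfacial residues aligned to candidate surface |
| PSD bins | [0, 0.3], (0.3, 0.65) | templates with PSD ≥ 0.65 are rejected; 0.3 goes to the closed lower bin |
| window-scan retention | top 5e-4 of all windows | cutoff score = ceil(f·N)-th best window, ties retained |
| similarity bins | 1e-6, 1e-5, 1e-4, 5e-4 rank fractions | percentile bins of retained windows |
| peptide length | 5–35 residues | usable template range; multimeric PRDs excluded |
| disorder cutoff | mean > 0.5 (strict) | motif counts as disordered |
| conservation window | ±31 residues, center excluded | local-conservation comparison |
| pseudocount α | 0 | additive smoothing of clue probabilities |
| LR cap | 1e6 | assigned when a clue never occurs in the TN set |
| strong threshold | 600 (strict >) | final-LR flag |
| prior odds | 1/600 | posterior conversion |

## Numerical and edge-case choices

* **Tie handling in the window scan.**  "Top 0.05%" is realized as: sort
  all N windows, take the score of the ceil(5e-4·N)-th best as the cutoff,
  keep every window at or above it.  Including ties keeps the rule
  deterministic and independent of sort order.  On small proteomes the
  boundary ties can push a retained window's rank fraction past the
  outermost percentile-bin edge; such windows are assigned the outermost
  bin (B4).  The standalone bin-assignment function, used on
  proteome-scale rank fractions, rejects ranks beyond 5e-4.
* **Overlapping consensus matches** are enumerated by attempting a regex
  match at every start position; `^`/`$` anchors keep their usual
  semantics.  This is the conservative superset of any single-pass scan.
* **Non-standard residues** map to 'X', which scores 0 against every
  letter in BLOSUM62 scoring (the matrix itself is biopython's copy of the
  published table).
* **Zero count cells.**  With α = 0, a clue value absent from TP estimates
  LR 0 (the pair's final score is then 0); absent from TN it receives the
  LR cap and a flag; absent from both (possible for held-out values during
  cross-validation) it is neutral, LR 1.
* **Conservation information content** is the sequence-logo definition:
  log2(20) minus the Shannon entropy of amino-acid frequencies among
  non-gap residues of the column, multiplied by the column's non-gap
  fraction.  Columns where the reference row is gapped are skipped; a
  column whose only non-gap entry is the reference residue scores
  log2(20) × 1/depth.  The neighbourhood mean for the local-conservation
  flag excludes the center residue (otherwise a peak competes against
  itself) and truncates at sequence ends; comparisons are strict, so
  constant tracks flag nothing.
* **Solvent accessibility** uses a fixed golden-spiral point set, making
  ASA values bit-reproducible; tests check the isolated-sphere and
  two-sphere-cap closed forms to 2% and cross-check against an independent
  Shrake–Rupley implementation.
* **PDB ingestion** keeps the first model only, prefers altloc 'A',
  ignores HETATM/waters, and defaults unknown elements to a 1.8 Å radius
  with a warning.
* **Cross-validation** partitions TP and TN lists independently into k
  seeded folds (sizes within 1); each fold is scored by tables trained on
  the remainder, and pooled held-out scores feed one ROC/PR curve so every
  pair contributes exactly once and curve denominators are fixed across
  evidence configurations.  Tied scores collapse to a single threshold
  step; AUC is trapezoidal, PR area is the uninterpolated step integral.

## Synthetic bench

The generator emulates the study's data conditions at two levels.

**Pair-level** (`generate_training_sets`): TP and TN pairs draw each
discovery route independently — a match with probability 0.4 (TP) vs 0.02
(TN), giving the planted match-clue LR of 20; conditional on a match,
disorder 0.8/0.3, conservation 0.7/0.2, PSD bin P1 0.6/0.3, similarity
bins skewed toward B1/B2 for TP; NS evidence is log-normal (σ = 1.2) with
median 20 for TP vs 0.8 for TN.  The `null()` twin equalizes every TN
frequency with its TP value, which removes all signal.

**File-level** (`generate_bundle`): a toy proteome (default 30 proteins,
60–120 residues) with concrete motif instances and template-peptide copies
spliced in at ledger-recorded positions; idealized PRD-peptide complexes
(Cα/Cβ pseudo-helix against an extended strand placed at an exact minimum
atom-atom gap); candidate-model PDBs; disorder tracks (planted motifs
~N(0.7, 0.1), background ~N(0.3, 0.1)); depth-8 ortholog alignments with
near-identical columns over planted motifs; structural alignments with PSD
values drawn inside the usable bins; and TP/TN/NS tables over the bundle's
pairs.  A `toy_psd` pseudo-distance (squashed Cα RMSD) exists for fixture
generation only and is not equivalent to a real structural aligner's PSD.

What the bench does **not** emulate: realistic domain architecture or
fold geometry, sequence composition bias, phylogenetic correlation among
orthologs, overlapping/homologous motif classes, or the extreme TP:TN
imbalance of a real interactome benchmark.  Passing tests demonstrate the
correctness of the estimation, filtering and combination machinery under
known ground truth — not genome-scale predictive performance.

Interface evidence alone is coverage-limited by construction: with match
probability 0.4 per route, many true pairs carry no candidate interface
and tie with unmatched negatives at the neutral score, bounding the
interface-only AUC near 0.8; the combined interface × NS run exceeds 0.9.
This mirrors the motivating observation that single evidence sources are
weak and the Bayesian combination amplifies them: the combined
strong-prediction count consistently exceeds either source alone by
several-fold on the bench.

## Problem sizes

The test suite and acceptance script use 2,000 + 2,000 pairs for
cross-validation runs (20–50 replicates for null bands), 10,000 + 10,000
for clue-LR recovery (20 seeds, checked against a conservative exact
binomial 99% interval), 100 random configurations for counting-oracle
equivalence, and the 30-protein bundle for the file-based pipeline.
These sizes give tight Monte-Carlo bands while keeping the whole bench
runnable in a couple of minutes on one core.

## Known limitations

* The pooled percentile for the window scan is per-template, not shared
  across templates of equal length.
* Pfam-hit redundancy resolution is out of scope; domain annotations are
  consumed as given, as are PSD values and residue correspondences from
  the external structural aligner.
* With α = 0 the LR estimates are unshrunk ratios; rare clue values can
  produce extreme LRs that the cap only bounds at 1e6.  Smoothing is
  available but off by default to match the plain counting estimator.
* The conservation column frequencies are unweighted; redundant orthologs
  inflate information content.
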