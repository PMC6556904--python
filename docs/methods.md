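# Methods

`protcleave` predicts protease-specific substrate cleavage sites from
sequence. This note records the model, the choices made where the design
was genuinely open, and what the synthetic benchmark does and does not
demonstrate.

## Problem framing

A protease cleaves the peptide bond between residues P1 and P1'
(Schechter–Berger nomenclature: P8…P1 run N-terminal of the scissile
bond, P1'…P8' C-terminal). Cleavage-site prediction is cast as binary
classification of candidate bonds: each bond position is represented by
the 16-residue P8–P8' window around it, encoded as a numeric feature
vector `x`, and a per-protease model estimates the propensity that the
bond is cleaved. Coordinates are 1-based; a site annotated at `p1` means
the bond between residues `p1` and `p1 + 1`. Windows that run past a
terminus are padded with the 21st letter 'X', which is also the
normalization target for non-standard residues (B, Z, U, O, J, `*`, `-`).

## Feature encoding

Eleven schemes, concatenated in fixed order, give up to 4562 components
per window (21×16 BINARY one-hot; 400×6 CKSAAP k-spaced residue-pair
compositions for k = 0…5 with denominator N_total = 16 − (k+1); 5 KNN
components; 20 AAC compositions; 16×20 PSSM; 16×21 BLOSUM62 rows; 16×64
AAindex values; 9 CHR components; 16×3 secondary structure; 16×2 solvent
accessibility; 16×2 disorder). Per-scheme handling of 'X' and padding:

- BINARY: 'X' occupies the 21st slot. BLOSUM: the 'X' row is all zeros,
  so padded positions contribute nothing.
- CKSAAP/AAC: 'X' counts toward the denominator but no pair/residue slot,
  so block sums fall below 1 exactly when padding is present.
- KNN: similarity between two equal-length peptides is the positionwise
  sum of max(BLOSUM62, 0); each component is the fraction of positives
  among the top-K most similar reference windows, K = 1, 3, 5, 7, 9% of
  the reference size (at least 1). Ties in similarity resolve by stable
  reference order. A query that is itself a reference window is excluded
  from its own ranking.
- PSSM: profile rows are squashed by the logistic 1/(1+e^(−s)) — the
  standard way to bring unbounded log-odds scores onto the same [0, 1]
  footing as the other blocks; padded positions are zero rows (not 0.5),
  so a fully padded window encodes to zeros.
- AAindex: each index's 20 residue values are min-max scaled to [0, 1];
  'X' takes the index mean. The 64-index list is versioned and recorded
  in every trained bundle. When the user supplies an aaindex1 file, 64
  indices are chosen by greedy max–min Euclidean distance between
  z-scored value vectors (deterministic, accession-order tie-break) —
  reproducibility was preferred over guessing any particular curated set.
  Without a file, a deterministic synthetic table
  (`synthetic-aaindex-v1`) stands in so the sequence-only pipeline runs
  self-contained; it is labelled synthetic and is not a published index
  set.
- CHR: the 9 components are (net charge, summed Kyte–Doolittle
  hydropathy, charge/(|hydropathy|+1)) over three segments — P8–P1,
  P1'–P8', full window — with K/R/H = +1 and D/E = −1. Only the
  dimension and the charge/hydrophobicity-ratio intent are fixed by
  precedent; this concrete 3-segment × 3-quantity construction is this
  package's (non-canonical) choice.
- SS/SA/DISO: one-hot (H/E/C and buried/exposed) and (p, 1−p) per
  position; padded positions take uniform priors (1/3 or 0.5).

Structural tracks and PSSM profiles are pluggable inputs (per-residue
TSVs, PSI-BLAST ASCII); the package never runs the upstream predictors.
For the PSSM the log-odds score block (first 20 columns) is used.

## Data preparation

Homology reduction is greedy longest-first clustering with a shared-5-mer
identity estimate (fraction of the shorter sequence's distinct 5-mers
found in the longer), default threshold 0.70 — a word-filter stand-in for
banded-alignment clustering; precomputed cluster files can be substituted.
Train/test splits are drawn at substrate level (default 5/6 : 1/6), never
at window level.

Positives are all annotated P1 windows for the target protease;
candidate negatives are every other bond position on the same substrates
(sites of *other* proteases may be negatives — models are per-protease).
When structural tracks are available, candidates are restricted to buried
P1 residues (reliable non-cleavage sites tend to be solvent-inaccessible);
if that empties the pool the filter is dropped with a warning and the
fallback is recorded in provenance. Negatives are then down-sampled
uniformly without replacement, pooled across substrates, to 3 per
positive (the ratio is configurable).

## Feature selection

Step 1 (mRMR, MID form): features are discretized to three levels at
mean ± one standard deviation (inclusive thresholds, so one-hot columns
keep two levels; constant columns code to a single level). The first
feature maximizes I(f; y); each next maximizes I(f; y) − mean_{s∈S}
I(f; s), with MI from empirical joint frequencies (0·log 0 = 0) and ties
resolved to the lowest column id. The top 100 features are the optimal
feature candidates.

Step 2 (forward selection): prefixes of the ranking are scored by mean
5-fold cross-validated AUC with the fold assignment fixed across all
prefix lengths (otherwise the curve is incomparable), and the smallest
prefix attaining the maximum is kept. One hyperparameter setting is used
for the whole curve rather than re-running the grid search at every
prefix length; the search is run once and reused (500 SVR fits instead
of 36 000).

## Model

An ε-SVR with RBF kernel regresses 0/1 labels; raw outputs clipped to
[0, 1] are read as cleavage propensity scores (the minimal calibration
consistent with treating the regression output as a probability-like
score). Features are min-max scaled to [0, 1] from training data only.
Hyperparameters come from an exhaustive grid — C ∈ 2^{−5..5}, γ ∈
2^{−7..3} (steps of 2²), ε ∈ {0.01, 0.1} — scored by mean 5-fold CV AUC.

Two cross-validation details matter and are deliberate:

- **Folds are substrate-grouped** (stratified). Windows from one
  substrate overlap by up to 15 residues; letting them straddle the
  train/validation boundary leaks sequence content. Measured on null
  data (no planted signal), window-level folds let the grid search find
  hyperparameters scoring ≈0.55 AUC where grouped folds stay ≈0.52.
  When there are fewer substrates than folds the split falls back to
  ungrouped stratification with a warning.
- **KNN features are re-encoded per fold** against the fold-training
  reference only (training rows additionally exclude themselves). With a
  single precomputed KNN block, a validation window's feature would
  embed labels of windows overlapping it; on null data this inflated the
  best-grid CV AUC to ≈0.7. At prediction time the full training
  reference snapshot stored in the bundle is used.

The reported CV AUC is computed at the chosen grid point on fold splits
disjoint from those the search maximized over (derived from seed +
1000003). Quoting the maximum of a 72-point search would be optimistically
biased — on null data the bias alone is worth several AUC points.

A trained bundle stores the enabled schemes, AAindex table version,
selected columns, scaling parameters, hyperparameters, the fitted
regressor, the KNN reference snapshot, a specificity→threshold table
(0.90/0.95/0.99/1.00, from training-negative scores) and provenance
(seeds, per-fold AUCs, training scores). Loading refuses other format
versions; scoring refuses a context whose AAindex version differs from
the bundle's.

## Evaluation

Sensitivity, specificity, accuracy and MCC are computed in two
algebraically equivalent parameterizations — TP/TN/FP/FN and the
miscount form in N+, N−, N−+ (positives called negative), N+− (negatives
called positive) — and asserted equal before reporting. Note the
miscount identities: Sn = 1 at N−+ = 0; MCC = 0 at N−+ = N+/2 with
N+− = N−/2; and total misclassification (N−+ = N+, N+− = N−) gives
Acc = 0, MCC = −1 (a claim of Acc = 1 in that case does not follow from
the accuracy formula and is not reproduced here). Degenerate
denominators (an empty class or vanished MCC marginal) report 0 with a
flag. A predicted positive is score ≥ threshold; ties count as positive.
AUC is trapezoidal over all distinct thresholds (Mann–Whitney-equivalent
under ties). `threshold_at_specificity` returns the smallest threshold
achieving the target on a defining negative set; at target 1.0 it sits
one score-grid increment (10⁻⁶) above the largest negative score.

## Scanning

Every bond of a query sequence is scored with every loaded model using
the same P8–P8' feature window as training; the human-readable output
shows the shorter P4–P4' segment with '|' at the bond, the N-/C-fragment
sizes (p1 and L − p1) and the score. Records are grouped by protease (in
sorted id order, making output invariant to bundle order) and ranked by
score. MEROPS-style id initials map to catalytic families (A/C/M/S →
aspartic/cysteine/metallo/serine; anything else warns and maps to
"other").

## Synthetic benchmark

The generator emulates a MEROPS-like substrate set: i.i.d. uniform
background over the 20 residues (a flagless choice that keeps
composition χ² nulls exact), substrates of 80–160 residues, and planted
sites whose 16-residue windows are redrawn from a position-weight matrix
interpolated toward uniform by a strength in [0, 1]. Sites are interior
(≥8 residues from each terminus) and non-overlapping; structural tracks,
when requested, come from 2-state Markov chains. Synthetic proteases use
the reserved id `X01.001` so family mapping warns rather than mislabels.

The caspase-like PWM puts Asp at P1 with weight 0.99 — cleavage after
Asp is essentially a requirement for caspases, so the near-absolute
column is the realistic emulation — and Asp at P4 with weight 0.85 (the
canonical DxxD pattern); all other columns are uniform. The Gly-rich
(MMP-like) PWM elevates Gly (0.6) at P7, P4, P2, P1, P3' and P6'.

What passing the synthetic benchmark shows: the pipeline detects and
localizes a 2-column positional motif at strength 0.9 (CV AUC ≈ 0.95+)
and reports chance-level AUC when nothing is planted. What it does not
show: performance on real substrate repertoires, whose specificity
involves longer-range context, structure and exosite effects absent from
the generator. Two quantitative caveats are intrinsic to the design:

- Because annotated sites are interior while negatives include
  near-terminal bonds, padded windows are genuinely (weakly) informative;
  the null-data CV AUC therefore sits slightly above 0.5 (≈0.52–0.56
  across seeds), which is a property of the sampling scheme, not leakage.
- A background window with Asp at P1 and P4 is statistically
  indistinguishable from a planted one (the motif spans only two
  columns), so even a Bayes-optimal scanner mistakes the top-ranked site
  on a minority of substrates. Simulating the optimal decision rule
  (rank by the D-at-P1/D-at-P4 category, random among exact ties) under
  the default generating conditions gives a top-1-on-planted ceiling of
  ≈0.80; the trained scanner measures ≈0.75–0.85 across draws, i.e.
  within a few points of that ceiling rather than a model deficiency.

## Numerical and degenerate-input conventions

Min-max scaling maps zero-range columns to 0. Grid-search ties keep the
earliest point in sorted-key product order. Forward-selection plateaus
resolve to the smallest prefix. mRMR ties resolve to the lowest column
id. Constant feature columns discretize to a single level and carry zero
MI. All randomness flows from explicit integer seeds (numpy
`default_rng`, scikit-learn `random_state`); retraining with the same
seed reproduces the same grid point, fold assignment and scores.

## Problem sizes

Defaults are desk-scale: synthetic benchmarks use 150 substrates (300
planted sites, 1200 windows after 1:3 down-sampling), a 72-point grid ×
5 folds, 100-candidate selection curves, and 25-substrate scan
proteomes. All sizes are arguments, so larger studies are a parameter
change, not a code change.

## Known limitations

- The AAindex default table is synthetic; analyses of physicochemical
  feature importance need a real aaindex1 file.
- The homology reducer is a k-mer word filter, coarser than banded
  alignment; borderline-identity pairs can slip through (the external
  cluster-file path exists for exact tools).
- SVR scores are clipped, not calibrated probabilities; threshold tables
  are defined on training negatives.
- Exopeptidase-style curation rules and allosteric/exosite effects are
  out of scope; the toolkit trusts its input annotations.
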