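# Methods

## Problem and model

`stacktide` is a binary sequence classifier for tumor T-cell antigen (TTCA)
activity. Rather than selecting one best model, it stacks a large panel of
weak-to-moderate classifiers: 12 feature encodings × 13 learning algorithms
give 156 baseline models, each contributing one probability column to a
probabilistic feature matrix; a wrapper genetic algorithm picks an
informative column subset; an extremely-randomized-trees (ET)
meta-classifier trained on that subset is the deployed predictor. The
stacking premise is that different (algorithm, encoding) pairs make
partially independent errors, and a meta-learner over their probabilities
recovers signal a single model misses.

## Peptide validation

Sequences are upper-cased strings over the 20 standard amino-acid letters,
minimum length 5 — the shortest length at which every encoder is defined
(order-3 patterns and rank-1 correlation terms included). Non-standard
residues (B, J, O, U, X, Z) are rejected rather than imputed, since every
encoder assumes the 20-letter alphabet. Duplicate sequences keep their
first occurrence; a sequence observed with both labels is dropped from both
classes, treating the conflicting annotation as unreliable.

## Feature encodings

Dimensions are fixed contracts checked by the test suite: AAC 20, AAI 531,
APAAC 22, CTD 147, DPC 400, PCP 11, PAAC 21, RSacid 32, RScharge 50,
RSDHP 32, RSpolar 32, RSsecond 40 (2139 features in total).

* **AAC / DPC** — residue and adjacent-pair frequencies in fixed
  alphabetical order; each sums to 1.
* **CTD** — seven physicochemical attributes (hydrophobicity, normalized
  van der Waals volume, polarity, polarizability, charge, secondary
  structure, solvent accessibility), each partitioning the alphabet into
  three groups. Per attribute: 3 composition fractions, 3 between-group
  transition frequencies, and per group five distribution points — the
  sequence position (as % of length) of the first occurrence and of the
  ceil(q·n_g)-th occurrence for q ∈ {25, 50, 75, 100}% (n_g = group count).
  The pure-ceiling index rule is used throughout; for a length-5
  homopolymer the occupied group's distribution block is
  (20, 40, 60, 80, 100)%. Absent groups contribute zeros.
* **PAAC (λ = 1, w = 0.05)** — Chou's pseudo amino acid composition:
  20 composition terms plus λ sequence-order factors θ_k, the mean squared
  difference of standardized hydrophobicity, hydrophilicity and side-chain
  mass between residues k apart; all terms normalized to sum to 1. λ = 1 is
  forced by the 21-dimension contract; w = 0.05 is the canonical default.
* **APAAC (λ = 1, w = 0.05)** — the amphiphilic variant: 2λ correlation
  terms keep hydrophobicity and hydrophilicity separate as products, so
  even a homopolymer has nonzero sequence-order terms.
* **AAI / PCP** — per-property means of standardized per-residue values.
  PCP uses 11 classical scales (Kyte–Doolittle hydropathy, Hopp–Woods
  hydrophilicity, side-chain mass, pI, net charge at pH 7, Grantham
  polarity, Chou–Fasman helix/sheet/turn propensities, aromaticity, and a
  consensus hydrophobicity scale), z-scored per property and overridable in
  config. AAI uses a deterministic **synthetic** 531-property panel
  (fixed-seed standardized draws): the real curated amino-acid-index panel
  is not redistributable here, and the encoder's role in the architecture —
  531 correlated property-mean channels — only requires a full-rank,
  reproducible panel, not biochemically meaningful ones. This is the one
  encoder whose values carry no biological interpretation.
* **RS\* reduced alphabets** — the sequence is translated into a small
  property alphabet, then n-gram composition blocks are concatenated.
  Partitions: acidity (4 classes), charge (5), hydrophobicity pattern (4),
  polarity (4), secondary-structure propensity (4: helix, sheet, turn,
  proline as the sole breaker class). Acid/DHP/polar and charge use
  adjacent + one-gap class dipeptides (2k²: 32 and 50). For the
  secondary-structure scheme no plain n-gram schedule over a single
  alphabet reaches the 40-dimension contract, so its schedule is adjacent
  dipeptides (16) + one-gap dipeptides (16) + class composition of the
  N-terminal half (4) and C-terminal half (4); terminal-half composition is
  a standard peptide-descriptor idea and every block still sums to 1. All
  groupings and schedules are config data, not code.

## Baseline grid

The 13 algorithms are AdaBoost, decision tree, extra trees, k-NN, LightGBM,
logistic regression, MLP, Gaussian naive Bayes, PLS, random forest, linear
SVM, RBF SVM, XGBoost (scikit-learn, LightGBM and XGBoost
implementations). Nine of them (ADA, ET, LGBM, LR, MLP, RF, SVMLN, SVMRBF,
XGB) are grid-searched under stratified 10-fold CV, maximizing mean CV
accuracy with ties broken toward the earlier grid point; grids are compact
config (tree counts {20, 50, 100, 200, 500}, SVM C on a log₂ grid, etc.)
and tuning is optional (`--tune`) because the fast fixed defaults are
adequate at the problem sizes the package targets. One stratified fold
partition, derived from the run seed, is shared by tuning, meta-feature
generation and GA fitness, so no baseline sees different folds.

PLS (regression on 0/1 labels) and the SVMs emit margins, not
probabilities; their decision values pass through a univariate logistic
squashing fitted on the training decision values, falling back to min-max
scaling when the fit is degenerate. This keeps every probabilistic feature
interpretable in [0, 1].

Per-baseline seeds are derived as CRC32(algorithm | encoding | run seed),
so a single run seed reproduces the whole grid bit-for-bit.

## Probabilistic features and leakage control

Training meta-features are strictly out-of-fold: sample *s*'s entry in
column (i, j) comes from the fold model that did not train on *s*. Test
features come from each baseline's full-training refit — the most common
stacking convention, using all data rather than averaging fold models.
Column order is algorithms (alphabetical) × encodings (panel order),
labelled `"ALG-ENC"`.

## GA selection

Chromosome: 156 binary inclusion genes + one parametric gene from
{20, 50, 100, 200, 500} (meta-ET tree count). Fitness: pooled 10-fold CV
MCC of the meta-ET restricted to active columns, cached by
(gene set, tree count). Defaults: population 20, 20 generations, mutation
probability 0.05 per gene, initial active count 5, active ceiling 20.
Operator details the named parameters do not pin down were fixed as:

* **SAR recombination** — guided uniform crossover between the elite and a
  tournament-selected mate (tournament size 2): each disagreeing gene takes
  the state with the higher recorded marginal fitness (mean fitness of all
  evaluated chromosomes carrying that state), a fair coin when unrecorded.
  The "self-assessment report" is this marginal-fitness bookkeeping. The
  operator is a plain function and can be swapped out.
* **Parsimony tie-break** — wherever two chromosomes have exactly equal
  fitness (elite update, tournaments, parent choice), the smaller tree
  count wins: an equally accurate but cheaper, lower-variance
  meta-classifier is preferable, and on fixtures where many chromosomes are
  perfect this keeps the search from drifting to needlessly large forests.
* **Repair** — after mutation, random active genes are deactivated until at
  most 20 remain; an empty chromosome gets one random active gene. Elitist
  replacement makes the best-fitness history non-decreasing.

## Metrics

ACC, Sn, Sp, MCC from the confusion matrix at threshold 0.5 (the implicit
operating point of all reported classifiers); MCC is defined as 0 when any
denominator factor vanishes. AUC is the exact Mann–Whitney rank statistic
(ties ½), invariant under monotone score transforms. Cross-validation
reports pool out-of-fold predictions into one confusion matrix rather than
averaging per-fold metrics — pooling keeps MCC well-defined for small
folds. Feature importance of the final model uses the meta-forest's
impurity importances with the sign of each column's point-biserial
association; a permutation-drop-in-MCC alternative is provided.

## Synthetic data

Peptides are drawn residue-wise i.i.d.: negatives from a uniform residue
distribution, positives with probability mass tilted onto a fixed enriched
set (F, I, L, V, K, R) by a log-multiplier of 0 ("none"), 0.4 ("weak") or
1.2 ("strong"); lengths uniform on 8–30; optional motif insertion in
positives. "Strong" was chosen so a few hundred peptides suffice for a
well-built pipeline to exceed 0.9 AUC, "weak" sits near the detection
boundary, and "none" yields exchangeable classes for permutation nulls.
The generator deliberately omits everything that makes real TTCA data hard
— MHC-binding structure, positional anchor residues, homology clusters,
label noise — so green tests demonstrate that the machinery is correct and
leakage-free, not that real-data performance is reproduced. A planted
feature-matrix fixture (signal columns equal to the label, the rest uniform
noise) serves the selection and attribution tests.

## Problem sizes used by the test and acceptance runs

Chosen once as the package's standard desk-scale benchmarks: the full
156-baseline grid runs on 200 synthetic peptides; the planted GA run uses
the default GA configuration on a 200 × 156 matrix; the end-to-end pipeline
benchmark uses 400 peptides with all 12 encoders, a 4-algorithm subset
(ET, LR, XGB, NB) and a reduced GA budget (population 10, 6 generations);
the permutation null uses 20 label permutations of a reduced
2-algorithm × 3-encoder stack. These sizes exercise every code path at full
structural width (the 156-column feature matrix) while keeping a complete
run on one CPU in minutes.

## Numerical and degenerate-input conventions

Composition blocks sum to 1 within 1e-9. Empty datasets encode to 0-row
matrices of correct width. Single-class inputs are rejected wherever a
fold or a metric needs both classes (AUC returns unset with a warning).
The majority-vote ensemble breaks an exact 78–78 tie by the mean score
against 0.5. All RNG flows through numpy's PCG64 `default_rng`; derived
seeds stay below 2³¹.

## Known limitations

* The curated TTCA benchmark used by existing predictors (474+474
  training peptides, the remainder held out) is distributed through a web
  service and is not bundled; without it the package makes no claim about
  real-data accuracy.
* The AAI panel is synthetic (above); swap in a real amino-acid-index table
  via `encoders.tables` to recover biochemically meaningful AAI features.
* The five reduced-alphabet encoders satisfy their dimension contracts but
  the original grouping tables are not available; groupings are config and
  may differ from the original descriptors.
* The SAR recombination operator is a faithful-in-spirit reconstruction;
  the original operator's exact mechanics are not public.
* No probability calibration of the meta output and no homology-aware
  splitting; with real data, sequence-identity clustering before splitting
  would be required to avoid optimistic estimates.
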