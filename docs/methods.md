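# Methods

## Scope and model of the workflow

`qsar-workbench` implements a project-based QSAR/QSPR modeling workflow in
six stages: (1) prepare data, (2) split data, (3) compute descriptors,
(4) build models, (5) validate, (6) publish.  The central object is the
**model matrix**: the full cartesian product of data splits × descriptor
subsets × learner methods, filtered only by each learner's endpoint support.
The system never performs competitive selection — every cell is attempted,
failures are recorded as data (`status="failed"` with a reason) without
aborting, and ranking exists only in the validation-stage triage views.
With the standard configuration (7 splits, 10 descriptor subsets, 5
categorical / 4 continuous learners) the matrix has 350 cells for a
categorical endpoint and 280 for a continuous one.

## Data preparation

Chemistry standardisation is an ordered list of steps recorded in the
dataset's `prep_spec` and replayed verbatim at prediction time:

- **desalt** — fragments without a carbon atom (inorganic counter-ions,
  water, mineral acids) are discarded; of the remaining fragments the one
  with the most heavy atoms is kept (ties: descending molecular weight, then
  ascending canonical SMILES).  A structure with no organic fragment (a pure
  salt) vanishes and the record is excluded with a logged reason.  This rule
  is idempotent and needs no salt catalogue; it deliberately keeps organic
  acids/bases that a catalogue-based stripper would remove.
- **neutralize** — a fixed SMARTS rule
  (`[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]`) protonates free
  anions (carboxylates, alkoxides, thiolates) and deprotonates protonated
  cations where valence allows.  Charge-separated pairs (zwitterions,
  quaternary ammonium) are untouched.
- **canonicalize** — canonical SMILES serialisation (always applied last).

Response preparation: `identity`, `log10` (strictly positive responses
required; the offending record is named otherwise), `unit_variance`
(centred on the mean, scaled by the sample standard deviation with ddof=1 —
the fitted centre/scale are stored in the spec so replay on new data uses
the *training* constants), and `categorize` via either a label map or a
strictly increasing threshold list.  Threshold bins are half-open and
lower-inclusive at the bottom: a value equal to a boundary goes to the
**upper** class.  Replaying a `prep_spec` on the raw dataset reproduces the
prepared dataset bit-identically; this is asserted by test.

## Splitting

- **random** — `round(n·f)` records to train, sampled uniformly.
- **stratified** — quantile bins (continuous; default 5) or classes
  (categorical); random sampling within each bin keeps per-bin train
  fractions within one record of the target.  Bins with fewer than two
  records are merged with a neighbour under a warning.
- **sphere-exclusion clustering** — the *recomputing* variant: at each round
  the unassigned molecule with the most unassigned neighbours (Tanimoto ≥
  threshold on 2048-bit ECFP6 by default) becomes a centroid and claims
  those neighbours.  Recomputing neighbour counts over the remaining pool
  each round makes the procedure exactly reproducible by a brute-force
  oracle (asserted by test); ties go to input order.  A property-space
  analogue runs the same procedure on Euclidean distance over unit-scaled
  descriptor vectors.
- **independent clusters (optimized)** — whole clusters are assigned to the
  test side so the achieved test fraction is as close as possible to
  `1 − f`.  The optimisation is an exact subset-sum dynamic program over
  cluster sizes (O(#clusters × n) time), with the achievable size closest to
  the target chosen (ties: the smaller test set) and one optimal subset
  reconstructed under a seed-shuffled cluster order so ties among optimal
  subsets are seed-determined.  A greedy-with-swaps heuristic was considered
  and rejected: it provably misses the optimum on cluster sizes as simple as
  {5, 3, 2} at f = 0.8, while the DP is optimal for any cluster count and
  equally cheap at these problem sizes.
- **random per cluster** — `round(size·f)` members of each cluster of size
  ≥ 2 go to train; singleton clusters are assigned by an independent
  Bernoulli(f) draw (the overall train fraction then converges to the
  target as singletons accumulate; always-to-train was the alternative and
  would bias the achieved fraction upward).
- **predefined** — a two-column `record_id {train|test}` table; coverage
  must be exact, with discrepancies listed in the error.

**Split diagnostics.** `analyze_split` embeds the dataset by classical
(Torgerson) metric MDS — double centring of the squared Tanimoto distance
matrix followed by eigendecomposition, coordinates from the top two
non-negative eigenvalues.  The embedding is defined only up to orthogonal
transformation and is not canonicalised; tests compare against an
independent eigendecomposition (and scikit-bio's PCoA) through a Procrustes
residual.  The overlap summary reports each test record's highest Tanimoto
similarity to any training record; whole-cluster (IndOpt) test sets show
systematically lower values than within-cluster (RPC) test sets, which is
the mechanism by which RPC-style splits flatter test statistics.

## Descriptors

Five blocks; a fingerprint counts as **one** descriptor in subset-size
accounting but expands to `fold_width` (default 1024) folded count columns
in a numeric matrix:

| Block | Accounting size | Content |
|---|---|---|
| Molprops | 19 | Crippen logP (column `ALogP`), molecular weight, atom/bond/rotatable-bond/ring/aromatic counts, four H-bond donor/acceptor variants, stereo, bridge and spiro counts |
| Chi | 12 | Kier–Hall connectivity indices: simple χ of order 0, 1, 2, 3-path, 3-cluster, 4-path and the same six with valence deltas δv = Zv − h (second row) or (Zv − h)/(Z − Zv − 1) |
| Estate | 161 | per-atom-type E-state sums and counts over the standard 79-type alphabet, plus total/max/min atom E-state |
| ECFP6 | 1 | Morgan fingerprint, radius 3, standard atom invariants |
| FCFP4 | 1 | Morgan fingerprint, radius 2, functional-class invariants |

The chi implementation enumerates simple paths and 3-star subgraphs on the
heavy-atom graph directly and is cross-checked against an independent
implementation for the simple orders; atoms with non-positive delta
contribute nothing (the standard convention).  E-state values use
I = ((2/N)²·δv + 1)/δ intrinsic states with 1/r² graph-distance
perturbations; Σ S = Σ I by antisymmetry, asserted as a property.  The
exact column inventories of the Chi and Estate blocks are this package's
own fixed, documented choice — subset-size arithmetic (12 + 1 + 161 + 1 +
19 = 194 for the full combination) is the compatibility contract, not
column-by-column parity with any proprietary implementation.

Subsets are unions of blocks; the standard ten are the five base blocks,
the four `+Molprops` pairings and the all-block union.  Descriptor
computation failures exclude the affected record from the matrix with a
logged reason.

## Learners

All learners run with declared library defaults (scikit-learn), not tuned:

- `pp_bayes` — Gaussian naive Bayes (categorical).
- `rp_tree` — CART decision tree (categorical).
- `rp_forest` — random forest, 100 trees (categorical).
- `nn` — multilayer perceptron, one hidden layer of 100 units, max 300
  iterations (both endpoint kinds), standardised inputs.
- `svm` — RBF SVM / SVR with library defaults, standardised inputs.
- `pls` — PLS regression with the component count chosen by internal 3-fold
  CV (RMSE criterion), capped at min(10, rank) (continuous).
- `pls_fixed` — PLS regression with a fixed component count (default 3,
  clipped to the data rank) (continuous).

Two PLS variants are registered so the continuous battery has four methods,
mirroring the two PLS implementations of a typical workbench deployment.
ROC scores come from the decision function (sign-aligned to the declared
positive class) where available, otherwise positive-class probabilities.
`model_id` is a hash of (split, subset, learner, params, seed, dataset
digest); `run_matrix` persists each result as it completes and skips
already-persisted ids, so interrupted runs resume and completed runs are
no-ops.

## Validation

- Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP); a rate whose
  denominator class is absent is reported as NaN, never 0.
- ROC by descending-score threshold sweep with tied scores grouped into one
  step; AUC by trapezoid, which equals positive–negative pairwise
  concordance with ties counted ½ (asserted to 1e-12 against a brute-force
  oracle).
- R² is the coefficient of determination 1 − SSres/SStot (not squared
  Pearson correlation); NaN when the truth has zero variance; RMSE always
  reported.
- REC: fraction of records with |error| ≤ ε over a default grid of 100
  evenly spaced tolerances from 0 to the maximum absolute error; the area
  is normalised by the grid span to [0, 1] so models on different response
  scales are comparable.
- The triage table is a plain DataFrame over all results (provenance triple
  + all scalar statistics) with stable mergesort ordering, non-mutating
  filters, a train-vs-test summary series and breakdown counts by learner,
  split and subset that always sum to the selection size.
- Y-scrambling permutes responses **within the training split**, refits,
  and records the test statistic per permutation, returning the scrambled
  mean/sd/max and the fraction of permutations reaching the observed value.

## Publication

A bundle directory contains the manifest, prep spec, descriptor config
(blocks, fold width, exact column order), the fitted estimator, per-column
training ranges, the training predictions and a deterministic HTML report
(convertible to PDF by any HTML renderer; no timestamps in the body, so
regeneration is byte-identical).  `predict` replays preparation and
descriptors exactly, so salt forms and their parents score identically and
training structures reproduce the stored training predictions exactly.
Applicability reporting is limited to per-column range warnings on
non-fingerprint descriptors — richer distance-based metrics are out of
scope.  Tree-learner reports include the descriptor-usage table ("number of
questions" per descriptor, summing to the number of internal nodes).
"Publishing" means registry + CLI + a documented programmatic call; a
network service can wrap `predict` but is not included.

## Synthetic fixtures

The generator assembles molecules from 12 ring scaffolds with three
substitution sites filled from a 28-fragment substituent pool (duplicate
rate < 1% at n ≤ 1000).  Classification sets plant a carboxylic-acid
pharmacophore in exactly `round(n·balance)` records (presence verified by
substructure match) and flip labels with the configured noise probability;
at noise 0.5 every learner scores chance-level AUC.  Regression sets use
response = 1.0·logP + 0.75·(ring count) + N(0, σ²), coefficients recorded
in `meta` for recovery tests.  A configurable fraction of records gains a
counter-ion fragment (`.Cl`, `.Br`, `.OS(=O)(=O)O`), exercising desalting
in-pipeline.

What the fixtures do **not** emulate: real assay noise structure, activity
cliffs, measurement censoring, series/temporal structure, or the chemistry
of any published toxicity dataset.  Passing tests demonstrate the machinery
(splitting bias, chance-correlation baselines, replayed preparation), not
predictive performance on real endpoints.

**Clustering threshold for fixtures.** The default Tanimoto threshold of
0.7 is appropriate for lead-optimisation series; the fragment grammar's
baseline pairwise similarity is much lower (median ≈ 0.09), so fixture
studies cluster at 0.25, which groups molecules by scaffold family (median
cluster count ≈ 56 at n = 120).  At 0.7 the fixture degenerates to
singletons and cluster-based splits lose their meaning.

## Problem sizes and numerical choices

The end-to-end study runs the full 350-cell categorical matrix on a
300-record fixture (noise 0.1, salt fraction 0.1, fold width 1024) and the
280-cell continuous matrix on a 200-record fixture (noise sd 0.4, fold
width 512); Y-scrambling uses 20 permutations.  These sizes exercise every
code path while keeping a complete run in the order of a minute on one CPU.
Ties in ROC and clustering are handled by the stated deterministic rules;
degenerate inputs (constant descriptor matrices, all-identical distance
matrices, zero-variance truths) produce defined failures, warnings or NaN
rather than silent zeros.  All randomness flows through explicit integer
seeds on `numpy.random.default_rng`.

## Known limitations

- Descriptor values are not numerically interchangeable with any
  proprietary descriptor implementation; only block/subset cardinalities
  and the scientific definitions are fixed.
- No 3-D descriptors, tautomer canonicalisation, stereo repair, temporal
  splitting, ensemble/data-fusion modeling, or Mahalanobis-style
  applicability metrics.
- The learner-parameter grid ("fourth dimension" of the matrix) is exposed
  through `LearnerSpec.params` but deliberately excluded from defaults.
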