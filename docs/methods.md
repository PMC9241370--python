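# Methods

## Problem and model

`saaspred` classifies single amino acid substitutions (SAAS) in plant
proteins as functional (altering normal protein function) or neutral. The
classifier is an ensemble of four supervised learners over five families of
sequence-derived features; the positive class is "functional" and the
decision rule is `score ≥ 0.5` on the predicted probability.

## Pseudoneutral simulation

Neutral training labels are scarce experimentally, so neutral examples are
simulated from evolution: if two proteins are ≥ 95% identical and differ at
an isolated residue, that substitution is assumed tolerated. Per alignment
and hit row the four rules are:

* **R1** — the alignment holds at least 3 sequences;
* **R2** — the candidate column holds exactly 2 distinct non-gap residues;
* **R3** — within the 5-column window centred on the candidate column
  (truncated at alignment ends), exactly one column shows any query/hit
  disagreement (gap-versus-residue counts as disagreement);
* **R4** — the hit differs from the query in exactly one column over their
  mutual non-gap span, with no internal gaps (terminal overhangs are
  tolerated).

Open design points resolved here (all config-exposed): the R3 window is
centred (±2); R2 counts non-gap residues only, so a column of one residue
plus gaps carries no substitution and is rejected; deduplication keeps the
first candidate in deterministic (protein_id, position, mutant) order, and
merges candidates whose host proteins align at ≥ 95% identity with matching
(wt, mut) at alignment-corresponding positions.

Raising the identity threshold or the minimum row count never increases the
output on the bundled fixture families (checked by the soundness suite);
with strongly heterogeneous alignments, dropping a low-identity row can in
principle turn a three-residue column biallelic and admit a new candidate,
so monotonicity is a property of near-homogeneous hit sets, not a theorem.

## Alignment conventions

Global alignment is affine-gap Needleman–Wunsch (Gotoh's three-state DP)
with BLOSUM62 substitution scores, gap open −10 and gap extend −1 (a
length-k gap costs −10 − (k−1)); traceback ties resolve diagonal > up >
left so alignments are deterministic. Percent identity divides identical
columns by the **full alignment length including gap columns**, so the 95%
threshold implicitly requires coverage; the denominator convention is a
`ScoringScheme` concern and can be changed in one place.

## Feature families

**Sequence evolutionary (5).** PSSM_FROM / PSSM_TO are the log-odds scores
of the wildtype and mutant residues at the substitution position;
PSSM_CHANGE is their absolute difference. Scores come either from a
PSI-BLAST ASCII matrix (the log-odds block; the weighted-percentage block
is ignored) or from the internal profile
`score[i][a] = log2(((count_i(a)+c)/(n_i+20c)) / q(a))` with Laplace
pseudocount `c = 1` and uniform background `q = 1/20`; a zero frequency at
`c = 0` is floored at −10. SFM is the frequency of the **mutant residue
only** among non-gap, non-X residues at the column (counting all
non-wildtype residues instead is selectable). CON_SCORE is the Shannon
entropy (bits) of the column's residue frequencies; note the conventional
name notwithstanding, larger values mean *less* conservation — the formula
is implemented exactly as the field publishes it.

**Physicochemical (one per retained AAindex accession).** Entries with
missing values and asymmetric matrices are excluded at parse time.  A
per-residue index must be collapsed to one number per substitution; the
mutant−wildtype difference is used because it captures the change the
substitution causes and preserves the one-feature-per-accession count (raw
wildtype/mutant value pairs are available but off by default). Matrix
entries contribute `M[wt][mut]`, symmetric by construction. A residue not
covered by an entry yields a missing value for the imputation stage.

**Database annotated (31).** The query is matched to the best
global-alignment hit in an annotated library, the substitution position is
mapped through the alignment, and for each of 25 annotation types
`SRD = min |pos − annotation| / length` with SRD = 1 when the type is
absent. Span annotations score 0 inside the span and
nearest-endpoint-distance otherwise (the point formula needs a span
convention). EC is a presence indicator (0 if any EC annotation exists)
and is excluded from the Function merge. The six merges pool their
category's annotations: FUNCTION, PTM, SUBLOC, FAMILY, and two structure
merges — STRUCTURE1 = {HELIX, STRAND}, STRUCTURE2 = {HELIX, STRAND, TURN};
the published category lists name two structure merges over three keys
without defining them, so this composition is provisional. Hits below 30%
identity (configurable) default all 31 features to 1: no reliable transfer.

**Coevolutionary (220).** For offsets −4..−1, +1..+4 the MI (bits) between
the substitution's alignment column and the neighbour's column, at ten
alignment depths N = 100..1000 step 100 (a depth with fewer rows uses all
rows and is noted in the run log). Rows with a gap or X in either column
are excluded pairwise. Per depth: 8 positional MI values, their min, max
and mean, and 11 parallel binary gap indicators (positional indicator = 1
when any row was excluded or the offset falls off the protein; the three
summary indicators share the any-gap flag) — 22 × 10 = 220. The
decomposition is forced by arithmetic: 8 + 3 MI features and their
one-to-one gap mirrors are the only reading that reaches the published
total. Binary indicators are the default; gap fractions are selectable.

**External.** The battery of third-party structure/disorder/PTM predictors
is out of scope; their columns can be merged from a pre-computed TSV keyed
by (protein_id, wt, position, mut).

## Dataset handling

The benchmark/independent split is stratified per class with
round-half-up class sizes — the only rounding that maps a 6367 + 6498
cohort at 80% to 5094/5198 + 1273/1300 exactly. Standardization is
z-score with **population** SD (n denominator; `ddof=1` available);
parameters (mean, SD, median) are fitted on the benchmark set only and
applied unchanged to the independent set. Missing values are imputed with
the benchmark median *before* scaling; features with SD < 1e-12
standardize to 0.

## Feature selection

Fitness of a feature subset is the mean MCC over repeated stratified
5-fold cross-validation of a random forest. One seed fixes both the CV
partition and the forest RNG for **every** subset, so subset comparisons
are paired (common random numbers) and the cached fitness of a subset is
exactly reproducible; the empty subset scores −1.

* **Stage 1 (OOB screen).** Each feature alone is scored by the out-of-bag
  error of a random forest; features at or below the 40% threshold
  survive. A forest grown to unit leaves on one continuous feature
  degenerates to bagged nearest-neighbour voting and overstates the error,
  so the screen regularizes leaves at 1% of the sample size, which tracks
  the feature's one-dimensional Bayes error.
* **Stage 2 (GA).** A single-state toggle search: start from a random
  subset (inclusion probability 0.5), toggle one uniformly chosen feature
  per iteration, keep the toggle only on strict fitness improvement, stop
  after a stagnation run of non-improving iterations ("strictly no
  improvement" is the stagnation reading implemented). The search is
  restarted with distinct seeds; the five best subsets (fitness, then
  smaller size, then lexical order) go forward.
* **Stage 3 (backward elimination).** From each of the five, repeatedly
  delete the single feature whose removal most improves fitness, strict
  improvements only; singletons stop (the empty subset is never
  evaluated). The best resulting subset wins, smaller-then-lexical on ties.

Full-scale settings (500 restarts, 500 stagnation, 10 CV repeats, 500-tree
fitness forests) are carried by the `paper-mode` CLI profile; the package
defaults (30-tree fitness forests, 2 CV repeats) are desk-scale choices
that keep a complete pipeline run on a 2000 × 20 table around ten seconds
per seed while leaving the selection behaviour unchanged on the planted
benchmark.

## Model building

Base learners: random forest (ntree/mtry/nodesize), XGBoost
(nrounds/max_depth/min_child_weight/gamma/subsample/colsample_bytree/
alpha/lambda/eta), SVM (kernel/gamma/cost) and a single-hidden-layer
feed-forward network (activation/hidden/learning rate). Hyperparameters
are tuned by repeated stratified 5-fold CV on mean MCC, ties to the first
grid point in deterministic order; the tuned configuration is refit on the
full training set (selecting the best single CV fold-model is available
but refitting is the default, standard practice when the tuned
configuration — not one stochastic fold-model — is the object of
interest). Stacking fits an unregularized logistic regression on
**out-of-fold** base probabilities (5-fold, stratified), preventing
leakage by construction, then scores new data with the refit base
learners; all 11 subsets of ≥ 2 learners are built. Compact default grids
keep a full 15-model build on 1600 × 30 around half a minute;
`paper-mode`-scale grids are provided alongside.

Metrics: SEN, SPE, PRE, ACC, MCC from confusion counts (any zero
denominator defines the metric as 0, with a warning); AUC is the
rank-based Mann–Whitney statistic with ties at 1/2, identical to
trapezoidal ROC integration. Reports use the column order MCC, ACC, SEN,
SPE, PRE, AUC.

## Synthetic study conditions

`make_protein_family` plants conservation (mutation-free columns), binary
column variation (each column has one fixed alternative residue), and
coevolution (column pairs switching jointly in the same rows); rows are
i.i.d. derivatives of the query at a configurable substitution rate
(default 5%, i.e. ≈ 95% identity hits). `make_labeled_table` draws i.i.d.
standard-normal features and Bernoulli labels through a logistic link over
the informative columns (default three features with coefficient 2, noise
SD 0.5), intercept-calibrated to near class balance. `make_annotated_library`
scatters annotations of all 25 types and guarantees one protein lacking a
type, so the SRD = 1 branch is always exercised.

What passing these conditions does **not** show: the generators have no
phylogeny (no tree-correlated rows), no alignment errors, no realistic
annotation density, and feature/label links are logistic by construction —
so recovery and AUC results certify the machinery (rules, formulas, search,
stacking, leakage-freedom), not field performance on curated plant
variants.

## Numerical choices and limitations

* Entropy/MI terms with zero probability contribute 0; MI is clamped at 0
  against floating-point drift.
* PSSM log-odds of unseen residues (pseudocount 0) floor at −10.
* All public positions are 1-based; `.` gaps normalize to `-`; `X` is
  tolerated in sequences but excluded from every frequency count.
* The GA is a single-state toggle search, not a population GA: no
  crossover, matching the published termination-by-stagnation behaviour.
* Monotonicity of the simulator under threshold tightening holds on
  near-homogeneous families (see above), and the exact published feature
  counts for AAindex (631) are database-version-dependent and not
  reproduced; the bundled fixture database is synthetic and labelled as
  such.
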