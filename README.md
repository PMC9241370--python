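# saaspred

Predicting whether a single amino acid substitution (SAAS) in a plant
protein is **functional** (protein-function-altering) or **neutral**.

Plant genomes carry large numbers of missense variants, but almost all
variant-effect predictors are trained on human clinical data. `saaspred`
implements, end to end, a plant-oriented supervised pipeline:

1. **Pseudoneutral simulation** — neutral-labelled substitutions are
   inferred from ≥ 95%-identical homologs in multiple sequence alignments
   under four isolation rules (≥ 3 sequences; exactly two residue kinds in
   the candidate column; exactly one query/hit disagreement in the
   five-column window around it; exactly one mismatch over the whole
   query/hit overlap), followed by Needleman–Wunsch-based deduplication.
2. **Feature extraction**, five families:
   - *sequence evolutionary*: PSSM_FROM, PSSM_TO, PSSM_CHANGE = |FROM − TO|,
     the mutant-residue column frequency SFM, and the column entropy
     CON_SCORE_i = −Σ_j P_ij log₂ P_ij;
   - *physicochemical*: one feature per retained AAindex accession
     (per-residue indices contribute the mutant−wildtype difference,
     symmetric residue-pair matrices the (wt, mut) entry);
   - *database annotated*: shortest relative distances
     SRD_i = min_j |pos − annotation_ij| / length over 25 annotation types
     on a best-hit annotated protein, plus six merged-category features;
   - *coevolutionary*: mutual information
     MI_ij = Σ_{a,b} P(a_i, b_j) log₂ [P(a_i,b_j)/(P(a_i)P(b_j))] between
     the substitution's column and its ±1..±4 neighbours at ten alignment
     depths (N = 100..1000), with min/max/mean summaries and binary gap
     indicators — 220 features;
   - *external*: a pluggable merge point for pre-computed predictor tables.
3. **Dataset handling** — stratified 80/20 benchmark/independent split and
   z-score standardization with parameters fitted on the benchmark set only.
4. **Three-stage feature selection** — per-feature random-forest OOB screen
   (retain OOB error ≤ 40%), a stagnation-terminated single-state genetic
   toggle search repeated with restarts, and backward elimination on the
   five best subsets; fitness is the mean MCC of repeated stratified 5-fold
   cross-validated random forests.
5. **Model building & evaluation** — tuned random forest, XGBoost, SVM and
   single-hidden-layer FFNN base learners; the 11 logistic-regression
   stacking ensembles over all subsets of ≥ 2 learners; prediction with a
   0.5 probability threshold; SEN, SPE, PRE, ACC, MCC and AUC reports.

## Worked example

```python
import numpy as np
from saaspred import SubstitutionEffectModel, CvConfig, stratified_split, standardize_pair
from saaspred.synthetic import make_labeled_table

table = make_labeled_table(n=2000, n_features=30,
                           informative_idx=tuple(range(10)),
                           coefficients=[2.0] * 10, seed=7)
bench, indep = stratified_split(table, 0.8, seed=7)
bench, indep, params = standardize_pair(bench, indep)
results = SubstitutionEffectModel(bench).fit(CvConfig(repeats=2, seed=7),
                                             seed=7, standardizer=params)
print(results.evaluate(indep).round(3).loc[
    ["random_forest", "gradient_boosted_trees", "svm", "ffnn_1hidden",
     "stack[random_forest+gradient_boosted_trees+svm+ffnn_1hidden]"]])
```

prints (AUC = probability a random functional record outscores a random
neutral one on the held-out 20%; MCC at the 0.5 threshold):

```
                                                                MCC    ACC    SEN    SPE    PRE    AUC
random_forest                                                 0.640  0.820  0.796  0.843  0.830  0.926
gradient_boosted_trees                                        0.710  0.855  0.847  0.863  0.856  0.933
svm                                                           0.755  0.878  0.883  0.873  0.869  0.957
ffnn_1hidden                                                  0.806  0.902  0.918  0.887  0.887  0.968
stack[random_forest+gradient_boosted_trees+svm+ffnn_1hidden]  0.805  0.902  0.908  0.897  0.894  0.968
```

All four learners separate the planted signal cleanly and the full stack
matches the best base learner.

The same workflow is available from the shell:

```sh
saaspred make-fixtures --out-dir demo
saaspred simulate-neutral --msa-dir demo/msa --min-identity 0.95 --out demo/saas.tsv
saaspred split --features demo/labeled_table.tsv --out-prefix demo/parts
saaspred select-features --features demo/parts.benchmark.tsv --out demo/selection.json
saaspred train --features demo/parts.benchmark.tsv --out demo/bundle
saaspred evaluate --features demo/parts.independent.tsv --bundle demo/bundle --out demo/metrics.tsv
saaspred predict --fasta query.fasta --substitution G87D --bundle demo/bundle
```

`predict` emits `protein_id  substitution  score  class` with
class = functional when score ≥ 0.5.

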