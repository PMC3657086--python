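# qsar-workbench

A scriptable, project-based system for building, validating and publishing
QSAR/QSPR models — statistical models that relate molecular structure
descriptors to an assay endpoint, used in lead optimisation to prioritise
compounds before synthesis.

The package is aimed at QSAR modelers who want to explore a large model
landscape systematically instead of hand-building one model at a time.  Its
core idea is the **model matrix**: given a prepared dataset, a set of named
train/test splits S, a set of named descriptor subsets D and a registry of
learners L, the workbench attempts every cell of S × D × L (filtered to
learners supporting the endpoint type) and records each result — fitted
model, train/test statistics, or a captured failure — without any
competitive selection.  Choosing among models is the modeler's job, guided
by a sortable triage table, train-versus-test summary statistics,
Y-scrambling baselines and chemical-space split diagnostics.

Key components:

- **Preparation** — desalting (largest organic fragment), SMARTS-rule
  neutralisation, canonicalisation, and response transforms (log10, unit
  variance with stored constants, categorisation by map or thresholds).
  Every step is recorded and replayed exactly at prediction time.
- **Splitting** — random, activity-stratified, independent whole-cluster
  (test fraction optimised exactly by subset-sum over cluster sizes),
  random-per-cluster, and predefined file-based splits, built on
  sphere-exclusion (Butina-style) Tanimoto clustering.  `analyze_split`
  embeds the data by classical MDS on fingerprint distances and quantifies
  train/test overlap — the diagnostic that separates genuinely hard test
  sets from flattering ones.
- **Descriptors** — Molprops (19 interpretable properties), Kier–Hall chi
  connectivity indices (12), electrotopological-state sums/counts (161),
  and ECFP6/FCFP4 circular fingerprints, combined into named subsets
  (standard battery: ten subsets, full union of accounting size 194).
- **Learners** — naive Bayes, decision tree, random forest (categorical);
  neural network and SVM (both); two PLS variants (continuous).  Library
  defaults, declared rather than tuned.
- **Validation** — confusion rates, tie-aware ROC/AUC, R²/RMSE, REC curves,
  triage tables, external validation sets, Y-scrambling.
- **Publication** — self-contained bundles (prep spec + descriptor config +
  fitted model + training ranges + HTML report) served by a registry and a
  `predict` entry point with out-of-range applicability warnings.
- **Fixtures** — a fragment-grammar generator of synthetic
  structure–activity datasets with planted signal, so the whole pipeline is
  testable offline.

## Worked example

```python
import qsar_workbench as qw
from qsar_workbench.fixtures import SyntheticSpec, generate_classification_set

ds = generate_classification_set(
    SyntheticSpec(120, 7, "classification", noise=0.1, salt_fraction=0.1))
ds = qw.standardize(ds, ["desalt", "neutralize", "canonicalize"])
cluster_of = qw.cluster_molecules(ds, similarity_threshold=0.25)

proj = qw.Project("my_project")
proj.set_dataset(ds)
proj.add_split(qw.random_split(ds, 0.75, seed=1, label="Rand75"))
proj.add_split(qw.independent_cluster_split(ds, cluster_of, 0.75, seed=1, label="IndOpt75"))
proj.add_split(qw.random_per_cluster_split(ds, cluster_of, 0.75, seed=1, label="RPC75"))
proj.set_subsets({"Molprops": ["Molprops"], "ECFP6_Molprops": ["ECFP6", "Molprops"]})
proj.compute_descriptors()
proj.set_learners(seed=0)

results = qw.run_matrix(proj)   # 3 splits × 2 subsets × 5 learners = 30 cells
t = qw.triage(results, sort_keys=["test_roc_auc"], ascending=False)
print(t.table[["split_label", "subset_label", "learner_name",
               "train_roc_auc", "test_roc_auc"]].head(5).to_string(index=False))
```

prints

```
split_label   subset_label learner_name  train_roc_auc  test_roc_auc
      RPC75 ECFP6_Molprops    rp_forest            1.0      0.912281
     Rand75 ECFP6_Molprops      rp_tree            1.0      0.911765
   IndOpt75 ECFP6_Molprops    rp_forest            1.0      0.900568
      RPC75 ECFP6_Molprops      rp_tree            1.0      0.893275
   IndOpt75 ECFP6_Molprops      rp_tree            1.0      0.892045
```

Each row is one matrix cell; the top model separates actives from inactives
on its held-out split with test AUC 0.91.  Note the within-cluster split
(RPC75) heads the table while the whole-cluster split (IndOpt75) trails —
the systematic split bias the diagnostics are designed to expose.
Y-scrambling the top model confirms the signal is real rather than a chance
correlation:

```python
from qsar_workbench.model_matrix import ModelSpec, y_scramble_model
r = next(x for x in results if x.model_id == t.table.iloc[0]["model_id"])
scr = y_scramble_model(ModelSpec(r.split_label, r.subset_label, r.learner_name),
                       ds, proj.matrices[r.subset_label], proj.splits[r.split_label],
                       proj.learners[r.learner_name], n_permutations=20, seed=3)
# observed test AUC 0.912; scrambled mean 0.485 (sd 0.114, max 0.699)
```

Publishing freezes the model with its full preparation pipeline; prediction
replays it, so salt forms score like their parents and out-of-range queries
are flagged:

```python
bundle = qw.publish(r, proj)
qw.predict(bundle, ["CCc1cc(C(=O)O)cc(N(C)C)c1.Cl", "C" * 32])
#                  prepared_smiles prediction  warnings
#        CCc1cc(C(=O)O)cc(N(C)C)c1     active
# CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCC   inactive  ALogP=12.73 outside training range [...]
```

The same workflow is available from the shell via the `qsarwb` CLI
(`qsarwb fixtures make`, `prepare`, `split`, `descriptors`, `build`,
`validate`, `publish`, `predict`, `save-protocol`); see `qsarwb --help`.

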