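# pinhub

Four-class classification of protein hub roles in a protein-interaction
network (PIN) from biological features of the proteins themselves.

In a PIN, proteins with more than eight interaction partners are *hubs*,
proteins with fewer than three are *non-hubs* (NH), and the rest are
*intermediately connected* (IC). Hubs split further by gene co-expression
with their partners: *party hubs* (PH) are co-expressed with most partners
simultaneously (local coordinators), *date hubs* (DH) bind different
partners at different times or places (global connectors). When the
interaction network itself is incomplete or unknown, predicting these four
roles from protein features — sequence, domain content, Gene Ontology
annotation, intrinsic disorder, evolutionary profiles — is the next best
thing. `pinhub` implements that classifier end to end, for computational
biologists who want to reproduce, stress or extend the approach.

## Method

A protein is encoded by n feature vectors X₁ … Xₙ (Xᵢ ∈ ℝ^kᵢ), and a
classifier maps them to a label y ∈ {1, 2, 3, 4} = {NH, IC, PH, DH}:

* **Sequence encodings** — amino-acid composition comp(i) = Rᵢ/N (20-dim);
  dipeptide composition dpep(i) = Dᵢ/(N−1) (400-dim); gapped pair
  compositions Eₖ(i)/(N−1−k) for k gaps (400-dim each); the 20×20
  co-occurrence matrix of gapped pairs with twelve Haralick texture
  statistics (energy, correlation, inertia, entropy, inverse difference
  moment, sum/difference moments, information measure of correlation);
  fractions of residues in 48 named physicochemical groups; sequence length.
* **Annotation encodings** — binary domain-content and repeated-domain
  vectors over a domain vocabulary; binary GO-term membership per ontology
  aspect and level; four scalar disorder summaries; PSSM-20 and PSSM-400
  fixed-length summaries of a PSI-BLAST profile.
* **Reduction** — each feature-set is reduced to three combined features by
  supervised PCA (ANOVA-F screening of features against the class labels,
  then PCA of the standardized survivors).
* **Classification** — Bayes with per-class Gaussian densities, Bayes with
  per-class Gaussian-mixture densities fitted by EM (component count chosen
  by cross-validation), or k-nearest neighbours. Decisions are MAP or
  minimum expected risk under a 4×4 cost matrix L (rows = true class):

  ```
  L = [[0, .1, .2, .2], [.1, 0, .2, .2], [.9, .9, 0, .2], [.9, .9, .2, 0]]
  ```

  which charges 0.9 for losing a true hub to NH/IC and so counteracts the
  extreme class imbalance (hubs are < 10% of proteins).
* **Fusion** — greedy forward selection over reduced feature-sets: sets are
  ranked by standalone cross-validated average CCR; a candidate is kept only
  if it strictly improves both the CV average CCR and the label correlation.
* **Evaluation** — 4×4 confusion matrix, average CCR (unweighted mean of
  per-class recalls), Pearson correlation of integer-coded labels,
  one-vs-rest sensitivity/specificity/PPV/NPV per class (and for the merged
  PH+DH super-class), and per-class ROC AUC.

Because the yeast label set and 2009-era annotation snapshots behind the
original study are not reproducible, the package ships a synthetic dataset
generator (`pinhub.synthetic_data`) that emulates the assumed structure:
scale-free degrees, degree-threshold roles, a co-expression PH/DH split,
and class-conditional sequences, annotations and profiles, with a single
`effect_size` knob scaling every class signal (0 = pure noise).

## Worked example

```bash
pinhub simulate --out-dir data --n-proteins 2000 --seed 1
pinhub run --data-dir data --out-dir results --seed 1 --classifier gauss --min-risk
```

The second command extracts all 17 feature-sets, splits 70/30 with
stratification, reduces each set to 3 features on the training portion,
runs greedy fusion with 5-fold CV, trains the minimum-risk Gaussian Bayes
classifier and prints the held-out evaluation (abridged):

```
"confusion_percent": [[94.1, 3.1, 1.0, 1.8],
                      [46.7, 31.7, 11.7, 10.0],
                      [31.6, 5.3, 52.6, 10.5],
                      [3.2, 0.0, 12.9, 83.9]],
"average_ccr": 65.6,
"correlation": 73.8,
"auc": {"NH": 0.903, "IC": 0.815, "PH": 0.846, "DH": 0.987}
```

Fusion selected `domains`, `disorder` and `dipeptides` for this seed. Read
the confusion rows as per-class recall percentages: 94.1% of non-hubs and
83.9% of date hubs are recovered, while intermediately connected proteins
(recall 31.7%) are the hardest class — most of their errors fall into the
adjacent non-hub class. The average CCR of 65.6% compares with a chance
level of 25%, and the merged PH+DH hub sensitivity for this run is 84.0%.
Artifacts (predictions, fusion trace, fitted models, report) land in
`results/`.

The same pipeline is available as a library:

```python
from pinhub import ExperimentConfig, SyntheticConfig, run_experiment, generate_dataset

generate_dataset(SyntheticConfig(n_proteins=2000, seed=1), "data")
report, artifacts = run_experiment(
    ExperimentConfig(seed=1, classifier="gauss", min_risk=True), "data"
)
print(report.average_ccr, artifacts["selected_sets"])
```

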