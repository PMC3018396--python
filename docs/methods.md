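# Methods

This note documents the models and procedures implemented in `pinhub`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not establish.

## Problem and model

Proteins of a protein-interaction network are labeled 1–4: non-hub (NH,
degree < 3), intermediately connected (IC, degree 3–8), party hub (PH,
degree > 8 and high average co-expression with partners), date hub (DH,
degree > 8, low co-expression). The classifier never sees the network; it
sees per-protein feature vectors and learns the mapping from features to
role. Classification is Bayesian: class priors are training frequencies,
class-conditional densities are either a single multivariate Gaussian or a
Gaussian mixture, and the decision is maximum a posteriori or minimum
expected risk under a user-supplied cost matrix.

## Conventions fixed by the package

* **Canonical residue order** is alphabetical by one-letter code
  (A C D E F G H I K L M N P Q R S T V W Y). Every 20- and 400-dimensional
  vector, and the co-occurrence matrix, uses it; a pair (a, b) is
  directional and flattens row-major. Nothing in the formulas prefers one
  order; fixing one makes vectors comparable across modules and files.
* **Coordinates** are 0-based half-open intervals internally; 1-based
  indices appear only while parsing PSI-BLAST ASCII files.
* **Nonstandard residues** (B, J, O, U, X, Z) are retained in sequences but
  contribute to no composition numerator, while the denominators stay the
  literal N, N−1, N−1−k of the composition formulas. Composition vectors
  over sequences with nonstandard letters therefore sum to slightly less
  than 1; this preserves the printed formulas exactly.
* **Tie-breaks** everywhere resolve to the lowest class index (MAP,
  minimum-risk, KNN votes) or the lowest row index (KNN distance ties);
  every fit is deterministic given its seed.

## Feature encodings

Sequence encodings follow the standard fixed-length protein summaries:
amino-acid composition (20), dipeptide composition (400), gapped pair
compositions for k = 1 and k = 2 gaps (400 each; k = 0 reduces exactly to
dipeptides), Haralick statistics of the k = 1 co-occurrence matrix
(configurable; the co-occurrence matrix is the 400-vector reshaped 20×20,
not symmetrized), 48 physicochemical group fractions with the raw length
appended, giving six sequence feature-sets. Haralick statistics use base-2
logarithms with 0·log 0 = 0; correlation is defined as 0 when a marginal is
degenerate; sum variance is taken about the sum average; "information
measure of correlation" is the first measure, IMC1 = (H − HXY1)/max(HX, HY).

The 48-group property table shipped as
`data/property_groups48_synthetic.tsv` is a constructed stand-in assembled
from standard residue classification schemes (hydrophobicity, volume,
polarity, polarizability, charge, secondary-structure and accessibility
triples plus classic binary groups); the original 48-property list is not
publicly tabulated. Only the aromatic group (H, F, W, Y) is definitional.
Any table in the same TSV dialect can be substituted.

Annotation encodings: binary domain presence over the vocabulary; a
repeated domain is two *adjacent* entries of the ordered domain list from
the same family (family map defaults to identity); GO membership vectors
are taken per declared level with no graph traversal — levels are whatever
the input table declares. Disorder is summarized by four scalars (fraction
of residues disordered, number of regions, longest region, mean region
length); the choice of scalars is this package's definition, since the
upstream description does not enumerate them.

PSSM profiles are stored positions × residue-types (L×20), the natural
orientation of PSI-BLAST ASCII files. PSSM-20 is the column mean of the
percentage block rescaled to fractions (softmax of mean scores as a flagged
fallback when the block is absent). PSSM-400 averages the 20-dim score rows
within each residue type of the query sequence, concatenates the 20 blocks
in canonical order and squashes elementwise through the logistic function;
absent residue types give a uniform 0.5 block. This is the standard PSSM-400
construction in the protein-localization literature; the aggregation is not
specified upstream.

## Supervised PCA

"Supervised PCA" is implemented as screen-then-project: features are ranked
by the one-way ANOVA F statistic of the four classes, the top
`screen_fraction` (default 0.5, never fewer than `n_components`) are kept,
standardized to zero mean / unit variance (constant features dropped), and
the leading principal components (default 3) of the screened block are
retained. ANOVA-F screening is the natural multiclass analogue of the
univariate-regression screening in the supervised-PCA literature; the exact
upstream variant is unspecified. `screen_fraction = 1` gives ordinary PCA
for comparison runs. Component signs are fixed (largest-magnitude loading
entry positive) so refits are bit-identical.

## Classifiers

* **Gaussian Bayes** — per-class sample mean and maximum-likelihood
  covariance plus a ridge of 1e-6 × (mean covariance diagonal); classes
  with fewer samples than dimension + 1 get a 1e-3 ridge and a warning.
  The ML (rather than unbiased) covariance is used so that the mixture
  model restricted to one component reproduces Gaussian-Bayes predictions
  exactly.
* **Mixture-density Bayes (MDM)** — per class, EM via scikit-learn
  `GaussianMixture` (full covariance, k-means++ initialization from the
  seed, `reg_covar` equal to the Gaussian ridge), driven one step at a time
  so the total log-likelihood trace is recorded; convergence at relative
  change ≤ 1e-6 or 500 iterations. The component count per class (1 to
  `max_components`, default 3) is chosen by 5-fold cross-validated held-out
  log-likelihood; candidate counts whose EM fails on a fold are pruned with
  a warning.
* **KNN** — Euclidean distances, majority vote among k neighbours, k chosen
  by cross-validation over {1, 3, 5, 7, 9} when not fixed. Implemented
  directly (distance matrix + stable sort) because the tie-break rules are
  part of the contract.
* **Posteriors** are computed in the log domain and normalized with
  log-sum-exp, so extreme points yield valid posteriors rather than NaN.

The minimum-risk rule picks argmin_j Σ_i L[i, j] P(i|x). The default cost
matrix (rows = true class, columns = predicted) charges 0.9 for predicting
NH/IC on a true hub and 0.1–0.2 otherwise. With this orientation a uniform
posterior already resolves to a hub class, which is the intended behaviour:
the rule exists to counteract class imbalance by making hub misses
expensive. Relative to MAP it can only move decisions toward the hub
classes, never away (a property the tests assert on random posteriors).
Class priors remain training frequencies; imbalance is handled through the
risk, not prior reweighting.

## Pipeline

Stratified 70/30 train/test split (per-class sampling without replacement,
round(fraction × class size) per class), 5-fold stratified CV inside the
training portion. Each feature-set's reduction is fitted on training rows
only; the fused input is the concatenation of the per-set 3-dim reductions.

Greedy forward fusion ranks reduced sets by standalone pooled-CV average
CCR, then walks the ranking: a candidate set is appended and kept only if
both the CV average CCR and the label correlation strictly improve;
rejected candidates are dropped and the walk continues until every
candidate has been considered. Fusion metrics are computed on CV, not on
the test portion, to avoid leakage; whether the original procedure used CV
or test metrics is not stated upstream. When CV predictions collapse to a
single class the correlation is undefined and treated as worse than any
finite value. The fold count is capped at the smallest class size so rare
classes appear in every partition.

Label correlation is the Pearson correlation of the integer codings
(1 = NH … 4 = DH) × 100; the upstream statistic is not named, and Pearson
on this coding reproduces its qualitative behaviour. Average CCR is the
unweighted mean of per-class recalls and depends only on the row-normalized
confusion matrix. One-vs-rest metrics are also computed for the merged
PH+DH super-class (hub classes collapsed before binarization, so a party
hub predicted as date hub still counts as a found hub). ROC AUC uses the
midrank (Mann–Whitney) formulation. Reports print percentages to one
decimal; internal computation keeps full precision.

## Synthetic data generator

The generator emulates the statistical structure the classifier assumes,
with the yeast class mix (81.4 / 9.8 / 3.3 / 5.5% for NH / IC / PH / DH) as
the default target. Labels are drawn from the mix; degrees then come from a
Zipf law (exponent 2.5) truncated to the label's degree band, and hub
average co-expression from the correct side of the 0.5 threshold (party
hubs Beta-skewed high, date hubs low), so role assignment — a pure function
of (degree, avgPCC, thresholds) — reproduces the labels exactly.
`generate_degrees` alone draws from the untruncated Zipf law.

Per class, every generator parameter is `base + effect_size × delta`:
residue composition, domain usage, GO-term usage (three aspects × two
levels, vocabulary sizes 19/8/15 and 65/33/60), mean domain count (hubs
multi-domain: 1.0 vs 4.5 at default effect), repeated-domain probability
(hubs ≈ 0.5 vs 0.04), and disordered fraction (date hubs most disordered,
≈ 0.42 vs 0.06). Distribution tilts are convex blends toward per-class
Dirichlet directions with per-family weights chosen so the feature families
rank as they do on real data — domain content strongest, sequence
compositions weak, Haralick/physicochemical near chance. Sequences are
log-normal in length (median 450, σ = 0.45), residues drawn from a
per-protein Dirichlet (concentration 100) around the class composition.
The emulated PSI-BLAST profile blends each position's residue with the
protein's own composition plus Dirichlet noise, so class information enters
the profile only through the protein level — otherwise PSSM features become
a label oracle. Disordered fractions get protein-level Beta spread (ν = 10)
for the same reason.

At `effect_size = 0` all classes collapse onto one distribution and the
pipeline stays at chance (average CCR ≈ 25%). At the default
`effect_size = 1` ("strong effects", documented in
`data/strong_effects_config.yaml`) the full pipeline reaches a seed-averaged
held-out average CCR in the mid-60s with merged-hub sensitivity around
75–85% at n = 2000 — comfortably above chance, with intermediately
connected proteins the hardest class, as on real data.

What the generator does *not* emulate: real interactome motif structure,
a true GO graph (levels are flat codes), evolutionary conservation,
correlated annotations between interacting proteins, and annotation
noise/missingness. Passing the synthetic benchmarks therefore shows the
pipeline recovers planted class-conditional structure under realistic
imbalance and noise — not that it would reach the same numbers on a real
proteome.

## Problem sizes and numerical choices

The synthetic benchmarks run at n = 2000 proteins with three replicate
seeds, the scale at which the rarest class (party hubs, 3.3%) still gives
a few dozen training samples for a 4×4-class Gaussian fit in the fused
3k-dimensional space. Ridge terms keep all covariances positive definite;
EM uses the same regularization; all randomness flows from a single seed
per run, and repeated runs are byte-identical.

## Known limitations

* The IC class is intrinsically hard (it borders NH in every feature) and
  dominates the residual error, mirroring the real-data behaviour.
* With dozens of proteins or fewer, per-class Gaussian fits rest on heavy
  ridging; results at such sizes are qualitative only.
* The greedy fusion is a single forward pass; it does not revisit rejected
  sets after later acceptances and does not guarantee the globally best
  subset.
* GO levels are taken from the input table as given; no term-level
  inference or graph traversal is performed.
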