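"""Orchestration: feature extraction, stratified splitting, cross-validated
greedy feature-set fusion, and the end-to-end experiment.

The experiment follows the published protocol: stratified 70/30
train/test split, each feature-set reduced to three combined features by
supervised PCA fitted on the training portion only, greedy forward fusion
of reduced feature-sets (a candidate set is kept only if it strictly
improves both the cross-validated average CCR and the label correlation),
then a final classifier trained on the fused training features and
evaluated once on the held-out 30%.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import annotation_features as af
from . import sequence_features as sf
from .classifiers import (
    CostMatrix,
    class_posteriors,
    fit_gaussian_bayes,
    fit_knn,
    fit_mdm_bayes,
    min_risk_decide,
    decide_map,
)
from .evaluation import EvaluationReport, evaluate
from .io_formats import FeatureSet, ProteinRecord, read_annotations, read_fasta, read_labels, read_pssm, read_vocabulary
from .reduction import ReductionModel, fit_supervised_pca, transform
from .synthetic_data import GO_LEVELS

logger = logging.getLogger("pinhub")

__all__ = [
    "FeatureCollection",
    "ExperimentConfig",
    "extract_features",
    "load_dataset",
    "stratified_split",
    "kfold_cv",
    "greedy_forward_fusion",
    "run_experiment",
]


@dataclass
class FeatureCollection:
    """Ordered, row-aligned named feature-sets X1..Xn for one protein list."""

    sets: list[FeatureSet]

    def __post_init__(self) -> None:
        ids = self.sets[0].protein_ids if self.sets else []
        for fs in self.sets:
            if fs.protein_ids != ids:
                raise ValueError(
                    f"feature set {fs.name!r} is not row-aligned with the collection"
                )

    @property
    def names(self) -> list[str]:
        return [fs.name for fs in self.sets]

    @property
    def protein_ids(self) -> list[str]:
        return self.sets[0].protein_ids if self.sets else []

    def get(self, name: str) -> FeatureSet:
        for fs in self.sets:
            if fs.name == name:
                return fs
        raise KeyError(name)

    def subset_rows(self, indices: np.ndarray) -> "FeatureCollection":
        ids = [self.protein_ids[i] for i in indices]
        return FeatureCollection([
            FeatureSet(fs.name, ids, fs.feature_names, fs.values[indices])
            for fs in self.sets
        ])


@dataclass
class ExperimentConfig:
    """All knobs of one experiment; every random draw derives from ``seed``."""

    seed: int = 0
    train_fraction: float = 0.70
    folds: int = 5
    classifier: str = "gauss"         # gauss | mdm | knn
    knn_k: int | None = None          # None -> choose by CV over {1,3,5,7,9}
    max_components: int = 3           # MDM per-class ceiling
    min_risk: bool = False
    cost_matrix_path: str | None = None  # None -> packaged default when min_risk
    n_components: int = 3
    screen_fraction: float = 0.5
    fusion: bool = True
    feature_sets: list[str] | None = None  # None -> all extracted sets

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train fraction must be in (0, 1)")
        if self.folds < 2:
            raise ValueError("need at least 2 CV folds")
        if self.classifier not in ("gauss", "mdm", "knn"):
            raise ValueError(f"unknown classifier {self.classifier!r}")

    def cost_matrix(self) -> CostMatrix:
        return CostMatrix.from_tsv(self.cost_matrix_path)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def load_dataset(data_dir: str | Path) -> tuple[list[ProteinRecord], dict[str, int]]:
    """Load a dataset directory written by :mod:`pinhub.synthetic_data`."""
    data_dir = Path(data_dir)
    records = read_fasta(data_dir / "proteins.fasta")
    labels = read_labels(data_dir / "labels.tsv")
    annotations = read_annotations(
        domains_path=data_dir / "domains.tsv",
        go_path=data_dir / "go.tsv",
        disorder_path=data_dir / "disorder.tsv",
    )
    pssm_dir = data_dir / "pssm"
    for rec in records:
        if rec.id in annotations:
            ann = annotations[rec.id]
            rec.annotations.domains = ann.domains
            rec.annotations.go = ann.go
            rec.annotations.disorder = ann.disorder
        pssm_path = pssm_dir / f"{rec.id}.pssm"
        if pssm_path.exists():
            rec.annotations.pssm = read_pssm(pssm_path)
    return records, labels


def extract_features(
    records: list[ProteinRecord],
    domain_vocab: list[str] | None = None,
    go_vocabs: dict[int, list[str]] | None = None,
    property_table: sf.PropertyTable | None = None,
    haralick_gap: int = 1,
    gap_counts: tuple[int, ...] = (1, 2),
) -> FeatureCollection:
    """Compute the seventeen per-protein feature-sets of the study.

    Six sequence encodings (AAC, dipeptides, one pair-composition per gap
    count, Haralick statistics of the gap-``haralick_gap`` co-occurrence
    matrix, 48 physicochemical fractions with the raw length appended), six
    GO membership sets, domain and repeated-domain vectors, disorder
    summaries, and PSSM-20 / PSSM-400.  Vocabularies default to the sorted
    union observed in ``records``.
    """
    ids = [rec.id for rec in records]
    table = property_table or sf.load_property_table()

    if domain_vocab is None:
        seen: set[str] = set()
        for rec in records:
            if rec.annotations.domains:
                seen.update(rec.annotations.domains.domains)
        domain_vocab = sorted(seen)
    if go_vocabs is None:
        go_vocabs = {}
        for rec in records:
            if rec.annotations.go:
                for level, terms in rec.annotations.go.terms_by_level.items():
                    go_vocabs.setdefault(level, set()).update(terms)
        go_vocabs = {lvl: sorted(terms) for lvl, terms in go_vocabs.items()}

    sets: list[FeatureSet] = []

    def add(name: str, feature_names: list[str], rows: list[np.ndarray]) -> None:
        sets.append(FeatureSet(name, ids, feature_names, np.vstack(rows)))

    add("aac", [f"aac_{a}" for a in sf.AMINO_ACIDS],
        [sf.aac(r.sequence) for r in records])
    add("dipeptides", sf.pair_feature_names("dp_"),
        [sf.dipeptide_comp(r.sequence) for r in records])
    for k in gap_counts:
        add(f"pairs_{k}gap", sf.pair_feature_names(f"g{k}_"),
            [sf.gapped_pair_comp(r.sequence, k) for r in records])
    add("haralick", list(sf.HARALICK_NAMES),
        [sf.haralick_features(sf.cooccurrence_matrix(r.sequence, haralick_gap))
         for r in records])
    add("physicochemical", list(table.names) + ["length"],
        [np.concatenate([sf.physicochemical_comp(r.sequence, table),
                         sf.length_feature(r.sequence)]) for r in records])

    for level in sorted(go_vocabs):
        vocab = go_vocabs[level]
        name = GO_LEVELS[level][0] if level in GO_LEVELS else f"go_l{level}"
        add(f"go_{name}", list(vocab),
            [af.go_level_vector(r.annotations.go, level, vocab) for r in records])

    add("domains", list(domain_vocab),
        [af.domain_vector(r.annotations.domains, domain_vocab, lenient=True)
         for r in records])
    add("repeated_domains", [f"rep_{d}" for d in domain_vocab],
        [af.repeated_domain_vector(r.annotations.domains, domain_vocab, lenient=True)
         for r in records])
    add("disorder", list(af.DISORDER_FEATURE_NAMES),
        [af.disorder_features(r.annotations.disorder, len(r.sequence))
         for r in records])

    if all(r.annotations.pssm is not None for r in records):
        add("pssm20", [f"p20_{a}" for a in sf.AMINO_ACIDS],
            [af.pssm20(r.annotations.pssm) for r in records])
        add("pssm400", sf.pair_feature_names("p400_"),
            [af.pssm400(r.annotations.pssm) for r in records])
    return FeatureCollection(sets)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def stratified_split(
    labels: np.ndarray, train_fraction: float = 0.70, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split; each class contributes round(fraction x size)
    training samples.  Deterministic given the seed."""
    labels = np.asarray(labels)
    rng = np.random.default_rng([seed % (2**31), 303])
    train: list[int] = []
    test: list[int] = []
    for label in np.unique(labels):
        members = np.flatnonzero(labels == label)
        if len(members) < 2:
            raise ValueError(f"class {label} has fewer than 2 members")
        n_train = int(np.floor(train_fraction * len(members) + 0.5))
        n_train = min(max(n_train, 1), len(members) - 1)
        perm = rng.permutation(members)
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
    return np.sort(np.asarray(train)), np.sort(np.asarray(test))


def kfold_cv(
    train_ids: np.ndarray, labels: np.ndarray, folds: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partition of the training ids; each id validates once."""
    train_ids = np.asarray(train_ids)
    y = np.asarray(labels)[train_ids]
    counts = np.bincount(y)[np.unique(y)]
    if folds > counts.min():
        raise ValueError(
            f"{folds} folds exceed the smallest class size {counts.min()}"
        )
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    return [
        (train_ids[fit_idx], train_ids[val_idx])
        for fit_idx, val_idx in splitter.split(np.zeros(len(y)), y)
    ]


# ---------------------------------------------------------------------------
# Classifier dispatch
# ---------------------------------------------------------------------------

def _train(config: ExperimentConfig, X: np.ndarray, y: np.ndarray):
    if config.classifier == "gauss":
        return fit_gaussian_bayes(X, y)
    if config.classifier == "mdm":
        return fit_mdm_bayes(X, y, max_components=config.max_components,
                             seed=config.seed)
    k = config.knn_k if config.knn_k is not None else _choose_knn_k(config, X, y)
    return fit_knn(X, y, min(k, len(X)))


def _choose_knn_k(config: ExperimentConfig, X: np.ndarray, y: np.ndarray) -> int:
    """Pick the neighbourhood size by stratified CV over a small odd grid."""
    best_k, best_score = 1, -np.inf
    idx = np.arange(len(y))
    folds = kfold_cv(idx, y, folds=min(config.folds, np.bincount(y)[np.unique(y)].min()),
                     seed=config.seed)
    for k in (1, 3, 5, 7, 9):
        if k > min(len(fit) for fit, _ in folds):
            break
        correct = 0
        for fit_idx, val_idx in folds:
            model = fit_knn(X[fit_idx], y[fit_idx], k)
            pred = decide_map(class_posteriors(model, X[val_idx]))
            correct += int((pred == y[val_idx]).sum())
        if correct > best_score:
            best_score, best_k = correct, k
    return best_k


def _predict(config: ExperimentConfig, model, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    posteriors = class_posteriors(model, X)
    if config.min_risk:
        return min_risk_decide(posteriors, config.cost_matrix()), posteriors
    return decide_map(posteriors), posteriors


def _cv_metrics(
    config: ExperimentConfig, X: np.ndarray, y: np.ndarray
) -> tuple[float, float]:
    """Pooled cross-validated (average CCR, label correlation) on (X, y).

    The fold count is capped at the smallest class size so rare classes
    appear in every validation partition."""
    idx = np.arange(len(y))
    smallest = int(np.bincount(y)[np.unique(y)].min())
    folds = kfold_cv(idx, y, folds=min(config.folds, max(smallest, 2)),
                     seed=config.seed)
    predicted = np.empty(len(y), dtype=int)
    for fit_idx, val_idx in folds:
        model = _train(config, X[fit_idx], y[fit_idx])
        predicted[val_idx], _ = _predict(config, model, X[val_idx])
    from .evaluation import average_ccr, confusion_matrix, label_correlation

    ccr = average_ccr(confusion_matrix(y, predicted))
    try:
        corr = label_correlation(y, predicted)
    except ValueError:  # constant predictions: no discrimination at all
        corr = float("-inf")
    return ccr, corr


# ---------------------------------------------------------------------------
# Greedy forward fusion
# ---------------------------------------------------------------------------

def greedy_forward_fusion(
    reduced: dict[str, np.ndarray],
    y: np.ndarray,
    config: ExperimentConfig,
) -> tuple[list[str], list[dict]]:
    """Greedy forward selection over reduced feature-sets.

    Sets are ranked by standalone cross-validated average CCR; starting
    from the best one, each further candidate is appended in rank order and
    kept only if both the CV average CCR and the label correlation strictly
    improve; a rejected candidate is dropped and the next one tried, until
    every candidate has been considered.  The trace records every trial's
    metrics.
    """
    if not reduced:
        raise ValueError("empty feature collection")
    y = np.asarray(y)
    trace: list[dict] = []

    def _corr_out(corr: float) -> float | None:
        return corr if np.isfinite(corr) else None

    standalone: dict[str, tuple[float, float]] = {}
    for name, X in reduced.items():
        ccr, corr = _cv_metrics(config, X, y)
        standalone[name] = (ccr, corr)
        trace.append({"stage": "standalone", "sets": [name],
                      "cv_average_ccr": ccr, "cv_correlation": _corr_out(corr)})
    ranked = sorted(standalone, key=lambda n: (-standalone[n][0], n))

    selected = [ranked[0]]
    best_ccr, best_corr = standalone[ranked[0]]
    trace.append({"stage": "fusion", "sets": list(selected), "accepted": True,
                  "cv_average_ccr": best_ccr, "cv_correlation": _corr_out(best_corr)})
    for name in ranked[1:]:
        trial = selected + [name]
        X = np.hstack([reduced[s] for s in trial])
        ccr, corr = _cv_metrics(config, X, y)
        accepted = ccr > best_ccr and corr > best_corr
        trace.append({"stage": "fusion", "sets": list(trial), "accepted": accepted,
                      "cv_average_ccr": ccr, "cv_correlation": _corr_out(corr)})
        if accepted:
            selected = trial
            best_ccr, best_corr = ccr, corr
    return selected, trace


# ---------------------------------------------------------------------------
# Full experiment
# ---------------------------------------------------------------------------

def run_experiment(
    config: ExperimentConfig,
    data_dir: str | Path,
    out_dir: str | Path | None = None,
    collection: FeatureCollection | None = None,
    labels: dict[str, int] | None = None,
) -> tuple[EvaluationReport, dict]:
    """Extract -> split -> reduce -> (fuse) -> train -> test -> evaluate.

    ``collection``/``labels`` may be passed directly to skip re-reading the
    dataset directory.  Reduction, fusion and training see only training
    rows; the test portion enters exactly once, for the final prediction.
    Returns the evaluation report and an artifact dictionary; artifacts are
    also written under ``out_dir`` when given.
    """
    t0 = time.time()
    if collection is None or labels is None:
        logger.info("loading dataset from %s", data_dir)
        records, labels = load_dataset(data_dir)
        collection = extract_features(records)
    if config.feature_sets is not None:
        collection = FeatureCollection(
            [collection.get(name) for name in config.feature_sets]
        )
    ids = collection.protein_ids
    missing = [pid for pid in ids if pid not in labels]
    if missing:
        raise ValueError(f"{len(missing)} proteins have no label (first: {missing[0]})")
    y = np.array([labels[pid] for pid in ids])

    train_idx, test_idx = stratified_split(y, config.train_fraction, config.seed)
    y_train, y_test = y[train_idx], y[test_idx]
    logger.info("split: %d train / %d test", len(train_idx), len(test_idx))

    models: dict[str, ReductionModel] = {}
    reduced_train: dict[str, np.ndarray] = {}
    reduced_test: dict[str, np.ndarray] = {}
    for fs in collection.sets:
        model = fit_supervised_pca(
            FeatureSet(fs.name, [ids[i] for i in train_idx], fs.feature_names,
                       fs.values[train_idx]),
            y_train,
            n_components=config.n_components,
            screen_fraction=config.screen_fraction,
        )
        models[fs.name] = model
        reduced_train[fs.name] = transform(model, fs.values[train_idx])
        reduced_test[fs.name] = transform(model, fs.values[test_idx])
    logger.info("reduced %d feature-sets to %d components each",
                len(models), config.n_components)

    if config.fusion and len(reduced_train) > 1:
        selected, trace = greedy_forward_fusion(reduced_train, y_train, config)
    else:
        selected, trace = list(reduced_train), []
    logger.info("selected feature-sets: %s", ", ".join(selected))

    X_train = np.hstack([reduced_train[s] for s in selected])
    X_test = np.hstack([reduced_test[s] for s in selected])
    classifier = _train(config, X_train, y_train)
    predicted, posteriors = _predict(config, classifier, X_test)
    report = evaluate(y_test, predicted, scores=posteriors)
    logger.info("test average CCR %.1f%%, correlation %.1f%% (%.1f s)",
                report.average_ccr, report.correlation, time.time() - t0)

    artifacts = {
        "selected_sets": selected,
        "fusion_trace": trace,
        "train_ids": [ids[i] for i in train_idx],
        "test_ids": [ids[i] for i in test_idx],
        "predictions": {ids[i]: int(p) for i, p in zip(test_idx, predicted)},
        "reduction_models": models,
        "classifier": classifier,
        "config": asdict(config),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_json(out_dir / "report.json")
        report.to_tsv(out_dir / "report.tsv")
        with open(out_dir / "predictions.tsv", "w") as fh:
            for pid, label in artifacts["predictions"].items():
                fh.write(f"{pid}\t{label}\n")
        (out_dir / "fusion_trace.json").write_text(json.dumps(trace, indent=2))
        (out_dir / "config.json").write_text(json.dumps(asdict(config), indent=2))
        for name, model in models.items():
            model.to_json(out_dir / f"reduction_{name}.json")
        if hasattr(classifier, "to_json"):
            classifier.to_json(out_dir / "classifier.json")
    return report, artifacts
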