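"""Supervised PCA: label-informed screening followed by PCA.

Each raw feature-set is reduced to a small number of combined features
(three by default) before classification.  "Supervised" follows the
screen-then-project recipe: rank features by a one-way ANOVA F statistic
across the four classes, keep the top fraction, standardize the survivors,
and take principal components of the screened block.  With
``screen_fraction=1`` the screening is a no-op and the model is ordinary
PCA on standardized features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA
from sklearn.feature_selection import f_classif

from .io_formats import FeatureSet

__all__ = ["ReductionModel", "fit_supervised_pca", "transform"]


@dataclass
class ReductionModel:
    """Fitted screen-then-PCA reduction for one feature-set."""

    n_features_in: int
    selected: np.ndarray          # indices of screening survivors (after variance filter)
    center: np.ndarray            # per-selected-feature mean
    scale: np.ndarray             # per-selected-feature std (unit where zero)
    loadings: np.ndarray          # (n_selected, n_components)
    explained_variance: np.ndarray
    screening_scores: np.ndarray  # ANOVA F per original feature (nan where undefined)
    feature_set_name: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_features_in": self.n_features_in,
            "selected": self.selected.tolist(),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "screening_scores": self.screening_scores.tolist(),
            "feature_set_name": self.feature_set_name,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReductionModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            n_features_in=payload["n_features_in"],
            selected=np.asarray(payload["selected"], dtype=int),
            center=np.asarray(payload["center"]),
            scale=np.asarray(payload["scale"]),
            loadings=np.asarray(payload["loadings"]),
            explained_variance=np.asarray(payload["explained_variance"]),
            screening_scores=np.asarray(payload["screening_scores"]),
            feature_set_name=payload.get("feature_set_name", ""),
            metadata=payload.get("metadata", {}),
        )


def fit_supervised_pca(
    X: FeatureSet | np.ndarray,
    y: np.ndarray,
    n_components: int = 3,
    screen_fraction: float = 0.5,
) -> ReductionModel:
    """Fit the screen-then-PCA reduction.

    Features are ranked by the one-way ANOVA F statistic of the class
    labels; the top ``screen_fraction`` (never fewer than ``n_components``)
    are kept, standardized, and projected onto their leading principal
    components.  Constant features are dropped before projection.  The fit
    is deterministic; each loading's sign is fixed so its largest-magnitude
    entry is positive.
    """
    name = X.name if isinstance(X, FeatureSet) else ""
    values = X.values if isinstance(X, FeatureSet) else np.asarray(X, dtype=float)
    y = np.asarray(y)
    if values.ndim != 2:
        raise ValueError("X must be 2-D")
    if len(values) != len(y):
        raise ValueError("X and y length mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("supervised PCA needs >= 2 classes")
    if not 0 < screen_fraction <= 1:
        raise ValueError("screen_fraction must be in (0, 1]")

    n, p = values.shape
    variances = values.var(axis=0)
    nonconstant = np.flatnonzero(variances > 0)
    if len(nonconstant) == 0:
        raise ValueError("all features are constant")

    scores = np.full(p, np.nan)
    f_stat, _ = f_classif(values[:, nonconstant], y)
    scores[nonconstant] = np.nan_to_num(f_stat, nan=0.0, posinf=np.finfo(float).max)

    n_keep = max(n_components, int(np.ceil(screen_fraction * len(nonconstant))))
    n_keep = min(n_keep, len(nonconstant))
    if n_keep < n_components:
        raise ValueError(
            f"only {n_keep} usable features, need >= {n_components} components"
        )
    # stable rank: descending score, ties by original index
    order = nonconstant[np.lexsort((nonconstant, -scores[nonconstant]))]
    selected = np.sort(order[:n_keep])

    block = values[:, selected]
    center = block.mean(axis=0)
    scale = block.std(axis=0)
    scale[scale == 0] = 1.0
    standardized = (block - center) / scale

    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(standardized)
    loadings = pca.components_.T.copy()  # (n_selected, n_components)
    for j in range(loadings.shape[1]):
        peak = np.argmax(np.abs(loadings[:, j]))
        if loadings[peak, j] < 0:
            loadings[:, j] *= -1
    return ReductionModel(
        n_features_in=p,
        selected=selected,
        center=center,
        scale=scale,
        loadings=loadings,
        explained_variance=pca.explained_variance_.copy(),
        screening_scores=scores,
        feature_set_name=name,
        metadata={"screen_fraction": screen_fraction},
    )


def transform(model: ReductionModel, X: FeatureSet | np.ndarray) -> np.ndarray:
    """Apply a fitted reduction; rows align with the input."""
    values = X.values if isinstance(X, FeatureSet) else np.asarray(X, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    if values.shape[1] != model.n_features_in:
        raise ValueError(
            f"X has {values.shape[1]} features, model expects {model.n_features_in}"
        )
    block = (values[:, model.selected] - model.center) / model.scale
    return block @ model.loadings
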