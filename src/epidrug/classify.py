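"""Tumor/normal discrimination from DMEG features.

Features (region-mean methylation and/or log2 expression of DMEG genes)
are z-scaled on training statistics, projected onto the principal
components explaining a target fraction of training variance, and a
Fisher linear discriminant is fitted on the component scores. Performance
is reported as ROC AUC on a stratified held-out half.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import train_test_split


@dataclass
class ClassifierModel:
    """PCA + linear-discriminant diagnostic model."""

    features: list[str]
    center: np.ndarray          # per-feature training mean
    scale: np.ndarray           # per-feature training SD (zeros replaced by 1)
    components: np.ndarray      # (n_components, n_features) orthonormal loadings
    n_components: int
    weights: np.ndarray         # discriminant weights on component scores
    intercept: float
    positive_label: str = "tumor"

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        X = X.reindex(columns=self.features)
        if X.isna().any().any():
            missing = [f for f in self.features if f not in X.columns or X[f].isna().any()]
            raise ValueError(f"feature matrix missing model features: {missing[:5]}")
        z = (X.to_numpy(dtype=float) - self.center) / self.scale
        return z @ self.components.T

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        """Signed discriminant score; larger means more tumor-like."""
        return self.transform(X) @ self.weights + self.intercept

    def to_json(self, path) -> None:
        payload = {
            "features": self.features,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "components": self.components.tolist(),
            "n_components": self.n_components,
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "positive_label": self.positive_label,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            features=d["features"],
            center=np.asarray(d["center"]),
            scale=np.asarray(d["scale"]),
            components=np.asarray(d["components"]),
            n_components=d["n_components"],
            weights=np.asarray(d["weights"]),
            intercept=d["intercept"],
            positive_label=d["positive_label"],
        )


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def split_samples(
    sample_ids: Sequence[str],
    labels: Mapping[str, str],
    fraction: float = 0.5,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Stratified train/test split of sample ids (default 50/50)."""
    ids = list(sample_ids)
    y = [labels[s] for s in ids]
    counts = pd.Series(y).value_counts()
    if (counts < 2).any():
        raise ValueError(f"every class needs >= 2 samples for a stratified split: {counts.to_dict()}")
    train, test = train_test_split(
        ids, train_size=fraction, stratify=y, random_state=seed, shuffle=True
    )
    return sorted(train), sorted(test)


def fit_classifier(
    features: pd.DataFrame,
    labels: Mapping[str, str],
    n_components: int | None = None,
    variance_target: float = 0.90,
    positive_label: str = "tumor",
) -> ClassifierModel:
    """Fit the PCA + Fisher-discriminant model on training samples.

    Parameters
    ----------
    features
        Samples x features DataFrame (training samples only).
    labels
        sample id -> class label; ``positive_label`` marks the tumor class.
    n_components
        Components retained; default: smallest count explaining
        ``variance_target`` of the training variance.
    """
    X = features.to_numpy(dtype=float)
    y = np.array([labels[s] for s in features.index]) == positive_label
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need >= 2 training samples per class")
    max_comp = min(X.shape[1], X.shape[0] - 1)
    if n_components is not None and not (1 <= n_components <= max_comp):
        raise ValueError(f"n_components must be in [1, {max_comp}]")

    center = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    scale = np.where(sd > 0, sd, 1.0)
    Z = (X - center) / scale

    pca = PCA(n_components=max_comp, svd_solver="full").fit(Z)
    if n_components is None:
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_components = int(np.searchsorted(cum, variance_target) + 1)
        n_components = min(n_components, max_comp)
    components = pca.components_[:n_components]
    scores = Z @ components.T

    lda = LinearDiscriminantAnalysis(solver="svd").fit(scores, y.astype(int))
    return ClassifierModel(
        features=list(features.columns),
        center=center,
        scale=scale,
        components=components,
        n_components=n_components,
        weights=lda.coef_.ravel(),
        intercept=float(lda.intercept_[0]),
        positive_label=positive_label,
    )


def roc_auc(scores: Iterable[float], labels: Iterable[bool]) -> RocResult:
    """ROC curve and trapezoidal AUC; equals the tie-corrected concordance."""
    s = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(labels), dtype=bool)
    if y.all() or (~y).all():
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, thr = roc_curve(y.astype(int), s)
    return RocResult(thresholds=thr, tpr=tpr, fpr=fpr, auc=float(_trapezoid_auc(fpr, tpr)))


def evaluate_split(
    features: pd.DataFrame,
    labels: Mapping[str, str],
    fraction: float = 0.5,
    seed: int = 0,
    n_components: int | None = None,
) -> dict:
    """Convenience: split, fit on train, report train and held-out AUC."""
    train, test = split_samples(features.index, labels, fraction=fraction, seed=seed)
    model = fit_classifier(features.loc[train], labels, n_components=n_components)
    out = {}
    for name, ids in (("train", train), ("test", test)):
        sc = model.decision_scores(features.loc[ids])
        y = [labels[s] == model.positive_label for s in ids]
        out[f"auc_{name}"] = roc_auc(sc, y).auc
    out["model"] = model
    out["train_ids"], out["test_ids"] = train, test
    return out
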