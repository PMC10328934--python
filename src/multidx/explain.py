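"""Additive per-feature attributions for the per-label models.

For a linear (logistic-regression) label model the attribution of feature j
for instance x is ``w_j * x_j`` in the log-odds link, with the intercept as
base value — additive by construction. For a random-forest label model the
attribution is the exact tree-path decomposition: walking each decision
path, every split assigns to its feature the change in the node's
positive-class fraction, and the root fraction is the base value; summing
path contributions telescopes exactly to the tree's predicted probability,
and averaging over trees to the forest's. Attributions are computed on raw
(uncalibrated) scores: the isotonic calibrator is monotone, hence
rank-preserving, and additivity through a step function is ill-defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .model import LabelModel, ModelBundle

__all__ = ["AttributionResult", "attribute", "top_features"]


@dataclass
class AttributionResult:
    label_id: str
    feature_names: list[str]
    attributions: np.ndarray   # (n_instances, n_features)
    base_value: float
    link: str                  # "logit" (linear) or "probability" (forest)
    n_instances: int

    @property
    def mean_abs(self) -> np.ndarray:
        return np.abs(self.attributions).mean(axis=0)

    def scores(self) -> np.ndarray:
        """Reconstructed model output per instance: base + sum(attributions)."""
        return self.base_value + self.attributions.sum(axis=1)


def _linear_attributions(model: LabelModel, X: sp.spmatrix) -> tuple[np.ndarray, float]:
    clf: LogisticRegression = model.clf
    Xs = model.scaler.transform(X) if model.scaler is not None else X
    Xd = Xs.toarray() if sp.issparse(Xs) else np.asarray(Xs)
    phi = Xd * clf.coef_[0][None, :]
    return phi, float(clf.intercept_[0])


def _tree_attributions(tree, X: np.ndarray, phi: np.ndarray) -> float:
    """Accumulate one tree's path attributions into ``phi``; returns the
    root positive-class fraction (the tree's base value)."""
    t = tree.tree_
    value = t.value[:, 0, :]
    frac = value[:, 1] / value.sum(axis=1)
    left, right, feat, thr = t.children_left, t.children_right, t.feature, t.threshold
    for i in range(X.shape[0]):
        node = 0
        while left[node] != -1:
            f = feat[node]
            nxt = left[node] if X[i, f] <= thr[node] else right[node]
            phi[i, f] += frac[nxt] - frac[node]
            node = nxt
    return float(frac[0])


def attribute(bundle: ModelBundle, label: str, X: sp.spmatrix | np.ndarray) -> AttributionResult:
    """Additive attributions for every instance in ``X`` under one label's
    model. Raises for skipped (untrainable) labels."""
    if label not in bundle.models:
        raise KeyError(f"unknown label {label!r}")
    model = bundle.models[label]
    if model.skipped:
        raise ValueError(f"label {label!r} has no trained model (skipped)")
    Xcsr = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()

    if isinstance(model.clf, LogisticRegression):
        phi, base = _linear_attributions(model, Xcsr)
        link = "logit"
    elif isinstance(model.clf, RandomForestClassifier):
        Xd = Xcsr.toarray()
        phi = np.zeros_like(Xd, dtype=float)
        bases = []
        for est in model.clf.estimators_:
            tree_phi = np.zeros_like(phi)
            bases.append(_tree_attributions(est, Xd, tree_phi))
            phi += tree_phi
        phi /= len(model.clf.estimators_)
        base = float(np.mean(bases))
        link = "probability"
    else:  # pragma: no cover - only LR/RF are constructed by this package
        raise TypeError(f"unsupported classifier {type(model.clf).__name__}")

    return AttributionResult(
        label_id=label,
        feature_names=list(bundle.schema.names),
        attributions=phi,
        base_value=base,
        link=link,
        n_instances=Xcsr.shape[0],
    )


def top_features(result: AttributionResult, n: int) -> list[tuple[str, float]]:
    """Top-n features by mean absolute attribution, lexicographic tie-break."""
    if n < 0:
        raise ValueError("n must be >= 0")
    ma = result.mean_abs
    order = sorted(range(len(ma)), key=lambda i: (-ma[i], result.feature_names[i]))
    return [(result.feature_names[i], float(ma[i])) for i in order[:n]]
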