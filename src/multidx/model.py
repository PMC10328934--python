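"""Binary-relevance multi-label model with per-label undersampled pipelines
and cross-validated isotonic calibration.

One independent binary classifier is trained per label. Each label's
pipeline is: majority undersampling to a 1:1 positive-to-negative ratio,
then (for logistic regression) per-feature maximum-absolute scaling, then
the base classifier. Undersampling combats the severe class imbalance of
diagnosis labels and makes per-label training cheap; it also distorts the
score scale, which is repaired afterwards by isotonic calibration fitted on
out-of-fold scores from a stratified cross-validation that repeats the full
pipeline (undersampling included) within each fold.

Per-label randomness is derived deterministically from the master seed and
the label index, so training is reproducible and independent of label order
or parallel execution.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MaxAbsScaler

from .features import FeatureSchema

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "LabelModel",
    "ModelBundle",
    "undersample",
    "fit_label_model",
    "fit_multilabel",
    "calibrate",
    "fit_isotonic_calibrator",
    "predict_proba",
]


@dataclass(frozen=True)
class TrainConfig:
    base: str = "LR"                      # "LR" or "RF"
    lr_penalty: str = "l2"                # "l1" or "l2"
    lr_regularization_strength: float = 1.0  # lambda; C = 1/lambda
    rf_n_trees: int = 200
    rf_max_depth: int | None = None
    undersample_ratio: float = 1.0        # positives per negative target
    calibration_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base not in ("LR", "RF"):
            raise ValueError(f"base must be LR or RF, got {self.base!r}")
        if self.lr_penalty not in ("l1", "l2"):
            raise ValueError("lr_penalty must be l1 or l2")
        if self.lr_regularization_strength <= 0:
            raise ValueError("lr_regularization_strength must be > 0")
        if self.calibration_folds < 2:
            raise ValueError("calibration_folds must be >= 2")


def _label_seed(master: int, label_index: int) -> int:
    """Deterministic per-label seed, independent of training order."""
    return int((master * 1_000_003 + 7919 * (label_index + 1)) % (2**31 - 1))


def undersample(y: np.ndarray, seed: int) -> np.ndarray:
    """Row indices keeping all positives and an equal-sized uniform sample
    of negatives (without replacement). If negatives are already the
    minority, all rows are kept. Returned indices are sorted.
    """
    y = np.asarray(y).ravel()
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0:
        raise ValueError("cannot undersample a label with zero positives")
    if len(neg) <= len(pos):
        return np.arange(len(y))
    rng = np.random.default_rng(seed)
    sampled = rng.choice(neg, size=len(pos), replace=False)
    return np.sort(np.concatenate([pos, sampled]))


@dataclass
class LabelModel:
    label_id: str
    skipped: bool = False
    scaler: MaxAbsScaler | None = None
    clf: object | None = None
    calibrator: IsotonicRegression | None = None
    train_prevalence: float = 0.0
    calibration_folds_used: int | None = None

    def raw_scores(self, X: sp.spmatrix) -> np.ndarray:
        """Uncalibrated positive-class scores in [0, 1]."""
        if self.skipped:
            # zero-positive labels predict their training prevalence (zero)
            return np.full(X.shape[0], self.train_prevalence)
        Xp = self.scaler.transform(X) if self.scaler is not None else X
        return self.clf.predict_proba(Xp)[:, 1]

    def scores(self, X: sp.spmatrix) -> np.ndarray:
        raw = self.raw_scores(X)
        if self.calibrator is None or self.skipped:
            return raw
        return np.clip(self.calibrator.predict(raw), 0.0, 1.0)


@dataclass
class ModelBundle:
    label_ids: list[str]
    models: dict[str, LabelModel]
    schema: FeatureSchema
    config: TrainConfig
    provenance: dict = field(default_factory=dict)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "schema.json").write_text(json.dumps(
            {"names": self.schema.names, "modalities": self.schema.modalities,
             "units": self.schema.units, "hash": self.schema.hash()}))
        (out / "labels.json").write_text(json.dumps(self.label_ids))
        (out / "config.json").write_text(json.dumps(dataclasses.asdict(self.config)))
        (out / "provenance.json").write_text(json.dumps(self.provenance))
        for lid, m in self.models.items():
            joblib.dump(m, out / f"label_{lid}.joblib")

    @classmethod
    def load(cls, in_dir: str | Path) -> "ModelBundle":
        p = Path(in_dir)
        sch = json.loads((p / "schema.json").read_text())
        schema = FeatureSchema(sch["names"], sch["modalities"], sch.get("units", {}))
        label_ids = json.loads((p / "labels.json").read_text())
        config = TrainConfig(**json.loads((p / "config.json").read_text()))
        models = {lid: joblib.load(p / f"label_{lid}.joblib") for lid in label_ids}
        return cls(label_ids, models, schema, config,
                   json.loads((p / "provenance.json").read_text()))


def _make_classifier(config: TrainConfig, seed: int):
    if config.base == "LR":
        return LogisticRegression(
            l1_ratio=1.0 if config.lr_penalty == "l1" else 0.0,
            C=1.0 / config.lr_regularization_strength,
            solver="liblinear",
            max_iter=2000,
            random_state=seed,
        )
    return RandomForestClassifier(
        n_estimators=config.rf_n_trees,
        max_depth=config.rf_max_depth,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )


def fit_label_model(
    X: sp.spmatrix,
    y: np.ndarray,
    config: TrainConfig,
    label_id: str = "",
    seed: int | None = None,
) -> LabelModel:
    """Fit one label's pipeline: undersample, [max-abs scale,] classify.

    Labels with zero training positives are returned skipped; they predict
    zero (their training prevalence).
    """
    y = np.asarray(y).ravel()
    prev = float(y.mean()) if len(y) else 0.0
    if seed is None:
        seed = config.seed
    if y.sum() == 0 or y.sum() == len(y):
        logger.warning("label %s is single-class in training; skipped", label_id)
        return LabelModel(label_id, skipped=True, train_prevalence=prev)

    idx = undersample(y, seed)
    Xs, ys = X[idx], y[idx]
    scaler = None
    if config.base == "LR":
        scaler = MaxAbsScaler().fit(Xs)
        Xs = scaler.transform(Xs)
    clf = _make_classifier(config, seed)
    clf.fit(Xs, ys)
    return LabelModel(label_id, scaler=scaler, clf=clf, train_prevalence=prev)


def fit_multilabel(
    X: sp.spmatrix,
    Y: sp.spmatrix | np.ndarray,
    label_ids: list[str],
    schema: FeatureSchema,
    config: TrainConfig,
    n_jobs: int = 1,
) -> ModelBundle:
    """Independently fit one pipeline per label column of ``Y``."""
    Yd = Y.toarray() if sp.issparse(Y) else np.asarray(Y)
    if X.shape[0] != Yd.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but Y has {Yd.shape[0]}")
    if Yd.shape[1] != len(label_ids):
        raise ValueError("label_ids must match Y columns")

    def _fit(l: int) -> LabelModel:
        return fit_label_model(X, Yd[:, l], config, label_ids[l],
                               seed=_label_seed(config.seed, l))

    if n_jobs == 1:
        models = [_fit(l) for l in range(len(label_ids))]
    else:
        models = joblib.Parallel(n_jobs=n_jobs)(
            joblib.delayed(_fit)(l) for l in range(len(label_ids)))
    return ModelBundle(
        list(label_ids),
        {m.label_id: m for m in models},
        schema,
        config,
        provenance={"seed": config.seed, "n_train_rows": int(X.shape[0])},
    )


def fit_isotonic_calibrator(scores: np.ndarray, y: np.ndarray) -> IsotonicRegression:
    """Nondecreasing map from raw scores to outcome frequencies on [0, 1].

    When the scores already equal the true conditional probabilities the
    fitted map is close to the identity on the score support.
    """
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    iso.fit(np.asarray(scores, float).ravel(), np.asarray(y, float).ravel())
    return iso


def _cv_isotonic(
    X: sp.spmatrix, y: np.ndarray, config: TrainConfig, seed: int, label_id: str
) -> tuple[IsotonicRegression | None, int | None]:
    """Out-of-fold scores from refitting the full pipeline per fold, then an
    isotonic fit mapping score to outcome. Falls back to fewer folds (down
    to 2) when positives cannot stratify; below that, no calibrator.
    """
    n_pos = int(y.sum())
    folds = min(config.calibration_folds, n_pos)
    if folds < 2:
        logger.warning("label %s: too few positives (%d) to calibrate", label_id, n_pos)
        return None, None
    if folds < config.calibration_folds:
        logger.info("label %s: falling back to %d calibration folds", label_id, folds)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.empty(len(y))
    oof[:] = np.nan
    for k, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        m = fit_label_model(X[tr], y[tr], config, label_id, seed=seed + 101 * (k + 1))
        oof[te] = m.raw_scores(X[te]) if not m.skipped else 0.0
    return fit_isotonic_calibrator(oof, y), folds


def calibrate(bundle: ModelBundle, X: sp.spmatrix, Y: sp.spmatrix | np.ndarray) -> ModelBundle:
    """Attach per-label isotonic calibrators fitted on cross-validated
    out-of-fold scores over the training data. Returns the same bundle,
    modified in place, for chaining.
    """
    Yd = Y.toarray() if sp.issparse(Y) else np.asarray(Y)
    if X.shape[0] != Yd.shape[0]:
        raise ValueError("misaligned rows")
    for l, lid in enumerate(bundle.label_ids):
        m = bundle.models[lid]
        if m.skipped:
            continue
        iso, folds = _cv_isotonic(X, Yd[:, l], bundle.config,
                                  _label_seed(bundle.config.seed, l), lid)
        m.calibrator = iso
        m.calibration_folds_used = folds
    return bundle


def predict_proba(bundle: ModelBundle, fm_or_X, schema: FeatureSchema | None = None) -> np.ndarray:
    """Calibrated probability matrix (rows align to input, columns to
    ``bundle.label_ids``). Refuses inputs whose schema hash differs.
    """
    from .features import FeatureMatrix

    if isinstance(fm_or_X, FeatureMatrix):
        X, schema = fm_or_X.matrix, fm_or_X.schema
    else:
        X = fm_or_X
    if schema is not None and schema.hash() != bundle.schema.hash():
        ours, theirs = set(bundle.schema.names), set(schema.names)
        raise ValueError(
            "feature schema mismatch; missing="
            f"{sorted(ours - theirs)[:10]} extra={sorted(theirs - ours)[:10]}"
        )
    out = np.zeros((X.shape[0], len(bundle.label_ids)))
    for l, lid in enumerate(bundle.label_ids):
        out[:, l] = bundle.models[lid].scores(X)
    if not np.isfinite(out).all():
        raise AssertionError("non-finite prediction produced")
    return out
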