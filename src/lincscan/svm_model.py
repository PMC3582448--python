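"""Binary RBF-kernel SVM: grid search, cross-validation, training, scoring.

The positive class is "noncoding" (label 1), the negative class "coding"
(label 0).  Decision values are mapped to a calibrated non-coding score via a
Platt sigmoid fitted on out-of-fold decision values, so a score of ~0.95 means
roughly a 95% chance of being non-coding.  The trained artifact (scaler,
support vectors, dual coefficients, calibration, feature configuration) is
persisted as one versioned JSON file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import LincscanError, ModelVersionError, ParseError, ValidationError
from .feature_extraction import (
    FeatureConfig,
    FeatureTable,
    ScalerParams,
    apply_scaler,
    fit_scaler,
)

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = "1"
LABEL_NONCODING = "noncoding"
LABEL_CODING = "coding"

#: Conventional LIBSVM grid: C = 2^-5 .. 2^15, gamma = 2^-15 .. 2^3 (step 2^2).
DEFAULT_GRID_C = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GRID_GAMMA = tuple(2.0**e for e in range(-15, 4, 2))

SVC_TOL = 1e-3  # pinned solver tolerance


@dataclass(frozen=True)
class SVMParams:
    C: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.C > 0 and np.isfinite(self.C)):
            raise ValidationError(f"C must be positive and finite, got {self.C}")
        if not (self.gamma > 0 and np.isfinite(self.gamma)):
            raise ValidationError(f"gamma must be positive and finite, got {self.gamma}")


def default_grid() -> list[SVMParams]:
    return [SVMParams(C, g) for C in DEFAULT_GRID_C for g in DEFAULT_GRID_GAMMA]


@dataclass
class LabeledDataset:
    """Raw feature vectors with binary labels (1 = noncoding, 0 = coding)."""

    ids: list[str]
    names: tuple[str, ...]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if len(self.ids) != self.X.shape[0] or len(self.ids) != self.y.shape[0]:
            raise ValidationError("ids, X and y must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("transcript ids must be unique")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValidationError("labels must be 0 (coding) or 1 (noncoding)")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_tables(
        cls, positive: FeatureTable, negative: FeatureTable
    ) -> "LabeledDataset":
        if positive.names != negative.names:
            raise ValidationError(
                f"feature order mismatch between classes: "
                f"{positive.names} vs {negative.names}"
            )
        return cls(
            ids=list(positive.ids) + list(negative.ids),
            names=positive.names,
            X=np.vstack([positive.X, negative.X])
            if len(positive) and len(negative)
            else np.vstack(
                [
                    positive.X.reshape(len(positive), -1),
                    negative.X.reshape(len(negative), -1),
                ]
            ),
            y=np.concatenate(
                [np.ones(len(positive), dtype=int), np.zeros(len(negative), dtype=int)]
            ),
        )

    def subset(self, indices: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            ids=[self.ids[i] for i in indices],
            names=self.names,
            X=self.X[indices],
            y=self.y[indices],
        )


@dataclass(frozen=True)
class Prediction:
    transcript_id: str
    label: str
    noncoding_score: float


@dataclass
class TrainedModel:
    """Everything needed to reproduce predictions, in one serializable object."""

    feature_names: tuple[str, ...]
    feature_config: FeatureConfig | None
    scaler: ScalerParams
    params: SVMParams
    support_vectors: np.ndarray  # scaled space, shape (n_sv, d)
    dual_coef: np.ndarray  # shape (n_sv,)
    intercept: float
    platt_a: float
    platt_b: float
    version: str = MODEL_FORMAT_VERSION

    def decision_values(self, X_scaled: np.ndarray) -> np.ndarray:
        """RBF decision function; positive values favor the noncoding class."""
        X_scaled = np.atleast_2d(X_scaled)
        diff = X_scaled[:, None, :] - self.support_vectors[None, :, :]
        sq = np.einsum("ijk,ijk->ij", diff, diff)
        kernel = np.exp(-self.params.gamma * sq)
        return kernel @ self.dual_coef + self.intercept

    def noncoding_scores(self, X_scaled: np.ndarray) -> np.ndarray:
        d = self.decision_values(X_scaled)
        return sigmoid_score(d, self.platt_a, self.platt_b)


def sigmoid_score(decision: np.ndarray, a: float, b: float) -> np.ndarray:
    """Platt score 1 / (1 + exp(a*d + b)), computed overflow-safely."""
    f = a * np.asarray(decision, dtype=float) + b
    out = np.empty_like(f)
    pos = f >= 0
    out[pos] = np.exp(-f[pos]) / (1.0 + np.exp(-f[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(f[~pos]))
    return out


def _fit_svc(X_scaled: np.ndarray, y: np.ndarray, params: SVMParams) -> SVC:
    svc = SVC(C=params.C, gamma=params.gamma, kernel="rbf", tol=SVC_TOL)
    svc.fit(X_scaled, y)
    return svc


def _check_two_classes(y: np.ndarray, context: str) -> None:
    if len(np.unique(y)) < 2:
        raise ValidationError(f"{context}: both classes must be present")


def _stratified_accuracy(
    data: LabeledDataset, params: SVMParams, folds: int, seed: int
) -> list[float]:
    """Per-fold held-out accuracy; the scaler is refitted inside each fold."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accuracies = []
    for train_idx, test_idx in skf.split(data.X, data.y):
        scaler = fit_scaler(data.X[train_idx])
        svc = _fit_svc(apply_scaler(data.X[train_idx], scaler), data.y[train_idx], params)
        pred = svc.predict(apply_scaler(data.X[test_idx], scaler))
        accuracies.append(float(np.mean(pred == data.y[test_idx])))
    return accuracies


def grid_search(
    data: LabeledDataset,
    grid: list[SVMParams] | None = None,
    folds: int = 5,
    subsample_n: int = 5000,
    seed: int = 0,
) -> tuple[SVMParams, float]:
    """Pick (C, gamma) by stratified k-fold CV accuracy on a seeded subsample.

    Ties are broken toward smaller C, then smaller gamma.
    """
    if grid is None:
        grid = default_grid()
    if not grid:
        raise ValidationError("parameter grid is empty")
    if folds < 2:
        raise ValidationError("grid search needs folds >= 2")
    _check_two_classes(data.y, "grid search")
    n = len(data)
    if subsample_n < n:
        rng = np.random.default_rng(seed)
        indices = np.sort(rng.choice(n, size=subsample_n, replace=False))
        sub = data.subset(indices)
    else:
        sub = data
    counts = np.bincount(sub.y, minlength=2)
    if counts.min() < folds:
        raise ValidationError(
            f"a class has only {counts.min()} instances after subsampling; "
            "increase the subsample size or reduce folds"
        )
    best: tuple[SVMParams, float] | None = None
    for params in sorted(grid, key=lambda p: (p.C, p.gamma)):
        acc = float(np.mean(_stratified_accuracy(sub, params, folds, seed)))
        if best is None or acc > best[1]:
            best = (params, acc)
    assert best is not None
    logger.info(
        "grid search: best C=%g gamma=%g (cv accuracy %.4f, %d candidates)",
        best[0].C,
        best[0].gamma,
        best[1],
        len(grid),
    )
    return best


def cross_validate(
    data: LabeledDataset, params: SVMParams, folds: int = 10, seed: int = 0
) -> list[float]:
    """Stratified k-fold CV; returns per-fold held-out accuracies."""
    if folds < 2:
        raise ValidationError("cross-validation needs folds >= 2")
    _check_two_classes(data.y, "cross-validation")
    counts = np.bincount(data.y, minlength=2)
    if counts.min() < folds:
        raise ValidationError(
            f"smallest class has {counts.min()} members, fewer than {folds} folds"
        )
    return _stratified_accuracy(data, params, folds, seed)


def _fit_platt(decision: np.ndarray, y: np.ndarray, max_iter: int = 100) -> tuple[float, float]:
    """Newton fit of the Platt sigmoid P(noncoding|d) = 1/(1+exp(A d + B)).

    Standard robust formulation with prior-corrected targets; returns (A, B).
    """
    decision = np.asarray(decision, dtype=float)
    y = np.asarray(y, dtype=int)
    prior1 = int(np.sum(y == 1))
    prior0 = int(np.sum(y == 0))
    hi = (prior1 + 1.0) / (prior1 + 2.0)
    lo = 1.0 / (prior0 + 2.0)
    t = np.where(y == 1, hi, lo)
    a = 0.0
    b = float(np.log((prior0 + 1.0) / (prior1 + 1.0)))
    sigma = 1e-12
    min_step = 1e-10

    def objective(av: float, bv: float) -> float:
        f = decision * av + bv
        # t*f + log(1+exp(-f)), computed stably
        return float(
            np.sum(np.where(f >= 0, t * f + np.log1p(np.exp(-np.abs(f))),
                            (t - 1.0) * f + np.log1p(np.exp(-np.abs(f)))))
        )

    fval = objective(a, b)
    for _ in range(max_iter):
        f = decision * a + b
        p = sigmoid_score(decision, a, b)  # P(label 1)
        q = 1.0 - p
        d2 = p * q
        h11 = float(np.sum(decision * decision * d2)) + sigma
        h22 = float(np.sum(d2)) + sigma
        h21 = float(np.sum(decision * d2))
        d1 = t - p
        g1 = float(np.sum(decision * d1))
        g2 = float(np.sum(d1))
        if abs(g1) < 1e-5 and abs(g2) < 1e-5:
            break
        det = h11 * h22 - h21 * h21
        da = -(h22 * g1 - h21 * g2) / det
        db = -(-h21 * g1 + h11 * g2) / det
        gd = g1 * da + g2 * db
        step = 1.0
        while step >= min_step:
            new_a = a + step * da
            new_b = b + step * db
            new_f = objective(new_a, new_b)
            if new_f < fval + 1e-4 * step * gd:
                a, b, fval = new_a, new_b, new_f
                break
            step /= 2.0
        else:
            logger.warning("Platt fit: line search failed; keeping current params")
            break
    return a, b


def train(
    data: LabeledDataset,
    params: SVMParams,
    seed: int = 0,
    feature_config: FeatureConfig | None = None,
    calibration_folds: int = 5,
) -> TrainedModel:
    """Fit scaler + RBF-SVM and calibrate scores on out-of-fold decision values."""
    _check_two_classes(data.y, "training")
    if np.allclose(data.X, data.X[0]):
        raise ValidationError("all feature vectors are identical; cannot train")
    if feature_config is not None and tuple(data.names) != feature_config.feature_order:
        raise ValidationError(
            f"dataset feature order {tuple(data.names)} does not match "
            f"config order {feature_config.feature_order}"
        )
    scaler = fit_scaler(data.X)
    X_scaled = apply_scaler(data.X, scaler)
    svc = _fit_svc(X_scaled, data.y, params)

    # Out-of-fold decision values for calibration, so the sigmoid is not fit
    # on optimistic training-set margins.
    counts = np.bincount(data.y, minlength=2)
    folds = min(calibration_folds, int(counts.min()))
    if folds >= 2:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        oof = np.zeros(len(data))
        for train_idx, test_idx in skf.split(X_scaled, data.y):
            if len(np.unique(data.y[train_idx])) < 2:
                oof[test_idx] = svc.decision_function(X_scaled[test_idx])
                continue
            fold_svc = _fit_svc(X_scaled[train_idx], data.y[train_idx], params)
            oof[test_idx] = fold_svc.decision_function(X_scaled[test_idx])
        platt_a, platt_b = _fit_platt(oof, data.y)
    else:
        platt_a, platt_b = _fit_platt(svc.decision_function(X_scaled), data.y)
    if platt_a >= 0:
        logger.warning(
            "Platt slope is non-negative (%.4g); scores will not increase with "
            "the decision value — training data may be inseparable",
            platt_a,
        )
    return TrainedModel(
        feature_names=tuple(data.names),
        feature_config=feature_config,
        scaler=scaler,
        params=params,
        support_vectors=np.asarray(svc.support_vectors_, dtype=float),
        dual_coef=np.asarray(svc.dual_coef_[0], dtype=float),
        intercept=float(svc.intercept_[0]),
        platt_a=platt_a,
        platt_b=platt_b,
    )


def predict(
    model: TrainedModel,
    table: FeatureTable,
    threshold: float = 0.5,
) -> list[Prediction]:
    """Score raw feature vectors; label noncoding when score >= threshold."""
    if table.scaled:
        raise ValidationError("predict expects raw (unscaled) feature vectors")
    expected = model.feature_names
    if tuple(table.names) != expected:
        raise ValidationError(
            f"feature order mismatch: model expects {expected}, got {tuple(table.names)}"
        )
    if len(table) == 0:
        return []
    X_scaled = apply_scaler(table.X, model.scaler)
    scores = model.noncoding_scores(X_scaled)
    return [
        Prediction(
            transcript_id=tid,
            label=LABEL_NONCODING if score >= threshold else LABEL_CODING,
            noncoding_score=float(score),
        )
        for tid, score in zip(table.ids, scores)
    ]


def save_model(model: TrainedModel, path: str) -> None:
    """Persist the trained artifact as one versioned JSON file."""
    payload = {
        "format_version": model.version,
        "feature_names": list(model.feature_names),
        "feature_config": (
            model.feature_config.to_dict() if model.feature_config else None
        ),
        "scaler": {"mins": list(model.scaler.mins), "maxs": list(model.scaler.maxs)},
        "svm": {
            "C": model.params.C,
            "gamma": model.params.gamma,
            "support_vectors": model.support_vectors.tolist(),
            "dual_coef": model.dual_coef.tolist(),
            "intercept": model.intercept,
        },
        "calibration": {"a": model.platt_a, "b": model.platt_b},
        "labels": {"positive": LABEL_NONCODING, "negative": LABEL_CODING},
    }
    with open(path, "w") as handle:
        json.dump(payload, handle)
        handle.write("\n")


def load_model(path: str) -> TrainedModel:
    try:
        with open(path) as handle:
            payload = json.load(handle)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not a valid model file ({exc})") from None
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelVersionError(
            f"{path}: unsupported model format version {version!r} "
            f"(this build reads version {MODEL_FORMAT_VERSION!r})"
        )
    try:
        svm = payload["svm"]
        config_data = payload["feature_config"]
        return TrainedModel(
            feature_names=tuple(payload["feature_names"]),
            feature_config=(
                FeatureConfig.from_dict(config_data) if config_data else None
            ),
            scaler=ScalerParams(
                mins=tuple(payload["scaler"]["mins"]),
                maxs=tuple(payload["scaler"]["maxs"]),
            ),
            params=SVMParams(C=svm["C"], gamma=svm["gamma"]),
            support_vectors=np.asarray(svm["support_vectors"], dtype=float),
            dual_coef=np.asarray(svm["dual_coef"], dtype=float),
            intercept=float(svm["intercept"]),
            platt_a=float(payload["calibration"]["a"]),
            platt_b=float(payload["calibration"]["b"]),
            version=version,
        )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: truncated or malformed model file ({exc})") from None


def balance_dataset(
    positive: LabeledDataset,
    negative: LabeledDataset,
    seed: int = 0,
    n_per_class: int | None = None,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Subsample to a balanced training set; the remainder becomes a test pool.

    Returns ``(train, holdout)``; both classes are cut to the smaller class's
    size (or to ``n_per_class``), deterministically from ``seed``.
    """
    if len(positive) == 0 or len(negative) == 0:
        raise ValidationError("both classes must be non-empty")
    n = min(len(positive), len(negative)) if n_per_class is None else n_per_class
    if n <= 0:
        raise ValidationError(f"requested per-class size {n} must be positive")
    if n > min(len(positive), len(negative)):
        raise ValidationError(
            f"requested {n} per class but classes have "
            f"{len(positive)} and {len(negative)} members"
        )
    rng = np.random.default_rng(seed)
    pos_pick = np.sort(rng.choice(len(positive), size=n, replace=False))
    neg_pick = np.sort(rng.choice(len(negative), size=n, replace=False))
    pos_rest = np.setdiff1d(np.arange(len(positive)), pos_pick)
    neg_rest = np.setdiff1d(np.arange(len(negative)), neg_pick)

    train_pos = positive.subset(pos_pick)
    train_neg = negative.subset(neg_pick)
    merged = LabeledDataset(
        ids=train_pos.ids + train_neg.ids,
        names=positive.names,
        X=np.vstack([train_pos.X, train_neg.X]),
        y=np.concatenate([train_pos.y, train_neg.y]),
    )
    order = rng.permutation(len(merged))
    train = merged.subset(order)

    rest_pos = positive.subset(pos_rest)
    rest_neg = negative.subset(neg_rest)
    holdout = LabeledDataset(
        ids=rest_pos.ids + rest_neg.ids,
        names=positive.names,
        X=np.vstack([rest_pos.X, rest_neg.X])
        if len(rest_pos) + len(rest_neg)
        else np.empty((0, len(positive.names))),
        y=np.concatenate([rest_pos.y, rest_neg.y]),
    )
    return train, holdout
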