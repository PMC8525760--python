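"""Late fusion: whole-face pain call from the three region confidences.

Each whole-face scene yields a 9-vector — the ears, eyes and
mouth-and-nostrils softmax confidence triples concatenated in that fixed
order.  A small feed-forward perceptron (9 → 5 sigmoid → 3 linear) maps it
to three output scores; the predicted pain level is their argmax (ties to
the lowest index).  The hidden width 5, learning rate 0.3 and momentum 0.2
are the reference pipeline's final hyperparameters.

Training minimises mean squared error against one-hot targets by
full-batch gradient descent with momentum, and the classifier is evaluated
by stratified 10-fold cross-validation: per-fold confusion matrices and
metrics are retained, reported metrics are fold averages, a pooled
out-of-fold confusion matrix is kept for matrix reporting, and a final
model is refit on all records.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .evaluation import THREE_LEVEL_CLASSES, ConfusionMatrix, confusion_matrix, metrics_from_matrix
from .region_cnn import RegionPrediction

N_FEATURES = 9
FEATURE_COLUMNS = ("e0", "e1", "e2", "y0", "y1", "y2", "m0", "m1", "m2")


class FusionError(ValueError):
    """Raised for malformed fusion records or training inputs."""


@dataclass(frozen=True)
class FusionRecord:
    """Concatenated region confidences with the scene's true pain level."""

    features: np.ndarray
    true_label: int
    scene_id: str

    def __post_init__(self) -> None:
        feat = np.asarray(self.features, dtype=float)
        if feat.shape != (N_FEATURES,):
            raise FusionError(f"features must have length {N_FEATURES}, got {feat.shape}")
        for k, name in enumerate(("ears", "eyes", "mouth_nostrils")):
            block = feat[3 * k : 3 * k + 3]
            if (block < -1e-9).any() or abs(block.sum() - 1.0) > 1e-6:
                raise FusionError(f"{name} confidence block is not a probability vector: {block}")
        if self.true_label not in (0, 1, 2):
            raise FusionError(f"true_label must be 0, 1 or 2, got {self.true_label}")
        object.__setattr__(self, "features", feat)


@dataclass(frozen=True)
class FusionModelSpec:
    hidden_neurons: int = 5
    learning_rate: float = 0.3
    momentum: float = 0.2
    folds: int = 10
    epochs: int = 500

    def __post_init__(self) -> None:
        if min(self.hidden_neurons, self.folds, self.epochs) <= 0:
            raise FusionError("hidden_neurons, folds and epochs must be positive")


def assemble_features(
    ears: RegionPrediction | None,
    eyes: RegionPrediction | None,
    mouth_nostrils: RegionPrediction | None,
) -> np.ndarray:
    """Concatenate the three confidence vectors in fixed ears→eyes→mouth order."""
    preds = {"ears": ears, "eyes": eyes, "mouth_nostrils": mouth_nostrils}
    missing = [name for name, p in preds.items() if p is None]
    if missing:
        raise FusionError(f"missing region prediction(s): {', '.join(missing)}")
    return np.concatenate([preds[n].confidences for n in ("ears", "eyes", "mouth_nostrils")])


class FusionNet:
    """9 → 5 (sigmoid) → 3 (linear) perceptron trained by momentum descent."""

    def __init__(self, spec: FusionModelSpec, rng: np.random.Generator) -> None:
        h = spec.hidden_neurons
        self.spec = spec
        self.w1 = rng.uniform(-0.5, 0.5, size=(N_FEATURES, h))
        self.b1 = np.zeros(h)
        self.w2 = rng.uniform(-0.5, 0.5, size=(h, 3))
        self.b2 = np.zeros(3)
        self._vel = [np.zeros_like(p) for p in (self.w1, self.b1, self.w2, self.b2)]
        self.loss_history: list[float] = []

    def forward(self, X: np.ndarray) -> np.ndarray:
        self._X = X
        self._hidden = 1.0 / (1.0 + np.exp(-(X @ self.w1 + self.b1)))
        return self._hidden @ self.w2 + self.b2

    def fit(self, X: np.ndarray, y: np.ndarray) -> None:
        """Full-batch gradient descent on MSE to one-hot targets."""
        X = np.asarray(X, dtype=float)
        targets = np.eye(3)[np.asarray(y, dtype=int)]
        n = len(X)
        lr, mu = self.spec.learning_rate, self.spec.momentum
        for _ in range(self.spec.epochs):
            out = self.forward(X)
            err = out - targets
            self.loss_history.append(float((err**2).mean()))
            dout = 2.0 * err / (n * 3)
            dw2 = self._hidden.T @ dout
            db2 = dout.sum(axis=0)
            dhid = (dout @ self.w2.T) * self._hidden * (1 - self._hidden)
            dw1 = X.T @ dhid
            db1 = dhid.sum(axis=0)
            params = (self.w1, self.b1, self.w2, self.b2)
            for p, g, v in zip(params, (dw1, db1, dw2, db2), self._vel):
                v *= mu
                v -= lr * g
                p += v

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(X, dtype=float))


@dataclass
class FusionCVResult:
    """Cross-validated fusion classifier with per-fold and pooled metrics."""

    spec: FusionModelSpec
    model: FusionNet
    fold_matrices: list[ConfusionMatrix]
    fold_accuracies_pct: list[float]
    mean_accuracy_pct: float
    pooled_matrix: ConfusionMatrix
    fold_assignment: np.ndarray

    @property
    def pooled_accuracy_pct(self) -> float:
        return metrics_from_matrix(self.pooled_matrix).overall_accuracy_pct


def train_fusion(
    records: list[FusionRecord], spec: FusionModelSpec, seed: int
) -> FusionCVResult:
    """Stratified k-fold CV of the fusion perceptron, then a refit on all records."""
    if len(records) < spec.folds:
        raise FusionError(f"need at least {spec.folds} records, got {len(records)}")
    X = np.stack([r.features for r in records])
    y = np.array([r.true_label for r in records], dtype=int)
    counts = np.bincount(y, minlength=3)
    if (counts < spec.folds).any():
        raise FusionError(
            f"stratified {spec.folds}-fold CV needs ≥{spec.folds} records per class, got {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=int(seed) % (2**31))
    children = np.random.SeedSequence(seed).spawn(spec.folds + 1)

    fold_matrices, fold_acc = [], []
    oof_pred = np.empty_like(y)
    fold_assignment = np.empty_like(y)
    for f, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        net = FusionNet(spec, np.random.default_rng(children[f]))
        net.fit(X[train_idx], y[train_idx])
        pred = net.predict_scores(X[test_idx]).argmax(axis=1)
        oof_pred[test_idx] = pred
        fold_assignment[test_idx] = f
        cm = confusion_matrix(y[test_idx], pred, THREE_LEVEL_CLASSES)
        fold_matrices.append(cm)
        fold_acc.append(metrics_from_matrix(cm).overall_accuracy_pct)

    final = FusionNet(spec, np.random.default_rng(children[-1]))
    final.fit(X, y)
    pooled = confusion_matrix(y, oof_pred, THREE_LEVEL_CLASSES)
    return FusionCVResult(
        spec=spec,
        model=final,
        fold_matrices=fold_matrices,
        fold_accuracies_pct=fold_acc,
        mean_accuracy_pct=float(np.mean(fold_acc)),
        pooled_matrix=pooled,
        fold_assignment=fold_assignment,
    )


def predict_fusion(model: FusionNet, features: np.ndarray) -> tuple[int, np.ndarray]:
    """Pain level (argmax of the linear outputs, ties→lowest) + raw scores.

    The output head is linear, so the scores are not probabilities.
    """
    feat = np.asarray(features, dtype=float)
    if feat.shape != (N_FEATURES,):
        raise FusionError(f"feature vector must have length {N_FEATURES}, got {feat.shape}")
    scores = model.predict_scores(feat[None, :])[0]
    return int(np.argmax(scores)), scores


def records_to_frame(records: list[FusionRecord]) -> pd.DataFrame:
    rows = [
        {"scene_id": r.scene_id, **dict(zip(FEATURE_COLUMNS, r.features)), "true_label": r.true_label}
        for r in records
    ]
    return pd.DataFrame(rows, columns=["scene_id", *FEATURE_COLUMNS, "true_label"])


def records_from_frame(df: pd.DataFrame) -> list[FusionRecord]:
    return [
        FusionRecord(
            features=np.array([row[c] for c in FEATURE_COLUMNS], dtype=float),
            true_label=int(row["true_label"]),
            scene_id=str(row["scene_id"]),
        )
        for _, row in df.iterrows()
    ]


def write_records_csv(records: list[FusionRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False, lineterminator="\n")


def read_records_csv(path: str | Path) -> list[FusionRecord]:
    return records_from_frame(pd.read_csv(path))
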