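"""Region-specific convolutional pain classifiers.

One network per facial region, all sharing the same architecture:

    conv(60 kernels, 7×7, ReLU) → maxpool(2×2) → batchnorm →
    conv(32 kernels, 5×5, ReLU) → maxpool(2×2) → batchnorm →
    flatten → dense(500 or 1000, ReLU) → dense(3, softmax)

with per-region hyperparameters (input size, penultimate dense width,
epoch budget) given by :func:`RegionModelSpec.for_region`.  Convolutions
are unpadded with stride 1; pools have stride 2.  Inputs are grayscale by
default, resized bilinearly to the spec's input size and scaled to [0, 1].

Training runs ``replicates`` independent initialisations (the study trained
three models per region and kept one); each replicate minimises categorical
cross-entropy with a momentum-free adaptive optimizer (RMSProp, 1e-3),
monitors validation loss each epoch, stops early after ``patience`` epochs
without improvement (hard cap at the spec's epoch budget) and restores the
best epoch's weights.  The replicate with the highest validation accuracy
wins; ties go to the lowest index.  Every random choice flows from the one
seed passed in.

The test suite and the synthetic acceptance runs use a scaled-down variant
(32×32 input, 8/8 kernels, dense 32) via :func:`RegionModelSpec.scaled`;
the full-size specs remain the defaults for real use.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from scipy.ndimage import map_coordinates

from ._nn import (
    BatchNorm,
    Conv2D,
    Dense,
    Flatten,
    MaxPool2x2,
    Network,
    ReLU,
    RMSProp,
    softmax,
    softmax_cross_entropy,
)
from .dataset import REGIONS, DatasetManifest

N_CLASSES = 3


class RegionCNNError(ValueError):
    """Raised for invalid specs, architectures or untrained models."""


@dataclass(frozen=True)
class RegionModelSpec:
    """Architecture + training hyperparameters of one region classifier."""

    region: str
    input_size: tuple[int, int]  # (height, width)
    dense1: int
    epochs: int
    channels: int = 1
    conv1_filters: int = 60
    conv1_kernel: int = 7
    conv2_filters: int = 32
    conv2_kernel: int = 5
    pool: int = 2
    batch_size: int = 50
    replicates: int = 3
    learning_rate: float = 1e-3
    patience: int = 5

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise RegionCNNError(f"unknown region {self.region!r}")
        if min(self.epochs, self.batch_size, self.replicates, self.dense1) <= 0:
            raise RegionCNNError("epochs, batch_size, replicates, dense1 must be positive")
        if self.channels not in (1, 3):
            raise RegionCNNError("channels must be 1 or 3")

    @classmethod
    def for_region(cls, region: str) -> "RegionModelSpec":
        """The final per-region hyperparameters of the reference pipeline."""
        table = {
            "ears": dict(input_size=(200, 200), dense1=1000, epochs=20),
            "eyes": dict(input_size=(80, 80), dense1=500, epochs=30),
            "mouth_nostrils": dict(input_size=(120, 120), dense1=1000, epochs=30),
        }
        if region not in table:
            raise RegionCNNError(f"unknown region {region!r}")
        return cls(region=region, **table[region])

    @classmethod
    def scaled(cls, region: str, epochs: int = 12, replicates: int = 2) -> "RegionModelSpec":
        """Desk-scale variant for tests and synthetic benchmarks."""
        return cls(
            region=region,
            input_size=(32, 32),
            dense1=32,
            epochs=epochs,
            conv1_filters=8,
            conv2_filters=8,
            replicates=replicates,
        )

    def replace(self, **kw) -> "RegionModelSpec":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class LayerShape:
    name: str
    detail: str
    output_shape: tuple[int, ...]


def build_architecture(spec: RegionModelSpec) -> list[LayerShape]:
    """Layer sequence with every intermediate feature-map shape.

    Raises naming the first layer whose output dimension would be
    non-positive.
    """
    h, w = spec.input_size
    report: list[LayerShape] = [LayerShape("input", f"{spec.channels} channel(s)", (h, w, spec.channels))]

    def conv(name, h, w, k, f):
        oh, ow = h - k + 1, w - k + 1
        if oh <= 0 or ow <= 0:
            raise RegionCNNError(
                f"input too small: layer {name} ({k}×{k} valid conv) would output {oh}×{ow}"
            )
        return oh, ow, f

    h, w, c = conv("conv1", h, w, spec.conv1_kernel, spec.conv1_filters)
    report.append(LayerShape("conv1", f"{spec.conv1_filters} kernels {spec.conv1_kernel}×{spec.conv1_kernel}, ReLU", (h, w, c)))
    h, w = h // 2, w // 2
    if h <= 0 or w <= 0:
        raise RegionCNNError("input too small: pool1 output would be empty")
    report.append(LayerShape("pool1", "2×2 max, stride 2", (h, w, c)))
    report.append(LayerShape("bn1", "batch normalization", (h, w, c)))
    h, w, c = conv("conv2", h, w, spec.conv2_kernel, spec.conv2_filters)
    report.append(LayerShape("conv2", f"{spec.conv2_filters} kernels {spec.conv2_kernel}×{spec.conv2_kernel}, ReLU", (h, w, c)))
    h, w = h // 2, w // 2
    if h <= 0 or w <= 0:
        raise RegionCNNError("input too small: pool2 output would be empty")
    report.append(LayerShape("pool2", "2×2 max, stride 2", (h, w, c)))
    report.append(LayerShape("bn2", "batch normalization", (h, w, c)))
    flat = h * w * c
    report.append(LayerShape("flatten", "", (flat,)))
    report.append(LayerShape("dense1", f"{spec.dense1} neurons, ReLU", (spec.dense1,)))
    report.append(LayerShape("dense_out", "3 neurons, softmax", (N_CLASSES,)))
    return report


def _build_network(spec: RegionModelSpec, rng: np.random.Generator) -> Network:
    shapes = build_architecture(spec)
    flat = shapes[-3].output_shape[0]
    return Network(
        [
            Conv2D(spec.channels, spec.conv1_filters, spec.conv1_kernel, rng),
            ReLU(),
            MaxPool2x2(),
            BatchNorm(spec.conv1_filters),
            Conv2D(spec.conv1_filters, spec.conv2_filters, spec.conv2_kernel, rng),
            ReLU(),
            MaxPool2x2(),
            BatchNorm(spec.conv2_filters),
            Flatten(),
            Dense(flat, spec.dense1, rng),
            ReLU(),
            Dense(spec.dense1, N_CLASSES, rng),
        ]
    )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def _resize_bilinear(image: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize mapping output pixel centers onto input coordinates.

    Output center i maps to input coordinate (i + 0.5) * in/out - 0.5,
    clamped at the edges.
    """
    oh, ow = out_shape
    ih, iw = image.shape[:2]
    if (ih, iw) == (oh, ow):
        return image.astype(float)
    ys = (np.arange(oh) + 0.5) * ih / oh - 0.5
    xs = (np.arange(ow) + 0.5) * iw / ow - 0.5
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    return map_coordinates(image.astype(float), [yy, xx], order=1, mode="nearest")


def preprocess_image(image, spec: RegionModelSpec) -> np.ndarray:
    """Load/convert to the spec's channels, resize, scale to [0, 1].

    Returns (H, W, channels) float64.  Accepts a path, a PIL image or a
    numpy array.
    """
    if isinstance(image, (str, Path)):
        try:
            image = np.asarray(Image.open(image))
        except Exception as exc:
            raise RegionCNNError(f"cannot read image {image}: {exc}") from exc
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 3 and spec.channels == 1:
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim == 2 and spec.channels == 3:
        arr = np.repeat(arr[..., None], 3, axis=-1)
    if arr.ndim == 2:
        resized = _resize_bilinear(arr, spec.input_size)[..., None]
    else:
        resized = np.stack(
            [_resize_bilinear(arr[..., c], spec.input_size) for c in range(spec.channels)],
            axis=-1,
        )
    return resized / 255.0


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionPrediction:
    """Softmax confidences plus the recommended class (argmax, ties→lowest)."""

    confidences: np.ndarray
    recommended: int

    @classmethod
    def from_confidences(cls, conf: np.ndarray) -> "RegionPrediction":
        conf = np.asarray(conf, dtype=float)
        if conf.shape != (N_CLASSES,):
            raise RegionCNNError(f"confidence vector must have length 3, got {conf.shape}")
        if (conf < -1e-9).any() or abs(conf.sum() - 1.0) > 1e-6:
            raise RegionCNNError("confidences must be a probability vector")
        return cls(confidences=conf, recommended=int(np.argmax(conf)))


@dataclass
class TrainedRegionModel:
    spec: RegionModelSpec
    network: Network
    training_log: pd.DataFrame
    selected_replicate: int
    val_accuracy: float

    def predict_batch(self, images: np.ndarray) -> np.ndarray:
        """Softmax confidence rows for a (N, H, W, C) batch."""
        logits = self.network.forward(np.asarray(images, dtype=float), train=False)
        return softmax(logits)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "spec.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    **dataclasses.asdict(self.spec),
                    "selected_replicate": self.selected_replicate,
                    "val_accuracy": float(self.val_accuracy),
                },
                fh,
            )
        state = self.network.get_state()
        np.savez(out / "weights.npz", **{f"arr_{i}": a for i, a in enumerate(state)})
        self.training_log.to_csv(out / "training_log.csv", index=False, lineterminator="\n")

    @classmethod
    def load(cls, model_dir: str | Path) -> "TrainedRegionModel":
        model_dir = Path(model_dir)
        with open(model_dir / "spec.yaml") as fh:
            meta = yaml.safe_load(fh)
        selected = meta.pop("selected_replicate")
        val_acc = meta.pop("val_accuracy")
        meta["input_size"] = tuple(meta["input_size"])
        spec = RegionModelSpec(**meta)
        net = _build_network(spec, np.random.default_rng(0))
        with np.load(model_dir / "weights.npz") as z:
            state = [z[f"arr_{i}"] for i in range(len(z.files))]
        net.set_state(state)
        log = pd.read_csv(model_dir / "training_log.csv")
        return cls(spec, net, log, int(selected), float(val_acc))


def _evaluate(net: Network, X: np.ndarray, y: np.ndarray,
              batch: int = 100) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(X), batch):
        logits = net.forward(X[i : i + batch], train=False)
        loss, _ = softmax_cross_entropy(logits, y[i : i + batch])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i : i + batch]).sum())
    return float(np.sum(losses) / len(X)), correct / len(X)


def fit_region_model_arrays(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    spec: RegionModelSpec,
    seed: int,
) -> TrainedRegionModel:
    """Train ``spec.replicates`` networks on in-memory arrays, keep the best."""
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    y_val = np.asarray(y_val, dtype=int)
    if len(X_train) == 0:
        raise RegionCNNError("empty training set")
    missing = set(range(N_CLASSES)) - set(np.unique(y_train).tolist())
    warnings: list[str] = []
    if missing:
        warnings.append(f"classes absent from training data: {sorted(missing)}")

    children = np.random.SeedSequence(seed).spawn(spec.replicates)
    best: tuple[float, int] | None = None
    best_net, best_state = None, None
    logs = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        net = _build_network(spec, rng)
        opt = RMSProp(net, lr=spec.learning_rate)
        best_val_loss, best_epoch_state, since_improve = np.inf, None, 0
        for epoch in range(spec.epochs):
            order = rng.permutation(len(X_train))
            epoch_losses = []
            for i in range(0, len(order), spec.batch_size):
                idx = order[i : i + spec.batch_size]
                logits = net.forward(X_train[idx], train=True)
                loss, dlogits = softmax_cross_entropy(logits, y_train[idx])
                net.backward(dlogits)
                opt.step()
                epoch_losses.append(loss * len(idx))
            val_loss, val_acc = _evaluate(net, X_val, y_val)
            logs.append(
                {
                    "replicate": r,
                    "epoch": epoch,
                    "train_loss": float(np.sum(epoch_losses) / len(X_train)),
                    "val_loss": val_loss,
                    "val_acc": val_acc,
                }
            )
            if val_loss < best_val_loss - 1e-9:
                best_val_loss = val_loss
                best_epoch_state = net.get_state()
                since_improve = 0
            else:
                since_improve += 1
                if since_improve >= spec.patience:
                    break
        if best_epoch_state is not None:
            net.set_state(best_epoch_state)
        _, val_acc = _evaluate(net, X_val, y_val)
        if best is None or val_acc > best[0] + 1e-12:
            best = (val_acc, r)
            best_net, best_state = net, net.get_state()
    assert best_net is not None and best is not None
    best_net.set_state(best_state)
    log = pd.DataFrame(logs, columns=["replicate", "epoch", "train_loss", "val_loss", "val_acc"])
    log.attrs["warnings"] = warnings
    return TrainedRegionModel(
        spec=spec,
        network=best_net,
        training_log=log,
        selected_replicate=best[1],
        val_accuracy=best[0],
    )


def load_split_arrays(
    manifest: DatasetManifest,
    spec: RegionModelSpec,
    split: str,
    image_root: str | Path = ".",
) -> tuple[np.ndarray, np.ndarray]:
    """Preprocessed image tensor + label vector for one region and split."""
    root = Path(image_root)
    df = manifest.frame
    sel = df[(df["region"] == spec.region) & (df["split"] == split)]
    X = np.stack([preprocess_image(root / p, spec) for p in sel["image_path"]]) if len(sel) else np.empty((0, *spec.input_size, spec.channels))
    return X, sel["pain_level"].to_numpy(dtype=int)


def train_region_model(
    manifest: DatasetManifest,
    spec: RegionModelSpec,
    seed: int,
    image_root: str | Path = ".",
) -> TrainedRegionModel:
    """Train one region classifier from a split manifest on disk."""
    X_train, y_train = load_split_arrays(manifest, spec, "train", image_root)
    X_val, y_val = load_split_arrays(manifest, spec, "val", image_root)
    if len(X_train) == 0:
        raise RegionCNNError(f"manifest has no train rows for region {spec.region!r}")
    if len(X_val) == 0:
        raise RegionCNNError(f"manifest has no val rows for region {spec.region!r}")
    return fit_region_model_arrays(X_train, y_train, X_val, y_val, spec, seed)


def predict_region(model: TrainedRegionModel, image) -> RegionPrediction:
    """Classify one region image: softmax confidences + recommendation."""
    if model.network is None:
        raise RegionCNNError("model is untrained")
    x = preprocess_image(image, model.spec)[None, ...]
    conf = model.predict_batch(x)[0]
    return RegionPrediction.from_confidences(conf)
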