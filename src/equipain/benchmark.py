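"""End-to-end synthetic benchmark of the whole pipeline.

Chains the package together on generated data: face scenes → region crops →
scaled-down region classifiers → fused whole-face calls → confusion-matrix
metrics.  Used by the test suite and the acceptance script; real-data runs
use the full-size specs through the CLI instead.

Problem sizes follow the reference protocol where one exists (40 scenes per
class in the fusion evaluation set, i.e. 120 scenes / 360 crops) and stay
desk-scale elsewhere (80 training / 20 validation scenes per class,
32×32 inputs).  Scene conditions default to the fully separable, noise-free
regime in which the generator's closed-form rule proves the classes
distinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import REGIONS
from .fusion import FusionCVResult, FusionModelSpec, FusionRecord, assemble_features, train_fusion
from .region_cnn import (
    RegionModelSpec,
    RegionPrediction,
    TrainedRegionModel,
    fit_region_model_arrays,
    preprocess_image,
)
from .synth import FaceScene, SceneParams, generate_face_scene, generate_region_image


def make_scene_set(
    n_per_class: int, separability: float, noise_sd: float, seed: int,
    size: tuple[int, int] = (96, 96),
) -> list[FaceScene]:
    """n_per_class whole-face scenes per pain level, seeded per scene."""
    scenes = []
    k = 0
    for level in range(3):
        for _ in range(n_per_class):
            scenes.append(
                generate_face_scene(
                    SceneParams(level, separability, noise_sd, seed + k), size
                )
            )
            k += 1
    return scenes


def region_arrays(
    scenes: list[FaceScene], region: str, spec: RegionModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Preprocessed crop tensor + labels for one region of a scene set."""
    X = np.stack([preprocess_image(s.crops[region].pixels, spec) for s in scenes])
    y = np.array([s.pain_level for s in scenes], dtype=int)
    return X, y


def make_region_arrays(
    region: str, n_per_class: int, separability: float, noise_sd: float, seed: int,
    spec: RegionModelSpec, size: tuple[int, int] = (32, 32),
) -> tuple[np.ndarray, np.ndarray]:
    """Standalone region images (not scene crops) as a training tensor."""
    X, y = [], []
    k = 0
    for level in range(3):
        for _ in range(n_per_class):
            img = generate_region_image(region, SceneParams(level, separability, noise_sd, seed + k), size)
            X.append(preprocess_image(img.pixels, spec))
            y.append(level)
            k += 1
    return np.stack(X), np.array(y, dtype=int)


@dataclass
class BenchmarkResult:
    region_models: dict[str, TrainedRegionModel]
    region_val_accuracy: dict[str, float]
    region_eval_accuracy_pct: dict[str, float]
    fusion: FusionCVResult

    @property
    def best_single_region_pct(self) -> float:
        return max(self.region_eval_accuracy_pct.values())


def run_pipeline_benchmark(
    seed: int,
    separability: float = 1.0,
    noise_sd: float = 0.0,
    n_train_per_class: int = 80,
    n_val_per_class: int = 20,
    n_eval_per_class: int = 40,
    epochs: int = 12,
    replicates: int = 2,
) -> BenchmarkResult:
    """Train the three region models on scene crops and fuse their calls.

    The evaluation set holds ``n_eval_per_class`` scenes per level (40 by
    default, the reference fusion-set size); fused performance is the
    stratified 10-fold CV of the fusion perceptron on those scenes'
    assembled confidence features.
    """
    base = int(np.random.SeedSequence(seed).generate_state(1)[0] % 2**24)
    train_s = make_scene_set(n_train_per_class, separability, noise_sd, base + 100_000)
    val_s = make_scene_set(n_val_per_class, separability, noise_sd, base + 200_000)
    eval_s = make_scene_set(n_eval_per_class, separability, noise_sd, base + 300_000)

    models: dict[str, TrainedRegionModel] = {}
    val_acc: dict[str, float] = {}
    eval_acc: dict[str, float] = {}
    eval_conf: dict[str, np.ndarray] = {}
    for i, region in enumerate(REGIONS):
        spec = RegionModelSpec.scaled(region, epochs=epochs, replicates=replicates)
        Xtr, ytr = region_arrays(train_s, region, spec)
        Xv, yv = region_arrays(val_s, region, spec)
        model = fit_region_model_arrays(Xtr, ytr, Xv, yv, spec, seed=seed + i)
        Xe, ye = region_arrays(eval_s, region, spec)
        conf = model.predict_batch(Xe)
        models[region] = model
        val_acc[region] = model.val_accuracy
        eval_acc[region] = float((conf.argmax(axis=1) == ye).mean() * 100.0)
        eval_conf[region] = conf

    records = []
    for i, scene in enumerate(eval_s):
        preds = {
            r: RegionPrediction.from_confidences(eval_conf[r][i]) for r in REGIONS
        }
        features = assemble_features(preds["ears"], preds["eyes"], preds["mouth_nostrils"])
        records.append(FusionRecord(features, scene.pain_level, f"scene{i:03d}"))
    fusion = train_fusion(records, FusionModelSpec(), seed=seed + 7)
    return BenchmarkResult(
        region_models=models,
        region_val_accuracy=val_acc,
        region_eval_accuracy_pct=eval_acc,
        fusion=fusion,
    )
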