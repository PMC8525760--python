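"""Procedural synthetic benchmark: region images, face scenes, cohorts, videos.

No footage from the original study was ever deposited, so the package ships
a fully seeded procedural generator that emulates its structure: three
facial regions per frame (ears, eyes, mouth-and-nostrils), three ordinal
pain levels, per-animal longitudinal captures at four daily timepoints, and
fixed-camera videos with sparse motion events.

Rendering model
---------------
Every image is an 8-bit grayscale raster (optionally replicated to RGB): a
low-frequency background texture (values ≥ 170 before noise) with dark
"ink" strokes for the facial features.  A scene's pain level drives a
continuous latent intensity:

* raw latent ``u`` is drawn uniformly from the class third of [0, 1]
  (level 0 → [0, 1/3), level 1 → [1/3, 2/3), level 2 → [2/3, 1));
* the separability ``s`` shrinks it towards the class-agnostic midpoint,
  ``l = 0.5 + s * (u - 0.5)`` — at s=0 every class renders from the
  identical latent 0.5, so class-conditional image distributions coincide
  and no classifier can beat chance;
* the geometry parameter ``g = (l + 0.25 * floor(3 l)) / 1.5`` is monotone
  in ``l`` with jumps at the class boundaries, so at s=1 the three classes
  occupy disjoint, gap-separated bands of ``g``.

``g`` controls region geometry (ears: spread of the two ear triangles;
eyes: orbital aperture closing; mouth/nostrils: nostril dilation) and the
ink gray value ``v(g) = round(30 + 80 g)``.

Closed-form classification rule (the separability oracle): the mean
intensity of ink pixels (raw value < 140) equals ``v(g)`` up to rounding;
thresholding it at ``v(g)`` evaluated at the inter-class gap midpoints
(g = 11/36 and 25/36) classifies any noise-free, separability-1 sample with
100% accuracy.  The geometric areas are monotone in ``g`` as well, so e.g.
the ears' ink fraction in the upper half-plane also separates level 0 from
level 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

from .dataset import (
    REGIONS,
    DatasetManifest,
    LabeledRegionImage,
    build_manifest,
)

INK_BASE = 30.0  #: ink gray value at g=0
INK_SPAN = 80.0  #: ink gray range over g in [0,1]
INK_CUTOFF = 140.0  #: raw values below this count as ink
BACKGROUND_LOW, BACKGROUND_HIGH = 170.0, 230.0
VIDEO_BACKGROUND_LOW, VIDEO_BACKGROUND_HIGH = 100.0, 156.0

#: geometry-parameter midpoints of the inter-class gaps at separability 1
_G_GAP_01 = (2 / 9 + 7 / 18) / 2  # 11/36
_G_GAP_12 = (11 / 18 + 7 / 9) / 2  # 25/36


class SynthError(ValueError):
    """Raised for invalid generator parameters."""


@dataclass(frozen=True)
class SceneParams:
    """Conditions under which one scene (or cohort) is rendered."""

    pain_level: int
    separability: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pain_level not in (0, 1, 2):
            raise SynthError(f"pain_level must be 0, 1 or 2, got {self.pain_level}")
        if not 0.0 <= self.separability <= 1.0:
            raise SynthError(f"separability must lie in [0,1], got {self.separability}")
        if self.noise_sd < 0:
            raise SynthError(f"noise_sd must be non-negative, got {self.noise_sd}")


@dataclass(frozen=True)
class RegionStyle:
    """Continuous pain intensity mapped onto one region's geometry."""

    region: str
    latent: float

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise SynthError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        if not 0.0 <= self.latent <= 1.0:
            raise SynthError(f"latent must lie in [0,1], got {self.latent}")


@dataclass(frozen=True)
class RenderedRegion:
    """A rendered region crop plus its label record."""

    pixels: np.ndarray
    region: str
    pain_level: int
    latent: float

    def save(self, path: str | Path) -> LabeledRegionImage:
        Image.fromarray(self.pixels).save(path, format="PNG")
        h, w = self.pixels.shape[:2]
        return LabeledRegionImage(
            image_path=str(path),
            region=self.region,
            pain_level=self.pain_level,
            animal_id="synthetic",
            crop_box=(0, 0, w, h),
        )


@dataclass(frozen=True)
class FaceScene:
    """Whole-face render with its three region crops and crop boxes."""

    image: np.ndarray
    crops: dict[str, RenderedRegion]
    boxes: dict[str, tuple[int, int, int, int]]
    pain_level: int
    latent: float


# ---------------------------------------------------------------------------
# Latent machinery
# ---------------------------------------------------------------------------


def draw_latent(pain_level: int, separability: float, rng: np.random.Generator) -> float:
    """Effective latent for one scene: class-third draw shrunk by separability."""
    u = (pain_level + rng.uniform()) / 3.0
    return 0.5 + separability * (u - 0.5)


def geometry_parameter(latent: float) -> float:
    """Monotone latent→geometry map with jumps at the class boundaries."""
    k = min(math.floor(3.0 * latent), 2)
    return (latent + 0.25 * k) / 1.5


def ink_value(g: float) -> float:
    return INK_BASE + INK_SPAN * g


def rule_thresholds() -> tuple[float, float]:
    """Ink-intensity cut points of the closed-form classification rule."""
    return ink_value(_G_GAP_01), ink_value(_G_GAP_12)


def ink_statistic(pixels: np.ndarray) -> float:
    """Mean raw intensity over ink pixels (value < 140); NaN if no ink."""
    gray = pixels if pixels.ndim == 2 else pixels[..., 0]
    mask = gray < INK_CUTOFF
    if not mask.any():
        return float("nan")
    return float(gray[mask].mean())


def upper_half_ink_fraction(pixels: np.ndarray) -> float:
    """Fraction of ink pixels in the upper half-plane (ears statistic)."""
    gray = pixels if pixels.ndim == 2 else pixels[..., 0]
    upper = gray[: gray.shape[0] // 2]
    return float((upper < INK_CUTOFF).mean())


def classify_by_rule(pixels: np.ndarray) -> int:
    """Closed-form pixel rule: threshold the ink-intensity statistic.

    Exact (100% accuracy) on noise-free, separability-1 renders of any
    region; see the module docstring for why the thresholds separate the
    rasterised classes with a margin.
    """
    s = ink_statistic(pixels)
    t01, t12 = rule_thresholds()
    if math.isnan(s):
        return 0
    if s < t01:
        return 0
    if s < t12:
        return 1
    return 2


# ---------------------------------------------------------------------------
# Rasterisation
# ---------------------------------------------------------------------------


def _background(shape: tuple[int, int], rng: np.random.Generator,
                low: float = BACKGROUND_LOW, high: float = BACKGROUND_HIGH) -> np.ndarray:
    """Low-frequency texture: a coarse seeded grid bilinearly upsampled."""
    h, w = shape
    coarse = rng.uniform(0.0, 1.0, size=(4, 4))
    ys = np.linspace(0, 3, h)
    xs = np.linspace(0, 3, w)
    y0 = np.clip(ys.astype(int), 0, 2)
    x0 = np.clip(xs.astype(int), 0, 2)
    fy = (ys - y0)[:, None]
    fx = (xs - x0)[None, :]
    c00 = coarse[y0][:, x0]
    c01 = coarse[y0][:, x0 + 1]
    c10 = coarse[y0 + 1][:, x0]
    c11 = coarse[y0 + 1][:, x0 + 1]
    tex = (1 - fy) * ((1 - fx) * c00 + fx * c01) + fy * ((1 - fx) * c10 + fx * c11)
    return low + (high - low) * tex


def _grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    return np.mgrid[0:h, 0:w].astype(float)


def _ears_mask(shape: tuple[int, int], g: float) -> np.ndarray:
    """Two apex-up triangles; base half-width (ear spread) grows with g."""
    h, w = shape
    yy, xx = _grid(shape)
    y_top, y_base = 0.08 * h, 0.48 * h
    b = w * (0.05 + 0.12 * g)
    frac = np.clip((yy - y_top) / (y_base - y_top), -1, 1)
    mask = np.zeros(shape, dtype=bool)
    for cx in (0.30 * w, 0.70 * w):
        mask |= (yy >= y_top) & (yy <= y_base) & (np.abs(xx - cx) <= b * frac)
    return mask


def _eyes_mask(shape: tuple[int, int], g: float) -> np.ndarray:
    """Filled orbital ellipse whose vertical aperture closes as pain grows,
    plus a fixed tension bar above the eye."""
    h, w = shape
    yy, xx = _grid(shape)
    cy, cx = 0.55 * h, 0.50 * w
    a = 0.32 * w
    b = max(0.04 * h, h * (0.26 - 0.16 * g))
    mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    bar = (np.abs(yy - 0.22 * h) <= 0.5) & (np.abs(xx - cx) <= 0.20 * w)
    return mask | bar


def _mouth_mask(shape: tuple[int, int], g: float) -> np.ndarray:
    """Two nostril ellipses dilating with pain plus a fixed lip line."""
    h, w = shape
    yy, xx = _grid(shape)
    rx = w * (0.05 + 0.08 * g)
    ry = h * (0.06 + 0.08 * g)
    mask = np.zeros(shape, dtype=bool)
    for cx in (0.35 * w, 0.65 * w):
        mask |= ((xx - cx) / rx) ** 2 + ((yy - 0.35 * h) / ry) ** 2 <= 1.0
    lip = (np.abs(yy - 0.70 * h) <= 0.5) & (np.abs(xx - 0.50 * w) <= 0.25 * w)
    return mask | lip


_REGION_MASKS = {"ears": _ears_mask, "eyes": _eyes_mask, "mouth_nostrils": _mouth_mask}


def _render_region_onto(canvas: np.ndarray, region: str, g: float) -> None:
    mask = _REGION_MASKS[region](canvas.shape, g)
    canvas[mask] = round(ink_value(g))


def _finalise(canvas: np.ndarray, noise_sd: float, rng: np.random.Generator,
              rgb: bool = False) -> np.ndarray:
    if noise_sd > 0:
        canvas = canvas + rng.normal(0.0, noise_sd, size=canvas.shape)
    out = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    if rgb:
        out = np.repeat(out[..., None], 3, axis=2)
    return out


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _check_size(size: tuple[int, int], minimum: tuple[int, int] = (8, 8)) -> tuple[int, int]:
    h, w = (int(v) for v in size)
    if h < minimum[0] or w < minimum[1]:
        raise SynthError(f"size {size} too small; minimum is {minimum} (rows, cols)")
    return h, w


def generate_region_image(
    region: str,
    params: SceneParams,
    size: tuple[int, int] = (64, 64),
    rgb: bool = False,
) -> RenderedRegion:
    """Render one facial-region crop under the given scene conditions.

    Deterministic: identical (region, params, size) give byte-identical
    pixels.
    """
    if region not in REGIONS:
        raise SynthError(f"unknown region {region!r}; expected one of {REGIONS}")
    h, w = _check_size(size)
    rng = np.random.default_rng(params.seed)
    latent = draw_latent(params.pain_level, params.separability, rng)
    canvas = _background((h, w), rng)
    _render_region_onto(canvas, region, geometry_parameter(latent))
    pixels = _finalise(canvas, params.noise_sd, rng, rgb=rgb)
    return RenderedRegion(pixels=pixels, region=region, pain_level=params.pain_level,
                          latent=latent)


def scene_boxes(size: tuple[int, int]) -> dict[str, tuple[int, int, int, int]]:
    """Non-overlapping (x, y, w, h) region boxes stacked ears/eyes/mouth."""
    h, w = _check_size(size, minimum=(24, 16))
    bh = h // 3
    bx, bw = w // 8, w - 2 * (w // 8)
    return {
        "ears": (bx, 0, bw, bh),
        "eyes": (bx, bh, bw, bh),
        "mouth_nostrils": (bx, 2 * bh, bw, h - 2 * bh),
    }


def generate_face_scene(
    params: SceneParams,
    size: tuple[int, int] = (96, 96),
    rgb: bool = False,
) -> FaceScene:
    """Render a whole-face image; the three region crops are exact sub-rasters.

    All three regions share the scene's single latent, hence its pain level.
    """
    h, w = _check_size(size, minimum=(24, 16))
    boxes = scene_boxes((h, w))
    rng = np.random.default_rng(params.seed)
    latent = draw_latent(params.pain_level, params.separability, rng)
    g = geometry_parameter(latent)
    canvas = _background((h, w), rng)
    for region, (x, y, bw, bh) in boxes.items():
        sub = canvas[y : y + bh, x : x + bw]
        _render_region_onto(sub, region, g)
    image = _finalise(canvas, params.noise_sd, rng, rgb=rgb)
    crops = {
        region: RenderedRegion(
            pixels=np.array(image[y : y + bh, x : x + bw], copy=True),
            region=region,
            pain_level=params.pain_level,
            latent=latent,
        )
        for region, (x, y, bw, bh) in boxes.items()
    }
    return FaceScene(image=image, crops=crops, boxes=boxes,
                     pain_level=params.pain_level, latent=latent)


def generate_cohort(
    out_dir: str | Path,
    n_animals: int,
    days: int,
    timepoints_per_day: int,
    class_weights: Sequence[float],
    params: SceneParams,
    scene_size: tuple[int, int] = (96, 96),
) -> DatasetManifest:
    """Longitudinal cohort: every animal filmed at each daily timepoint.

    Emulates the study design of per-animal captures at four timepoints a
    day over the peri-operative week.  Each (animal, day, timepoint) slot
    draws its pain level from ``class_weights`` and renders one face scene;
    the manifest gets three region rows per scene.  ``params.pain_level`` is
    ignored — cohort labels come from the weights.

    Files are written under ``out_dir`` as
    ``{animal}_{day}_{timepoint}_{region}.png`` (plus the whole-face frame
    ``..._face.png``) and the manifest as ``manifest.csv``.
    """
    if min(n_animals, days, timepoints_per_day) <= 0:
        raise SynthError("n_animals, days and timepoints_per_day must be positive")
    weights = np.asarray(class_weights, dtype=float)
    if weights.shape != (3,) or (weights < 0).any() or abs(weights.sum() - 1.0) > 1e-9:
        raise SynthError(f"class_weights must be a 3-simplex, got {class_weights}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for a in range(n_animals):
        for d in range(days):
            for t in range(timepoints_per_day):
                slot_rng = np.random.default_rng(
                    np.random.SeedSequence([params.seed, a, d, t])
                )
                level = int(slot_rng.choice(3, p=weights))
                slot_seed = int(slot_rng.integers(0, 2**31))
                scene = generate_face_scene(
                    SceneParams(level, params.separability, params.noise_sd, slot_seed),
                    size=scene_size,
                )
                stem = f"a{a:02d}_d{d}_t{t}"
                face_name = f"{stem}_face.png"
                Image.fromarray(scene.image).save(out_dir / face_name, format="PNG")
                for region, crop in scene.crops.items():
                    crop_name = f"{stem}_{region}.png"
                    Image.fromarray(crop.pixels).save(out_dir / crop_name, format="PNG")
                    rows.append(
                        LabeledRegionImage(
                            image_path=crop_name,
                            region=region,
                            pain_level=level,
                            animal_id=f"a{a:02d}",
                            source_frame=face_name,
                            crop_box=scene.boxes[region],
                            curated=True,
                        )
                    )
    manifest = build_manifest(rows)
    manifest.write_csv(out_dir / "manifest.csv")
    return manifest


def motion_floor(magnitude: float, frame_shape: tuple[int, int]) -> float:
    """Guaranteed mean-absolute-difference at an event frame.

    The event block covers ``~magnitude/4`` of the frame and every painted
    pixel moves by at least 99 gray levels against the video background.
    """
    h, w = frame_shape
    bh, bw = _block_dims(magnitude, (h, w))
    return 99.0 * (bh * bw) / (h * w)


def _block_dims(magnitude: float, shape: tuple[int, int]) -> tuple[int, int]:
    m = min(max(float(magnitude), 0.0), 1.0)
    s = math.sqrt(m)
    h, w = shape
    return max(1, int(h // 2 * s)), max(1, int(w // 2 * s))


_BLOCK_SLOTS = ((0.0, 0.0), (0.0, 0.5), (0.5, 0.0), (0.5, 0.5))


def generate_motion_video(
    n_frames: int,
    event_frames: Iterable[int],
    magnitude: float,
    params: SceneParams,
    frame_size: tuple[int, int] = (48, 64),
) -> list[np.ndarray]:
    """Fixed-camera toy video: static background, block jumps at events.

    At each event frame a block (cycling over the four quadrants) flips
    between bright (255) and dark (0), so the consecutive-frame mean
    absolute difference is at least :func:`motion_floor` there and exactly 0
    elsewhere when ``noise_sd`` is 0.  Per-frame Gaussian noise is added
    when ``noise_sd > 0``.
    """
    if n_frames <= 0:
        raise SynthError("n_frames must be positive")
    if magnitude <= 0:
        raise SynthError("magnitude must be positive")
    events = sorted(set(int(e) for e in event_frames))
    if events and (events[0] < 1 or events[-1] >= n_frames):
        raise SynthError(f"event_frames must lie in [1, {n_frames}), got {events}")
    h, w = _check_size(frame_size)
    rng = np.random.default_rng(params.seed)
    base = _background((h, w), rng, VIDEO_BACKGROUND_LOW, VIDEO_BACKGROUND_HIGH)
    bh, bw = _block_dims(magnitude, (h, w))

    canvas = base.copy()
    visits = [0, 0, 0, 0]
    frames = []
    event_set = set(events)
    n_seen = 0
    for i in range(n_frames):
        if i in event_set:
            slot = n_seen % 4
            fy, fx = _BLOCK_SLOTS[slot]
            y0, x0 = int(fy * h), int(fx * w)
            canvas[y0 : y0 + bh, x0 : x0 + bw] = 255.0 if visits[slot] % 2 == 0 else 0.0
            visits[slot] += 1
            n_seen += 1
        frame = canvas.copy()
        if params.noise_sd > 0:
            frame = frame + rng.normal(0.0, params.noise_sd, size=frame.shape)
        frames.append(np.clip(np.rint(frame), 0, 255).astype(np.uint8))
    return frames
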