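"""The labeled image database: schema, manifests, splits, cropping.

A manifest is the single source of truth for the database.  Each row is one
cropped facial-region image carrying its region (ears / eyes /
mouth-and-nostrils), its three-level grimace-scale pain label (0 = not
present, 1 = moderately present, 2 = obviously present), the animal it came
from, the whole-face source frame and the crop box inside that frame.
Rows sharing a ``source_frame`` constitute one whole-face scene.

Crop boxes are (x, y, width, height) in pixels, 0-based, origin top-left,
half-open — the crop is ``frame[y:y+h, x:x+w]``.

The train/validation/test split is stratified per (region, class) cell:
validation and test each receive exactly floor(frac·n) rows of a cell of
size n, the remainder goes to training.  Applied at 10%/10% to the reference
database composition this floor rule reproduces the reported per-region
split sizes exactly (e.g. ears 1905/237/237).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

REGIONS = ("ears", "eyes", "mouth_nostrils")
PAIN_LEVELS = (0, 1, 2)
SPLITS = ("train", "val", "test")

#: Per-region per-class image counts of the reference database
#: (rows: pain levels 0,1,2).  Total 4850 images.
REFERENCE_COMPOSITION: dict[str, tuple[int, int, int]] = {
    "ears": (1991, 203, 185),
    "eyes": (477, 488, 471),
    "mouth_nostrils": (506, 393, 136),
}

MANIFEST_COLUMNS = (
    "image_path",
    "region",
    "pain_level",
    "animal_id",
    "source_frame",
    "crop_x",
    "crop_y",
    "crop_w",
    "crop_h",
    "curated",
    "split",
)


class DatasetError(ValueError):
    """Raised for schema violations in rows, manifests or crop boxes."""


@dataclass(frozen=True)
class LabeledRegionImage:
    """One cropped facial-region image and its provenance."""

    image_path: str
    region: str
    pain_level: int
    animal_id: str
    source_frame: str = ""
    crop_box: tuple[int, int, int, int] = (0, 0, 0, 0)
    curated: bool = True
    split: str = ""

    def validate(self) -> list[str]:
        problems = []
        if self.region not in REGIONS:
            problems.append(f"region {self.region!r} not in {REGIONS}")
        if self.pain_level not in PAIN_LEVELS:
            problems.append(f"pain_level {self.pain_level!r} not in {PAIN_LEVELS}")
        if self.split and self.split not in SPLITS:
            problems.append(f"split {self.split!r} not in {SPLITS}")
        x, y, w, h = self.crop_box
        if min(x, y) < 0 or min(w, h) < 0:
            problems.append(f"negative crop_box {self.crop_box}")
        return problems

    def to_row(self) -> dict:
        x, y, w, h = self.crop_box
        return {
            "image_path": self.image_path,
            "region": self.region,
            "pain_level": self.pain_level,
            "animal_id": self.animal_id,
            "source_frame": self.source_frame,
            "crop_x": x,
            "crop_y": y,
            "crop_w": w,
            "crop_h": h,
            "curated": self.curated,
            "split": self.split,
        }


@dataclass(frozen=True)
class DatasetManifest:
    """Rows of labeled region images plus the derived count table."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"manifest missing columns {missing}")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DatasetManifest):
            return NotImplemented
        return self.frame.equals(other.frame)

    @property
    def count_table(self) -> pd.DataFrame:
        """Per-region (rows = pain level) image counts, zero-filled."""
        table = pd.DataFrame(0, index=list(PAIN_LEVELS), columns=list(REGIONS))
        tally = self.frame.groupby(["pain_level", "region"]).size()
        for (lvl, reg), n in tally.items():
            table.loc[lvl, reg] = n
        return table

    @property
    def total_images(self) -> int:
        return len(self.frame)

    def rows(self) -> Iterable[LabeledRegionImage]:
        for r in self.frame.itertuples(index=False):
            yield LabeledRegionImage(
                image_path=r.image_path,
                region=r.region,
                pain_level=int(r.pain_level),
                animal_id=str(r.animal_id),
                source_frame=str(r.source_frame),
                crop_box=(int(r.crop_x), int(r.crop_y), int(r.crop_w), int(r.crop_h)),
                curated=bool(r.curated),
                split=str(r.split) if isinstance(r.split, str) else "",
            )

    def write_csv(self, path: str | Path) -> None:
        df = self.frame.copy()
        df["curated"] = df["curated"].astype(bool)
        df.to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def read_csv(cls, path: str | Path) -> "DatasetManifest":
        df = pd.read_csv(
            path,
            dtype={
                "image_path": str,
                "region": str,
                "animal_id": str,
                "source_frame": str,
                "split": str,
            },
            keep_default_na=False,
        )
        df["pain_level"] = df["pain_level"].astype(int)
        for c in ("crop_x", "crop_y", "crop_w", "crop_h"):
            df[c] = df[c].astype(int)
        df["curated"] = df["curated"].astype(str).str.lower().isin(("true", "1"))
        return cls(df)


def build_manifest(rows: Sequence[LabeledRegionImage]) -> DatasetManifest:
    """Assemble and validate a manifest from individual labeled rows.

    Rejects invalid pain levels / regions with a per-row error report and
    duplicate (image_path, region) pairs.
    """
    problems = []
    for i, row in enumerate(rows):
        for p in row.validate():
            problems.append(f"row {i} ({row.image_path}): {p}")
    if problems:
        raise DatasetError("invalid rows:\n" + "\n".join(problems))
    df = pd.DataFrame([r.to_row() for r in rows], columns=list(MANIFEST_COLUMNS))
    if len(df):
        dup = df.duplicated(subset=["image_path", "region"])
        if dup.any():
            dupes = df.loc[dup, ["image_path", "region"]].to_records(index=False)
            raise DatasetError(f"duplicate image_path+region pairs: {list(dupes)[:5]}")
    return DatasetManifest(df)


def manifest_from_composition(
    composition: dict[str, tuple[int, int, int]] = REFERENCE_COMPOSITION,
) -> DatasetManifest:
    """A synthetic-path manifest whose count table equals ``composition``.

    Used to reason about split arithmetic when only the published counts of
    the original database are available (no images were deposited).
    """
    rows = []
    for region, counts in composition.items():
        for level, n in zip(PAIN_LEVELS, counts):
            for k in range(n):
                rows.append(
                    LabeledRegionImage(
                        image_path=f"{region}/c{level}_{k:05d}.png",
                        region=region,
                        pain_level=level,
                        animal_id="synthetic",
                        source_frame=f"frame_{region}_c{level}_{k:05d}.png",
                    )
                )
    return build_manifest(rows)


def stratified_split(
    manifest: DatasetManifest,
    val_frac: float,
    test_frac: float,
    seed: int,
) -> DatasetManifest:
    """Assign train/val/test per (region, class) cell with the floor rule.

    A cell of size n contributes exactly floor(val_frac·n) validation and
    floor(test_frac·n) test rows (seeded uniform shuffle), remainder train.
    """
    if val_frac < 0 or test_frac < 0:
        raise DatasetError("split fractions must be non-negative")
    if val_frac + test_frac >= 1:
        raise DatasetError("val_frac + test_frac must be < 1")
    rng = np.random.default_rng(seed)
    split = pd.Series("train", index=manifest.frame.index)
    groups = manifest.frame.groupby(["region", "pain_level"]).groups
    for key in sorted(groups):
        idx = np.asarray(groups[key])
        n = len(idx)
        # tiny epsilon guards against 0.1*n landing just below an integer
        n_val = math.floor(val_frac * n + 1e-9)
        n_test = math.floor(test_frac * n + 1e-9)
        perm = rng.permutation(n)
        split.loc[idx[perm[:n_val]]] = "val"
        split.loc[idx[perm[n_val : n_val + n_test]]] = "test"
    df = manifest.frame.copy()
    df["split"] = split
    return DatasetManifest(df)


def split_sizes(manifest: DatasetManifest) -> pd.DataFrame:
    """Per-region split sizes (columns train/val/test)."""
    out = pd.DataFrame(0, index=list(REGIONS), columns=list(SPLITS))
    tally = manifest.frame.groupby(["region", "split"]).size()
    for (reg, spl), n in tally.items():
        out.loc[reg, spl] = n
    return out


def crop_region(frame: np.ndarray, box: tuple[int, int, int, int]) -> np.ndarray:
    """Cut ``frame[y:y+h, x:x+w]`` (a copy); the box must lie inside the frame."""
    x, y, w, h = (int(v) for v in box)
    if w <= 0 or h <= 0:
        raise DatasetError(f"crop box must have positive size, got {box}")
    H, W = frame.shape[:2]
    if x < 0 or y < 0 or x + w > W or y + h > H:
        raise DatasetError(f"crop box {box} exceeds frame bounds {(W, H)}")
    return np.array(frame[y : y + h, x : x + w], copy=True)


def paste_region(frame: np.ndarray, box: tuple[int, int, int, int], patch: np.ndarray) -> np.ndarray:
    """Inverse of :func:`crop_region`; returns a new frame with the patch pasted."""
    x, y, w, h = (int(v) for v in box)
    if patch.shape[:2] != (h, w):
        raise DatasetError(f"patch shape {patch.shape[:2]} does not match box {box}")
    out = np.array(frame, copy=True)
    out[y : y + h, x : x + w] = patch
    return out


def scene_table(manifest: DatasetManifest) -> pd.DataFrame:
    """One row per whole-face scene (grouped by source_frame).

    Columns: source_frame, pain_level, n_regions, complete (all three
    regions present).  Scenes with inconsistent pain labels are rejected —
    a scene has a single whole-face pain level by construction.
    """
    df = manifest.frame
    grouped = df.groupby("source_frame")
    levels = grouped["pain_level"].nunique()
    bad = levels[levels > 1]
    if len(bad):
        raise DatasetError(f"scenes with conflicting pain labels: {list(bad.index)[:5]}")
    out = grouped.agg(
        pain_level=("pain_level", "first"),
        n_regions=("region", "nunique"),
    ).reset_index()
    out["complete"] = out["n_regions"] == len(REGIONS)
    return out


def sample_fusion_set(
    manifest: DatasetManifest, n_per_class: int, seed: int
) -> DatasetManifest:
    """Sample whole-face scenes for fusion evaluation, n_per_class per level.

    Seeded sampling without replacement among complete scenes (all three
    region crops present); every selected scene contributes its three crops.
    """
    if n_per_class < 0:
        raise DatasetError("n_per_class must be non-negative")
    scenes = scene_table(manifest)
    complete = scenes[scenes["complete"]]
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    deficits = {}
    for level in PAIN_LEVELS:
        pool = complete.loc[complete["pain_level"] == level, "source_frame"].tolist()
        if len(pool) < n_per_class:
            deficits[level] = n_per_class - len(pool)
            continue
        pick = rng.choice(len(pool), size=n_per_class, replace=False)
        chosen.extend(pool[i] for i in sorted(pick))
    if deficits:
        raise DatasetError(
            "insufficient complete scenes per class, deficits: "
            + ", ".join(f"level {k}: {v}" for k, v in deficits.items())
        )
    df = manifest.frame[manifest.frame["source_frame"].isin(chosen)].copy()
    return DatasetManifest(df)
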