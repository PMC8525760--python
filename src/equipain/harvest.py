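"""Motion-triggered frame extraction from fixed-camera video.

The upstream step of the pipeline: horses are filmed from a fixed camera,
and only frames in which something moved are worth labeling.  The motion
operator is deliberately the simplest one that satisfies the contract —
the mean absolute pixel difference between consecutive frames after
grayscale conversion — and the harvest policy is a pure function of the
scored sequence:

frame i (i ≥ 1) is saved iff

* ``motion_score(frame[i-1], frame[i]) > motion_threshold``, and
* ``i - last_saved_index > min_gap``, and
* fewer than ``max_frames`` frames have been saved.

Frame 0 has no predecessor and is never saved.  Raising the threshold can
only shrink the saved set, and consecutive saved indices always differ by
more than ``min_gap``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from PIL import Image


class HarvestError(ValueError):
    """Raised for invalid frames, policies or sources."""


@dataclass(frozen=True)
class HarvestPolicy:
    motion_threshold: float = 0.0
    min_gap: int = 0
    max_frames: int | None = None

    def __post_init__(self) -> None:
        if self.motion_threshold < 0:
            raise HarvestError("motion_threshold must be non-negative")
        if self.min_gap < 0:
            raise HarvestError("min_gap must be non-negative")
        if self.max_frames is not None and self.max_frames < 0:
            raise HarvestError("max_frames must be non-negative")


@dataclass(frozen=True)
class HarvestResult:
    saved_frame_indices: tuple[int, ...]
    motion_scores: tuple[float, ...]
    manifest: pd.DataFrame


def _to_gray(frame: np.ndarray) -> np.ndarray:
    arr = np.asarray(frame, dtype=float)
    if arr.ndim == 3:
        # ITU-R 601 luma weights
        arr = arr[..., 0] * 0.299 + arr[..., 1] * 0.587 + arr[..., 2] * 0.114
    elif arr.ndim != 2:
        raise HarvestError(f"frames must be 2-D or 3-D rasters, got ndim={arr.ndim}")
    return arr


def motion_score(frame_a: np.ndarray, frame_b: np.ndarray) -> float:
    """Mean absolute pixel difference after grayscale conversion.

    Symmetric; 0 iff the frames are identical.
    """
    a, b = _to_gray(frame_a), _to_gray(frame_b)
    if a.shape != b.shape:
        raise HarvestError(f"frame shape mismatch: {a.shape} vs {b.shape}")
    return float(np.abs(a - b).mean())


def iter_frames(source) -> Iterator[tuple[np.ndarray, str]]:
    """Yield (frame, name) from a directory of ordered PNGs, a video file,
    or any iterable of arrays."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.is_dir():
            files = sorted(
                p for p in path.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg")
            )
            if not files:
                raise HarvestError(f"no image frames found in directory {path}")
            for p in files:
                yield np.asarray(Image.open(p)), p.stem
            return
        if not path.exists():
            raise HarvestError(f"unreadable video source: {path}")
        import imageio.v3 as iio

        for i, frame in enumerate(iio.imiter(path)):
            yield np.asarray(frame), f"{path.stem}_{i}"
        return
    for i, frame in enumerate(source):
        yield np.asarray(frame), f"frame_{i}"


def harvest_frames(
    video_source,
    policy: HarvestPolicy,
    out_dir: str | Path | None = None,
    source_name: str = "video",
) -> HarvestResult:
    """Apply the harvest policy to a frame sequence.

    When ``out_dir`` is given, saved frames are written as
    ``{source_name}_f{index:06d}.png`` and the manifest records their paths.
    """
    scores: list[float] = []
    saved: list[int] = []
    records: list[dict] = []
    prev: np.ndarray | None = None
    last_saved = None
    n = 0
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    for i, (frame, _name) in enumerate(iter_frames(video_source)):
        n += 1
        if i == 0:
            prev = frame
            continue
        score = motion_score(prev, frame)
        scores.append(score)
        cap_ok = policy.max_frames is None or len(saved) < policy.max_frames
        gap_ok = last_saved is None or (i - last_saved) > policy.min_gap
        if score > policy.motion_threshold and gap_ok and cap_ok:
            saved.append(i)
            last_saved = i
            saved_path = ""
            if out_path is not None:
                saved_path = str(out_path / f"{source_name}_f{i:06d}.png")
                Image.fromarray(np.asarray(frame, dtype=np.uint8)).save(
                    saved_path, format="PNG"
                )
            records.append(
                {
                    "source": source_name,
                    "frame_index": i,
                    "motion_score": score,
                    "saved_path": saved_path,
                }
            )
        prev = frame

    if n == 0:
        raise HarvestError("video source yielded zero frames")
    manifest = pd.DataFrame(
        records, columns=["source", "frame_index", "motion_score", "saved_path"]
    )
    if out_path is not None:
        manifest.to_csv(out_path / f"{source_name}_harvest.csv", index=False,
                        lineterminator="\n")
    return HarvestResult(
        saved_frame_indices=tuple(saved),
        motion_scores=tuple(scores),
        manifest=manifest,
    )
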