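"""Clip management, leakage-free partitioning, padding and window extraction.

The train/test split is a *hard cut*: a contiguous block of ceil(L/6) frames
at one end of each clip (head or tail, decided by a seeded fair coin per
clip) is the test set and the remainder the training set.  Each subset is
then padded independently by replicating its first and last frame N times, so
a window of 2N+1 frames never mixes frames from both splits.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from PIL import Image

N_MAX = 2
DEFAULT_INPUT_SIZE = 448
LABEL_THRESHOLD = 127          # 8-bit masks: > 127 -> vessel


@dataclasses.dataclass
class ClipRecord:
    """One video clip: ordered frame/label paths and its split assignment.

    ``test_start``/``test_end`` delimit the held-out contiguous block
    (end-exclusive frame indices); both None means unassigned.
    """

    clip_id: str
    frame_paths: List[str]
    label_paths: List[str]
    frame_rate: float = 12.5
    test_start: Optional[int] = None
    test_end: Optional[int] = None

    def __post_init__(self):
        if len(self.frame_paths) != len(self.label_paths):
            raise ValueError(
                f"clip {self.clip_id}: {len(self.frame_paths)} frames but "
                f"{len(self.label_paths)} labels")

    @property
    def n_frames(self) -> int:
        return len(self.frame_paths)

    @property
    def split_assigned(self) -> bool:
        return self.test_start is not None

    def test_indices(self) -> np.ndarray:
        if not self.split_assigned:
            raise ValueError(f"clip {self.clip_id} has no split assigned")
        return np.arange(self.test_start, self.test_end)

    def train_indices(self) -> np.ndarray:
        test = set(self.test_indices().tolist())
        return np.array([i for i in range(self.n_frames) if i not in test])


@dataclasses.dataclass
class FrameWindow:
    """2N+1 consecutive frames centred on the target frame, plus its label."""

    frames: np.ndarray          # (2N+1, H, W) float32 in [0, 1]
    target_index_in_clip: int
    label: np.ndarray           # (H, W) in {0, 1}
    n: int

    def __post_init__(self):
        d = self.frames.shape[0]
        if d != 2 * self.n + 1:
            raise ValueError(f"window depth {d} != 2N+1 for N={self.n}")
        if self.label.shape != self.frames.shape[1:]:
            raise ValueError("label shape differs from frame shape")


# ---------------------------------------------------------------------------
# partition
# ---------------------------------------------------------------------------

def partition_length(length: int, test_fraction: float,
                     head: bool) -> Tuple[np.ndarray, np.ndarray]:
    """Train/test frame indices for one clip of ``length`` frames.

    The test block holds ``ceil(length * test_fraction)`` contiguous frames
    at the head or tail; the remainder is the training block.
    """
    if not (0 < test_fraction < 1):
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    n_test = math.ceil(length * test_fraction)
    if head:
        test = np.arange(0, n_test)
        trainset = np.arange(n_test, length)
    else:
        test = np.arange(length - n_test, length)
        trainset = np.arange(0, length - n_test)
    return trainset, test


def partition_clips(clips: Sequence[ClipRecord],
                    test_fraction: float = 1.0 / 6.0,
                    seed: int = 0) -> List[ClipRecord]:
    """Assign a contiguous head-or-tail test block to every clip.

    The block holds ``ceil(L * test_fraction)`` frames (so every clip
    contributes at least one test frame); whether it sits at the head or the
    tail is a seeded fair coin per clip.
    """
    if not (0 < test_fraction < 1):
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    out = []
    for clip in clips:
        length = clip.n_frames
        if length < 2 * N_MAX + 1:
            raise ValueError(
                f"clip {clip.clip_id} too short ({length} frames; need at "
                f"least {2 * N_MAX + 1})")
        head = bool(rng.integers(2))
        _, test = partition_length(length, test_fraction, head)
        out.append(dataclasses.replace(clip, test_start=int(test[0]),
                                       test_end=int(test[-1]) + 1))
    return out


# ---------------------------------------------------------------------------
# padding and windows
# ---------------------------------------------------------------------------

def pad_subset(frames: Sequence, n: int) -> list:
    """Replicate the first and last element N times (boundary padding).

    Applied per split subset, so padded windows never reach across the
    train/test cut.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("cannot pad an empty frame list")
    if n < 0:
        raise ValueError(f"N must be >= 0, got {n}")
    return [frames[0]] * n + frames + [frames[-1]] * n


def extract_windows(padded_frames: Sequence, labels: Sequence,
                    n: int) -> List[FrameWindow]:
    """One window of depth 2N+1 per original frame of the padded subset.

    ``padded_frames`` must come from :func:`pad_subset`; ``labels`` are the
    *unpadded* per-frame masks, attached to each window's central frame.
    """
    padded = list(padded_frames)
    labels = list(labels)
    length = len(padded) - 2 * n
    if length < 1:
        raise ValueError(f"padded list of {len(padded)} too short for N={n}")
    if len(labels) != length:
        raise ValueError(
            f"{len(labels)} labels for {length} original frames")
    windows = []
    for k in range(length):
        stack = np.stack([np.asarray(f, dtype=np.float32)
                          for f in padded[k:k + 2 * n + 1]])
        windows.append(FrameWindow(frames=stack, target_index_in_clip=k,
                                   label=np.asarray(labels[k]), n=n))
    return windows


def windows_to_arrays(windows: Sequence[FrameWindow]
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Stack windows into (M, 2N+1, H, W) inputs and (M, H, W) labels."""
    x = np.stack([w.frames for w in windows]).astype(np.float32)
    y = np.stack([w.label for w in windows]).astype(np.float32)
    return x, y


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _to_gray_array(image: Union[str, Path, np.ndarray]) -> np.ndarray:
    """Load/convert to single-channel float32 luminance in [0, 1]."""
    if isinstance(image, (str, Path)):
        try:
            with Image.open(image) as im:
                return np.asarray(im.convert("L"), np.float32) / 255.0
        except Exception as exc:
            raise ValueError(f"cannot read image {image}: {exc}") from exc
    arr = np.asarray(image)
    if arr.ndim == 3:
        arr = (0.299 * arr[..., 0] + 0.587 * arr[..., 1]
               + 0.114 * arr[..., 2])
    arr = arr.astype(np.float32)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)


def preprocess(image: Union[str, Path, np.ndarray],
               size: int = DEFAULT_INPUT_SIZE) -> np.ndarray:
    """Luminance in [0, 1], bilinearly resized to the network input size."""
    arr = _to_gray_array(image)
    if arr.shape == (size, size):
        return arr
    im = Image.fromarray(np.rint(arr * 255).astype(np.uint8))
    im = im.resize((size, size), Image.BILINEAR)
    return np.asarray(im, np.float32) / 255.0


def preprocess_label(label: Union[str, Path, np.ndarray],
                     size: int = DEFAULT_INPUT_SIZE) -> np.ndarray:
    """Binary mask resized with nearest-neighbour, re-binarized to {0, 1}."""
    if isinstance(label, (str, Path)):
        try:
            with Image.open(label) as im:
                arr = np.asarray(im.convert("L"))
        except Exception as exc:
            raise ValueError(f"cannot read label {label}: {exc}") from exc
        binary = arr > LABEL_THRESHOLD
    else:
        arr = np.asarray(label)
        binary = arr > (LABEL_THRESHOLD if arr.dtype == np.uint8
                        and arr.max() > 1 else 0.5)
    if binary.shape != (size, size):
        im = Image.fromarray(binary.astype(np.uint8))
        im = im.resize((size, size), Image.NEAREST)
        binary = np.asarray(im) > 0
    return binary.astype(np.uint8)


# ---------------------------------------------------------------------------
# manifests and window assembly
# ---------------------------------------------------------------------------

def load_manifest(path: Union[str, Path]) -> List[ClipRecord]:
    """Read a clip manifest CSV (schema as written by the simulator)."""
    df = pd.read_csv(path)
    clips = []
    for _, row in df.iterrows():
        frames = sorted(str(p) for p in Path(row["frames_dir"]).glob("*.png"))
        labels = sorted(str(p) for p in Path(row["masks_dir"]).glob("*.png"))
        ts = row.get("test_start")
        te = row.get("test_end")
        clips.append(ClipRecord(
            clip_id=str(row["clip_id"]), frame_paths=frames,
            label_paths=labels, frame_rate=float(row["frame_rate"]),
            test_start=None if pd.isna(ts) else int(ts),
            test_end=None if pd.isna(te) else int(te)))
    return clips


def save_manifest(clips: Sequence[ClipRecord], path: Union[str, Path]) -> None:
    rows = []
    for c in clips:
        rows.append({
            "clip_id": c.clip_id,
            "frame_rate": c.frame_rate,
            "n_frames": c.n_frames,
            "frames_dir": str(Path(c.frame_paths[0]).parent),
            "masks_dir": str(Path(c.label_paths[0]).parent),
            "test_start": c.test_start,
            "test_end": c.test_end,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def subset_windows(frames: Sequence, labels: Sequence, indices: np.ndarray,
                   n: int) -> List[FrameWindow]:
    """Pad one split subset and extract its windows (leakage-free)."""
    sub_f = [frames[i] for i in indices]
    sub_l = [labels[i] for i in indices]
    return extract_windows(pad_subset(sub_f, n), sub_l, n)


def clip_windows(clip: ClipRecord, n: int, size: int = DEFAULT_INPUT_SIZE,
                 subset: str = "all") -> List[FrameWindow]:
    """Load, preprocess and window one clip (``subset``: train/test/all)."""
    frames = [preprocess(p, size) for p in clip.frame_paths]
    labels = [preprocess_label(p, size) for p in clip.label_paths]
    if subset == "all":
        idx = np.arange(clip.n_frames)
    elif subset == "train":
        idx = clip.train_indices()
    elif subset == "test":
        idx = clip.test_indices()
    else:
        raise ValueError(f"unknown subset {subset!r}")
    return subset_windows(frames, labels, idx, n)


def dataset_windows(clips: Sequence[ClipRecord], n: int,
                    size: int = DEFAULT_INPUT_SIZE,
                    subset: str = "train") -> Tuple[np.ndarray, np.ndarray]:
    """Pooled window arrays over all clips for one split."""
    windows: List[FrameWindow] = []
    for clip in clips:
        windows.extend(clip_windows(clip, n, size, subset))
    if not windows:
        raise ValueError(f"no {subset} windows in the given clips")
    return windows_to_arrays(windows)
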