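"""Manifest/image I/O, preprocessing, and stratified splitting.

A dataset is a CSV manifest listing image paths and binary labels; images
are decoded, converted to RGB, bilinearly resized to the working
resolution (256x256 by default) and scaled to [0, 1].  Splitting is
stratified: every part preserves the global class proportions to within
one sample per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

__all__ = [
    "DatasetManifest",
    "SplitPlan",
    "load_manifest",
    "load_and_preprocess",
    "preprocess_array",
    "stratified_split",
]

TARGET_SIZE = (256, 256)


@dataclass
class DatasetManifest:
    """Image paths with binary labels (and an optional group tag column)."""

    records: pd.DataFrame  # columns: path, label[, group]

    def __post_init__(self) -> None:
        required = {"path", "label"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"manifest needs columns {sorted(required)}")
        labels = self.records["label"].to_numpy()
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if np.unique(labels).size < 2:
            raise ValueError("manifest must contain both classes")

    @property
    def labels(self) -> np.ndarray:
        return self.records["label"].to_numpy().astype(int)

    @property
    def class_counts(self) -> dict[int, int]:
        return self.records["label"].value_counts().to_dict()

    def __len__(self) -> int:
        return len(self.records)


def load_manifest(path: str | Path, root: str | Path | None = None) -> DatasetManifest:
    """Read a CSV manifest; relative image paths resolve against ``root``
    (defaults to the manifest's directory)."""
    path = Path(path)
    frame = pd.read_csv(path)
    if "filename" in frame.columns and "path" not in frame.columns:
        frame = frame.rename(columns={"filename": "path"})
    root = Path(root) if root is not None else path.parent
    frame["path"] = [str(root / p) if not Path(p).is_absolute() else p for p in frame["path"]]
    return DatasetManifest(frame)


def load_and_preprocess(
    manifest: DatasetManifest, target_size: tuple[int, int] = TARGET_SIZE
) -> tuple[np.ndarray, np.ndarray]:
    """Decode, resize and normalize every image in the manifest.

    Returns an (N, H, W, 3) float array in [0, 1] plus the label vector.
    Grayscale sources are replicated to three identical channels.  A
    per-file error (with the offending path) is raised on unreadable input.
    """
    images = np.empty((len(manifest), *target_size, 3))
    for i, p in enumerate(manifest.records["path"]):
        try:
            with Image.open(p) as img:
                rgb = img.convert("RGB")
        except (OSError, UnidentifiedImageError) as exc:
            raise OSError(f"cannot read image {p!r}: {exc}") from exc
        if rgb.size != (target_size[1], target_size[0]):
            rgb = rgb.resize((target_size[1], target_size[0]), Image.BILINEAR)
        images[i] = np.asarray(rgb, dtype=float) / 255.0
    return images, manifest.labels


def preprocess_array(images: np.ndarray) -> np.ndarray:
    """Scale a uint8 RGB stack to [0, 1]; idempotent on float input
    already in [0, 1]."""
    images = np.asarray(images, dtype=float)
    if images.max(initial=0.0) > 1.0:
        images = images / 255.0
    return np.clip(images, 0.0, 1.0)


@dataclass
class SplitPlan:
    """Disjoint, covering index lists of one stratified partition."""

    parts: dict[str, np.ndarray]
    seed: int
    fractions: dict[str, float] = field(default_factory=dict)

    @property
    def train(self) -> np.ndarray:
        return self.parts["train"]

    @property
    def test(self) -> np.ndarray:
        return self.parts["test"]


def stratified_split(
    labels: np.ndarray,
    fractions: dict[str, float] | None = None,
    seed: int = 0,
) -> SplitPlan:
    """Stratified random partition of ``range(len(labels))``.

    ``fractions`` maps part names to fractions summing to 1 (default the
    80/20 train/test split).  Within each class, indices are shuffled and
    cut at the rounded cumulative fractions, so per-part class proportions
    match the global ones to within one sample.  Deterministic given
    ``seed``; distinct seeds give distinct shuffles.
    """
    labels = np.asarray(labels).astype(int)
    fractions = fractions or {"train": 0.8, "test": 0.2}
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    names = list(fractions)
    parts: dict[str, list[int]] = {name: [] for name in names}
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < len(names):
            raise ValueError(f"class {cls} too small to stratify into {len(names)} parts")
        rng.shuffle(idx)
        bounds = np.round(np.cumsum([fractions[n] for n in names]) * len(idx)).astype(int)
        bounds[-1] = len(idx)
        start = 0
        for name, stop in zip(names, bounds):
            if stop <= start:
                raise ValueError(f"class {cls} too small for part {name!r}")
            parts[name].extend(idx[start:stop])
            start = stop
    arrays = {name: np.sort(np.array(ix)) for name, ix in parts.items()}
    return SplitPlan(parts=arrays, seed=seed, fractions=dict(fractions))
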