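"""Loading, exporting and splitting labeled patch sets.

A patch set is a directory of small PNG/JPEG images plus a manifest CSV
with columns ``path,label``; labels come from the three-class
vocabulary {stubble, soil_leaves, film}.  Images are converted to 8-bit
grayscale with the ITU-R BT.601 luma weights (0.299 R + 0.587 G +
0.114 B) and are expected to be 10x20 pixels unless resizing is
requested.  The train/test split is stratified 8:2 and seeded.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path as FilePath
from typing import Sequence

import numpy as np
from PIL import Image

from .patch import PATCH_SHAPE, Patch

__all__ = [
    "LABELS",
    "LabeledPatchSet",
    "SplitIndices",
    "load_patchset",
    "save_patchset",
    "split_8_2",
]

#: The three-class label vocabulary.
LABELS = ("stubble", "soil_leaves", "film")


@dataclass
class LabeledPatchSet:
    """Parallel lists of patches, class labels and provenance ids."""

    patches: list[Patch]
    labels: list[str]
    ids: list[str]

    def __post_init__(self) -> None:
        if not (len(self.patches) == len(self.labels) == len(self.ids)):
            raise ValueError("patches, labels and ids must have equal length")
        bad = sorted(set(self.labels) - set(LABELS))
        if bad:
            raise ValueError(f"unknown labels {bad}; expected one of {LABELS}")

    def __len__(self) -> int:
        return len(self.patches)

    def subset(self, indices: Sequence[int]) -> "LabeledPatchSet":
        return LabeledPatchSet(
            [self.patches[i] for i in indices],
            [self.labels[i] for i in indices],
            [self.ids[i] for i in indices],
        )


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint, exhaustive train/test index lists of a stratified split."""

    train: tuple[int, ...]
    test: tuple[int, ...]
    seed: int


def _to_gray(img: Image.Image) -> np.ndarray:
    if img.mode != "L":
        img = img.convert("L")  # Pillow's L uses the BT.601 luma weights
    return np.asarray(img, dtype=np.int64)


def load_patchset(
    manifest: str | FilePath,
    expected_shape: tuple[int, int] | None = PATCH_SHAPE,
    resize: bool = False,
) -> LabeledPatchSet:
    """Read a ``path,label`` manifest CSV into a labeled patch set.

    Image paths are resolved relative to the manifest's directory.
    Off-geometry images are rejected unless ``resize`` is set, in which
    case they are resampled (bilinear) to ``expected_shape``.
    """
    manifest = FilePath(manifest)
    root = manifest.parent
    patches: list[Patch] = []
    labels: list[str] = []
    ids: list[str] = []
    with open(manifest, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"path", "label"} <= set(reader.fieldnames):
            raise ValueError(f"{manifest}: manifest must have 'path' and 'label' columns")
        for lineno, row in enumerate(reader, start=2):
            path, label = row.get("path"), row.get("label")
            if not path or not label:
                raise ValueError(f"{manifest}:{lineno}: malformed row {row!r}")
            if label not in LABELS:
                raise ValueError(
                    f"{manifest}:{lineno}: unknown label {label!r}; expected {LABELS}"
                )
            img_path = root / path
            if not img_path.exists():
                raise FileNotFoundError(f"{manifest}:{lineno}: missing image {img_path}")
            img = Image.open(img_path)
            if expected_shape is not None and img.size != expected_shape[::-1]:
                if not resize:
                    raise ValueError(
                        f"{manifest}:{lineno}: image {path} is "
                        f"{img.size[1]}x{img.size[0]}, expected "
                        f"{expected_shape[0]}x{expected_shape[1]} (set resize=True)"
                    )
                img = img.resize(expected_shape[::-1], Image.BILINEAR)
            patches.append(Patch(_to_gray(img)))
            labels.append(label)
            ids.append(path)
    return LabeledPatchSet(patches, labels, ids)


def save_patchset(dataset: LabeledPatchSet, outdir: str | FilePath,
                  manifest_name: str = "manifest.csv") -> FilePath:
    """Export patches as PNGs plus a manifest CSV; returns the manifest path."""
    outdir = FilePath(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (patch, label) in enumerate(zip(dataset.patches, dataset.labels)):
        name = f"{label}_{i:05d}.png"
        Image.fromarray(patch.pixels.astype(np.uint8), mode="L").save(outdir / name)
        rows.append((name, label))
    manifest = outdir / manifest_name
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label"])
        writer.writerows(rows)
    return manifest


def split_8_2(dataset: LabeledPatchSet, seed: int = 0,
              test_fraction: float = 0.2, min_per_class: int = 5) -> SplitIndices:
    """Stratified seeded 8:2 split.

    Per class, ``round(test_fraction * n_class)`` samples go to the test
    set after a seeded shuffle; the remainder train.
    """
    labels = np.asarray(dataset.labels)
    rng = np.random.default_rng(seed)
    train: list[int] = []
    test: list[int] = []
    for label in LABELS:
        idx = np.flatnonzero(labels == label)
        if idx.size == 0:
            continue
        if idx.size < min_per_class:
            raise ValueError(
                f"class {label!r} has {idx.size} samples; need at least {min_per_class}"
            )
        perm = rng.permutation(idx)
        n_test = int(round(test_fraction * idx.size))
        test.extend(int(i) for i in perm[:n_test])
        train.extend(int(i) for i in perm[n_test:])
    return SplitIndices(train=tuple(sorted(train)), test=tuple(sorted(test)), seed=seed)
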