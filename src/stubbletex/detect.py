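"""Block-scanning detection of stubble inside a region of interest.

The detector tiles a fixed ROI (default 100x200 pixels, the band of
stubble row facing the camera) into classifier-sized blocks (10x20),
classifies every block independently with a trained patch classifier,
and reports the blocks labeled stubble.  Scanning runs row by row,
block by block, top-to-bottom then left-to-right; the stride defaults
to the block size (non-overlapping tiling) and can be reduced for
denser scans.  Detected blocks are framed in red on an annotated copy
of the image.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .classify import TrainedModel, predict
from .patch import PATCH_SHAPE, Patch

__all__ = ["ROI", "Detection", "scan_roi", "annotate", "save_detections"]

#: Annotation stroke color (RGB) and width in pixels.
RED = (255, 0, 0)
STROKE = 1


@dataclass(frozen=True)
class ROI:
    """A rectangular detection window inside a source image."""

    top: int = 0
    left: int = 0
    height: int = 100
    width: int = 200

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("ROI height and width must be positive")
        if self.top < 0 or self.left < 0:
            raise ValueError("ROI offsets must be non-negative")

    def validate_within(self, image: np.ndarray) -> None:
        h, w = image.shape[:2]
        if self.top + self.height > h or self.left + self.width > w:
            raise ValueError(
                f"ROI {self} exceeds the {h}x{w} image bounds"
            )


@dataclass(frozen=True)
class Detection:
    """One classified block within the ROI (offsets relative to the ROI)."""

    row: int
    col: int
    height: int
    width: int
    label: str
    score: float | None = None


def scan_roi(
    image: np.ndarray,
    roi: ROI,
    model: TrainedModel | None,
    feature_fn: Callable[[Patch], object],
    block_h: int = PATCH_SHAPE[0],
    block_w: int = PATCH_SHAPE[1],
    stride_r: int | None = None,
    stride_c: int | None = None,
    keep: str | None = "stubble",
    levels: int = 256,
    classify_fn: Callable[[Patch], str] | None = None,
) -> list[Detection]:
    """Classify every block of the ROI; return the stubble-positive ones.

    Blocks are enumerated top-to-bottom, left-to-right.  ``feature_fn``
    maps a block :class:`Patch` to its feature vector (anything with a
    ``values`` attribute, or a plain array).  With ``keep=None`` every
    block's detection is returned regardless of label.  ``classify_fn``
    substitutes an arbitrary per-block labeling function for the model
    (used for oracle pipelines in testing).
    """
    roi.validate_within(image)
    if block_h > roi.height or block_w > roi.width:
        raise ValueError("ROI is smaller than one block")
    if model is None and classify_fn is None:
        raise ValueError("either a trained model or classify_fn is required")
    stride_r = block_h if stride_r is None else stride_r
    stride_c = block_w if stride_c is None else stride_c
    if stride_r < 1 or stride_c < 1:
        raise ValueError("strides must be positive")

    window = np.asarray(image)[
        roi.top : roi.top + roi.height, roi.left : roi.left + roi.width
    ]
    positions = [
        (r, c)
        for r in range(0, roi.height - block_h + 1, stride_r)
        for c in range(0, roi.width - block_w + 1, stride_c)
    ]
    blocks = [Patch(window[r : r + block_h, c : c + block_w], levels=levels)
              for r, c in positions]

    if classify_fn is not None:
        labels = [classify_fn(b) for b in blocks]
        scores = [None] * len(blocks)
    else:
        feats = []
        for block in blocks:
            fv = feature_fn(block)
            feats.append(getattr(fv, "values", fv))
        feats = np.asarray(feats, dtype=np.float64)
        labels = list(predict(model, feats))
        if hasattr(model.pipeline, "predict_proba"):
            proba = model.pipeline.predict_proba(feats)
            cls = list(model.pipeline.classes_)
            scores = [float(p[cls.index(lab)]) for p, lab in zip(proba, labels)]
        else:
            scores = [None] * len(blocks)

    detections = [
        Detection(row=r, col=c, height=block_h, width=block_w,
                  label=lab, score=sc)
        for (r, c), lab, sc in zip(positions, labels, scores)
    ]
    if keep is not None:
        detections = [d for d in detections if d.label == keep]
    return detections


def annotate(image: np.ndarray, detections: Sequence[Detection],
             roi: ROI | None = None) -> np.ndarray:
    """Draw red rectangles at detection boxes on an RGB copy of the image.

    Detection offsets are relative to ``roi`` when given, absolute
    otherwise.  The source image is never modified.
    """
    img = np.asarray(image)
    if img.ndim == 2:
        out = np.stack([img] * 3, axis=-1).astype(np.uint8)
    else:
        out = img.astype(np.uint8).copy()
    h, w = out.shape[:2]
    dr = roi.top if roi is not None else 0
    dc = roi.left if roi is not None else 0
    for det in detections:
        r0, c0 = det.row + dr, det.col + dc
        r1, c1 = r0 + det.height, c0 + det.width
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            raise ValueError(f"detection box {det} is out of the image bounds")
        out[r0 : r0 + STROKE, c0:c1] = RED
        out[r1 - STROKE : r1, c0:c1] = RED
        out[r0:r1, c0 : c0 + STROKE] = RED
        out[r0:r1, c1 - STROKE : c1] = RED
    return out


def save_detections(detections: Sequence[Detection], path) -> None:
    """Export detections as CSV (roi_row, roi_col, label, score)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["roi_row", "roi_col", "label", "score"])
        for det in detections:
            writer.writerow([det.row, det.col, det.label,
                             "" if det.score is None else f"{det.score:.6f}"])
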