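"""Core containers: gray-level patches and named feature vectors.

A :class:`Patch` is the unit of classification: a small 2-D block of
integer gray levels cut from a field image (default geometry 10 rows by
20 columns, 256 gray levels).  A :class:`FeatureVector` is an ordered
real-valued descriptor whose layout records, per entry, which statistic
of which source (original image or a wavelet sub-band) at which scan
angle produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Patch", "FeatureVector", "requantize"]

#: Default patch geometry: rows, columns.
PATCH_SHAPE = (10, 20)

#: Default number of gray levels.
GRAY_LEVELS = 256


@dataclass(frozen=True)
class Patch:
    """A 2-D block of integer gray levels in ``[0, levels - 1]``.

    Parameters
    ----------
    pixels
        2-D integer array of gray levels.
    levels
        Number of gray levels the pixel values are drawn from
        (default 256).
    """

    pixels: np.ndarray
    levels: int = GRAY_LEVELS

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("patch pixels must be a non-empty 2-D array")
        if not np.issubdtype(px.dtype, np.integer):
            if not np.all(px == np.round(px)):
                raise ValueError("patch pixels must be integer gray levels")
            px = px.astype(np.int64)
        if self.levels < 2:
            raise ValueError("a patch needs at least 2 gray levels")
        if px.min() < 0 or px.max() >= self.levels:
            raise ValueError(
                f"pixel values must lie in [0, {self.levels - 1}]; "
                f"got range [{px.min()}, {px.max()}]"
            )
        object.__setattr__(self, "pixels", px.astype(np.int64))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def requantize(patch: Patch, levels: int) -> Patch:
    """Uniformly rebin a patch's gray levels to a coarser scale.

    Each source level ``g`` maps to ``floor(g * levels / patch.levels)``,
    which partitions the source range into ``levels`` equal bins.  Used
    to tame the sparsity of a 256-level co-occurrence matrix on a
    200-pixel patch.
    """
    if levels < 2:
        raise ValueError("need at least 2 target levels")
    if levels >= patch.levels:
        return patch
    rebinned = (patch.pixels * levels) // patch.levels
    return Patch(rebinned, levels=levels)


@dataclass(frozen=True)
class FeatureVector:
    """Ordered real feature values with a parallel label layout.

    ``layout[i]`` is a ``(source, statistic, angle)`` triple naming entry
    ``i``: the source is ``"original"`` or a wavelet sub-band tag such as
    ``"coif3:V"``; the angle is in degrees, or ``None`` for angle-free
    features (e.g. LBP histogram bins).
    """

    values: np.ndarray
    layout: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64).ravel()
        layout = tuple(self.layout)
        if len(layout) != vals.size:
            raise ValueError(
                f"layout length {len(layout)} != value count {vals.size}"
            )
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "layout", layout)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def names(self) -> list[str]:
        """Flat column names, e.g. ``original/con/90``."""
        out = []
        for source, stat, angle in self.layout:
            tail = "" if angle is None else f"/{angle}"
            out.append(f"{source}/{stat}{tail}")
        return out

    def concat(self, other: "FeatureVector") -> "FeatureVector":
        return FeatureVector(
            np.concatenate([self.values, other.values]),
            self.layout + other.layout,
        )
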