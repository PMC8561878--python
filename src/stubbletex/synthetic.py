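"""Seeded synthetic texture patches and composite field scenes.

No public set of labeled cotton-field patches exists, so the generator
emulates the three texture classes the detection task distinguishes:

* ``stubble`` — vertically striated, high-contrast texture: upright
  stalk remnants photographed against darker ground produce strong
  intensity changes across the image columns, hence strong
  vertical-detail (HL) energy after a wavelet decomposition;
* ``soil_leaves`` — isotropic speckle: soil and shredded leaves have
  grain at the pixel scale with no preferred orientation;
* ``film`` — residual plastic mulch film: a bright, smooth, low-
  variance surface.

Three separability levels control how much noise corrupts the class
signal: ``easy`` is near-noiseless, ``medium`` adds realistic grain,
and ``hard`` additionally tilts the stubble striation (a tractor
driving obliquely tips the stalks in the image) and blurs the patch
(camera shake).  All outputs are deterministic functions of the
configuration and seed.

A :class:`SyntheticField` composites the same textures into a full
camera frame (default 480x640) with vertical stubble row bands and
optional film bands over a soil background, together with a
block-level ground-truth label grid for scoring a block-scanning
detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, rotate

from .dataset import LABELS, LabeledPatchSet
from .patch import GRAY_LEVELS, PATCH_SHAPE, Patch

__all__ = [
    "SynthConfig",
    "FieldLayout",
    "SyntheticField",
    "generate_patch",
    "generate_dataset",
    "generate_field",
]

#: Noise scale (gray levels) per separability setting.
_NOISE_SIGMA = {"easy": 2.0, "medium": 14.0, "hard": 26.0}

#: Stubble striation tilt (degrees) and blur sigma per separability.
_TILT_DEG = {"easy": 0.0, "medium": 0.0, "hard": 12.0}
_BLUR_SIGMA = {"easy": 0.0, "medium": 0.0, "hard": 0.8}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic texture classes.

    All intensities are on the 8-bit gray scale.  The stubble stripes
    alternate between ``stripe_low`` and ``stripe_high`` with the given
    period in pixels; soil speckle is zero-mean grain of the given
    standard deviation around ``soil_level``; film is near-constant at
    ``film_level``.
    """

    patch_h: int = PATCH_SHAPE[0]
    patch_w: int = PATCH_SHAPE[1]
    n_per_class: int = 350
    separability: str = "medium"
    seed: int = 0
    levels: int = GRAY_LEVELS
    stripe_period: int = 4
    stripe_low: int = 60
    stripe_high: int = 190
    soil_level: int = 110
    soil_grain_sigma: float = 35.0
    film_level: int = 225
    film_smoothness: float = 4.0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be at least 1")
        if self.separability not in _NOISE_SIGMA:
            raise ValueError(
                f"separability must be one of {sorted(_NOISE_SIGMA)}"
            )
        for name in ("stripe_low", "stripe_high", "soil_level", "film_level"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name}={v} outside [0, 255]")


def _finish(raw: np.ndarray, cfg: SynthConfig, rng: np.random.Generator,
            noise: bool = True) -> Patch:
    """Add class-independent sensor noise, clip and quantize."""
    out = raw.astype(np.float64)
    if noise:
        out = out + rng.normal(0.0, _NOISE_SIGMA[cfg.separability], out.shape)
    blur = _BLUR_SIGMA[cfg.separability]
    if blur > 0:
        out = gaussian_filter(out, blur)
    out = np.clip(np.floor(out + 0.5), 0, cfg.levels - 1)
    return Patch(out.astype(np.int64), levels=cfg.levels)


def _stubble_texture(shape: tuple[int, int], cfg: SynthConfig,
                     rng: np.random.Generator, col_phase: int = 0) -> np.ndarray:
    """Vertical square-wave stripes with per-stalk amplitude jitter."""
    h, w = shape
    cols = np.arange(w) + col_phase
    stripe = ((cols // (cfg.stripe_period // 2)) % 2).astype(np.float64)
    base = cfg.stripe_low + stripe * (cfg.stripe_high - cfg.stripe_low)
    img = np.tile(base, (h, 1))
    # slight per-column brightness jitter so stalks are not identical
    img = img + rng.normal(0.0, 6.0, (1, w))
    tilt = _TILT_DEG[cfg.separability]
    if tilt:
        img = rotate(img, tilt, reshape=False, mode="nearest", order=1)
    return img


def _soil_texture(shape: tuple[int, int], cfg: SynthConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Isotropic speckle: white grain, very lightly smoothed."""
    img = cfg.soil_level + rng.normal(0.0, cfg.soil_grain_sigma, shape)
    return gaussian_filter(img, 0.5)


def _film_texture(shape: tuple[int, int], cfg: SynthConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Bright, smooth sheet with a faint large-scale undulation."""
    img = cfg.film_level + gaussian_filter(
        rng.normal(0.0, cfg.film_smoothness, shape), 2.0
    )
    return img


_TEXTURES = {
    "stubble": _stubble_texture,
    "soil_leaves": _soil_texture,
    "film": _film_texture,
}


def generate_patch(class_label: str, cfg: SynthConfig = SynthConfig(),
                   seed: int | None = None, noise: bool = True) -> Patch:
    """One synthetic patch of the requested class; deterministic per seed.

    With ``noise=False`` the class-independent sensor noise is omitted
    (a zero-noise film patch is exactly constant; zero-noise stubble is
    columnwise-constant stripes).
    """
    if class_label not in _TEXTURES:
        raise ValueError(f"unknown class {class_label!r}; expected one of {LABELS}")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    shape = (cfg.patch_h, cfg.patch_w)
    if class_label == "stubble":
        phase = int(rng.integers(cfg.stripe_period))
        if noise:
            raw = _stubble_texture(shape, cfg, rng, col_phase=phase)
        else:
            # exact columnwise stripes, no per-stalk jitter
            cols = np.arange(cfg.patch_w) + phase
            stripe = ((cols // (cfg.stripe_period // 2)) % 2).astype(np.float64)
            raw = np.tile(cfg.stripe_low + stripe * (cfg.stripe_high - cfg.stripe_low),
                          (cfg.patch_h, 1))
    elif class_label == "film" and not noise:
        raw = np.full(shape, float(cfg.film_level))
    else:
        raw = _TEXTURES[class_label](shape, cfg, rng)
    return _finish(raw, cfg, rng, noise=noise)


def generate_dataset(cfg: SynthConfig = SynthConfig()) -> LabeledPatchSet:
    """``n_per_class`` seeded patches of each of the three classes."""
    patches: list[Patch] = []
    labels: list[str] = []
    ids: list[str] = []
    # one independent child seed per patch, derived from the master seed
    seeds = np.random.SeedSequence(cfg.seed).generate_state(3 * cfg.n_per_class)
    k = 0
    for label in LABELS:
        for i in range(cfg.n_per_class):
            patches.append(generate_patch(label, cfg, seed=int(seeds[k] % (2**31))))
            labels.append(label)
            ids.append(f"synthetic/{label}/{i:05d}")
            k += 1
    return LabeledPatchSet(patches, labels, ids)


@dataclass(frozen=True)
class FieldLayout:
    """Column bands of a synthetic field scene.

    Bands are half-open column intervals ``[start, stop)`` in pixels;
    anything not covered by a stubble or film band is soil background.
    """

    image_h: int = 480
    image_w: int = 640
    stubble_bands: tuple[tuple[int, int], ...] = ((260, 380),)
    film_bands: tuple[tuple[int, int], ...] = ((40, 140), (500, 600))

    def __post_init__(self) -> None:
        spans = sorted(
            [(a, b, "stubble") for a, b in self.stubble_bands]
            + [(a, b, "film") for a, b in self.film_bands]
        )
        prev_end = 0
        for a, b, kind in spans:
            if a < 0 or b > self.image_w or a >= b:
                raise ValueError(f"{kind} band ({a}, {b}) does not fit the image")
            if a < prev_end:
                raise ValueError(f"overlapping layout declarations at column {a}")
            prev_end = b

    def label_at(self, col: int) -> str:
        for a, b in self.stubble_bands:
            if a <= col < b:
                return "stubble"
        for a, b in self.film_bands:
            if a <= col < b:
                return "film"
        return "soil_leaves"


@dataclass(frozen=True)
class SyntheticField:
    """A composite field image with block-level ground truth.

    ``mask[r, c]`` labels the 10x20 block whose top-left pixel is
    ``(r * block_h, c * block_w)``; blocks straddling a band boundary
    take the label of their centre column.
    """

    image: np.ndarray
    mask: np.ndarray
    layout: FieldLayout
    block_shape: tuple[int, int] = PATCH_SHAPE


def generate_field(cfg: SynthConfig = SynthConfig(),
                   layout: FieldLayout = FieldLayout(),
                   seed: int | None = None) -> SyntheticField:
    """Composite the class textures into a full frame plus truth mask.

    Stripe phase is a function of the absolute column, so stubble
    striation is continuous across block boundaries — a block cut from
    anywhere inside a stubble band contains stripe texture by
    construction.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    h, w = layout.image_h, layout.image_w
    img = _soil_texture((h, w), cfg, rng)
    for a, b in layout.stubble_bands:
        img[:, a:b] = _stubble_texture((h, b - a), cfg, rng, col_phase=a)
    for a, b in layout.film_bands:
        img[:, a:b] = _film_texture((h, b - a), cfg, rng)
    image = _finish(img, cfg, rng).pixels

    bh, bw = PATCH_SHAPE
    mask = np.empty((h // bh, w // bw), dtype=object)
    for bc in range(w // bw):
        center_col = bc * bw + bw // 2
        mask[:, bc] = layout.label_at(center_col)
    return SyntheticField(image=image, mask=mask, layout=layout)
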