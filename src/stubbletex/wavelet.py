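"""Single-level 2-D wavelet decomposition, sub-band features and base screening.

One level of separable 2-D DWT splits a patch into four orthogonal
sub-band coefficient arrays: the approximation A (LL) and the
horizontal / vertical / diagonal details H (LH), V (HL), D (HH).
Texture statistics computed on a quantized sub-band extend the
original-image descriptor; concatenating the original-image GLCM vector
with the GLCM vector of one selected sub-band gives the 48-dimensional
fusion feature.

The candidate wavelet bases are the 22 workhorse orthogonal families
used for this kind of screening: Daubechies db1-db10, Symlets sym2-sym8
and Coiflets coif1-coif5.  Which base and sub-band to fuse is decided
empirically by :func:`screen_wavelet_bases`: every (base, sub-band)
pair is scored by cross-validated classification accuracy of its
sub-band GLCM features, and pairs above an accuracy threshold (0.7 by
default) are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pywt

from .patch import FeatureVector, Patch
from .texture import glcm_feature_vector

__all__ = [
    "WAVELET_BASES",
    "SUBBANDS",
    "WaveletSpec",
    "SubbandSet",
    "FusionConfig",
    "dwt2",
    "idwt2",
    "quantize_subband",
    "fusion_feature",
    "screen_wavelet_bases",
    "screening_report",
]

#: The 22-base candidate set.
WAVELET_BASES = tuple(
    [f"db{i}" for i in range(1, 11)]
    + [f"sym{i}" for i in range(2, 9)]
    + [f"coif{i}" for i in range(1, 6)]
)

#: Sub-band tags: approximation plus horizontal/vertical/diagonal detail.
SUBBANDS = ("A", "H", "V", "D")


@dataclass(frozen=True)
class WaveletSpec:
    """A named wavelet base for single-level decomposition."""

    name: str = "coif3"
    level: int = 1
    boundary_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.name not in WAVELET_BASES:
            raise ValueError(
                f"unknown wavelet base {self.name!r}; valid bases: "
                + ", ".join(WAVELET_BASES)
            )
        if self.level != 1:
            raise ValueError("only single-level decomposition is supported")


@dataclass(frozen=True)
class SubbandSet:
    """The four single-level DWT coefficient arrays of one patch.

    H/V/D follow the LH/HL/HH correspondence: H holds horizontal detail
    (vertical frequency content), V vertical detail, D diagonal detail.
    """

    A: np.ndarray
    H: np.ndarray
    V: np.ndarray
    D: np.ndarray
    source_shape: tuple[int, int]
    spec: WaveletSpec

    def band(self, tag: str) -> np.ndarray:
        if tag not in SUBBANDS:
            raise ValueError(f"sub-band must be one of {SUBBANDS}, got {tag!r}")
        return getattr(self, tag)


@dataclass(frozen=True)
class FusionConfig:
    """Which wavelet base and sub-band to fuse with the original features."""

    base: WaveletSpec = field(default_factory=lambda: WaveletSpec("coif3"))
    subband: str = "V"
    distance: int = 1

    def __post_init__(self) -> None:
        if self.subband not in SUBBANDS:
            raise ValueError(f"sub-band must be one of {SUBBANDS}")


def dwt2(patch: Patch, spec: WaveletSpec = WaveletSpec()) -> SubbandSet:
    """One level of separable 2-D DWT with dyadic downsampling."""
    if patch.height < 2 or patch.width < 2:
        raise ValueError("patch must be at least 2x2 for a 2-D decomposition")
    a, (h, v, d) = pywt.dwt2(
        patch.pixels.astype(np.float64), spec.name, mode=spec.boundary_mode
    )
    # pywt returns (cA, (cH, cV, cD)) where cH is the LH band (horizontal
    # detail) and cV the HL band (vertical detail).
    return SubbandSet(A=a, H=h, V=v, D=d, source_shape=patch.shape, spec=spec)


def idwt2(bands: SubbandSet) -> np.ndarray:
    """Inverse transform; reconstructs the source patch (trimmed to its shape)."""
    rec = pywt.idwt2(
        (bands.A, (bands.H, bands.V, bands.D)),
        bands.spec.name,
        mode=bands.spec.boundary_mode,
    )
    h, w = bands.source_shape
    return rec[:h, :w]


def quantize_subband(coeffs: np.ndarray, levels: int = 256) -> Patch:
    """Linearly rescale real coefficients to integer gray levels.

    Min-max affine map onto ``[0, levels - 1]`` with round-half-up via
    ``floor(x + 0.5)``; a constant array maps to all zeros.
    """
    arr = np.atleast_2d(np.asarray(coeffs, dtype=np.float64))
    if arr.size == 0:
        raise ValueError("empty coefficient array")
    if levels < 2:
        raise ValueError("need at least 2 gray levels")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return Patch(np.zeros(arr.shape, dtype=np.int64), levels=levels)
    scaled = np.floor((arr - lo) / (hi - lo) * (levels - 1) + 0.5).astype(np.int64)
    return Patch(np.clip(scaled, 0, levels - 1), levels=levels)


def subband_patch(patch: Patch, spec: WaveletSpec, subband: str,
                  levels: int = 256) -> Patch:
    """Decompose, select one sub-band and quantize it to gray levels."""
    return quantize_subband(dwt2(patch, spec).band(subband), levels=levels)


def fusion_feature(patch: Patch, cfg: FusionConfig = FusionConfig()) -> FeatureVector:
    """48-dim fusion descriptor: original GLCM ++ sub-band GLCM.

    The first 24 entries are the original patch's GLCM vector; the last
    24 are the GLCM vector of the selected sub-band after quantization
    back to the patch's gray scale.  Layout labels record the source of
    every entry.
    """
    original = glcm_feature_vector(patch, distance=cfg.distance, source="original")
    band = subband_patch(patch, cfg.base, cfg.subband, levels=patch.levels)
    extra = glcm_feature_vector(
        band, distance=cfg.distance, source=f"{cfg.base.name}:{cfg.subband}"
    )
    return original.concat(extra)


def _subband_features(patches: Sequence[Patch], spec: WaveletSpec,
                      subband: str) -> np.ndarray:
    return np.array(
        [glcm_feature_vector(subband_patch(p, spec, subband)).values for p in patches]
    )


def screening_report(
    patches: Sequence[Patch],
    labels: Sequence[str],
    bases: Sequence[WaveletSpec] | None = None,
    model_spec=None,
    folds: int = 10,
    seed: int = 0,
    threshold: float = 0.7,
):
    """Cross-validated accuracy of every (base, sub-band) GLCM feature set.

    Returns a DataFrame with one row per (base, sub-band) pair —
    88 rows for the full 22-base set — holding the tenfold-CV accuracy
    of the classifier on that sub-band's 24-dim GLCM features and a
    flag marking pairs above the accuracy threshold.
    """
    import pandas as pd

    from .classify import ModelSpec, evaluate_cv

    if bases is None:
        bases = [WaveletSpec(name) for name in WAVELET_BASES]
    bases = list(bases)
    if not bases:
        raise ValueError("empty wavelet base list")
    if len(set(labels)) < 2:
        raise ValueError("screening needs at least 2 classes")
    if model_spec is None:
        model_spec = ModelSpec(family="BPNN", seed=seed)

    rows = []
    for spec in bases:
        for subband in SUBBANDS:
            feats = _subband_features(patches, spec, subband)
            report = evaluate_cv(feats, labels, model_spec, folds=folds, seed=seed)
            rows.append(
                {
                    "base": spec.name,
                    "subband": subband,
                    "accuracy": report.Ac,
                    "selected": report.Ac > threshold,
                }
            )
    frame = pd.DataFrame(rows)
    frame.attrs["threshold"] = threshold
    return frame


def screen_wavelet_bases(
    patches: Sequence[Patch],
    labels: Sequence[str],
    bases: Sequence[WaveletSpec] | None = None,
    threshold: float = 0.7,
    model_spec=None,
    folds: int = 10,
    seed: int = 0,
) -> list[tuple[WaveletSpec, str, float]]:
    """Select (base, sub-band) pairs whose CV accuracy exceeds the threshold.

    Returns ``(spec, subband, accuracy)`` triples sorted by descending
    accuracy.
    """
    frame = screening_report(
        patches, labels, bases=bases, model_spec=model_spec,
        folds=folds, seed=seed, threshold=threshold,
    )
    chosen = frame[frame["selected"]].sort_values("accuracy", ascending=False)
    return [
        (WaveletSpec(row.base), row.subband, float(row.accuracy))
        for row in chosen.itertuples()
    ]
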