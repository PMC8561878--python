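"""Hand-computed texture representations: GLCM, GLRLM and rotation-invariant LBP.

Three classical texture descriptions of a gray-level patch:

* the gray-level co-occurrence matrix (GLCM) — frequencies of ordered
  gray-level pairs at a fixed pixel offset (distance ``d``, direction
  ``theta``), summarised by six Haralick-style statistics;
* the gray-level run-length matrix (GLRLM) — counts of maximal runs of
  identical gray level by run length along a scan direction, summarised
  by eleven run statistics;
* the rotation-invariant local binary pattern (LBP) — the per-pixel
  8-bit neighbour-threshold word reduced to its minimum over cyclic bit
  rotations, summarised by per-block code histograms.

All four conventional scan directions {0, 45, 90, 135} degrees are
supported.  The angle-to-offset convention (in (row, col) steps for a
matrix whose row index grows downward) is::

    0   -> ( 0, +d)    scan left-to-right along rows
    45  -> (-d, +d)    up-right diagonal
    90  -> (-d,  0)    up along columns
    135 -> (-d, -d)    up-left diagonal

Pairs are ordered (non-symmetric) by default: the pair (a, b) at offset
+delta is counted once, without also counting its transpose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patch import FeatureVector, Patch

__all__ = [
    "ANGLES",
    "GLCMMatrix",
    "GLCMStats",
    "GLRLMMatrix",
    "GLRLMStats",
    "LBPCodeImage",
    "compute_glcm",
    "glcm_stats",
    "glcm_feature_vector",
    "compute_glrlm",
    "glrlm_stats",
    "glrlm_feature_vector",
    "lbp_ri_codes",
    "lbp_feature_vector",
    "ri_code_table",
]

#: The four scan directions, in degrees.
ANGLES = (0, 45, 90, 135)

#: angle -> (row step, col step) unit offset.
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

GLCM_STAT_NAMES = ("asm", "ent", "cor", "dis", "con", "hom")

GLRLM_STAT_NAMES = (
    "sr", "lr", "gln", "rln", "rr", "lgr", "hgr", "srlg", "srhg", "lrlg", "lrhg",
)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GLCMMatrix:
    """Co-occurrence counts (or probabilities) of gray pairs at one offset."""

    counts: np.ndarray
    k: int
    distance: int
    angle: int
    normalized: bool


@dataclass(frozen=True)
class GLCMStats:
    """The six co-occurrence statistics of a normalized GLCM.

    asm
        angular second moment, sum of squared probabilities; 1 for a
        point mass, 1/k^2 for a uniform matrix.
    ent
        entropy (bits), with 0*log(0) := 0.
    cor
        gray-level correlation between the pair members, computed from
        the marginal means and standard deviations of the normalized
        matrix; defined as 0 when a marginal std is 0 (constant patch).
    dis
        dissimilarity, expected |i - j|.
    con
        contrast, expected (i - j)^2.
    hom
        homogeneity (inverse difference moment), expected 1/(1+(i-j)^2).
    """

    asm: float
    ent: float
    cor: float
    dis: float
    con: float
    hom: float

    def as_array(self) -> np.ndarray:
        return np.array([self.asm, self.ent, self.cor, self.dis, self.con, self.hom])


def _angle_offset(angle: int, distance: int) -> tuple[int, int]:
    if angle not in _ANGLE_OFFSETS:
        raise ValueError(f"angle must be one of {ANGLES}, got {angle}")
    dr, dc = _ANGLE_OFFSETS[angle]
    return dr * distance, dc * distance


def compute_glcm(
    patch: Patch,
    distance: int = 1,
    angle: int = 0,
    normalize: bool = True,
    symmetric: bool = False,
) -> GLCMMatrix:
    """Count ordered gray-level pairs at offset (distance, angle).

    Entry ``(i, j)`` counts pixels of value ``i`` whose offset partner
    has value ``j``.  With ``symmetric=True`` each pair is also counted
    in the transposed position.
    """
    if distance < 1:
        raise ValueError("distance must be a positive integer")
    dr, dc = _angle_offset(angle, distance)
    px = patch.pixels
    h, w = px.shape

    # Clip the array to the region where both pair members exist.
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(
            f"degenerate geometry: no pixel pair at offset ({dr}, {dc}) "
            f"in a {h}x{w} patch"
        )
    first = px[r0:r1, c0:c1]
    second = px[r0 + dr : r1 + dr, c0 + dc : c1 + dc]

    k = patch.levels
    flat = first.ravel() * k + second.ravel()
    counts = np.bincount(flat, minlength=k * k).astype(np.float64).reshape(k, k)
    if symmetric:
        counts = counts + counts.T
    if normalize:
        counts = counts / counts.sum()
    return GLCMMatrix(counts, k=k, distance=distance, angle=angle, normalized=normalize)


def glcm_stats(glcm: GLCMMatrix) -> GLCMStats:
    """The six statistics of a (probability-normalized) co-occurrence matrix.

    The matrix is normalized internally if it holds raw counts.  Entropy
    uses log base 2.  Correlation uses the marginal means/stds of the
    normalized matrix and is defined as 0 when either marginal std
    vanishes (single-gray patch), where the ratio form is 0/0.
    """
    p = np.asarray(glcm.counts, dtype=np.float64)
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero co-occurrence matrix")
    if not glcm.normalized or not np.isclose(total, 1.0, atol=1e-9):
        p = p / total

    k = glcm.k
    # A k x k matrix from an n-pixel patch has at most n nonzero
    # entries; every statistic is a sum over those entries only.
    ni, nj = np.nonzero(p)
    pv = p[ni, nj]
    diff = (ni - nj).astype(np.float64)

    asm = float(np.sum(pv * pv))
    ent = float(-np.sum(pv * np.log2(pv)))
    dis = float(np.sum(pv * np.abs(diff)))
    con = float(np.sum(pv * diff**2))
    hom = float(np.sum(pv / (1.0 + diff**2)))

    pi = np.bincount(ni, weights=pv, minlength=k)
    pj = np.bincount(nj, weights=pv, minlength=k)
    i = np.arange(k, dtype=np.float64)
    ui = float(i @ pi)
    uj = float(i @ pj)
    si = float(np.sqrt(((i - ui) ** 2) @ pi))
    sj = float(np.sqrt(((i - uj) ** 2) @ pj))
    if si <= 0 or sj <= 0:
        cor = 0.0
    else:
        cor = float((np.sum(ni * nj * pv) - ui * uj) / (si * sj))
    return GLCMStats(asm=asm, ent=ent, cor=cor, dis=dis, con=con, hom=hom)


def glcm_feature_vector(
    patch: Patch, distance: int = 1, source: str = "original"
) -> FeatureVector:
    """24-dim GLCM descriptor: 6 statistics at each of the 4 angles.

    Ordering is angle-major (all six statistics at 0 degrees, then 45,
    90, 135).
    """
    values: list[float] = []
    layout: list[tuple] = []
    for angle in ANGLES:
        stats = glcm_stats(compute_glcm(patch, distance=distance, angle=angle))
        values.extend(stats.as_array())
        layout.extend((source, name, angle) for name in GLCM_STAT_NAMES)
    return FeatureVector(np.array(values), tuple(layout))


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GLRLMMatrix:
    """Maximal-run counts by (gray level, run length) along one direction.

    ``runs[g, j-1]`` counts maximal runs of gray value ``g`` with length
    exactly ``j``.  Gray bins are 1-based in the run statistics (gray
    value ``g`` carries weight ``i = g + 1``) so the ``1/i^2`` weights
    are defined for the darkest bin.
    """

    runs: np.ndarray
    angle: int
    levels: int
    n_pixels_scanned: int

    @property
    def total_runs(self) -> int:
        return int(self.runs.sum())


@dataclass(frozen=True)
class GLRLMStats:
    """Eleven run-length statistics (short/long run emphasis, etc.)."""

    sr: float
    lr: float
    gln: float
    rln: float
    rr: float
    lgr: float
    hgr: float
    srlg: float
    srhg: float
    lrlg: float
    lrhg: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.sr, self.lr, self.gln, self.rln, self.rr, self.lgr,
             self.hgr, self.srlg, self.srhg, self.lrlg, self.lrhg]
        )


def _scan_lines(px: np.ndarray, angle: int) -> list[np.ndarray]:
    """The parallel scan lines of a direction, each a 1-D pixel sequence.

    Every pixel lies on exactly one line of its direction, for all four
    directions (the diagonals partition the image into its diagonals).
    """
    h, w = px.shape
    if angle == 0:
        return [px[r, :] for r in range(h)]
    if angle == 90:
        return [px[:, c] for c in range(w)]
    if angle == 45:
        # anti-diagonals (bottom-left to top-right)
        flipped = px[::-1, :]
        return [np.diagonal(flipped, offset=o) for o in range(-(h - 1), w)]
    if angle == 135:
        # main diagonals (top-left to bottom-right); reading order is
        # irrelevant to run statistics.
        return [np.diagonal(px, offset=o) for o in range(-(h - 1), w)]
    raise ValueError(f"angle must be one of {ANGLES}, got {angle}")


def _run_lengths(line: np.ndarray) -> list[tuple[int, int]]:
    """(gray value, run length) for each maximal run in a scan line."""
    if line.size == 0:
        return []
    boundaries = np.flatnonzero(np.diff(line)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [line.size]])
    return [(int(line[s]), int(e - s)) for s, e in zip(starts, ends)]


def compute_glrlm(patch: Patch, angle: int = 0) -> GLRLMMatrix:
    """Count maximal gray-level runs by length along one scan direction.

    Each pixel belongs to exactly one maximal run, so the pixel
    conservation identity ``sum_ij j * Q(i, j) == h * w`` holds for
    every direction.
    """
    px = patch.pixels
    lines = _scan_lines(px, angle)
    max_len = max(line.size for line in lines)
    runs = np.zeros((patch.levels, max_len), dtype=np.int64)
    n_pixels = 0
    for line in lines:
        n_pixels += line.size
        for gray, length in _run_lengths(np.asarray(line)):
            runs[gray, length - 1] += 1
    return GLRLMMatrix(runs, angle=angle, levels=patch.levels, n_pixels_scanned=n_pixels)


def glrlm_stats(glrlm: GLRLMMatrix) -> GLRLMStats:
    """Eleven run statistics of a run-length matrix.

    The run-percentage statistic ``rr`` is the number of runs divided by
    the number of pixels scanned, and the long-run low/high-gray
    statistics weight by ``j^2 / i^2`` and ``j^2 * i^2`` respectively —
    the standard emphasis forms (see the methods note for the rationale
    in repairing two inconsistently printed textbook variants).
    """
    q = np.asarray(glrlm.runs, dtype=np.float64)
    s = q.sum()
    if s <= 0:
        raise ValueError("empty run-length matrix")
    m, n = q.shape
    i = np.arange(1, m + 1, dtype=np.float64)[:, None]  # 1-based gray bins
    j = np.arange(1, n + 1, dtype=np.float64)[None, :]

    sr = float(np.sum(q / j**2) / s)
    lr = float(np.sum(q * j**2) / s)
    gln = float(np.sum(q.sum(axis=1) ** 2) / s)
    rln = float(np.sum(q.sum(axis=0) ** 2) / s)
    rr = float(s / glrlm.n_pixels_scanned)
    lgr = float(np.sum(q / i**2) / s)
    hgr = float(np.sum(q * i**2) / s)
    srlg = float(np.sum(q / (i**2 * j**2)) / s)
    srhg = float(np.sum(q * i**2 / j**2) / s)
    lrlg = float(np.sum(q * j**2 / i**2) / s)
    lrhg = float(np.sum(q * j**2 * i**2) / s)
    return GLRLMStats(sr=sr, lr=lr, gln=gln, rln=rln, rr=rr, lgr=lgr, hgr=hgr,
                      srlg=srlg, srhg=srhg, lrlg=lrlg, lrhg=lrhg)


def glrlm_feature_vector(patch: Patch, source: str = "original") -> FeatureVector:
    """44-dim GLRLM descriptor: 11 statistics at each of the 4 angles."""
    values: list[float] = []
    layout: list[tuple] = []
    for angle in ANGLES:
        stats = glrlm_stats(compute_glrlm(patch, angle=angle))
        values.extend(stats.as_array())
        layout.extend((source, name, angle) for name in GLRLM_STAT_NAMES)
    return FeatureVector(np.array(values), tuple(layout))


# ---------------------------------------------------------------------------
# Rotation-invariant LBP
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LBPCodeImage:
    """Per-pixel rotation-invariant LBP codes of a patch."""

    codes: np.ndarray
    P: int
    R: int


def _min_rotation(code: int, bits: int) -> int:
    best = code
    mask = (1 << bits) - 1
    for shift in range(1, bits):
        rotated = ((code >> shift) | (code << (bits - shift))) & mask
        best = min(best, rotated)
    return best


_RI_TABLE_CACHE: dict[int, np.ndarray] = {}


def ri_code_table(P: int = 8) -> np.ndarray:
    """Lookup table mapping every raw P-bit word to its minimal rotation."""
    if P not in _RI_TABLE_CACHE:
        _RI_TABLE_CACHE[P] = np.array(
            [_min_rotation(c, P) for c in range(1 << P)], dtype=np.int64
        )
    return _RI_TABLE_CACHE[P]


#: The 36 attainable rotation-invariant codes for P=8, ascending.
RI_CODES_P8 = tuple(sorted(set(_min_rotation(c, 8) for c in range(256))))

# Neighbour order for P=8, R=1: counter-clockwise from the east
# neighbour; diagonals sit at the integer corners of the 3x3 box.
_NEIGHBOR_OFFSETS_8 = (
    (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1),
)


def lbp_ri_codes(patch: Patch, P: int = 8, R: int = 1) -> LBPCodeImage:
    """Rotation-invariant LBP code of every pixel.

    Each pixel's P neighbours on the radius-R circle are thresholded at
    the centre value (``>=`` maps to 1), assembled into a P-bit word
    (bit ``i`` for neighbour ``i``), and the word is replaced by its
    minimum over all P cyclic bit rotations.  The patch is edge-
    replicated by R so the code image keeps the patch's full size.
    """
    if P != 8 or R < 1:
        raise ValueError("this implementation samples the 8-neighbour ring (P=8, R>=1)")
    h, w = patch.shape
    if h < 2 * R + 1 or w < 2 * R + 1:
        raise ValueError(f"patch must be at least {2*R+1}x{2*R+1} for R={R}")
    px = np.pad(patch.pixels, R, mode="edge")
    center = patch.pixels
    word = np.zeros((h, w), dtype=np.int64)
    for bit, (dr, dc) in enumerate(_NEIGHBOR_OFFSETS_8):
        neighbor = px[R + dr * R : R + dr * R + h, R + dc * R : R + dc * R + w]
        word |= (neighbor >= center).astype(np.int64) << bit
    codes = ri_code_table(P)[word]
    return LBPCodeImage(codes, P=P, R=R)


def lbp_feature_vector(
    patch: Patch,
    block_shape: tuple[int, int] = (5, 5),
    P: int = 8,
    R: int = 1,
    source: str = "original",
) -> FeatureVector:
    """Blockwise rotation-invariant LBP histogram descriptor.

    The code image is partitioned into blocks (5x5 by default, giving a
    2x4 grid of eight sub-regions on a 10x20 patch); each block yields a
    histogram over the 36 attainable rotation-invariant codes for P=8,
    and the histograms are concatenated block-major (row by row of the
    block grid), for 8 * 36 = 288 entries.
    """
    bh, bw = block_shape
    h, w = patch.shape
    if h % bh or w % bw:
        raise ValueError(
            f"patch {h}x{w} does not partition into {bh}x{bw} blocks"
        )
    codes = lbp_ri_codes(patch, P=P, R=R).codes
    bins = np.asarray(RI_CODES_P8)
    code_to_bin = np.full(1 << P, -1, dtype=np.int64)
    code_to_bin[bins] = np.arange(bins.size)

    values: list[float] = []
    layout: list[tuple] = []
    for br in range(h // bh):
        for bc in range(w // bw):
            block = codes[br * bh : (br + 1) * bh, bc * bw : (bc + 1) * bw]
            hist = np.bincount(code_to_bin[block].ravel(), minlength=bins.size)
            values.extend(hist.astype(np.float64))
            layout.extend(
                (source, f"lbp[{br},{bc}]:{int(c)}", None) for c in bins
            )
    return FeatureVector(np.array(values), tuple(layout))
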