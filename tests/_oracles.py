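"""Independent brute-force oracles for the texture operations.

Deliberately naive re-implementations (explicit Python loops, term-by-
term sums) kept free of any code shared with the package, so tests can
compare the vectorized implementations against them.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_glcm(pixels: np.ndarray, levels: int, distance: int, angle: int) -> np.ndarray:
    """Loop over every pixel and its offset partner."""
    dr, dc = OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    h, w = pixels.shape
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[pixels[r, c], pixels[r2, c2]] += 1
    return counts


def brute_glcm_stats(p: np.ndarray) -> dict:
    """Term-by-term evaluation of the six co-occurrence statistics."""
    p = p / p.sum()
    k = p.shape[0]
    asm = ent = dis = con = hom = 0.0
    for i in range(k):
        for j in range(k):
            v = p[i, j]
            asm += v * v
            if v > 0:
                ent -= v * math.log2(v)
            dis += v * abs(i - j)
            con += v * (i - j) ** 2
            hom += v / (1 + (i - j) ** 2)
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    ui = sum(i * pi[i] for i in range(k))
    uj = sum(j * pj[j] for j in range(k))
    si = math.sqrt(sum((i - ui) ** 2 * pi[i] for i in range(k)))
    sj = math.sqrt(sum((j - uj) ** 2 * pj[j] for j in range(k)))
    if si > 0 and sj > 0:
        cor = (sum(i * j * p[i, j] for i in range(k) for j in range(k)) - ui * uj) / (si * sj)
    else:
        cor = 0.0
    return {"asm": asm, "ent": ent, "cor": cor, "dis": dis, "con": con, "hom": hom}


def _lines(pixels: np.ndarray, angle: int) -> list[list[int]]:
    h, w = pixels.shape
    if angle == 0:
        return [list(pixels[r, :]) for r in range(h)]
    if angle == 90:
        return [list(pixels[:, c]) for c in range(w)]
    lines = []
    if angle == 45:
        starts = [(h - 1, 0)] * 1
        # walk every anti-diagonal from its bottom-left end
        cells = {}
        for r in range(h):
            for c in range(w):
                cells.setdefault(r + c, []).append((r, c))
        for key in sorted(cells):
            seq = sorted(cells[key], key=lambda rc: -rc[0])  # bottom-left to top-right
            lines.append([int(pixels[r, c]) for r, c in seq])
        return lines
    if angle == 135:
        cells = {}
        for r in range(h):
            for c in range(w):
                cells.setdefault(c - r, []).append((r, c))
        for key in sorted(cells):
            seq = sorted(cells[key])
            lines.append([int(pixels[r, c]) for r, c in seq])
        return lines
    raise ValueError(angle)


def brute_glrlm(pixels: np.ndarray, levels: int, angle: int) -> np.ndarray:
    """Walk each scan line and split it into maximal runs."""
    lines = _lines(pixels, angle)
    max_len = max(len(line) for line in lines)
    runs = np.zeros((levels, max_len), dtype=int)
    for line in lines:
        i = 0
        while i < len(line):
            j = i
            while j < len(line) and line[j] == line[i]:
                j += 1
            runs[line[i], j - i - 1] += 1
            i = j
    return runs


def brute_glrlm_stats(q: np.ndarray, n_pixels: int) -> dict:
    """Double-loop evaluation of the eleven run statistics (1-based gray bins)."""
    s = q.sum()
    out = dict.fromkeys(
        ["sr", "lr", "gln", "rln", "rr", "lgr", "hgr", "srlg", "srhg", "lrlg", "lrhg"], 0.0
    )
    m, n = q.shape
    for gi in range(m):
        i = gi + 1
        for jj in range(n):
            j = jj + 1
            v = q[gi, jj]
            if v == 0:
                continue
            out["sr"] += v / j**2 / s
            out["lr"] += v * j**2 / s
            out["lgr"] += v / i**2 / s
            out["hgr"] += v * i**2 / s
            out["srlg"] += v / (i**2 * j**2) / s
            out["srhg"] += v * i**2 / j**2 / s
            out["lrlg"] += v * j**2 / i**2 / s
            out["lrhg"] += v * i**2 * j**2 / s
    out["gln"] = sum(q[gi, :].sum() ** 2 for gi in range(m)) / s
    out["rln"] = sum(q[:, jj].sum() ** 2 for jj in range(n)) / s
    out["rr"] = s / n_pixels
    return out


def brute_lbp_codes(pixels: np.ndarray) -> np.ndarray:
    """Raw 8-bit word per pixel then explicit enumeration of 8 rotations."""
    h, w = pixels.shape
    padded = np.pad(pixels, 1, mode="edge")
    offsets = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]
    codes = np.zeros((h, w), dtype=int)
    for r in range(h):
        for c in range(w):
            center = padded[r + 1, c + 1]
            word = 0
            for bit, (dr, dc) in enumerate(offsets):
                if padded[r + 1 + dr, c + 1 + dc] >= center:
                    word |= 1 << bit
            best = word
            for rot in range(1, 8):
                rotated = ((word >> rot) | (word << (8 - rot))) & 0xFF
                best = min(best, rotated)
            codes[r, c] = best
    return codes
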