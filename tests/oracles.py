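"""Naive reference implementations used only as independent test oracles.

Everything here is deliberately written as plain double loops over pixels —
slow, obvious, and structurally unrelated to the vectorized implementations
they check.
"""

from __future__ import annotations

import math

import numpy as np

# (d_row, d_col) unit offsets, same angle convention as the package
OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def naive_quantize_minmax(patch: np.ndarray, ng: int) -> np.ndarray:
    """Element-by-element uniform binning of [min, max] into ng bins."""
    arr = np.asarray(patch, dtype=float)
    lo, hi = arr.min(), arr.max()
    out = np.zeros(arr.shape, dtype=int)
    if hi <= lo:
        return out
    for idx in np.ndindex(arr.shape):
        level = int((arr[idx] - lo) / (hi - lo) * ng)
        out[idx] = min(level, ng - 1)
    return out


def naive_cooc_counts(levels: np.ndarray, ng: int, d: int, angle: int,
                      symmetric: bool = True) -> np.ndarray:
    """Unnormalized co-occurrence counts by explicit pair enumeration."""
    lv = np.atleast_2d(np.asarray(levels))
    rows, cols = lv.shape
    dr, dc = OFFSETS[angle]
    dr, dc = dr * d, dc * d
    counts = np.zeros((ng, ng), dtype=float)
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols:
                counts[lv[r, c], lv[r2, c2]] += 1
                if symmetric:
                    counts[lv[r2, c2], lv[r, c]] += 1
    return counts


def naive_diff_marginal(counts: np.ndarray) -> np.ndarray:
    """p_{x-y} from normalized counts by explicit |i-j| accumulation."""
    ng = counts.shape[0]
    p = counts / counts.sum()
    out = np.zeros(ng)
    for i in range(ng):
        for j in range(ng):
            out[abs(i - j)] += p[i, j]
    return out


def naive_rlm_counts(levels: np.ndarray, ng: int, angle: int) -> np.ndarray:
    """Run-length counts by walking every scan line pixel by pixel."""
    lv = np.atleast_2d(np.asarray(levels))
    rows, cols = lv.shape
    kmax = max(rows, cols)
    counts = np.zeros((ng, kmax), dtype=int)

    if angle == 0:
        lines = [list(lv[r, :]) for r in range(rows)]
    elif angle == 90:
        lines = [list(lv[:, c]) for c in range(cols)]
    elif angle == 45:
        starts = [(rows - 1, c) for c in range(cols)] + [(r, 0) for r in range(rows - 1)]
        lines = []
        for r0, c0 in starts:
            line, r, c = [], r0, c0
            while r >= 0 and c < cols:
                line.append(lv[r, c])
                r, c = r - 1, c + 1
            lines.append(line)
    elif angle == 135:
        starts = [(rows - 1, c) for c in range(cols)] + [(r, cols - 1) for r in range(rows - 1)]
        lines = []
        for r0, c0 in starts:
            line, r, c = [], r0, c0
            while r >= 0 and c >= 0:
                line.append(lv[r, c])
                r, c = r - 1, c - 1
            lines.append(line)
    else:
        raise ValueError(angle)

    for line in lines:
        i = 0
        while i < len(line):
            j = i
            while j < len(line) and line[j] == line[i]:
                j += 1
            counts[line[i], j - i - 1] += 1
            i = j
    return counts


def naive_difference_entropy(diff_marginal: np.ndarray, base: float = 10.0) -> float:
    total = 0.0
    for p in diff_marginal:
        if p > 0:
            total -= p * math.log(p, base)
    return total


def naive_long_run_emphasis(counts: np.ndarray) -> float:
    num = den = 0.0
    for i in range(counts.shape[0]):
        for k in range(counts.shape[1]):
            num += (k + 1) ** 2 * counts[i, k]
            den += counts[i, k]
    return num / den


def naive_features(patch: np.ndarray, ng: int, d: int, angle: int,
                   base: float = 10.0) -> tuple[float, float, float]:
    """Monolithic end-to-end reference: (DifEntr, LngREmph, MOD)."""
    levels = naive_quantize_minmax(patch, ng)
    cooc = naive_cooc_counts(levels, ng, d, angle)
    de = naive_difference_entropy(naive_diff_marginal(cooc), base)
    lre = naive_long_run_emphasis(naive_rlm_counts(levels, ng, angle))
    return de, lre, float(np.asarray(patch, dtype=float).mean())
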