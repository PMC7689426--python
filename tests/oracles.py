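"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain double loops straight from
the published definitions, independent of the package's vectorized
implementations, so the two routes can disagree.
"""

from __future__ import annotations

import math

import numpy as np


def bf_glcm_counts(levels: np.ndarray, ng: int, dr: int, dc: int) -> np.ndarray:
    """Symmetric co-occurrence counts by exhaustive pixel-pair enumeration."""
    h, w = levels.shape
    counts = np.zeros((ng, ng), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                i, j = levels[r, c], levels[r2, c2]
                if i > 0 and j > 0:
                    counts[i - 1, j - 1] += 1
                    counts[j - 1, i - 1] += 1
    return counts


def bf_glcm_features(p: np.ndarray) -> dict[str, float]:
    """Haralick statistics evaluated loop-wise from the probability matrix."""
    ng = p.shape[0]
    mu_x = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    var_x = sum((i + 1 - mu_x) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    asm = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    contrast = sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    if var_x > 0:
        num = sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
        correlation = (num - mu_x * mu_x) / var_x
    else:
        correlation = 0.0
    entropy = -sum(p[i, j] * math.log(p[i, j])
                   for i in range(ng) for j in range(ng) if p[i, j] > 0)
    idm = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))

    p_sum = {}
    p_dif = {}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] = p_sum.get(i + j + 2, 0.0) + p[i, j]
            p_dif[abs(i - j)] = p_dif.get(abs(i - j), 0.0) + p[i, j]
    sum_avg = sum(k * v for k, v in p_sum.items())
    sum_var = sum((k - sum_avg) ** 2 * v for k, v in p_sum.items())
    sum_ent = -sum(v * math.log(v) for v in p_sum.values() if v > 0)
    dif_avg = sum(k * v for k, v in p_dif.items())
    dif_var = sum((k - dif_avg) ** 2 * v for k, v in p_dif.items())
    dif_ent = -sum(v * math.log(v) for v in p_dif.values() if v > 0)
    return {
        "AngScMom": asm, "Contrast": contrast, "Correlat": correlation,
        "Entropy": entropy, "SumEntrp": sum_ent, "SumOfSqs": var_x,
        "SumAverg": sum_avg, "SumVarnc": sum_var, "InvDfMom": idm,
        "DifEntrp": dif_ent, "DifVarnc": dif_var,
    }


def bf_runs(levels: np.ndarray, angle: int) -> list[tuple[int, int]]:
    """(level, length) of every maximal run, by explicit scan-line walking."""
    h, w = levels.shape
    if angle == 0:
        lines = [[(r, c) for c in range(w)] for r in range(h)]
    elif angle == 90:
        lines = [[(r, c) for r in range(h)] for c in range(w)]
    elif angle == 45:
        lines = []
        for k in range(-(h - 1), w):
            lines.append([(r, r + k) for r in range(h) if 0 <= r + k < w])
    elif angle == 135:
        lines = []
        for k in range(-(h - 1), w):
            lines.append([(r, (w - 1) - (r + k)) for r in range(h) if 0 <= r + k < w])
    else:
        raise ValueError(angle)
    runs = []
    for line in lines:
        cur, length = 0, 0
        for (r, c) in line:
            v = int(levels[r, c])
            if v == cur and v > 0:
                length += 1
            else:
                if cur > 0:
                    runs.append((cur, length))
                cur, length = v, (1 if v > 0 else 0)
        if cur > 0:
            runs.append((cur, length))
    return runs


def bf_rlm_features(runs: list[tuple[int, int]], n_pixels: int) -> dict[str, float]:
    n_runs = len(runs)
    sre = sum(1.0 / l ** 2 for _, l in runs) / n_runs
    lre = sum(float(l) ** 2 for _, l in runs) / n_runs
    by_level = {}
    by_length = {}
    for g, l in runs:
        by_level[g] = by_level.get(g, 0) + 1
        by_length[l] = by_length.get(l, 0) + 1
    gln = sum(v ** 2 for v in by_level.values()) / n_runs
    rln = sum(v ** 2 for v in by_length.values()) / n_runs
    return {"ShrtREmp": sre, "LngREmph": lre, "GLevNonU": gln,
            "RLNonUni": rln, "Fraction": n_runs / n_pixels}


def bf_point_in_polygon(x: float, y: float, vertices: np.ndarray) -> bool:
    """Even-odd ray-casting point-in-polygon test."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


def bf_icc21(data: np.ndarray) -> float:
    """ICC(2,1) via explicitly written two-way ANOVA mean squares."""
    n, k = data.shape
    grand = data.mean()
    msr = k * sum((data[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((data[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum((data[i, j] - data[i].mean() - data[:, j].mean() + grand) ** 2
              for i in range(n) for j in range(k))
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def bf_bilinear(img: np.ndarray, r: float, c: float) -> float:
    """Direct bilinear interpolation at fractional (row, col)."""
    r0, c0 = int(math.floor(r)), int(math.floor(c))
    r0 = min(max(r0, 0), img.shape[0] - 2)
    c0 = min(max(c0, 0), img.shape[1] - 2)
    fr, fc = r - r0, c - c0
    return ((1 - fr) * (1 - fc) * img[r0, c0] + (1 - fr) * fc * img[r0, c0 + 1]
            + fr * (1 - fc) * img[r0 + 1, c0] + fr * fc * img[r0 + 1, c0 + 1])
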