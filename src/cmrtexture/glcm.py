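"""Grey-level co-occurrence matrices and the classical Haralick statistics.

A co-occurrence matrix at interpixel distance ``a`` and direction offset
``(dr, dc)`` counts every ordered in-ROI pixel pair ``(p, p + a*(dr, dc))``,
accumulated symmetrically (each pair increments both (i, j) and (j, i)).
Features follow Haralick's published definitions evaluated on the jointly
normalized probability matrix; entropies use the natural log with the
0*log(0) = 0 convention, and the sum-variance moment is taken about the sum
average.  A single-level (zero-variance) matrix defines correlation as 0.

Direction set: {(0, a), (a, 0), (a, a), (a, -a)} labelled 0, 90, 45 and 135
degrees.  The 6-bit quantized image is the canonical input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import QuantizedImage, RoiMask

DIRECTIONS = {0: (0, 1), 90: (1, 0), 45: (1, 1), 135: (1, -1)}

GLCM_FEATURE_NAMES = (
    "AngScMom", "Contrast", "Correlat", "Entropy", "SumEntrp", "SumOfSqs",
    "SumAverg", "SumVarnc", "InvDfMom", "DifEntrp", "DifVarnc",
)


@dataclass(frozen=True)
class CooccurrenceMatrix:
    counts: np.ndarray      # Ng x Ng symmetric integer counts
    distance: int
    direction: tuple[int, int]

    @property
    def probabilities(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total


def _pair_views(levels: np.ndarray, dr: int, dc: int):
    """Return aligned views (src, dst) such that dst = src shifted by (dr, dc)."""
    h, w = levels.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r1 <= r0 or c1 <= c0:
        return None, None
    src = levels[r0:r1, c0:c1]
    dst = levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    return src, dst


def build_cooccurrence(q: QuantizedImage, mask: RoiMask | None = None,
                       distance: int = 1,
                       direction: tuple[int, int] = (0, 1)) -> CooccurrenceMatrix:
    """Count co-occurring level pairs at ``distance * direction`` within the mask."""
    if distance < 1:
        raise ValueError("distance must be >= 1")
    levels = q.levels
    ng = q.n_levels
    dr, dc = distance * direction[0], distance * direction[1]
    src, dst = _pair_views(levels, dr, dc)
    counts = np.zeros((ng, ng), dtype=np.int64)
    if src is not None:
        valid = (src > 0) & (dst > 0)
        i = src[valid] - 1
        j = dst[valid] - 1
        if i.size:
            flat = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng)
            counts = flat + flat.T
    if counts.sum() == 0:
        raise ValueError("empty co-occurrence: no valid pixel pair at this "
                         f"distance/direction ({distance}, {direction})")
    return CooccurrenceMatrix(counts, distance, direction)


def glcm_features(m: CooccurrenceMatrix) -> dict[str, float]:
    """The 11 Haralick statistics of a co-occurrence probability matrix."""
    p = m.probabilities
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    pi = p.sum(axis=1)                 # marginal (symmetric: px == py)
    mu = float(i @ pi)
    var = float(((i - mu) ** 2) @ pi)

    ii, jj = np.meshgrid(i, i, indexing="ij")
    asm = float((p ** 2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if var > 0:
        correlation = float(((ii * jj * p).sum() - mu * mu) / var)
    else:
        correlation = 0.0              # degenerate single-level matrix
    entropy = float(-np.sum(p[p > 0] * np.log(p[p > 0])))
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())

    # p_{x+y}(k), k = 2..2Ng and p_{|x-y|}(k), k = 0..Ng-1
    sums = (np.arange(ng)[:, None] + np.arange(ng)[None, :]).ravel()
    diffs = np.abs(np.arange(ng)[:, None] - np.arange(ng)[None, :]).ravel()
    p_sum = np.bincount(sums, weights=p.ravel(), minlength=2 * ng - 1)
    p_dif = np.bincount(diffs, weights=p.ravel(), minlength=ng)
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    k_dif = np.arange(ng, dtype=float)

    sum_avg = float(k_sum @ p_sum)
    sum_var = float(((k_sum - sum_avg) ** 2) @ p_sum)
    sum_ent = float(-np.sum(p_sum[p_sum > 0] * np.log(p_sum[p_sum > 0])))
    dif_avg = float(k_dif @ p_dif)
    dif_var = float(((k_dif - dif_avg) ** 2) @ p_dif)
    dif_ent = float(-np.sum(p_dif[p_dif > 0] * np.log(p_dif[p_dif > 0])))

    return {
        "AngScMom": asm,
        "Contrast": contrast,
        "Correlat": correlation,
        "Entropy": entropy,
        "SumEntrp": sum_ent,
        "SumOfSqs": var,
        "SumAverg": sum_avg,
        "SumVarnc": sum_var,
        "InvDfMom": idm,
        "DifEntrp": dif_ent,
        "DifVarnc": dif_var,
    }
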