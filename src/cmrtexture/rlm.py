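"""Run-length matrices and Galloway's five run statistics.

A run is a maximal sequence of in-ROI pixels with identical quantized level
along a scan line; runs are truncated at mask boundaries.  Angles: 0 degrees
scans rows, 90 degrees columns, 45 degrees the (1, 1) diagonals and 135
degrees the (1, -1) anti-diagonals.  Every in-mask pixel lies on exactly one
scan line per angle, so the run lengths at an angle sum to the mask size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import QuantizedImage, RoiMask

RLM_ANGLES = (0, 45, 90, 135)

RLM_FEATURE_NAMES = ("ShrtREmp", "LngREmph", "GLevNonU", "RLNonUni", "Fraction")


@dataclass(frozen=True)
class RunLengthTable:
    """Runs of a masked quantized image at one angle, as (level, length) arrays."""

    levels: np.ndarray     # level of each run (1..Ng)
    lengths: np.ndarray    # length of each run (>= 1)
    angle: int
    n_pixels: int          # in-mask pixels traversed at this angle

    def matrix(self, ng: int) -> np.ndarray:
        """Dense Ng x Lmax run-length matrix (row: level, column: length)."""
        lmax = int(self.lengths.max()) if self.lengths.size else 1
        out = np.zeros((ng, lmax), dtype=np.int64)
        np.add.at(out, (self.levels - 1, self.lengths - 1), 1)
        return out


def _scan_lines(levels: np.ndarray, angle: int) -> list[np.ndarray]:
    h, w = levels.shape
    if angle == 0:
        return [levels[r] for r in range(h)]
    if angle == 90:
        return [levels[:, c] for c in range(w)]
    if angle == 45:
        return [np.diagonal(levels, offset=k) for k in range(-(h - 1), w)]
    if angle == 135:
        fl = levels[:, ::-1]
        return [np.diagonal(fl, offset=k) for k in range(-(h - 1), w)]
    raise ValueError("angle must be one of 0, 45, 90, 135")


def build_run_table(q: QuantizedImage, mask: RoiMask | None = None,
                    angle: int = 0) -> RunLengthTable:
    """Enumerate maximal equal-level runs along the angle's scan lines."""
    levels = q.levels
    n_pixels = int((levels > 0).sum())
    if n_pixels == 0:
        raise ValueError("empty mask")
    lines = _scan_lines(levels, angle)
    # Concatenate lines with 0 separators; out-of-mask pixels are already 0,
    # so a single run-length encoding pass yields every in-mask run.
    flat = np.zeros(sum(len(l) for l in lines) + len(lines), dtype=levels.dtype)
    pos = 0
    for l in lines:
        flat[pos:pos + len(l)] = l
        pos += len(l) + 1
    change = np.flatnonzero(np.diff(flat) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(flat)]))
    vals = flat[starts]
    keep = vals > 0
    return RunLengthTable(levels=vals[keep].astype(np.int64),
                          lengths=(ends - starts)[keep].astype(np.int64),
                          angle=angle, n_pixels=n_pixels)


def rlm_features(q: QuantizedImage, mask: RoiMask | None = None,
                 angle: int = 0) -> dict[str, float]:
    """Short/long-run emphasis, the two non-uniformities, and run percentage."""
    t = build_run_table(q, mask, angle)
    lengths = t.lengths.astype(float)
    n_runs = lengths.size
    sre = float(np.sum(1.0 / lengths ** 2) / n_runs)
    lre = float(np.sum(lengths ** 2) / n_runs)
    per_level = np.bincount(t.levels)
    gln = float(np.sum(per_level.astype(float) ** 2) / n_runs)
    per_length = np.bincount(t.lengths)
    rln = float(np.sum(per_length.astype(float) ** 2) / n_runs)
    fraction = float(n_runs / t.n_pixels)
    return {
        "ShrtREmp": sre,
        "LngREmph": lre,
        "GLevNonU": gln,
        "RLNonUni": rln,
        "Fraction": fraction,
    }
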