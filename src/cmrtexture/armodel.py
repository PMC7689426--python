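"""Causal autoregressive texture model.

Each in-ROI pixel is regressed on its four causal neighbours — west,
north-west, north and north-east — after mean-centering by the ROI mean:

    v(p) = theta1*v(W) + theta2*v(NW) + theta3*v(N) + theta4*v(NE) + e

Theta is the minimum-norm least-squares solution over the pixels whose four
neighbours are all in-mask, and sigma is the standard deviation of the fit
residuals.  A rank-deficient design (e.g. a constant ROI) degenerates to
theta = 0, sigma = 0 with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np

from .images import QuantizedImage, RoiMask

AR_FEATURE_NAMES = ("Teta1", "Teta2", "Teta3", "Teta4", "Sigma")

_NEIGHBOURS = ((0, -1), (-1, -1), (-1, 0), (-1, 1))  # W, NW, N, NE


def ar_design(levels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix (n x 4) and target vector over eligible pixels.

    ``levels`` uses 0 for out-of-mask pixels; values are mean-centered by the
    in-mask mean before assembly.
    """
    inside = levels > 0
    vals = np.where(inside, levels.astype(float), 0.0)
    mean = vals[inside].mean() if inside.any() else 0.0
    centered = np.where(inside, vals - mean, 0.0)

    h, w = levels.shape
    inside_pad = np.pad(inside, 1, constant_values=False)
    centered_pad = np.pad(centered, 1)
    eligible = inside.copy()
    for dr, dc in _NEIGHBOURS:
        eligible &= inside_pad[1 + dr:1 + dr + h, 1 + dc:1 + dc + w]
    rr, cc = np.nonzero(eligible)
    cols = [centered_pad[1 + rr + dr, 1 + cc + dc] for dr, dc in _NEIGHBOURS]
    x = np.column_stack(cols) if rr.size else np.empty((0, 4))
    y = centered[rr, cc]
    return x, y


def ar_features(q: QuantizedImage, mask: RoiMask | None = None) -> dict[str, float]:
    x, y = ar_design(q.levels)
    if x.shape[0] < 20:
        raise ValueError("autoregressive fit requires >= 20 eligible pixels "
                         f"(got {x.shape[0]})")
    if not np.any(x) and not np.any(y):
        warnings.warn("constant ROI: autoregressive model degenerate, theta = 0")
        theta = np.zeros(4)
        sigma = 0.0
    else:
        theta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ theta
        sigma = float(resid.std())
    return {
        "Teta1": float(theta[0]),
        "Teta2": float(theta[1]),
        "Teta3": float(theta[2]),
        "Teta4": float(theta[3]),
        "Sigma": sigma,
    }
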