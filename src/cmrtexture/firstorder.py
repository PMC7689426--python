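"""Histogram and absolute-gradient first-order statistics.

Histogram moments are computed on the windowed (mean +/- 3 sigma, clipped)
in-ROI intensities.  The absolute gradient is the Euclidean magnitude of the
central-difference gradient on the 4-bit quantized image, evaluated only at
pixels whose four axial neighbours are all in-mask.  Skewness is the third
standardized moment and kurtosis the excess fourth; both are defined as 0
when the variance vanishes so constant fixtures flow through.
"""

from __future__ import annotations

import numpy as np

from .images import GrayImage, QuantizedImage, RoiMask

HISTOGRAM_FEATURE_NAMES = ("Mean", "Variance", "Skewness", "Kurtosis")
GRADIENT_FEATURE_NAMES = ("GrMean", "GrVariance", "GrSkewness", "GrKurtosis", "GrNonZeros")


def _moments(values: np.ndarray) -> dict[str, float]:
    mean = float(values.mean())
    var = float(values.var())
    if var > 0:
        z = (values - mean) / np.sqrt(var)
        skew = float(np.mean(z ** 3))
        kurt = float(np.mean(z ** 4) - 3.0)
    else:
        skew = kurt = 0.0
    return {"Mean": mean, "Variance": var, "Skewness": skew, "Kurtosis": kurt}


def histogram_features(img: GrayImage, mask: RoiMask) -> dict[str, float]:
    vals = img.pixels[mask.inside]
    mu, sigma = vals.mean(), vals.std()
    windowed = np.clip(vals, mu - 3 * sigma, mu + 3 * sigma)
    return _moments(windowed)


def gradient_magnitude(q4: QuantizedImage) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel gradient magnitude and the validity mask where it is defined."""
    levels = q4.levels.astype(float)
    inside = q4.levels > 0
    h, w = levels.shape
    valid = np.zeros((h, w), dtype=bool)
    valid[1:-1, 1:-1] = (inside[1:-1, 1:-1] & inside[:-2, 1:-1] & inside[2:, 1:-1]
                         & inside[1:-1, :-2] & inside[1:-1, 2:])
    gr = np.zeros((h, w))
    gc = np.zeros((h, w))
    gr[1:-1, :] = (levels[2:, :] - levels[:-2, :]) / 2.0
    gc[:, 1:-1] = (levels[:, 2:] - levels[:, :-2]) / 2.0
    mag = np.sqrt(gr ** 2 + gc ** 2)
    return mag, valid


def gradient_features(q4: QuantizedImage) -> dict[str, float]:
    mag, valid = gradient_magnitude(q4)
    g = mag[valid]
    if g.size == 0:
        return {"GrMean": 0.0, "GrVariance": 0.0, "GrSkewness": 0.0,
                "GrKurtosis": 0.0, "GrNonZeros": 0.0}
    feats = _moments(g)
    return {
        "GrMean": feats["Mean"],
        "GrVariance": feats["Variance"],
        "GrSkewness": feats["Skewness"],
        "GrKurtosis": feats["Kurtosis"],
        "GrNonZeros": float(np.count_nonzero(g) / g.size),
    }


def first_order_features(img: GrayImage, q4: QuantizedImage,
                         mask: RoiMask) -> dict[str, float]:
    """Histogram (4) and absolute-gradient (5) statistics, prefixed by family."""
    out = {f"Hist.{k}": v for k, v in histogram_features(img, mask).items()}
    out.update({f"Grad.{k.removeprefix('Gr')}": v
                for k, v in gradient_features(q4).items()})
    return out
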