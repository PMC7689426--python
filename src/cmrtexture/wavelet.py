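"""Haar wavelet sub-band energies.

The analysis window is the largest dyadic square that fits inside the mask's
bounding box (centred within it).  An orthonormal Haar transform is applied
recursively; at each scale s the energy of a sub-band is the mean of its
squared coefficients.  Four sub-bands (LL, LH horizontal, HL vertical, HH
diagonal) at up to seven scales give up to 28 features; scales whose
sub-band would be empty are reported as missing (None), as are all of them
when no 2x2 window fits.
"""

from __future__ import annotations

import numpy as np
import pywt

from .images import GrayImage, RoiMask

WAVELET_SUBBANDS = ("LL", "LH", "HL", "HH")
MAX_WAVELET_SCALE = 7


def dyadic_window(mask: RoiMask) -> tuple[int, int, int] | None:
    """(row0, col0, side) of the largest dyadic square inside the mask bbox."""
    rows = np.any(mask.inside, axis=1)
    cols = np.any(mask.inside, axis=0)
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    bh, bw = r1 - r0 + 1, c1 - c0 + 1
    side = 1 << int(np.floor(np.log2(min(bh, bw))))
    if side < 2:
        return None
    return (int(r0 + (bh - side) // 2), int(c0 + (bw - side) // 2), int(side))


def wavelet_features(img: GrayImage, mask: RoiMask,
                     scales: range = range(1, MAX_WAVELET_SCALE + 1)) -> dict[str, float | None]:
    out: dict[str, float | None] = {
        f"Wav.s{s}.{b}": None for s in scales for b in WAVELET_SUBBANDS
    }
    win = dyadic_window(mask)
    if win is None:
        return out
    r0, c0, side = win
    ll = img.pixels[r0:r0 + side, c0:c0 + side]
    max_scale = int(np.log2(side))
    for s in scales:
        if s > max_scale:
            break
        ll, (lh, hl, hh) = pywt.dwt2(ll, "haar")
        out[f"Wav.s{s}.LL"] = float(np.mean(ll ** 2))
        out[f"Wav.s{s}.LH"] = float(np.mean(lh ** 2))
        out[f"Wav.s{s}.HL"] = float(np.mean(hl ** 2))
        out[f"Wav.s{s}.HH"] = float(np.mean(hh ** 2))
    return out
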