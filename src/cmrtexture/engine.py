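"""Per-ROI evaluation of the full texture panel.

``extract_vector`` runs every registry descriptor over one masked image;
``extract_panel`` does so for the paired T2w/LGE images of a subject and
tags the two vectors by sequence.  Evaluation is deterministic: descriptors
are computed in registry order from cached per-family intermediates.
Missing values (wavelet scales the window cannot realize, or an
autoregressive fit with too few eligible pixels) propagate as None and are
never silently imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .armodel import ar_features
from .firstorder import gradient_features, histogram_features
from .glcm import DIRECTIONS, GLCM_FEATURE_NAMES, build_cooccurrence, glcm_features
from .images import (GrayImage, QuantizedImage, RoiMask, RoiPolygon,
                     normalize_and_quantize, rasterize_roi)
from .registry import FeatureDescriptor, default_registry, validate_registry
from .rlm import rlm_features
from .wavelet import wavelet_features

MAX_GLCM_DISTANCE = 5


@dataclass(frozen=True)
class FeatureVector:
    """Ordered canonical name -> value (None = missing), tagged by sequence."""

    values: dict[str, float | None]
    sequence: str   # "T2w" or "LGE"

    def __len__(self) -> int:
        return len(self.values)


def _crop(img: GrayImage, mask: RoiMask, margin: int = 1) -> tuple[GrayImage, RoiMask]:
    rows = np.any(mask.inside, axis=1)
    cols = np.any(mask.inside, axis=0)
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    r0 = max(0, r0 - margin)
    c0 = max(0, c0 - margin)
    r1 = min(mask.inside.shape[0] - 1, r1 + margin)
    c1 = min(mask.inside.shape[1] - 1, c1 + margin)
    sub_px = img.pixels[r0:r1 + 1, c0:c1 + 1]
    if sub_px.shape[0] < 2 or sub_px.shape[1] < 2:  # pragma: no cover
        return img, mask
    return (GrayImage(sub_px, img.spacing_row, img.spacing_col),
            RoiMask(mask.inside[r0:r1 + 1, c0:c1 + 1]))


class _RoiContext:
    """Caches quantizations and per-family feature blocks for one masked image."""

    def __init__(self, img: GrayImage, mask: RoiMask):
        self.img, self.mask = _crop(img, mask)
        self._q: dict[int, QuantizedImage] = {}
        self._cache: dict[tuple, dict] = {}

    def quantized(self, bits: int) -> QuantizedImage:
        if bits not in self._q:
            self._q[bits] = normalize_and_quantize(self.img, self.mask, bits)
        return self._q[bits]

    def _normalized_image(self) -> GrayImage:
        """ROI-standardized intensities, clipped at the +/-3 sigma window.

        The wavelet family consumes z = (v - mu) / sigma clipped to [-3, 3],
        so its energies are in normalized units and, like the quantized
        families, depend on the ROI through the normalization window.
        """
        def _compute():
            from .images import normalization_window
            win = normalization_window(self.img, self.mask)
            if win.sigma == 0:
                z = np.zeros_like(self.img.pixels)
            else:
                z = np.clip((self.img.pixels - win.mu) / win.sigma, -3.0, 3.0)
            return {"img": GrayImage(z, self.img.spacing_row, self.img.spacing_col)}
        return self.block(("zimg",), _compute)["img"]

    def block(self, key: tuple, compute) -> dict:
        if key not in self._cache:
            self._cache[key] = compute()
        return self._cache[key]

    def value(self, d: FeatureDescriptor) -> float | None:
        if d.family == "histogram":
            blk = self.block(("hist",), lambda: histogram_features(self.img, self.mask))
            return blk[d.params["stat"]]
        if d.family == "glcm":
            dist, angle = d.params["distance"], d.params["angle"]

            def _glcm():
                try:
                    return glcm_features(build_cooccurrence(
                        self.quantized(6), self.mask, dist, DIRECTIONS[angle]))
                except ValueError as exc:   # ROI too thin for this offset
                    warnings.warn(f"GLCM d={dist} a={angle} missing: {exc}")
                    return dict.fromkeys(GLCM_FEATURE_NAMES)
            return self.block(("glcm", dist, angle), _glcm)[d.params["stat"]]
        if d.family == "rlm":
            angle = d.params["angle"]
            blk = self.block(("rlm", angle),
                             lambda: rlm_features(self.quantized(6), self.mask, angle))
            return blk[d.params["stat"]]
        if d.family == "gradient":
            blk = self.block(("grad",), lambda: gradient_features(self.quantized(4)))
            return blk["Gr" + d.params["stat"]]
        if d.family == "ar":
            def _ar():
                try:
                    return ar_features(self.quantized(6), self.mask)
                except ValueError as exc:
                    warnings.warn(f"autoregressive features missing: {exc}")
                    return {k: None for k in ("Teta1", "Teta2", "Teta3", "Teta4", "Sigma")}
            return self.block(("ar",), _ar)[d.params["stat"]]
        if d.family == "wavelet":
            blk = self.block(("wav",), lambda: wavelet_features(
                self._normalized_image(), self.mask))
            return blk[f"Wav.s{d.params['scale']}.{d.params['band']}"]
        raise ValueError(f"unknown family {d.family!r}")  # pragma: no cover


def extract_vector(img: GrayImage, mask: RoiMask,
                   registry: list[FeatureDescriptor] | None = None,
                   sequence: str = "T2w") -> FeatureVector:
    if registry is None:
        registry = default_registry()
    validate_registry(registry)
    ctx = _RoiContext(img, mask)
    return FeatureVector({d.name: ctx.value(d) for d in registry}, sequence)


def extract_panel(img_t2w: GrayImage, mask_t2w: RoiMask,
                  img_lge: GrayImage, mask_lge: RoiMask,
                  registry: list[FeatureDescriptor] | None = None
                  ) -> dict[str, FeatureVector]:
    """Evaluate the registry over both sequences of one subject."""
    return {
        "T2w": extract_vector(img_t2w, mask_t2w, registry, "T2w"),
        "LGE": extract_vector(img_lge, mask_lge, registry, "LGE"),
    }


def extract_from_polygon(img: GrayImage, poly: RoiPolygon,
                         registry: list[FeatureDescriptor] | None = None,
                         sequence: str = "T2w") -> FeatureVector:
    return extract_vector(img, rasterize_roi(poly, img.shape), registry, sequence)
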