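"""Image and ROI handling for the texture pipeline.

Short-axis CMR slices arrive either as single-frame monochrome DICOM or as a
16-bit PGM raster fixture with a plain-text JSON sidecar carrying the pixel
spacing.  Before texture computation every image is resampled to a uniform
in-plane resolution (the pipeline default is 0.390625 mm, i.e. a 200 mm
field of view on a 512 matrix), the reader-drawn left-ventricular polygon is
rasterized on the resampled grid, and in-ROI intensities are windowed to
mean +/- 3 standard deviations and quantized to the bit depth each texture
family consumes (6 bits for co-occurrence and run-length statistics, 4 bits
for the absolute gradient).

Coordinate convention: row-major grids, x = column index, y = row index,
pixel centers at integer coordinates, 0-based.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from scipy.ndimage import map_coordinates
from shapely.geometry import Polygon as _ShapelyPolygon

DEFAULT_SPACING_MM = 0.390625  # 200 mm FOV / 512 matrix

__all__ = [
    "DEFAULT_SPACING_MM",
    "GrayImage",
    "RoiPolygon",
    "RoiMask",
    "NormalizationWindow",
    "QuantizedImage",
    "read_image",
    "write_pgm",
    "load_roi_json",
    "save_roi_json",
    "resample_to_spacing",
    "rasterize_roi",
    "normalize_and_quantize",
]


@dataclass(frozen=True)
class GrayImage:
    """2D intensity grid with physical pixel spacing in mm."""

    pixels: np.ndarray
    spacing_row: float
    spacing_col: float

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("GrayImage requires a 2D pixel grid")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("GrayImage requires at least 2x2 pixels")
        if not np.all(np.isfinite(px)):
            raise ValueError("GrayImage intensities must be finite")
        if self.spacing_row <= 0 or self.spacing_col <= 0:
            raise ValueError("pixel spacing must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RoiPolygon:
    """Reader-drawn LV region: ordered (x=col, y=row) vertices, implicitly closed."""

    vertices: np.ndarray
    reader: int = 1
    read: int = 1

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("RoiPolygon requires >= 3 (x, y) vertices")
        if not np.all(np.isfinite(v)):
            raise ValueError("polygon vertices must be finite")
        poly = _ShapelyPolygon(v)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("polygon must be simple (non-self-intersecting)")
        object.__setattr__(self, "vertices", v)

    def shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)


@dataclass(frozen=True)
class RoiMask:
    """Boolean raster of an ROI, congruent with its image."""

    inside: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.inside, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2D")
        if int(m.sum()) < 16:
            raise ValueError("ROI too small: fewer than 16 pixels")
        object.__setattr__(self, "inside", m)

    @property
    def n_pixels(self) -> int:
        return int(self.inside.sum())


@dataclass(frozen=True)
class NormalizationWindow:
    """The +/- 3 sigma intensity window computed over in-ROI pixels."""

    mu: float
    sigma: float

    @property
    def lo(self) -> float:
        return self.mu - 3.0 * self.sigma

    @property
    def hi(self) -> float:
        return self.mu + 3.0 * self.sigma


@dataclass(frozen=True)
class QuantizedImage:
    """Integer grid with in-mask values in [1, Ng]; 0 marks out-of-mask pixels."""

    levels: np.ndarray
    bits: int
    mask: RoiMask | None = None
    window: NormalizationWindow | None = None

    @property
    def n_levels(self) -> int:
        return 1 << self.bits


# ---------------------------------------------------------------------------
# I/O

def _read_pgm(path: Path) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise ValueError(f"{path}: raster fixture must be 2D grayscale")
    return arr.astype(float)


def read_image(path, fmt: str | None = None) -> GrayImage:
    """Read a single-frame image from DICOM or the PGM raster fixture format.

    For raster fixtures, the pixel spacing comes from a JSON sidecar
    ``<stem>.json`` next to the image with a ``"spacing"`` entry (mm/pixel,
    scalar or ``[row, col]``) and an optional affine intensity rescale
    ``"slope"``/``"intercept"``.  Missing spacing is a hard error: resampling
    to the uniform grid would be impossible.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "dicom" if path.suffix.lower() in {".dcm", ".dicom", ".ima"} else "raster"

    if fmt == "dicom":
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected single-frame 2D DICOM")
        spacing = getattr(ds, "PixelSpacing", None)
        if spacing is None or len(spacing) < 2:
            raise ValueError(f"{path}: spacing unavailable (no PixelSpacing)")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        px = arr.astype(float) * slope + intercept
        return GrayImage(px, float(spacing[0]), float(spacing[1]))

    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise ValueError(f"{path}: spacing unavailable (no sidecar {sidecar.name})")
    meta = json.loads(sidecar.read_text())
    if "spacing" not in meta:
        raise ValueError(f"{path}: spacing unavailable in sidecar")
    sp = meta["spacing"]
    sp_row, sp_col = (float(sp), float(sp)) if np.isscalar(sp) else (float(sp[0]), float(sp[1]))
    px = _read_pgm(path)
    px = px * float(meta.get("slope", 1.0)) + float(meta.get("intercept", 0.0))
    return GrayImage(px, sp_row, sp_col)


def write_pgm(img: GrayImage, path, sidecar: bool = True) -> None:
    """Write a 16-bit ASCII PGM plus a spacing/rescale sidecar.

    Intensities are affinely mapped onto [0, 65535]; the sidecar records the
    inverse map so ``read_image`` round-trips the physical values.
    """
    path = Path(path)
    px = img.pixels
    lo, hi = float(px.min()), float(px.max())
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    raw = np.rint((px - lo) / scale).astype(np.uint16) if hi > lo else np.zeros_like(px, dtype=np.uint16)
    h, w = raw.shape
    lines = [f"P2\n{w} {h}\n65535\n"]
    for row in raw:
        lines.append(" ".join(map(str, row.tolist())) + "\n")
    path.write_text("".join(lines))
    if sidecar:
        meta = {
            "spacing": [img.spacing_row, img.spacing_col],
            "slope": scale,
            "intercept": lo,
        }
        path.with_suffix(".json").write_text(json.dumps(meta))


def load_roi_json(path) -> RoiPolygon:
    d = json.loads(Path(path).read_text())
    return RoiPolygon(np.asarray(d["vertices"], dtype=float),
                      reader=int(d.get("reader", 1)), read=int(d.get("read", 1)))


def save_roi_json(poly: RoiPolygon, path) -> None:
    Path(path).write_text(json.dumps({
        "vertices": [[float(x), float(y)] for x, y in poly.vertices],
        "reader": poly.reader,
        "read": poly.read,
    }))


# ---------------------------------------------------------------------------
# Geometry and resampling

def resample_to_spacing(img: GrayImage, target: float = DEFAULT_SPACING_MM) -> GrayImage:
    """Bilinearly resample onto an isotropic grid with ``target`` mm/pixel.

    The physical extent is preserved to within one output pixel.  An image
    already on the target grid is returned pixel-identical.
    """
    if target <= 0:
        raise ValueError("target spacing must be positive")
    if (abs(img.spacing_row - target) < 1e-12 * target
            and abs(img.spacing_col - target) < 1e-12 * target):
        return GrayImage(img.pixels.copy(), target, target)

    n_rows = int(np.floor((img.shape[0] - 1) * img.spacing_row / target)) + 1
    n_cols = int(np.floor((img.shape[1] - 1) * img.spacing_col / target)) + 1
    if n_rows < 2 or n_cols < 2:
        raise ValueError("resampled grid smaller than 2x2")
    rows = np.arange(n_rows) * (target / img.spacing_row)
    cols = np.arange(n_cols) * (target / img.spacing_col)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    out = map_coordinates(img.pixels, [rr, cc], order=1, mode="nearest")
    return GrayImage(out, target, target)


def rescale_polygon(poly: RoiPolygon, spacing_row: float, spacing_col: float,
                    target: float) -> RoiPolygon:
    """Map polygon vertices from the native grid onto the resampled grid."""
    v = poly.vertices.copy()
    v[:, 0] *= spacing_col / target
    v[:, 1] *= spacing_row / target
    return RoiPolygon(v, reader=poly.reader, read=poly.read)


def rasterize_roi(poly: RoiPolygon, shape: tuple[int, int]) -> RoiMask:
    """Rasterize a polygon: a pixel is inside iff its center is inside.

    The polygon is validated to be simple, so geometric containment coincides
    with the even-odd fill rule.  Deterministic by construction.
    """
    geom = poly.shapely()
    h, w = shape
    minx, miny, maxx, maxy = geom.bounds
    c0 = max(0, int(np.floor(minx)))
    c1 = min(w - 1, int(np.ceil(maxx)))
    r0 = max(0, int(np.floor(miny)))
    r1 = min(h - 1, int(np.ceil(maxy)))
    inside = np.zeros(shape, dtype=bool)
    if c1 >= c0 and r1 >= r0:
        cols = np.arange(c0, c1 + 1)
        rows = np.arange(r0, r1 + 1)
        cc, rr = np.meshgrid(cols, rows)
        hit = shapely.contains_xy(geom, cc.ravel().astype(float), rr.ravel().astype(float))
        inside[r0:r1 + 1, c0:c1 + 1] = hit.reshape(rr.shape)
    if int(inside.sum()) < 16:
        raise ValueError("ROI too small: mask has fewer than 16 pixels")
    return RoiMask(inside)


# ---------------------------------------------------------------------------
# Normalization and quantization

def normalization_window(img: GrayImage, mask: RoiMask) -> NormalizationWindow:
    vals = img.pixels[mask.inside]
    return NormalizationWindow(mu=float(vals.mean()), sigma=float(vals.std()))


def normalize_and_quantize(img: GrayImage, mask: RoiMask, bits: int) -> QuantizedImage:
    """Window in-ROI intensities to mu +/- 3 sigma and quantize to 2**bits levels.

    level(v) = clamp(1 + floor((v - lo) / (hi - lo) * Ng), 1, Ng); values at or
    below the window floor map to 1, at or above the ceiling to Ng.  A
    zero-variance ROI degenerates to all-ones with a warning so constant
    fixtures still flow through the pipeline.
    """
    if bits not in (4, 6):
        raise ValueError("bits must be 4 or 6")
    if mask.inside.shape != img.shape:
        raise ValueError("mask shape does not match image")
    ng = 1 << bits
    win = normalization_window(img, mask)
    levels = np.zeros(img.shape, dtype=np.int32)
    if win.sigma == 0.0:
        warnings.warn("degenerate +/-3 sigma window (sigma = 0): all levels set to 1")
        levels[mask.inside] = 1
        return QuantizedImage(levels, bits, mask, win)
    vals = img.pixels[mask.inside]
    lv = 1 + np.floor((vals - win.lo) / (win.hi - win.lo) * ng).astype(np.int64)
    np.clip(lv, 1, ng, out=lv)
    levels[mask.inside] = lv
    return QuantizedImage(levels, bits, mask, win)
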