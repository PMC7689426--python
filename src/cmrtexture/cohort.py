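"""Synthetic InterTAK-like imaging cohort.

Generates paired T2w/LGE-like short-axis slices with a left-ventricular
ROI drawn three times (reader 1 twice, reader 2 once), clinical covariates
and a binary 5-year MACCE label, emulating the 58-subject study cohort:
6 events (10.3%), 56 women (96.6%), age 68.4 +/- 11.8 years, BMI
24.4 +/- 4.3 kg/m^2, 256 x 256 images at 0.390625 mm.

Image model.  The LV is a slightly elliptical disc (myocardial annulus plus
blood pool) on a dark background.  T2w-like intensities inside the LV are a
smooth Gaussian random field whose correlation length and amplitude vary
from subject to subject — the reproducible between-subject texture signal —
with the outcome effect injected only here: event subjects get a longer
correlation length and a larger field amplitude.  LGE-like intensities are
a high-frequency, subject-indistinguishable field whose amplitude
(``lge_granularity``) makes LGE features hypersensitive to re-segmentation,
so they fail reliability filtering the way the study's LGE features did.
Reader variability is emulated by radial vertex jitter on the base polygon.

Random fields are white noise filtered with an isotropic Gaussian kernel of
width ell (pixels) and standardized before scaling — simple, seedable and
sufficient to modulate co-occurrence and run-length statistics.  Images are
rendered lazily from stored per-subject seeds, so demographics-only sweeps
are cheap while identical (spec, seed) still yields a bit-identical cohort.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .images import DEFAULT_SPACING_MM, GrayImage, RoiPolygon, save_roi_json, write_pgm

READINGS = ("reader1_read1", "reader1_read2", "reader2_read1")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    # cohort composition (study demographics)
    n_subjects: int = 58
    n_events: int = 6
    n_female: int = 56
    age_mean: float = 68.4
    age_sd: float = 11.8
    age_clip: tuple[float, float] = (30.0, 95.0)
    bmi_mean: float = 24.4
    bmi_sd: float = 4.3
    bmi_clip: tuple[float, float] = (14.0, 45.0)
    # geometry (pixels on the target grid)
    image_size: int = 256
    spacing: float = DEFAULT_SPACING_MM
    inner_radius: tuple[float, float] = (40.3, 40.7)
    outer_radius: tuple[float, float] = (62.0, 62.4)
    center_jitter: float = 3.0
    ellipticity: tuple[float, float] = (0.985, 1.0)
    n_vertices: int = 24
    # T2w-like sequence: smooth field with per-subject parameters
    t2w_base: float = 400.0
    t2w_sigma: float = 80.0
    t2w_sigma_subject_sd: float = 15.0
    t2w_ell: float = 3.0
    t2w_ell_subject_sd: float = 0.5
    t2w_noise_sd: float = 20.0
    t2w_pool_offset: float = 200.0
    # outcome effect, injected into T2w fields of event subjects only
    delta_ell: float = 2.5
    delta_sigma: float = 50.0
    # LGE-like sequence: high-frequency field, no subject-level parameters.
    # The field amplitude ramps up toward the LV boundary (edge weighting), so
    # re-segmentation swaps extreme-valued pixels and shifts the +/-3 sigma
    # window — the mechanism that makes LGE features unreliable.
    lge_base: float = 500.0
    lge_ell: float = 0.8
    lge_granularity: float = 80.0
    lge_edge_min: float = 0.3
    lge_edge_power: float = 3.0
    lge_noise_sd: float = 10.0
    lge_pool_offset: float = 100.0
    # background and readers
    background: float = 100.0
    background_noise_sd: float = 10.0
    roi_jitter: float = 1.5

    def __post_init__(self):
        if not 0 <= self.n_events <= self.n_subjects:
            raise ValueError("0 <= n_events <= n_subjects required")
        if not 0 <= self.n_female <= self.n_subjects:
            raise ValueError("0 <= n_female <= n_subjects required")
        if self.t2w_ell <= 0 or self.lge_ell <= 0:
            raise ValueError("correlation lengths must be positive")
        for sd in (self.age_sd, self.bmi_sd, self.t2w_noise_sd, self.lge_noise_sd,
                   self.background_noise_sd, self.roi_jitter):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")
        if self.outer_radius[0] <= self.inner_radius[1]:
            raise ValueError("degenerate ring radii")
        if self.outer_radius[1] + self.center_jitter + 2 >= self.image_size / 2:
            raise ValueError("ring does not fit inside the image")

    def null(self) -> "SyntheticCohortSpec":
        """Uninformative-T2w variant: the outcome effect switched off."""
        return replace(self, delta_ell=0.0, delta_sigma=0.0)


@dataclass(frozen=True)
class SubjectGeometry:
    center: tuple[float, float]     # (row, col)
    inner_radius: float
    outer_radius: float
    ellipticity: float              # row-axis / col-axis ratio


@dataclass
class SyntheticSubject:
    subject_id: str
    age: float
    sex: int                        # 1 = female
    bmi: float
    macce: int
    geometry: SubjectGeometry
    rois: dict[str, RoiPolygon]
    _spec: SyntheticCohortSpec
    _render_seed: int
    _ell: float
    _sigma: float
    _images: tuple[GrayImage, GrayImage] | None = None

    def _render(self) -> tuple[GrayImage, GrayImage]:
        if self._images is None:
            self._images = render_subject(self._spec, self.geometry, self._ell,
                                          self._sigma, self._render_seed)
        return self._images

    @property
    def t2w(self) -> GrayImage:
        return self._render()[0]

    @property
    def lge(self) -> GrayImage:
        return self._render()[1]


# ---------------------------------------------------------------------------
# Rendering

def _elliptical_radius(spec: SyntheticCohortSpec, geom: SubjectGeometry) -> np.ndarray:
    n = spec.image_size
    rr, cc = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float),
                         indexing="ij")
    return np.hypot((rr - geom.center[0]) / geom.ellipticity, cc - geom.center[1])


def _random_field(rng: np.random.Generator, n: int, ell: float) -> np.ndarray:
    field = gaussian_filter(rng.standard_normal((n, n)), sigma=ell, mode="reflect")
    return (field - field.mean()) / field.std()


def render_subject(spec: SyntheticCohortSpec, geom: SubjectGeometry,
                   ell: float, sigma: float, seed: int
                   ) -> tuple[GrayImage, GrayImage]:
    """Render the T2w/LGE pair for one subject's geometry and field parameters."""
    if geom.inner_radius >= geom.outer_radius:
        raise ValueError("degenerate ring radii")
    rng = np.random.default_rng(seed)
    n = spec.image_size
    rho = _elliptical_radius(spec, geom)
    disc = rho <= geom.outer_radius
    pool = rho <= max(geom.inner_radius - 4.0, 2.0)

    t2w = spec.background + spec.background_noise_sd * rng.standard_normal((n, n))
    smooth = _random_field(rng, n, ell)
    t2w[disc] = (spec.t2w_base + sigma * smooth[disc]
                 + spec.t2w_noise_sd * rng.standard_normal((n, n))[disc])
    t2w[pool] += spec.t2w_pool_offset

    lge = spec.background + spec.background_noise_sd * rng.standard_normal((n, n))
    grainy = _random_field(rng, n, spec.lge_ell)
    edge_w = (spec.lge_edge_min + (1.0 - spec.lge_edge_min)
              * np.clip(rho / geom.outer_radius, 0.0, 1.0) ** spec.lge_edge_power)
    lge[disc] = (spec.lge_base + spec.lge_granularity * (edge_w * grainy)[disc]
                 + spec.lge_noise_sd * rng.standard_normal((n, n))[disc])
    lge[pool] += spec.lge_pool_offset

    sp = spec.spacing
    return GrayImage(t2w, sp, sp), GrayImage(lge, sp, sp)


def base_polygon(spec: SyntheticCohortSpec, geom: SubjectGeometry) -> RoiPolygon:
    """Trace of the LV outer boundary: n_vertices points just outside the ring."""
    theta = np.linspace(0.0, 2.0 * np.pi, spec.n_vertices, endpoint=False)
    r = geom.outer_radius + 0.5
    x = geom.center[1] + r * np.cos(theta)
    y = geom.center[0] + r * geom.ellipticity * np.sin(theta)
    return RoiPolygon(np.column_stack([x, y]))


def perturb_polygon(poly: RoiPolygon, magnitude: float, seed: int,
                    reader: int = 1, read: int = 1) -> RoiPolygon:
    """Radially jitter each vertex by N(0, magnitude^2) pixels.

    The result must stay simple; after 10 failed attempts the last valid
    polygon (the input, if none succeeded) is returned with a warning.
    Magnitude 0 is the identity.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if magnitude == 0:
        return RoiPolygon(poly.vertices.copy(), reader=reader, read=read)
    rng = np.random.default_rng(seed)
    centroid = poly.vertices.mean(axis=0)
    for _ in range(10):
        offsets = poly.vertices - centroid
        radii = np.hypot(offsets[:, 0], offsets[:, 1])
        scale = 1.0 + rng.normal(0.0, magnitude, len(radii)) / radii
        v = centroid + offsets * scale[:, None]
        try:
            return RoiPolygon(v, reader=reader, read=read)
        except ValueError:
            continue
    warnings.warn("polygon perturbation kept breaking simplicity; "
                  "returning the unperturbed polygon")
    return RoiPolygon(poly.vertices.copy(), reader=reader, read=read)


# ---------------------------------------------------------------------------
# Cohort assembly

def generate_cohort(spec: SyntheticCohortSpec = SyntheticCohortSpec(),
                    seed: int = 0) -> list[SyntheticSubject]:
    """Generate the cohort: exact label/sex counts, seeded everything.

    Ages and BMIs are drawn from the configured normals and clipped to
    plausible ranges (clipping is logged).  Identical (spec, seed) yields a
    bit-identical cohort; images render lazily from stored child seeds.
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    n = spec.n_subjects

    ages = rng.normal(spec.age_mean, spec.age_sd, n)
    bmis = rng.normal(spec.bmi_mean, spec.bmi_sd, n)
    n_clip = int(np.sum((ages < spec.age_clip[0]) | (ages > spec.age_clip[1]))
                 + np.sum((bmis < spec.bmi_clip[0]) | (bmis > spec.bmi_clip[1])))
    if n_clip:
        warnings.warn(f"{n_clip} demographic draws clipped to plausible ranges")
    ages = np.clip(ages, *spec.age_clip)
    bmis = np.clip(bmis, *spec.bmi_clip)

    macce = np.zeros(n, dtype=int)
    macce[rng.permutation(n)[:spec.n_events]] = 1
    female = np.zeros(n, dtype=int)
    female[rng.permutation(n)[:spec.n_female]] = 1

    render_seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]
    subjects = []
    for i in range(n):
        geom = SubjectGeometry(
            center=(spec.image_size / 2 + rng.uniform(-spec.center_jitter, spec.center_jitter),
                    spec.image_size / 2 + rng.uniform(-spec.center_jitter, spec.center_jitter)),
            inner_radius=float(rng.uniform(*spec.inner_radius)),
            outer_radius=float(rng.uniform(*spec.outer_radius)),
            ellipticity=float(rng.uniform(*spec.ellipticity)),
        )
        ell = max(0.5, rng.normal(spec.t2w_ell, spec.t2w_ell_subject_sd))
        sigma = max(10.0, rng.normal(spec.t2w_sigma, spec.t2w_sigma_subject_sd))
        if macce[i] == 1:
            ell += spec.delta_ell
            sigma += spec.delta_sigma
        base = base_polygon(spec, geom)
        rois = {
            "reader1_read1": perturb_polygon(base, spec.roi_jitter,
                                             int(rng.integers(2 ** 31)), 1, 1),
            "reader1_read2": perturb_polygon(base, spec.roi_jitter,
                                             int(rng.integers(2 ** 31)), 1, 2),
            "reader2_read1": perturb_polygon(base, spec.roi_jitter,
                                             int(rng.integers(2 ** 31)), 2, 1),
        }
        subjects.append(SyntheticSubject(
            subject_id=f"S{i + 1:03d}", age=float(ages[i]), sex=int(female[i]),
            bmi=float(bmis[i]), macce=int(macce[i]), geometry=geom, rois=rois,
            _spec=spec, _render_seed=render_seeds[i], _ell=float(ell),
            _sigma=float(sigma)))
    return subjects


def write_cohort(subjects: list[SyntheticSubject], out_dir,
                 spec: SyntheticCohortSpec, seed: int) -> None:
    """Persist the cohort: PGM images + sidecars, ROI JSONs, cohort CSV, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        write_pgm(s.t2w, out / f"{s.subject_id}_T2w.pgm")
        write_pgm(s.lge, out / f"{s.subject_id}_LGE.pgm")
        for key, poly in s.rois.items():
            save_roi_json(poly, out / f"{s.subject_id}_roi_{key}.json")
        rows.append(f"{s.subject_id},{s.age:.6f},{s.sex},{s.bmi:.6f},{s.macce}")
    (out / "cohort.csv").write_text(
        "subject_id,age,sex,bmi,MACCE\n" + "\n".join(rows) + "\n")
    (out / "manifest.json").write_text(json.dumps(
        {"spec": asdict(spec), "seed": seed}, indent=2, default=list))
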