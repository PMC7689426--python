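import time
import warnings

import numpy as np
import pytest

from cmrtexture.cohort import SyntheticCohortSpec
from cmrtexture.images import GrayImage, QuantizedImage, RoiMask

N_CALIBRATION_SEEDS = 20


def run_nb_pipeline(spec, seed):
    """Default-conditions pipeline with the NaiveBayes classifier."""
    from cmrtexture.pipeline import RunConfig, run_pipeline

    cfg = RunConfig(seed=seed, classifiers=("NaiveBayes",), cohort=spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(cfg)


@pytest.fixture(scope="session")
def strong_effect_runs():
    """Full pipeline on default (strong T2w effect) cohorts, 20 seeds."""
    spec = SyntheticCohortSpec()
    runs, durations = [], []
    for seed in range(1, N_CALIBRATION_SEEDS + 1):
        t0 = time.monotonic()
        res = run_nb_pipeline(spec, seed)
        durations.append(time.monotonic() - t0)
        auc = res.classifier_results["NaiveBayes"]["metrics"][1]["pooled"]["roc_auc"]
        runs.append({"kept": res.kept, "auc": auc})
    return {"runs": runs, "durations": durations}


@pytest.fixture(scope="session")
def null_effect_aucs():
    """Pipeline AUCs on effect-free cohorts, 20 seeds."""
    spec = SyntheticCohortSpec().null()
    aucs = []
    for seed in range(1, N_CALIBRATION_SEEDS + 1):
        res = run_nb_pipeline(spec, seed)
        aucs.append(res.classifier_results["NaiveBayes"]
                    ["metrics"][1]["pooled"]["roc_auc"])
    return aucs


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_quantized(levels, bits=6) -> QuantizedImage:
    """QuantizedImage straight from a level array (0 = out of mask)."""
    return QuantizedImage(np.asarray(levels), bits)


def make_gray(pixels, spacing=1.0) -> GrayImage:
    return GrayImage(np.asarray(pixels, dtype=float), spacing, spacing)


def full_mask(shape) -> RoiMask:
    return RoiMask(np.ones(shape, dtype=bool))


@pytest.fixture(scope="session")
def small_cohort_spec():
    """Reduced cohort for structural tests (defaults are exercised elsewhere)."""
    return SyntheticCohortSpec(
        n_subjects=10, n_events=3, n_female=9, image_size=128,
        inner_radius=(20.0, 20.4), outer_radius=(31.0, 31.4),
        center_jitter=2.0,
    )


@pytest.fixture(scope="session")
def glcm_fixture_images():
    """>= 20 small integer images (<= 8x8) for exhaustive-enumeration checks."""
    gen = np.random.default_rng(4242)
    images = []
    for _ in range(18):
        shape = gen.choice([4, 5, 6, 8], size=2)
        levels = gen.integers(1, 5, size=tuple(shape))
        if gen.random() < 0.5:   # knock holes into the mask
            holes = gen.random(size=levels.shape) < 0.2
            levels = np.where(holes, 0, levels)
        images.append(levels.astype(np.int64))
    images.append(np.ones((4, 4), dtype=np.int64))            # constant
    images.append(np.indices((6, 6)).sum(0) % 4 + 1)          # diagonal stripes
    images.append(np.tile([1, 2], (6, 3)).astype(np.int64))   # alternating cols
    return images
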