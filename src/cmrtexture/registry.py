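"""Data-driven feature registry.

Every computable texture feature is named by a descriptor; the shipped
default panel enumerates six families per ROI:

* 4 histogram moments,
* 11 Haralick statistics x 5 interpixel distances x 4 directions = 220 GLCM,
* 5 Galloway statistics x 4 angles = 20 RLM,
* 5 absolute-gradient statistics,
* 5 causal autoregressive parameters (theta1..4, sigma),
* 4 Haar sub-band energies x 7 scales = 28 wavelet,

282 features in total.  The panel size is a property of the registry, not a
hard-coded constant: registries round-trip through a plain-text file with
one ``family;param=value;...;name`` line per descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .armodel import AR_FEATURE_NAMES
from .firstorder import HISTOGRAM_FEATURE_NAMES
from .glcm import GLCM_FEATURE_NAMES
from .rlm import RLM_ANGLES, RLM_FEATURE_NAMES
from .wavelet import MAX_WAVELET_SCALE, WAVELET_SUBBANDS

FAMILIES = ("histogram", "glcm", "rlm", "gradient", "ar", "wavelet")

_GRADIENT_NAMES = ("Mean", "Variance", "Skewness", "Kurtosis", "NonZeros")


@dataclass(frozen=True)
class FeatureDescriptor:
    family: str
    name: str                      # canonical, e.g. "GLCM.d4.a135.DifVarnc"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown feature family {self.family!r}")


def default_registry() -> list[FeatureDescriptor]:
    reg: list[FeatureDescriptor] = []
    for stat in HISTOGRAM_FEATURE_NAMES:
        reg.append(FeatureDescriptor("histogram", f"Hist.{stat}", {"stat": stat}))
    for d in range(1, 6):
        for angle in (0, 90, 45, 135):
            for stat in GLCM_FEATURE_NAMES:
                reg.append(FeatureDescriptor(
                    "glcm", f"GLCM.d{d}.a{angle}.{stat}",
                    {"distance": d, "angle": angle, "stat": stat}))
    for angle in RLM_ANGLES:
        for stat in RLM_FEATURE_NAMES:
            reg.append(FeatureDescriptor(
                "rlm", f"RLM.a{angle}.{stat}", {"angle": angle, "stat": stat}))
    for stat in _GRADIENT_NAMES:
        reg.append(FeatureDescriptor("gradient", f"Grad.{stat}", {"stat": stat}))
    for stat in AR_FEATURE_NAMES:
        reg.append(FeatureDescriptor("ar", f"AR.{stat}", {"stat": stat}))
    for s in range(1, MAX_WAVELET_SCALE + 1):
        for band in WAVELET_SUBBANDS:
            reg.append(FeatureDescriptor(
                "wavelet", f"Wav.s{s}.{band}", {"scale": s, "band": band}))
    return reg


def validate_registry(registry: list[FeatureDescriptor]) -> None:
    names = [d.name for d in registry]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate feature names in registry: {dup}")


def save_registry(registry: list[FeatureDescriptor], path) -> None:
    lines = []
    for d in registry:
        parts = [d.family] + [f"{k}={v}" for k, v in sorted(d.params.items())] + [d.name]
        lines.append(";".join(parts))
    Path(path).write_text("\n".join(lines) + "\n")


def _coerce(value: str):
    try:
        return int(value)
    except ValueError:
        try:
            return float(value)
        except ValueError:
            return value


def load_registry(path) -> list[FeatureDescriptor]:
    reg = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(";")
        family, name = parts[0], parts[-1]
        params = {}
        for kv in parts[1:-1]:
            k, _, v = kv.partition("=")
            params[k] = _coerce(v)
        reg.append(FeatureDescriptor(family, name, params))
    validate_registry(reg)
    return reg
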