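"""Second-order texture feature extraction for single lesions.

The pipeline per lesion is: fixed-bin-width discretization of the HU
intensities, construction of the five texture-matrix families (GLCM,
GLRLM, GLSZM, GLDM, NGTDM), and evaluation of the canonical 75-feature
set (24 + 16 + 16 + 14 + 5).  Feature names follow the
``original_<family>_<Feature>`` convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from ..io import LesionRegion
from . import _features, _matrices
from ._matrices import DIRECTIONS_13, glcm_per_angle, glrlm_per_angle, glszm, gldm, ngtdm

__all__ = [
    "DiscretizedLesion",
    "ExtractionConfig",
    "FeatureVector",
    "FEATURE_NAMES",
    "FAMILY_SIZES",
    "discretize",
    "compute_glcm",
    "compute_glrlm",
    "compute_glszm",
    "compute_gldm",
    "compute_ngtdm",
    "compute_features",
]

FAMILY_SIZES = {"glcm": 24, "glrlm": 16, "glszm": 16, "gldm": 14, "ngtdm": 5}

_GLCM_NAMES = [
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
]
_GLRLM_NAMES = [
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
]
_GLSZM_NAMES = [
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
]
_GLDM_NAMES = [
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
]
_NGTDM_NAMES = ["Busyness", "Coarseness", "Complexity", "Contrast", "Strength"]

#: Canonical ordered 75 feature names (family order, alphabetical within).
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"original_{family}_{name}"
    for family, names in (
        ("glcm", _GLCM_NAMES),
        ("glrlm", _GLRLM_NAMES),
        ("glszm", _GLSZM_NAMES),
        ("gldm", _GLDM_NAMES),
        ("ngtdm", _NGTDM_NAMES),
    )
    for name in names
)
assert len(FEATURE_NAMES) == sum(FAMILY_SIZES.values()) == 75


@dataclass(frozen=True)
class ExtractionConfig:
    """Extraction settings, serialized next to outputs for provenance.

    bin_width: HU per discretization bin (fixed-bin-width scheme).
    distance: Chebyshev pair distance for the GLCM.
    gldm_alpha: level-difference tolerance for dependence counting.
    connectivity: neighbourhood for zones/dependence/tone-difference.
    """

    bin_width: float = 25.0
    distance: int = 1
    gldm_alpha: float = 0.0
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.connectivity != 26:
            raise ValueError("only 26-connectivity is supported")

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"bin_width = {self.bin_width:g}",
            f"distance = {self.distance}",
            f"gldm_alpha = {self.gldm_alpha:g}",
            f"connectivity = {self.connectivity}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ExtractionConfig":
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
        return cls(
            bin_width=float(kv.get("bin_width", 25)),
            distance=int(kv.get("distance", 1)),
            gldm_alpha=float(kv.get("gldm_alpha", 0)),
            connectivity=int(kv.get("connectivity", 26)),
        )


@dataclass(frozen=True)
class DiscretizedLesion:
    """Per-voxel integer gray levels 1..Ng plus the binning metadata.

    Level i covers the half-open interval
    [min + (i-1)*bin_width, min + i*bin_width).
    """

    gray_levels: np.ndarray
    n_levels: int
    bin_width: float
    min_intensity: float
    voxel_coordinates: np.ndarray

    def bin_edges(self, level: int) -> tuple[float, float]:
        lo = self.min_intensity + (level - 1) * self.bin_width
        return lo, lo + self.bin_width

    def to_grid(self) -> np.ndarray:
        """Embed levels in a bounding-box grid; 0 marks outside-mask."""
        coords = self.voxel_coordinates
        lo = coords.min(axis=0)
        shape = coords.max(axis=0) - lo + 1
        grid = np.zeros(tuple(shape), dtype=np.int32)
        grid[tuple((coords - lo).T)] = self.gray_levels
        return grid


def discretize(region: LesionRegion, bin_width: float = 25.0) -> DiscretizedLesion:
    """Fixed-bin-width discretization anchored at the lesion's minimum HU."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    x = region.voxel_intensities
    lo = float(x.min())
    levels = np.floor((x - lo) / bin_width).astype(np.int32) + 1
    n_levels = int(math.floor((float(x.max()) - lo) / bin_width)) + 1
    return DiscretizedLesion(
        gray_levels=levels,
        n_levels=n_levels,
        bin_width=float(bin_width),
        min_intensity=lo,
        voxel_coordinates=region.voxel_coordinates,
    )


def compute_glcm(d: DiscretizedLesion, distance: int = 1) -> np.ndarray:
    """Per-angle symmetric normalized GLCMs, shape (13, Ng, Ng)."""
    return glcm_per_angle(d.to_grid(), d.n_levels, distance)


def compute_glrlm(d: DiscretizedLesion) -> np.ndarray:
    """Per-angle run-length count matrices, shape (13, Ng, Nr)."""
    return glrlm_per_angle(d.to_grid(), d.n_levels)


def compute_glszm(d: DiscretizedLesion) -> np.ndarray:
    """Size-zone count matrix (Ng, Ns), 26-connected zones."""
    return glszm(d.to_grid(), d.n_levels)


def compute_gldm(d: DiscretizedLesion, alpha: float = 0.0) -> np.ndarray:
    """Dependence count matrix (Ng, Nd); column j = dependence j-1."""
    return gldm(d.to_grid(), d.n_levels, alpha)


def compute_ngtdm(d: DiscretizedLesion) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-level (n_i, p_i, s_i) triples."""
    return ngtdm(d.to_grid(), d.n_levels)


class FeatureVector(Mapping):
    """Ordered mapping of the canonical 75 feature names to finite values."""

    __slots__ = ("values",)

    def __init__(self, values: Mapping[str, float]):
        if tuple(values) != FEATURE_NAMES:
            missing = set(FEATURE_NAMES) - set(values)
            extra = set(values) - set(FEATURE_NAMES)
            raise ValueError(
                f"feature vector must carry the canonical 75 names in order "
                f"(missing={sorted(missing)[:3]}..., extra={sorted(extra)[:3]}...)"
            )
        bad = [k for k, v in values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad}")
        self.values = {k: float(v) for k, v in values.items()}

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def __repr__(self) -> str:
        return f"FeatureVector({len(self.values)} features)"


def compute_features(region: LesionRegion, config: ExtractionConfig | None = None) -> FeatureVector:
    """Discretize one lesion and evaluate all 75 second-order features."""
    config = config or ExtractionConfig()
    d = discretize(region, config.bin_width)
    grid = d.to_grid()
    ng = d.n_levels

    out: dict[str, float] = {}
    fam = _features.glcm_features(_matrices.glcm_per_angle(grid, ng, config.distance), ng)
    out.update({f"original_glcm_{k}": fam[k] for k in _GLCM_NAMES})
    fam = _features.glrlm_features(_matrices.glrlm_per_angle(grid, ng), ng)
    out.update({f"original_glrlm_{k}": fam[k] for k in _GLRLM_NAMES})
    fam = _features.glszm_features(_matrices.glszm(grid, ng), ng)
    out.update({f"original_glszm_{k}": fam[k] for k in _GLSZM_NAMES})
    fam = _features.gldm_features(_matrices.gldm(grid, ng, config.gldm_alpha), ng)
    out.update({f"original_gldm_{k}": fam[k] for k in _GLDM_NAMES})
    n, p, s = _matrices.ngtdm(grid, ng)
    fam = _features.ngtdm_features(n, p, s)
    out.update({f"original_ngtdm_{k}": fam[k] for k in _NGTDM_NAMES})
    return FeatureVector(out)
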