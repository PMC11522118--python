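"""Synthetic two-cohort lesion phantoms with controllable interlesional dispersion.

Each patient carries several ellipsoidal lesions embedded in a liver-like
constant background (60 HU).  Lesion texture is a stationary Gaussian
random field: white noise N(mean_hu, sd_hu) smoothed with an isotropic
Gaussian kernel of scale ``correlation_length_vox`` and rescaled so the
field variance stays sd_hu**2 (larger correlation lengths give coarser
texture at equal contrast).

The interlesional-heterogeneity ground truth is the dispersion tau: each
lesion's texture parameters are the patient's parameters multiplied by
independent lognormal factors with log-sd tau, so the coefficient of
variation of a parameter across one patient's lesions is analytically
sqrt(exp(tau**2) - 1).  Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import ImageVolume, LabelMask, write_mask, write_volume

__all__ = [
    "TextureParams",
    "CohortSpec",
    "PatientPhantom",
    "generate_lesion",
    "generate_patient",
    "iterate_patients",
    "generate_study",
]

BACKGROUND_HU = 60.0
DEFAULT_SPACING = (0.7, 0.7, 1.5)

#: Between-patient lognormal log-sd of the texture parameters around the
#: cohort prior (fixed; the recoverable dial is the within-patient tau).
PATIENT_LEVEL_LOG_SD = 0.1

_PARAM_FIELDS = ("mean_hu", "sd_hu", "correlation_length_vox", "lesion_radius_vox")


@dataclass(frozen=True)
class TextureParams:
    """Parameters of one lesion's (or one patient's) texture field."""

    mean_hu: float = 90.0
    sd_hu: float = 20.0
    correlation_length_vox: float = 1.5
    lesion_radius_vox: float = 7.0

    def __post_init__(self) -> None:
        if self.sd_hu <= 0:
            raise ValueError("sd_hu must be > 0")
        if self.correlation_length_vox <= 0:
            raise ValueError("correlation_length_vox must be > 0")
        if self.lesion_radius_vox < 2:
            raise ValueError("lesion_radius_vox must be >= 2")

    def scaled(self, factors: np.ndarray) -> "TextureParams":
        """Multiply each parameter by its factor, clipping at validity bounds."""
        values = dict(zip(_PARAM_FIELDS, factors))
        return TextureParams(
            mean_hu=self.mean_hu * values["mean_hu"],
            sd_hu=max(self.sd_hu * values["sd_hu"], 1e-9),
            correlation_length_vox=max(
                self.correlation_length_vox * values["correlation_length_vox"], 1e-3
            ),
            lesion_radius_vox=max(self.lesion_radius_vox * values["lesion_radius_vox"], 2.0),
        )


@dataclass(frozen=True)
class CohortSpec:
    """One cohort of a synthetic study.

    ``interlesional_dispersion`` (tau >= 0) is the within-patient log-sd of
    the per-lesion parameter factors — the quantity the CV statistic is
    meant to recover.
    """

    name: str
    n_patients: int
    lesions_per_patient: tuple[int, int] = (2, 85)
    patient_texture_prior: TextureParams = field(default_factory=TextureParams)
    interlesional_dispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("cohort name must be non-empty")
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        lo, hi = self.lesions_per_patient
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid lesions_per_patient range {self.lesions_per_patient}")
        if self.interlesional_dispersion < 0:
            raise ValueError("interlesional_dispersion (tau) must be >= 0")


@dataclass(frozen=True)
class PatientPhantom:
    """One generated patient: volume, mask, and the ground-truth parameters."""

    patient_id: str
    volume: ImageVolume
    mask: LabelMask
    lesion_params: tuple[TextureParams, ...]
    patient_params: TextureParams


def _smoothing_sd_factor(sigma: float) -> float:
    """Standard-deviation shrinkage of white noise under Gaussian smoothing.

    For the separable 3-D kernel scipy applies (1-D weights k, three
    identical axes) the smoothed field's variance is (sum k^2)^3 times the
    input variance; dividing by this factor's square root restores the
    target sd in the field interior.
    """
    radius = int(4.0 * sigma + 0.5)  # scipy's default truncation
    if radius == 0:
        return 1.0
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    k /= k.sum()
    return float((k**2).sum() ** 1.5)


def _texture_field(shape: tuple[int, int, int], params: TextureParams,
                   rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(shape)
    sigma = params.correlation_length_vox
    smoothed = ndimage.gaussian_filter(noise, sigma=sigma)
    return params.mean_hu + params.sd_hu * smoothed / _smoothing_sd_factor(sigma)


def _ellipsoid_mask(shape: tuple[int, int, int], radii: np.ndarray) -> np.ndarray:
    center = (np.array(shape) - 1) / 2.0
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return r2 <= 1.0


def generate_lesion(params: TextureParams, rng: np.random.Generator,
                    shape: tuple[int, int, int] | None = None,
                    spacing: tuple[float, float, float] = DEFAULT_SPACING,
                    ) -> tuple[ImageVolume, LabelMask]:
    """One ellipsoidal lesion (+/-30% axis anisotropy) in a padded volume."""
    radii = params.lesion_radius_vox * (1.0 + rng.uniform(-0.3, 0.3, size=3))
    radii = np.maximum(radii, 1.0)
    if shape is None:
        shape = tuple(int(2 * math.ceil(r)) + 3 for r in radii)
    else:
        if any(2 * r + 2 > n for r, n in zip(radii, shape)):
            raise ValueError(
                f"lesion radius {params.lesion_radius_vox} too large for volume shape {shape}"
            )
    mask = _ellipsoid_mask(shape, radii)
    field = _texture_field(shape, params, rng)
    data = np.full(shape, BACKGROUND_HU, dtype=np.float32)
    data[mask] = field[mask]
    return (
        ImageVolume(data=data, spacing=spacing),
        LabelMask(labels=mask.astype(np.int16)),
    )


#: Lognormal draws are truncated at this many log-sd so that a single
#: extreme factor cannot produce an unrealistically large or degenerate
#: lesion; <1.3% of draws are affected at any tau.
_FACTOR_TRUNCATION_SD = 2.5


def _draw_params(base: TextureParams, log_sd: float, rng: np.random.Generator) -> TextureParams:
    if log_sd == 0:
        return base
    z = rng.normal(0.0, 1.0, size=len(_PARAM_FIELDS))
    z = np.clip(z, -_FACTOR_TRUNCATION_SD, _FACTOR_TRUNCATION_SD)
    return base.scaled(np.exp(log_sd * z))


def generate_patient(spec: CohortSpec, patient_index: int,
                     spacing: tuple[float, float, float] = DEFAULT_SPACING,
                     max_placement_tries: int = 500) -> PatientPhantom:
    """Generate one patient's multi-lesion volume and ground-truth parameters."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, patient_index]))
    patient_params = _draw_params(spec.patient_texture_prior, PATIENT_LEVEL_LOG_SD, rng)
    lo, hi = spec.lesions_per_patient
    n_lesions = int(rng.integers(lo, hi + 1))
    tau = spec.interlesional_dispersion
    lesion_params = tuple(_draw_params(patient_params, tau, rng) for _ in range(n_lesions))

    lesions = [generate_lesion(p, rng, spacing=spacing) for p in lesion_params]
    boxes = [vol.data.shape for vol, _ in lesions]

    # pack lesion bounding boxes without overlap into one volume
    max_box = np.max(boxes, axis=0)
    # ~2x volume slack keeps random rejection-sampling placement reliable;
    # if a draw still fails, the volume is grown once before giving up
    origins: list[np.ndarray] = []
    for slack in (2.0, 5.0):
        per_axis = int(math.ceil((slack * n_lesions) ** (1.0 / 3.0)))
        side = per_axis * (max_box + 1) + 2
        placed: list[tuple[np.ndarray, np.ndarray]] = []
        origins = []
        failed = False
        for box in boxes:
            box = np.array(box)
            ok = False
            for _ in range(max_placement_tries):
                origin = np.array([rng.integers(1, s - b) for s, b in zip(side, box)])
                if all(
                    np.any(origin + box <= o0) or np.any(o0 + b0 <= origin)
                    for o0, b0 in placed
                ):
                    placed.append((origin, box))
                    origins.append(origin)
                    ok = True
                    break
            if not ok:
                failed = True
                break
        if not failed:
            break
    else:
        raise RuntimeError(
            f"could not place {n_lesions} lesions after {max_placement_tries} tries"
        )

    data = np.full(tuple(side), BACKGROUND_HU, dtype=np.float32)
    labels = np.zeros(tuple(side), dtype=np.int16)
    for k, ((vol, msk), origin) in enumerate(zip(lesions, origins), start=1):
        sl = tuple(slice(o, o + n) for o, n in zip(origin, vol.data.shape))
        inside = msk.labels > 0
        data[sl][inside] = vol.data[inside]
        labels[sl][inside] = k

    patient_id = f"{spec.name}-{patient_index:03d}"
    return PatientPhantom(
        patient_id=patient_id,
        volume=ImageVolume(data=data, spacing=spacing),
        mask=LabelMask(labels=labels),
        lesion_params=lesion_params,
        patient_params=patient_params,
    )


def iterate_patients(spec: CohortSpec,
                     spacing: tuple[float, float, float] = DEFAULT_SPACING,
                     ) -> Iterator[PatientPhantom]:
    """All patients of a cohort, deterministically from (spec, seed)."""
    for idx in range(spec.n_patients):
        yield generate_patient(spec, idx, spacing=spacing)


def _params_rows(phantom: PatientPhantom, cohort: str, tau: float) -> list[dict]:
    rows = []
    for k, p in enumerate(phantom.lesion_params, start=1):
        rows.append({
            "patient_id": phantom.patient_id,
            "cohort": cohort,
            "lesion_id": k,
            "tau": tau,
            "mean_hu": p.mean_hu,
            "sd_hu": p.sd_hu,
            "correlation_length_vox": p.correlation_length_vox,
            "lesion_radius_vox": p.lesion_radius_vox,
            "patient_mean_hu": phantom.patient_params.mean_hu,
            "patient_sd_hu": phantom.patient_params.sd_hu,
        })
    return rows


def generate_study(spec_a: CohortSpec, spec_b: CohortSpec, out_dir: str | Path,
                   overwrite: bool = False,
                   spacing: tuple[float, float, float] = DEFAULT_SPACING) -> Path:
    """Write a full two-cohort study: NRRD volumes/masks, manifest, ground truth.

    Returns the manifest path.  The manifest has columns patient_id,
    cohort, volume_path, mask_path; the ground-truth CSV logs every
    lesion's drawn texture parameters and the cohort tau.
    """
    if spec_a.name == spec_b.name:
        raise ValueError("cohort names must be distinct")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out_dir} is not empty (pass overwrite=True)")
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest_rows = []
    truth_rows = []
    for spec in (spec_a, spec_b):
        for phantom in iterate_patients(spec, spacing=spacing):
            vol_path = out_dir / f"{phantom.patient_id}_volume.nrrd"
            mask_path = out_dir / f"{phantom.patient_id}_mask.nrrd"
            write_volume(phantom.volume, vol_path)
            write_mask(phantom.mask, spacing, mask_path)
            manifest_rows.append({
                "patient_id": phantom.patient_id,
                "cohort": spec.name,
                "volume_path": vol_path.name,
                "mask_path": mask_path.name,
            })
            truth_rows.extend(_params_rows(phantom, spec.name, spec.interlesional_dispersion))

    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    pd.DataFrame(truth_rows).to_csv(out_dir / "ground_truth.csv", index=False, float_format="%.12g")
    return manifest_path
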