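"""Patient-wise coefficient of variation: the interlesional heterogeneity statistic.

For each patient and each texture feature, the coefficient of variation

    CV = sigma / mu * 100%

is computed across that patient's lesions, with sigma the sample (n-1)
standard deviation.  A high CV marks a feature that varies strongly
between the lesions of one patient.  Features whose mean across lesions is
non-positive get a flag (the CV's sign/magnitude is not interpretable
there) but the raw value is kept, never silently dropped.  Patients with
fewer than two lesions have no defined CV and are excluded with a logged
warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CVResult",
    "CVMatrix",
    "patient_cv",
    "build_cv_matrix",
    "mean_cv_per_feature",
    "heatmap_table",
]


class CVResult(NamedTuple):
    value: float
    mean_nonpositive: bool


def patient_cv(values: Sequence[float], use_abs_mean: bool = False) -> CVResult:
    """CV in percent across one patient's lesion values for one feature.

    ``use_abs_mean`` divides by |mu| instead of mu (an option for features
    whose domain includes negative values); the flag is set whenever
    mu <= 0 regardless.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("patient_cv needs at least 2 lesion values (insufficient_lesions)")
    mu = x.mean()
    sd = x.std(ddof=1)
    denom = abs(mu) if use_abs_mean else mu
    if denom == 0:
        return CVResult(value=np.inf if sd > 0 else 0.0, mean_nonpositive=True)
    return CVResult(value=sd / denom * 100.0, mean_nonpositive=mu <= 0)


@dataclass(frozen=True)
class CVMatrix:
    """Patients x features table of patient-wise CVs (percent) plus flags.

    ``values``: DataFrame indexed by patient id, one column per feature.
    ``mean_nonpositive``: same-shaped boolean DataFrame.
    ``n_lesions``: lesions per patient that fed the CVs.
    """

    values: pd.DataFrame
    mean_nonpositive: pd.DataFrame
    n_lesions: pd.Series

    @property
    def patients(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)


def build_cv_matrix(feature_table: pd.DataFrame, manifest: pd.DataFrame,
                    use_abs_mean: bool = False) -> CVMatrix:
    """One CV per (patient, feature) over that patient's lesions.

    ``feature_table`` holds one row per lesion (columns patient_id,
    lesion_id, then features); every patient must appear in the manifest
    and lesion ids must be unique within a patient.  Patients with fewer
    than two lesions are dropped with a warning.
    """
    known = set(manifest["patient_id"])
    offenders = sorted(set(feature_table["patient_id"]) - known)
    if offenders:
        raise ValueError(f"feature table references unknown patient ids: {offenders}")
    dup = feature_table.duplicated(subset=["patient_id", "lesion_id"])
    if dup.any():
        pairs = feature_table.loc[dup, ["patient_id", "lesion_id"]].values.tolist()
        raise ValueError(f"duplicated (patient_id, lesion_id) rows: {pairs}")

    feature_cols = [c for c in feature_table.columns if c not in ("patient_id", "lesion_id")]
    values: dict[str, dict[str, float]] = {}
    flags: dict[str, dict[str, bool]] = {}
    n_lesions: dict[str, int] = {}
    n_dropped = 0
    for patient_id, group in feature_table.groupby("patient_id", sort=False):
        if len(group) < 2:
            n_dropped += 1
            continue
        row_v: dict[str, float] = {}
        row_f: dict[str, bool] = {}
        for col in feature_cols:
            cv = patient_cv(group[col].to_numpy(), use_abs_mean=use_abs_mean)
            row_v[col] = cv.value
            row_f[col] = cv.mean_nonpositive
        values[str(patient_id)] = row_v
        flags[str(patient_id)] = row_f
        n_lesions[str(patient_id)] = len(group)
    if n_dropped:
        logger.warning(
            "%d patient(s) with <2 lesions excluded from the CV matrix", n_dropped
        )
    value_df = pd.DataFrame.from_dict(values, orient="index", columns=feature_cols)
    flag_df = pd.DataFrame.from_dict(flags, orient="index", columns=feature_cols)
    return CVMatrix(
        values=value_df,
        mean_nonpositive=flag_df.astype(bool) if len(flag_df) else flag_df,
        n_lesions=pd.Series(n_lesions, dtype=int),
    )


def _cohort_patients(cv: CVMatrix, manifest: pd.DataFrame, cohort: str) -> list[str]:
    members = manifest.loc[manifest["cohort"] == cohort, "patient_id"]
    if members.empty:
        raise ValueError(f"cohort {cohort!r} has no patients in the manifest")
    return [p for p in cv.patients if p in set(members)]


def mean_cv_per_feature(cv: CVMatrix, manifest: pd.DataFrame, cohort: str,
                        exclude_features: Sequence[str] = (),
                        skip_flagged: bool = False) -> pd.DataFrame:
    """Across-patient mean of the patient-wise CVs for one cohort.

    Returns a DataFrame (feature, mean_cv, n) where n is the number of
    patients that contributed.  ``exclude_features`` drops columns from
    the summary (e.g. a dominating feature for plotting);
    ``skip_flagged`` excludes flagged (non-positive mean) entries.
    """
    patients = _cohort_patients(cv, manifest, cohort)
    sub = cv.values.loc[patients].drop(columns=list(exclude_features), errors="ignore")
    if skip_flagged:
        flags = cv.mean_nonpositive.loc[patients, sub.columns]
        sub = sub.mask(flags)
    finite = sub.replace([np.inf, -np.inf], np.nan)
    return pd.DataFrame({
        "feature": sub.columns,
        "mean_cv": finite.mean(axis=0, skipna=True).to_numpy(),
        "n": finite.notna().sum(axis=0).to_numpy(),
    })


def heatmap_table(cv: CVMatrix) -> pd.DataFrame:
    """Long-format (patient, feature, cv, mean_nonpositive) table.

    Row order preserves the matrix's patient and feature order (the
    heatmap is deliberately unclustered).
    """
    columns = ["patient_id", "feature", "cv", "mean_nonpositive"]
    if cv.values.empty:
        return pd.DataFrame(columns=columns)
    records = [
        (pid, feat, cv.values.at[pid, feat], bool(cv.mean_nonpositive.at[pid, feat]))
        for pid in cv.values.index
        for feat in cv.values.columns
    ]
    return pd.DataFrame.from_records(records, columns=columns)
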