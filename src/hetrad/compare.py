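"""Two-cohort screening of feature variability and study descriptives.

Each feature's patient-wise CVs are compared between the two cohorts with
a two-sided unpaired t-test (Welch by default).  The primary screen
applies no multiple-testing correction; Benjamini-Hochberg q-values are
reported alongside without altering the primary significance flag.
Lesion-count and lesion-size descriptives are compared with the
Wilcoxon-Mann-Whitney test (exact for small samples without ties).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .heterogeneity import CVMatrix, _cohort_patients

__all__ = [
    "FeatureComparison",
    "ComparisonReport",
    "compare_feature",
    "screen_all",
    "radar_table",
    "cohort_descriptives",
]


@dataclass(frozen=True)
class FeatureComparison:
    """Per-feature two-cohort comparison of patient-wise CVs."""

    feature: str
    mean_cv_a: float
    mean_cv_b: float
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float
    significant: bool
    higher_cv_cohort: str  # "A" | "B" | "tie"
    testable: bool = True


def compare_feature(cv_a: Sequence[float], cv_b: Sequence[float],
                    alpha: float = 0.05, feature: str = "",
                    equal_var: bool = False) -> FeatureComparison:
    """Two-sided unpaired t-test on two cohorts' CV values for one feature.

    Welch's unequal-variance form is the default; ``equal_var=True``
    selects the pooled-variance (Student) form for sensitivity checks.
    Fewer than two finite values on either side makes the comparison
    untestable (excluded from report counts).
    """
    a = np.asarray(cv_a, dtype=float)
    b = np.asarray(cv_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    mean_a = float(a.mean()) if a.size else np.nan
    mean_b = float(b.mean()) if b.size else np.nan
    if mean_a == mean_b:
        direction = "tie"
    elif np.isnan(mean_a) or np.isnan(mean_b):
        direction = "tie"
    else:
        direction = "A" if mean_a > mean_b else "B"
    if a.size < 2 or b.size < 2:
        return FeatureComparison(
            feature=feature, mean_cv_a=mean_a, mean_cv_b=mean_b,
            n_a=int(a.size), n_b=int(b.size), t_statistic=np.nan,
            p_value=np.nan, significant=False, higher_cv_cohort=direction,
            testable=False,
        )
    if np.ptp(a) == 0 and np.ptp(b) == 0 and mean_a == mean_b:
        t, p = 0.0, 1.0  # identical constant groups: no evidence, by definition
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return FeatureComparison(
        feature=feature, mean_cv_a=mean_a, mean_cv_b=mean_b,
        n_a=int(a.size), n_b=int(b.size), t_statistic=float(t),
        p_value=float(p), significant=bool(p < alpha),
        higher_cv_cohort=direction,
    )


@dataclass(frozen=True)
class ComparisonReport:
    """All per-feature comparisons plus the screen's summary counts."""

    table: pd.DataFrame
    alpha: float
    cohort_a: str
    cohort_b: str

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def n_higher_a(self) -> int:
        sig = self.table[self.table["significant"]]
        return int((sig["higher_cv_cohort"] == "A").sum())

    @property
    def n_higher_b(self) -> int:
        sig = self.table[self.table["significant"]]
        return int((sig["higher_cv_cohort"] == "B").sum())


def screen_all(cv: CVMatrix, manifest: pd.DataFrame, alpha: float = 0.05,
               equal_var: bool = False, drop_flagged: bool = False) -> ComparisonReport:
    """Per-feature screen across all features of the CV matrix.

    The manifest must define exactly two cohorts.  ``drop_flagged``
    removes non-positive-mean CV entries before testing (sensitivity
    mode; the primary screen keeps them).  A Benjamini-Hochberg adjusted
    ``q_value`` column is added for reference only.
    """
    cohorts = sorted(set(manifest["cohort"]))
    if len(cohorts) != 2:
        raise ValueError(f"expected exactly 2 cohorts, found {cohorts}")
    name_a, name_b = cohorts  # alphabetical: stable under row reordering
    patients_a = _cohort_patients(cv, manifest, name_a)
    patients_b = _cohort_patients(cv, manifest, name_b)

    rows = []
    for feature in cv.features:
        col_a = cv.values.loc[patients_a, feature]
        col_b = cv.values.loc[patients_b, feature]
        if drop_flagged:
            col_a = col_a[~cv.mean_nonpositive.loc[patients_a, feature]]
            col_b = col_b[~cv.mean_nonpositive.loc[patients_b, feature]]
        rows.append(compare_feature(col_a, col_b, alpha=alpha, feature=feature,
                                    equal_var=equal_var))
    table = pd.DataFrame([r.__dict__ for r in rows])

    q = np.full(len(table), np.nan)
    testable = table["testable"] & table["p_value"].notna()
    if testable.any():
        q[testable.to_numpy()] = stats.false_discovery_control(
            table.loc[testable, "p_value"].to_numpy(), method="bh"
        )
    table["q_value"] = q
    return ComparisonReport(table=table, alpha=alpha, cohort_a=name_a, cohort_b=name_b)


def radar_table(report: ComparisonReport) -> pd.DataFrame:
    """Significant features only, ordered by name, with both cohort mean CVs."""
    sig = report.table[report.table["significant"]]
    out = sig[["feature", "mean_cv_a", "mean_cv_b", "higher_cv_cohort"]].copy()
    return out.sort_values("feature").reset_index(drop=True)


def _mwu(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) == 0 or len(y) == 0:
        return np.nan
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue)


def cohort_descriptives(manifest: pd.DataFrame, lesion_table: pd.DataFrame) -> pd.DataFrame:
    """Study descriptives per cohort, with Wilcoxon-Mann-Whitney p-values.

    ``lesion_table`` needs one row per lesion with columns patient_id and
    (optionally) volume_mm3.  Reports per cohort: patient count, total
    lesion count, mean/median/min/max lesions per patient, mean lesion
    volume, and — when the manifest has a ``sex`` column — the M/F split.
    The two cohorts' per-patient lesion counts and per-lesion volumes are
    compared with the rank-sum test.
    """
    offenders = sorted(set(lesion_table["patient_id"]) - set(manifest["patient_id"]))
    if offenders:
        raise ValueError(f"lesion table references unknown patient ids: {offenders}")
    cohorts = list(dict.fromkeys(manifest["cohort"]))
    merged = lesion_table.merge(manifest[["patient_id", "cohort"]], on="patient_id")

    rows = {}
    counts_by_cohort = {}
    sizes_by_cohort = {}
    for cohort in cohorts:
        members = manifest.loc[manifest["cohort"] == cohort, "patient_id"]
        sub = merged[merged["cohort"] == cohort]
        counts = sub.groupby("patient_id", sort=False).size().reindex(members, fill_value=0)
        counts_by_cohort[cohort] = counts.to_numpy()
        row = {
            "n_patients": int(len(members)),
            "n_lesions": int(len(sub)),
            "lesions_per_patient_mean": float(counts.mean()),
            "lesions_per_patient_median": float(counts.median()),
            "lesions_per_patient_min": int(counts.min()),
            "lesions_per_patient_max": int(counts.max()),
        }
        if "volume_mm3" in sub.columns:
            sizes_by_cohort[cohort] = sub["volume_mm3"].to_numpy(dtype=float)
            row["lesion_volume_mm3_mean"] = float(sub["volume_mm3"].mean())
        if "sex" in manifest.columns:
            sex = manifest.loc[manifest["cohort"] == cohort, "sex"]
            n_m = int((sex == "M").sum())
            row["n_male"] = n_m
            row["n_female"] = int((sex == "F").sum())
            row["male_percent"] = 100.0 * n_m / len(members)
        rows[cohort] = row

    out = pd.DataFrame(rows).T
    out.index.name = "cohort"
    if len(cohorts) == 2:
        a, b = cohorts
        out["p_lesion_count"] = _mwu(counts_by_cohort[a], counts_by_cohort[b])
        if a in sizes_by_cohort and b in sizes_by_cohort:
            out["p_lesion_volume"] = _mwu(sizes_by_cohort[a], sizes_by_cohort[b])
    return out
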