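"""Acquisition-parameter variability: coefficients of variation.

For each acquisition parameter the dispersion across the whole cohort
and within each treatment center is quantified by the coefficient of
variation, CV = sample SD / mean.  Missing values are dropped per
parameter (listwise deletion); within-center CVs are only computed for
centers contributing at least two non-missing values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError

ACQUISITION_PARAMETERS = (
    "te_ms",
    "pixel_spacing_mm",
    "slice_thickness_mm",
    "n_bvalues",
    "highest_bvalue",
)


@dataclass(frozen=True)
class CVResult:
    parameter: str
    cv_all_centers: float
    cv_within_centers_median: Optional[float]
    cv_within_centers_range: Optional[tuple[float, float]]
    n_used: int
    n_missing: int


def coefficient_of_variation(values) -> float:
    """Sample SD (n-1) divided by mean; NaNs dropped first."""
    arr = np.asarray(
        [v for v in np.asarray(values, dtype=float).ravel() if np.isfinite(v)]
    )
    if arr.size < 2:
        raise InsufficientDataError(
            f"CV needs at least 2 non-missing values, got {arr.size}"
        )
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("CV requires a positive mean")
    return float(arr.std(ddof=1) / mean)


def cv_by_center(manifest: pd.DataFrame, parameter: str) -> CVResult:
    """Overall and within-center CV of one acquisition parameter."""
    if parameter not in ACQUISITION_PARAMETERS:
        raise ValueError(
            f"parameter must be one of {ACQUISITION_PARAMETERS}, got {parameter!r}"
        )
    values = pd.to_numeric(manifest[parameter], errors="coerce")
    n_total = len(values)
    non_missing = values.dropna()
    cv_all = coefficient_of_variation(non_missing.to_numpy())

    center_cvs = []
    for _, grp in manifest.assign(_v=values).groupby("center_id"):
        v = grp["_v"].dropna().to_numpy()
        if v.size >= 2:
            center_cvs.append(float(np.std(v, ddof=1) / np.mean(v)))
    if center_cvs:
        med = float(np.median(center_cvs))
        rng = (float(np.min(center_cvs)), float(np.max(center_cvs)))
    else:
        med = rng = None
    return CVResult(
        parameter=parameter,
        cv_all_centers=cv_all,
        cv_within_centers_median=med,
        cv_within_centers_range=rng,
        n_used=int(non_missing.size),
        n_missing=int(n_total - non_missing.size),
    )


def variability_table(manifest: pd.DataFrame) -> pd.DataFrame:
    """One row per acquisition parameter, mirroring a cohort CV table."""
    rows = []
    for parameter in ACQUISITION_PARAMETERS:
        r = cv_by_center(manifest, parameter)
        rows.append(
            {
                "parameter": r.parameter,
                "cv_all_centers": r.cv_all_centers,
                "cv_within_centers_median": r.cv_within_centers_median,
                "cv_within_centers_min": (
                    r.cv_within_centers_range[0] if r.cv_within_centers_range else np.nan
                ),
                "cv_within_centers_max": (
                    r.cv_within_centers_range[1] if r.cv_within_centers_range else np.nan
                ),
                "n_used": r.n_used,
                "n_missing": r.n_missing,
            }
        )
    return pd.DataFrame(rows)
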