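"""ROI summarization and the scan inclusion/exclusion flow.

ADC within a region of interest is summarized by the median after
removing the annotated exclusion region (necrotic / cystic /
hemorrhagic areas) and voxels where the fit was invalid.  Scans enter
the analysis through a fixed-priority inclusion filter: no measurable
tumor, then poor quality, then missing DWI, then tumor outside the
field of view; each excluded scan is counted under the first matching
reason so the accounting always conserves the input count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import NoEvaluableROIError
from .fitting import ADCMap

EXCLUSION_REASONS = ("no_measurable_tumor", "poor_quality", "no_dwi", "outside_fov")

_REQUIRED_FLAGS = ("quality_score", "has_dwi", "has_measurable_tumor", "in_fov")


@dataclass(frozen=True)
class ROISummary:
    scan_id: str
    region: str  # "tumor" | "muscle"
    median_adc: float
    n_voxels: int
    n_excluded_voxels: int

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("a reported ROI summary needs >= 1 voxel")
        if not np.isfinite(self.median_adc):
            raise ValueError("median ADC must be finite")


@dataclass(frozen=True)
class InclusionReport:
    n_input_scans: int
    n_excluded_by_reason: dict
    n_included: int

    def __post_init__(self) -> None:
        if self.n_included + sum(self.n_excluded_by_reason.values()) != self.n_input_scans:
            raise ValueError("inclusion accounting does not conserve scans")

    def to_dict(self) -> dict:
        return {
            "n_input_scans": self.n_input_scans,
            "n_excluded_by_reason": dict(self.n_excluded_by_reason),
            "n_included": self.n_included,
        }


def roi_median_adc(
    adc_map: ADCMap,
    mask: np.ndarray,
    exclusion_mask: Optional[np.ndarray] = None,
    scan_id: str = "",
    region: str = "tumor",
) -> ROISummary:
    """Median ADC over (mask - exclusion_mask - invalid voxels)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != adc_map.adc.shape:
        raise ValueError("mask shape does not match ADC map")
    effective = mask.copy()
    n_excluded = 0
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
        if exclusion_mask.shape != mask.shape:
            raise ValueError("exclusion mask shape does not match ADC map")
        n_excluded = int(np.count_nonzero(mask & exclusion_mask))
        effective &= ~exclusion_mask
    effective &= ~adc_map.invalid_mask
    n_voxels = int(np.count_nonzero(effective))
    if n_voxels == 0:
        raise NoEvaluableROIError(
            f"ROI {region!r} of scan {scan_id!r} has no evaluable voxels"
        )
    median = float(np.median(adc_map.adc[effective]))
    return ROISummary(
        scan_id=scan_id,
        region=region,
        median_adc=median,
        n_voxels=n_voxels,
        n_excluded_voxels=n_excluded,
    )


def apply_inclusion_flow(manifest: pd.DataFrame) -> tuple[pd.DataFrame, InclusionReport]:
    """Filter a manifest, assigning each excluded scan a unique reason.

    Priority order: no measurable tumor -> poor quality (score 1) ->
    no DWI -> tumor outside FOV.  Raises on rows with missing flags,
    listing the offending scan ids.
    """
    missing_cols = [c for c in _REQUIRED_FLAGS if c not in manifest.columns]
    if missing_cols:
        raise ValueError(f"manifest lacks required flag columns: {missing_cols}")
    bad = manifest[[*_REQUIRED_FLAGS]].isna().any(axis=1)
    if bad.any():
        ids = manifest.loc[bad, "scan_id"].tolist() if "scan_id" in manifest else list(
            manifest.index[bad]
        )
        raise ValueError(f"scans with missing inclusion flags: {ids}")

    reasons = {r: 0 for r in EXCLUSION_REASONS}
    keep = np.ones(len(manifest), dtype=bool)
    for i, (_, row) in enumerate(manifest.iterrows()):
        if not bool(row["has_measurable_tumor"]):
            reasons["no_measurable_tumor"] += 1
        elif int(row["quality_score"]) == 1:
            reasons["poor_quality"] += 1
        elif not bool(row["has_dwi"]):
            reasons["no_dwi"] += 1
        elif not bool(row["in_fov"]):
            reasons["outside_fov"] += 1
        else:
            continue
        keep[i] = False
    included = manifest.loc[keep].reset_index(drop=True)
    report = InclusionReport(
        n_input_scans=len(manifest),
        n_excluded_by_reason=reasons,
        n_included=len(included),
    )
    return included, report


def summarize_cohort(
    summaries: pd.DataFrame, manifest: pd.DataFrame
) -> pd.DataFrame:
    """Per-timepoint, per-region mean/SD/min/max of median ADC.

    ``summaries`` needs columns scan_id, region, median_adc; timepoints
    are joined in from the manifest.  SD uses the n-1 denominator; cells
    with fewer than two observations report NaN for SD, and region /
    timepoint cells without data are simply absent.
    """
    if summaries.empty:
        return pd.DataFrame(
            columns=["timepoint", "region", "n", "mean", "sd", "min", "max"]
        )
    merged = summaries.merge(
        manifest[["scan_id", "timepoint"]], on="scan_id", how="left"
    )
    rows = []
    for (tp, region), grp in merged.groupby(["timepoint", "region"], sort=True):
        vals = grp["median_adc"].to_numpy(dtype=float)
        rows.append(
            {
                "timepoint": tp,
                "region": region,
                "n": len(vals),
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) >= 2 else np.nan,
                "min": float(np.min(vals)),
                "max": float(np.max(vals)),
            }
        )
    return pd.DataFrame(rows)
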