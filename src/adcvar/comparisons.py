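"""Group comparisons of tumor ADC against acquisition parameters.

For each acquisition parameter the cohort is dichotomized at the
parameter's median and the two groups' median ADC values are compared
by a Mann-Whitney U test, Bonferroni-corrected across parameters and
timepoints.  Simple per-parameter linear regressions guard against
artifacts of dichotomizing continuous covariates, and diagnosis versus
response ADC is compared either paired (Wilcoxon signed-rank on
per-patient differences) or unpaired (Mann-Whitney).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateSplitError, InsufficientDataError


@dataclass(frozen=True)
class MedianSplitResult:
    parameter: str
    timepoint: str
    split_value: float
    n_low: int
    n_high: int
    u_statistic: float
    p_raw: float
    p_bonferroni: float
    significant: bool


@dataclass(frozen=True)
class RegressionResult:
    parameter: str
    timepoint: str
    slope: float
    intercept: float
    p_slope: float
    n: int


@dataclass(frozen=True)
class TimepointTestResult:
    region: str
    mode: str  # "paired" | "unpaired"
    statistic: float
    p_value: float
    n: int
    effect: float  # mean difference (paired) / difference of means (unpaired)


def median_split(values) -> tuple[np.ndarray, np.ndarray, float]:
    """Split indices of ``values`` at the median (ties go low).

    Returns (low indices, high indices, split value) over the
    non-missing entries; records with value <= median go to the low
    group, > median to the high group.
    """
    arr = np.asarray(values, dtype=float)
    finite = np.flatnonzero(np.isfinite(arr))
    if finite.size < 2:
        raise InsufficientDataError("median split needs >= 2 non-missing values")
    split = float(np.median(arr[finite]))
    low = finite[arr[finite] <= split]
    high = finite[arr[finite] > split]
    if low.size == 0 or high.size == 0:
        raise DegenerateSplitError(
            f"median split at {split} leaves an empty group (all values equal?)"
        )
    return low, high, split


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U counts pairs with x > y plus half the ties.  The p-value is exact
    (full enumeration of the null permutation distribution) when
    n_x * n_y <= 400 and there are no ties across the pooled sample;
    otherwise the normal approximation with tie and continuity
    correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and x.size * y.size <= 400:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def bonferroni_adjust(p_values, m: Optional[int] = None):
    """min(1, m * p) for each p; m defaults to the number of p-values."""
    arr = np.atleast_1d(np.asarray(p_values, dtype=float))
    if m is None:
        m = arr.size
    if m < arr.size:
        raise ValueError("m must be at least the number of p-values")
    out = np.minimum(1.0, m * arr)
    return float(out[0]) if np.isscalar(p_values) or arr.size == 1 else out


def simple_linear_regression(x, y, parameter: str = "", timepoint: str = "") -> RegressionResult:
    """OLS of ADC on one acquisition parameter, with slope t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise InsufficientDataError("regression needs >= 3 complete observations")
    if np.var(x) == 0:
        raise InsufficientDataError("regression covariate has zero variance")
    fit = stats.linregress(x, y)
    return RegressionResult(
        parameter=parameter,
        timepoint=timepoint,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_slope=float(fit.pvalue),
        n=int(x.size),
    )


def compare_timepoints(
    diag_values,
    resp_values,
    region: str = "tumor",
    paired: bool = True,
) -> TimepointTestResult:
    """Diagnosis vs response comparison of per-patient median ADC.

    Paired mode expects aligned arrays (one entry per patient with both
    scans) and runs the Wilcoxon signed-rank test on differences;
    unpaired mode treats the arrays as independent samples and runs a
    Mann-Whitney U test.
    """
    diag = np.asarray(diag_values, dtype=float)
    resp = np.asarray(resp_values, dtype=float)
    if paired:
        if diag.shape != resp.shape:
            raise ValueError("paired comparison needs aligned arrays")
        ok = np.isfinite(diag) & np.isfinite(resp)
        diag, resp = diag[ok], resp[ok]
        if diag.size < 2:
            raise InsufficientDataError("paired test needs >= 2 complete pairs")
        diff = resp - diag
        if np.all(diff == 0):
            stat, p = float(diag.size * (diag.size + 1) / 4), 1.0
        else:
            res = stats.wilcoxon(resp, diag, zero_method="zsplit")
            stat, p = float(res.statistic), float(res.pvalue)
        return TimepointTestResult(
            region=region,
            mode="paired",
            statistic=stat,
            p_value=p,
            n=int(diag.size),
            effect=float(diff.mean()),
        )
    diag = diag[np.isfinite(diag)]
    resp = resp[np.isfinite(resp)]
    u, p = mann_whitney_u(resp, diag)
    return TimepointTestResult(
        region=region,
        mode="unpaired",
        statistic=u,
        p_value=p,
        n=int(diag.size + resp.size),
        effect=float(resp.mean() - diag.mean()),
    )


def run_median_split_tests(
    data: pd.DataFrame,
    parameters,
    adc_col: str = "median_adc",
    timepoint_col: str = "timepoint",
    m: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Median-split Mann-Whitney tests for each parameter x timepoint.

    ``data`` has one row per scan with the parameter columns, the ADC
    summary and the timepoint.  Parameter/timepoint cells whose split is
    degenerate (all values identical) are skipped.
    """
    rows = []
    for parameter in parameters:
        for tp, grp in data.groupby(timepoint_col, sort=True):
            values = grp[parameter].to_numpy(dtype=float)
            adc = grp[adc_col].to_numpy(dtype=float)
            try:
                low, high, split = median_split(values)
            except (DegenerateSplitError, InsufficientDataError):
                continue
            u, p_raw = mann_whitney_u(adc[low], adc[high])
            p_adj = float(bonferroni_adjust(p_raw, m))
            rows.append(
                MedianSplitResult(
                    parameter=parameter,
                    timepoint=tp,
                    split_value=split,
                    n_low=int(low.size),
                    n_high=int(high.size),
                    u_statistic=u,
                    p_raw=p_raw,
                    p_bonferroni=p_adj,
                    significant=p_adj < alpha,
                ).__dict__
            )
    return pd.DataFrame(rows)


def run_regressions(
    data: pd.DataFrame,
    parameters,
    adc_col: str = "median_adc",
    timepoint_col: str = "timepoint",
) -> pd.DataFrame:
    """Per-parameter simple OLS of ADC on the parameter, by timepoint."""
    rows = []
    for parameter in parameters:
        for tp, grp in data.groupby(timepoint_col, sort=True):
            try:
                res = simple_linear_regression(
                    grp[parameter], grp[adc_col], parameter=parameter, timepoint=tp
                )
            except InsufficientDataError:
                continue
            rows.append(res.__dict__)
    return pd.DataFrame(rows)
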