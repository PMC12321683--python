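"""Sensitivity of ADC to the choice of b-values.

For scans acquired with many b-values, the ADC is re-estimated from
every subset of b-values that contains the non-weighted image (b=0).
Estimates are grouped by the highest b-value in the subset, because
under a bi-exponential (perfusion-contaminated) signal the fitted
mono-exponential ADC falls as the highest b-value grows.  The size of
that fall is summarized as a percent decrease per 100 s/mm2 from a
log-linear fit of the group means, and its consequence for treatment
monitoring is quantified by the four possible longitudinal changes one
obtains by using either the highest or the second-highest b-value at
diagnosis and at response.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError
from .fitting import BValueSet, compute_adc_map
from .roi import roi_median_adc


@dataclass(frozen=True)
class BValueCombination:
    """A subset of a scan's b-values containing b=0."""

    bvalues: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.bvalues)
        if len(vals) < 2 or vals[0] != 0.0 or list(vals) != sorted(set(vals)):
            raise ValueError("combination must be ascending, unique, starting at 0")
        object.__setattr__(self, "bvalues", vals)

    @property
    def highest_b(self) -> float:
        return self.bvalues[-1]


@dataclass(frozen=True)
class HighestBGroup:
    """Mean ADC of all combinations sharing one highest b-value."""

    highest_b: float
    mean_adc: float
    se_adc: Optional[float]  # sample SD / sqrt(n); None when n == 1
    n_combinations: int

    def __post_init__(self) -> None:
        if self.n_combinations < 1:
            raise ValueError("a group needs at least one combination")
        if self.n_combinations == 1 and self.se_adc is not None:
            raise ValueError("se is undefined for a single combination")


@dataclass(frozen=True)
class LongitudinalDelta:
    """Percent ADC change for one (diagnosis, response) b-max choice."""

    diag_choice: str  # "highest" | "second_highest"
    resp_choice: str
    percent_change: float
    se_percent: Optional[float]
    n_eff: float


def enumerate_combinations(bvalues) -> list[BValueCombination]:
    """All subsets containing b=0 and >= 1 non-zero b-value.

    For m non-zero b-values there are 2^m - 1 combinations.  Output is
    deterministic: ordered by subset size, then lexicographically.
    """
    bset = BValueSet.coerce(bvalues)
    nonzero = bset.values[1:]
    if not nonzero:
        raise InsufficientDataError("need at least one non-zero b-value")
    combos = []
    for size in range(1, len(nonzero) + 1):
        for subset in itertools.combinations(nonzero, size):
            combos.append(BValueCombination((0.0,) + subset))
    return combos


def adc_over_combinations(
    scan,
    mask: np.ndarray,
    exclusion_mask: Optional[np.ndarray] = None,
) -> list[tuple[BValueCombination, float]]:
    """ROI-median ADC for every b-value combination of a scan."""
    results = []
    for combo in enumerate_combinations(scan.bvalues):
        adc_map = compute_adc_map(scan, combo.bvalues)
        summary = roi_median_adc(
            adc_map, mask, exclusion_mask, scan_id=scan.scan_id
        )
        results.append((combo, summary.median_adc))
    return results


def group_by_highest_b(combination_adcs) -> list[HighestBGroup]:
    """Mean and SE of ADC per distinct highest b-value, ascending."""
    if not combination_adcs:
        raise InsufficientDataError("no combination ADCs to group")
    buckets: dict[float, list[float]] = {}
    for combo, adc in combination_adcs:
        buckets.setdefault(combo.highest_b, []).append(adc)
    groups = []
    for hb in sorted(buckets):
        vals = np.asarray(buckets[hb], dtype=float)
        n = vals.size
        se = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else None
        groups.append(
            HighestBGroup(
                highest_b=hb, mean_adc=float(vals.mean()), se_adc=se, n_combinations=n
            )
        )
    return groups


def slope_per_100(
    groups,
    fit_range: tuple[float, float] = (200.0, 1000.0),
    method: str = "loglinear",
) -> float:
    """Percent ADC decrease per 100 s/mm2 of highest b-value.

    ``loglinear`` fits ln(mean ADC) against the highest b-value over
    ``fit_range`` (bounds inclusive) and reports
    100 * (1 - exp(100 * slope)), so an "X% per 100" figure compounds
    consistently.  ``relative_linear`` fits mean ADC directly and
    reports -100 * slope * 100 / mean(ADC in range).
    """
    sel = [g for g in groups if fit_range[0] <= g.highest_b <= fit_range[1]]
    if len(sel) < 2:
        raise InsufficientDataError(
            f"need >= 2 highest-b groups inside {fit_range}, got {len(sel)}"
        )
    hb = np.asarray([g.highest_b for g in sel], dtype=float)
    adc = np.asarray([g.mean_adc for g in sel], dtype=float)
    if method == "loglinear":
        if np.any(adc <= 0):
            raise ValueError("log-linear slope needs positive group means")
        slope = np.polyfit(hb, np.log(adc), 1)[0]
        return float(100.0 * (1.0 - math.exp(slope * 100.0)))
    if method == "relative_linear":
        slope = np.polyfit(hb, adc, 1)[0]
        return float(-100.0 * slope * 100.0 / adc.mean())
    raise ValueError(f"unknown slope method {method!r}")


def _pick(groups) -> dict[str, HighestBGroup]:
    ordered = sorted(groups, key=lambda g: g.highest_b)
    if len(ordered) < 2:
        raise InsufficientDataError(
            "need groups for at least two distinct highest b-values"
        )
    return {"highest": ordered[-1], "second_highest": ordered[-2]}


def longitudinal_four_combinations(
    diag_groups, resp_groups
) -> list[LongitudinalDelta]:
    """The four longitudinal percent changes from b-max choices.

    Using either the highest or the second-highest b-value group at
    diagnosis and at response gives 2 x 2 percent changes
    100 * (ADC_resp - ADC_diag) / ADC_diag.  The percent-change SE is
    propagated from the two group SEs by the first-order delta method;
    n_eff is the average of the two groups' combination counts.
    """
    diag = _pick(diag_groups)
    resp = _pick(resp_groups)
    deltas = []
    for d_choice in ("highest", "second_highest"):
        for r_choice in ("highest", "second_highest"):
            gd, gr = diag[d_choice], resp[r_choice]
            a_d, a_r = gd.mean_adc, gr.mean_adc
            pct = 100.0 * (a_r - a_d) / a_d
            if gd.se_adc is not None and gr.se_adc is not None:
                se = 100.0 * math.sqrt(
                    gr.se_adc**2 / a_d**2 + (a_r**2 * gd.se_adc**2) / a_d**4
                )
            else:
                se = None
            deltas.append(
                LongitudinalDelta(
                    diag_choice=d_choice,
                    resp_choice=r_choice,
                    percent_change=pct,
                    se_percent=se,
                    n_eff=(gd.n_combinations + gr.n_combinations) / 2.0,
                )
            )
    return deltas


def welch_t_from_summaries(
    mean1: float, se1: float, n1: float, mean2: float, se2: float, n2: float
) -> tuple[float, float, float]:
    """Welch t-test from summary statistics (means, SEs, sample sizes).

    t = (mean1 - mean2) / sqrt(se1^2 + se2^2), with Welch-Satterthwaite
    degrees of freedom and a two-sided p-value.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("sample sizes must be >= 2")
    v1, v2 = se1**2, se2**2
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), float(df), p


def delta_pairwise_tests(deltas) -> list[dict]:
    """Welch t-tests between every pair of the four longitudinal deltas."""
    out = []
    for d1, d2 in itertools.combinations(deltas, 2):
        if d1.se_percent is None or d2.se_percent is None:
            continue
        t, df, p = welch_t_from_summaries(
            d1.percent_change, d1.se_percent, d1.n_eff,
            d2.percent_change, d2.se_percent, d2.n_eff,
        )
        out.append(
            {
                "combo_1": f"{d1.diag_choice}/{d1.resp_choice}",
                "combo_2": f"{d2.diag_choice}/{d2.resp_choice}",
                "t": t,
                "df": df,
                "p_value": p,
            }
        )
    return out
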