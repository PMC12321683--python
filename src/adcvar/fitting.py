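"""Mono-exponential ADC estimation from multi-b DWI signals.

The apparent diffusion coefficient is the decay rate of the DWI signal
under the mono-exponential model ``S(b) = S0 * exp(-b * ADC)``.  ADC is
estimated by ordinary least squares on ``ln S`` against ``b`` (the
2-parameter log-linear normal equations, solved in closed form), and is
reported in um^2/ms (= 1e-3 mm^2/s) with b in s/mm2.  With exactly two
b-values the estimator reduces to the two-point ratio formula
``ln(S(b0)/S(b1)) / (b1 - b0) * 1e3``.

Voxels with any non-positive signal in the fitted subset cannot enter
the log fit; map-level fitting flags them in an invalid mask instead of
silently zero-filling, and vector-level fitting raises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .exceptions import InvalidSubsetError

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import SyntheticScan


@dataclass(frozen=True)
class BValueSet:
    """An ascending set of b-values (s/mm2) starting at b=0."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if len(vals) < 2:
            raise InvalidSubsetError("a b-value set needs at least two values")
        if vals[0] != 0.0:
            raise InvalidSubsetError("a b-value set must start at b=0")
        if any(b2 <= b1 for b1, b2 in zip(vals, vals[1:])):
            raise InvalidSubsetError("b-values must be strictly increasing")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    @property
    def highest(self) -> float:
        return self.values[-1]

    @classmethod
    def coerce(cls, values) -> "BValueSet":
        if isinstance(values, cls):
            return values
        return cls(tuple(sorted(float(v) for v in values)))


@dataclass
class ADCMap:
    """Voxelwise ADC (um^2/ms) with fit provenance.

    ``invalid_mask`` is True exactly where any input signal in the
    fitted subset was <= 0; ``adc`` is NaN there and finite elsewhere.
    """

    adc: np.ndarray
    fit_bvalues: BValueSet
    invalid_mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.adc.shape != self.invalid_mask.shape:
            raise ValueError("adc and invalid_mask shapes differ")


def fit_adc_loglinear(bvalues, signals) -> float:
    """Fit a single signal vector; raises on non-positive signals.

    Parameters
    ----------
    bvalues : sequence of float
        b-values in s/mm2, at least two, not all equal.
    signals : sequence of float
        Positive signal at each b-value.

    Returns
    -------
    float
        ADC in um^2/ms, i.e. -slope * 1e3 of the OLS line of ln(signal)
        against b.
    """
    b = np.asarray(list(bvalues), dtype=float)
    s = np.asarray(signals, dtype=float)
    if b.ndim != 1 or b.shape != s.shape:
        raise ValueError("bvalues and signals must be 1-D and equal length")
    if b.size < 2:
        raise InvalidSubsetError("need at least two b-values to fit ADC")
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("all signals must be finite and > 0 for a log fit")
    bc = b - b.mean()
    denom = bc @ bc
    if denom == 0:
        raise InvalidSubsetError("b-values are all identical")
    y = np.log(s)
    slope = (bc @ (y - y.mean())) / denom
    return float(-slope * 1e3)


def fit_adc_map(bvalues, signal_stack: np.ndarray) -> ADCMap:
    """Vectorized log-linear fit over a stack of volumes.

    Parameters
    ----------
    bvalues : sequence of float
        One b-value per leading-axis entry of ``signal_stack``.
    signal_stack : ndarray, shape (n_b, ...)
        Signal volumes; trailing axes are the voxel grid.
    """
    bset = BValueSet.coerce(bvalues)
    b = np.asarray(bset.values, dtype=float)
    sig = np.asarray(signal_stack, dtype=float)
    if sig.shape[0] != b.size:
        raise ValueError("signal stack leading axis must match b-values")
    invalid = np.any(~np.isfinite(sig) | (sig <= 0.0), axis=0)
    safe = np.where(sig > 0.0, sig, 1.0)
    y = np.log(safe)
    bc = b - b.mean()
    denom = float(bc @ bc)
    yc = y - y.mean(axis=0)
    slope = np.tensordot(bc, yc, axes=(0, 0)) / denom
    adc = -slope * 1e3
    adc[invalid] = np.nan
    return ADCMap(adc=adc, fit_bvalues=bset, invalid_mask=invalid)


def compute_adc_map(scan: "SyntheticScan", bvalue_subset=None) -> ADCMap:
    """ADC map of a scan from a subset of its b-values.

    The subset must be contained in the scan's b-values, include b=0 and
    at least one non-zero b-value.  Defaults to the full set.
    """
    scan_b = tuple(scan.bvalues)
    if scan.dwi is None:
        raise InvalidSubsetError(f"scan {scan.scan_id} carries no DWI volumes")
    if bvalue_subset is None:
        subset = BValueSet.coerce(scan_b)
    else:
        subset = BValueSet.coerce(bvalue_subset)
    missing = set(subset.values) - set(scan_b)
    if missing:
        raise InvalidSubsetError(
            f"subset b-values {sorted(missing)} not acquired in scan {scan.scan_id}"
        )
    idx = [scan_b.index(b) for b in subset.values]
    return fit_adc_map(subset, scan.dwi[idx])
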