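"""Pipeline configuration.

Configuration is split into a cohort block (what the synthetic generator
produces) and an analysis block (how the downstream statistics are run).
Values load from YAML, reject unknown keys, and serialize back so every
output directory carries the exact resolved configuration.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

from .exceptions import ConfigError

# Catalog of multi-b acquisition schemes (s/mm2).  Weights are the
# cohort-wide scheme frequencies; each center perturbs them (Dirichlet)
# so that variability exists both between and within centers.
DEFAULT_BVALUE_SCHEMES: tuple[tuple[float, ...], ...] = (
    (0.0, 1000.0),
    (0.0, 800.0),
    (0.0, 500.0, 1000.0),
    (0.0, 100.0, 800.0),
    (0.0, 100.0, 200.0, 400.0, 600.0, 800.0),
    (0.0, 50.0, 100.0, 200.0, 500.0, 800.0, 1000.0),
)
DEFAULT_SCHEME_WEIGHTS: tuple[float, ...] = (0.35, 0.10, 0.25, 0.05, 0.10, 0.15)


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name} must be a probability in [0, 1], got {value}")


@dataclass
class CohortConfig:
    """Parameters of the synthetic multicenter cohort generator.

    ADC values are in um^2/ms, echo time in ms, pixel spacing and slice
    thickness in mm, b-values in s/mm2, signals in arbitrary units.
    """

    n_patients: int = 114
    n_centers: int = 22

    # Per-patient "true" median ADC marginals (um^2/ms)
    tumor_diag_mean: float = 1.09
    tumor_diag_sd: float = 0.30
    tumor_resp_mean: float = 1.58
    tumor_resp_sd: float = 0.38
    tumor_rho: float = 0.5
    muscle_diag_mean: float = 1.20
    muscle_diag_sd: float = 0.14
    muscle_resp_mean: float = 1.24
    muscle_resp_sd: float = 0.16
    muscle_rho: float = 0.5
    adc_trunc_low: float = 0.3
    adc_trunc_high: float = 2.8
    # Match realized cohort moments (ADC means/SDs, center-mean spread)
    # exactly rather than only in expectation (empirical=TRUE style).
    empirical_moments: bool = True

    # Longitudinal design: fractions of patients scanned at both
    # timepoints, diagnosis only, response only; and the size of the
    # subset with an evaluable muscle region.
    frac_both_timepoints: float = 81.0 / 114.0
    frac_response_only: float = 2.0 / 114.0
    frac_muscle_subset: float = 16.0 / 114.0

    # Bi-exponential signal mechanism (perfusion fraction f, tissue and
    # pseudo-diffusivities in um^2/ms).  tumor_f controls how strongly
    # the fitted ADC falls as the highest b-value grows.
    tumor_f: float = 0.0675
    muscle_f: float = 0.0
    d_pseudo: float = 20.0
    exclusion_region_d: float = 2.3
    background_d: float = 1.6

    s0_tumor: float = 1000.0
    s0_muscle: float = 800.0
    s0_background: float = 600.0
    noise_sigma: float = 20.0

    # Acquisition parameter distributions: global mean, total CV across
    # the cohort, and typical within-center CV.  The between-center SD
    # is derived so the two levels compose to the total CV.
    te_mean: float = 75.0
    te_cv_total: float = 0.18
    te_cv_within: float = 0.13
    pixel_mean: float = 1.2
    pixel_cv_total: float = 0.31
    pixel_cv_within: float = 0.22
    slice_mean: float = 5.0
    slice_cv_total: float = 0.22
    slice_cv_within: float = 0.14

    bvalue_schemes: tuple[tuple[float, ...], ...] = DEFAULT_BVALUE_SCHEMES
    scheme_weights: tuple[float, ...] = DEFAULT_SCHEME_WEIGHTS
    scheme_dirichlet: float = 3.0

    p_missing: float = 0.075
    p_exclusion_region: float = 0.5

    # Inclusion-flow probabilities (all zero by default: the default
    # cohort is fully analyzable; raise them to exercise the filter).
    p_no_measurable_tumor: float = 0.0
    p_quality1: float = 0.0
    p_no_dwi: float = 0.0
    p_outside_fov: float = 0.0

    shape: tuple[int, int, int] = (32, 32, 8)

    def __post_init__(self) -> None:
        self.shape = tuple(int(v) for v in self.shape)  # YAML gives lists
        self.bvalue_schemes = tuple(tuple(float(b) for b in s) for s in self.bvalue_schemes)
        self.scheme_weights = tuple(float(w) for w in self.scheme_weights)
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if not 1 <= self.n_centers <= self.n_patients:
            raise ConfigError(
                f"n_centers must be in [1, n_patients], got {self.n_centers} "
                f"with n_patients={self.n_patients}"
            )
        for name in ("te", "pixel", "slice"):
            mean = getattr(self, f"{name}_mean")
            cv_total = getattr(self, f"{name}_cv_total")
            cv_within = getattr(self, f"{name}_cv_within")
            if mean <= 0:
                raise ConfigError(f"{name}_mean must be > 0")
            if not 0 <= cv_within <= cv_total:
                raise ConfigError(f"require 0 <= {name}_cv_within <= {name}_cv_total")
        if len(self.bvalue_schemes) != len(self.scheme_weights):
            raise ConfigError("scheme_weights must match bvalue_schemes in length")
        if abs(sum(self.scheme_weights) - 1.0) > 1e-9:
            raise ConfigError("scheme_weights must sum to 1")
        for scheme in self.bvalue_schemes:
            if len(scheme) < 2 or scheme[0] != 0.0 or list(scheme) != sorted(set(scheme)):
                raise ConfigError(f"invalid b-value scheme {scheme}")
        for name in (
            "p_missing",
            "p_exclusion_region",
            "p_no_measurable_tumor",
            "p_quality1",
            "p_no_dwi",
            "p_outside_fov",
            "frac_both_timepoints",
            "frac_response_only",
            "frac_muscle_subset",
        ):
            _check_prob(name, getattr(self, name))
        if self.frac_both_timepoints + self.frac_response_only > 1.0:
            raise ConfigError("timepoint fractions exceed 1")
        if not (0 < self.adc_trunc_low < self.adc_trunc_high):
            raise ConfigError("ADC truncation bounds must satisfy 0 < low < high")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if not 0 <= self.tumor_f < 1 or not 0 <= self.muscle_f < 1:
            raise ConfigError("perfusion fractions must lie in [0, 1)")
        if self.scheme_dirichlet <= 0:
            raise ConfigError("scheme_dirichlet must be > 0")
        if len(self.shape) != 3 or any(v < 4 for v in self.shape):
            raise ConfigError("shape must be a 3-vector with all dims >= 4")

    def between_sd(self, name: str) -> float:
        """Between-center SD for a two-level continuous parameter."""
        mean = getattr(self, f"{name}_mean")
        cv_total = getattr(self, f"{name}_cv_total")
        cv_within = getattr(self, f"{name}_cv_within")
        return mean * math.sqrt(max(cv_total**2 - cv_within**2, 0.0))

    def within_sd(self, name: str) -> float:
        return getattr(self, f"{name}_mean") * getattr(self, f"{name}_cv_within")


@dataclass
class AnalysisConfig:
    """Knobs of the statistical analyses."""

    alpha: float = 0.05
    bonferroni_m: int = 10  # 5 parameters x 2 timepoints
    slope_fit_lo: float = 200.0
    slope_fit_hi: float = 1000.0
    slope_method: str = "loglinear"  # or "relative_linear"
    min_bvalues_bsens: int = 6  # "more than five" read strictly
    single_slice: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.bonferroni_m < 1:
            raise ConfigError("bonferroni_m must be >= 1")
        if self.slope_fit_lo >= self.slope_fit_hi:
            raise ConfigError("slope fit range must have lo < hi")
        if self.slope_method not in ("loglinear", "relative_linear"):
            raise ConfigError(f"unknown slope_method {self.slope_method!r}")
        if self.min_bvalues_bsens < 3:
            raise ConfigError("min_bvalues_bsens must be >= 3")


@dataclass
class PipelineConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data or {})
        unknown = set(data) - {"seed", "cohort", "analysis"}
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        cohort = _build_section(CohortConfig, data.get("cohort", {}))
        analysis = _build_section(AnalysisConfig, data.get("analysis", {}))
        return cls(seed=int(data.get("seed", 0)), cohort=cohort, analysis=analysis)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "cohort": dataclasses.asdict(self.cohort),
            "analysis": dataclasses.asdict(self.analysis),
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=True)


def _build_section(cls, data: dict[str, Any]):
    if not isinstance(data, dict):
        raise ConfigError(f"{cls.__name__} section must be a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def _plain(obj):
    """Recursively convert tuples to lists for clean YAML output."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
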