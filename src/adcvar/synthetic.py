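"""Synthetic multicenter DWI cohort generator.

Real multicenter tumor DWI with per-scan acquisition metadata is not
publicly available, so every downstream stage of this package is driven
by a simulated cohort whose statistical structure matches what has been
reported for multicenter pediatric sarcoma imaging:

* per-center acquisition parameters (echo time, pixel spacing, slice
  thickness) drawn from a two-level normal model so that both the
  cohort-wide and within-center coefficients of variation are realistic;
* categorical multi-b acquisition schemes with center-specific weights;
* per-patient "true" median ADC values for tumor (diagnosis/response)
  and healthy muscle drawn from truncated (bivariate) normals;
* voxel signals from a two-compartment bi-exponential (IVIM-like)
  model, which is the smallest mechanism that makes the fitted
  mono-exponential ADC decrease when higher b-values are used;
* Rician magnitude noise;
* ellipsoidal tumor masks with an interior exclusion region (necrotic /
  cystic / hemorrhagic emulation) and a separate muscle block for a
  subset of patients.

The generator is deterministic for a fixed master seed: each scan draws
from an independent stream keyed by the master seed and a stable hash of
its scan id.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import CohortConfig
from .exceptions import ConfigError, InfeasibleTargetError
from .fitting import fit_adc_loglinear

MANIFEST_COLUMNS = [
    "scan_id",
    "patient_id",
    "center_id",
    "timepoint",
    "te_ms",
    "pixel_spacing_mm",
    "slice_thickness_mm",
    "n_bvalues",
    "highest_bvalue",
    "bvalues",
    "quality_score",
    "has_dwi",
    "has_measurable_tumor",
    "in_fov",
    "dwi_path",
    "tumor_mask_path",
    "exclusion_mask_path",
    "muscle_mask_path",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """The five acquisition parameters of interest for one scan.

    Any field may be None, emulating metadata that could not be
    recovered from the image headers.
    """

    te_ms: Optional[float]
    pixel_spacing_mm: Optional[float]
    slice_thickness_mm: Optional[float]
    n_bvalues: Optional[int]
    highest_bvalue: Optional[float]

    def __post_init__(self) -> None:
        for name in ("te_ms", "pixel_spacing_mm", "slice_thickness_mm", "highest_bvalue"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when present")
        if self.n_bvalues is not None and self.n_bvalues < 2:
            raise ValueError("n_bvalues must be >= 2 when present")


@dataclass(frozen=True)
class CenterProfile:
    """Acquisition habits of one treatment center."""

    center_id: str
    te_center_mean: float
    pixel_spacing_center_mean: float
    slice_thickness_center_mean: float
    bvalue_scheme_weights: tuple[float, ...]
    n_scans: int = 0

    def __post_init__(self) -> None:
        if min(self.te_center_mean, self.pixel_spacing_center_mean,
               self.slice_thickness_center_mean) <= 0:
            raise ValueError("center means must be positive")
        if abs(sum(self.bvalue_scheme_weights) - 1.0) > 1e-9:
            raise ValueError("scheme weights must sum to 1")
        if self.n_scans < 0:
            raise ValueError("n_scans must be >= 0")


@dataclass(frozen=True)
class TissueState:
    """Ground-truth bi-exponential signal parameters for one region.

    f is the fast (pseudo-diffusion) volume fraction, d_tissue and
    d_pseudo are diffusivities in um^2/ms.  target_adc is the
    mono-exponential ADC this tissue is calibrated to produce when
    fitted with its scan's own b-values.
    """

    f: float
    d_tissue: float
    d_pseudo: float
    target_adc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f < 1.0:
            raise ValueError("f must lie in [0, 1)")
        if not 0.0 < self.d_tissue < self.d_pseudo:
            raise ValueError("require 0 < d_tissue < d_pseudo")
        if self.target_adc <= 0:
            raise ValueError("target_adc must be positive")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    center_id: str
    adc_diag_true: float
    adc_resp_true: Optional[float]
    muscle_adc_true: Optional[dict]  # {"diagnosis": x, "response": y} or None
    has_response_scan: bool
    has_diagnosis_scan: bool = True


@dataclass
class SyntheticScan:
    """One simulated DWI examination.

    ``dwi`` is a (n_b, nx, ny, nz) float array aligned with ``bvalues``;
    masks are boolean volumes on the same grid (``exclusion_mask`` is a
    subset of ``tumor_mask``; ``muscle_mask`` may be None).
    """

    scan_id: str
    patient_id: str
    center_id: str
    timepoint: str  # "diagnosis" | "response"
    acquisition: AcquisitionParams
    bvalues: tuple[float, ...]
    dwi: Optional[np.ndarray]
    tumor_mask: Optional[np.ndarray]
    exclusion_mask: Optional[np.ndarray]
    muscle_mask: Optional[np.ndarray]
    quality_score: int
    has_dwi: bool
    has_measurable_tumor: bool
    in_fov: bool
    ground_truth: dict = field(default_factory=dict)  # region -> TissueState
    voxel_size_mm: tuple[float, float, float] = (1.2, 1.2, 5.0)


# ---------------------------------------------------------------------------
# Signal model


def ivim_signal(b, tissue: TissueState, s0: float = 1.0):
    """Two-compartment bi-exponential DWI signal.

    S(b) = s0 * [f * exp(-b * d_pseudo * 1e-3) + (1-f) * exp(-b * d_tissue * 1e-3)]

    The 1e-3 factor converts um^2/ms * s/mm2 into a dimensionless
    exponent.  Monotonically non-increasing in b.
    """
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr < 0):
        raise ValueError("b-values must be non-negative")
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    fast = tissue.f * np.exp(-b_arr * tissue.d_pseudo * 1e-3)
    slow = (1.0 - tissue.f) * np.exp(-b_arr * tissue.d_tissue * 1e-3)
    out = s0 * (fast + slow)
    return float(out) if np.isscalar(b) else out


def _fitted_adc_for_d(d: float, f: float, d_pseudo: float, bvalues) -> float:
    tissue = TissueState(f=f, d_tissue=d, d_pseudo=d_pseudo, target_adc=max(d, 1e-6))
    return fit_adc_loglinear(bvalues, ivim_signal(np.asarray(bvalues, float), tissue))


def solve_d_for_target_adc(
    target_adc: float,
    f: float,
    d_pseudo: float,
    b_ref: float = 1000.0,
    bvalues=None,
    bracket: tuple[float, float] = (0.01, 4.0),
    tol: float = 1e-9,
) -> float:
    """Tissue diffusivity that makes the fitted ADC hit a target.

    By default the target is the two-point mono-exponential ADC at
    ``{0, b_ref}``; passing ``bvalues`` calibrates instead against the
    log-linear OLS fit over that whole set (used by the cohort
    generator so each scan's standard ADC map reproduces the patient's
    true ADC regardless of its acquisition scheme).  The fitted ADC is
    continuous and strictly increasing in d_tissue, so a bracketing
    root search applies.
    """
    if target_adc <= 0:
        raise InfeasibleTargetError("target_adc must be positive")
    if bvalues is None:
        bvalues = (0.0, float(b_ref))
    if f == 0.0:
        # Pure mono-exponential: the log-linear fit returns d exactly.
        d = float(target_adc)
        if not bracket[0] <= d <= bracket[1]:
            raise InfeasibleTargetError(
                f"target ADC {target_adc} outside bracket {bracket}"
            )
        return d

    def objective(d: float) -> float:
        return _fitted_adc_for_d(d, f, d_pseudo, bvalues) - target_adc

    lo, hi = bracket
    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo > 0 or f_hi < 0:
        raise InfeasibleTargetError(
            f"no tissue diffusivity in {bracket} um^2/ms yields ADC {target_adc}"
        )
    return float(brentq(objective, lo, hi, xtol=tol))


def add_rician_noise(volume: np.ndarray, sigma: float, rng) -> np.ndarray:
    """Rician magnitude noise: v -> sqrt((v+e1)^2 + e2^2), e ~ N(0, sigma)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return volume
    e1 = rng.normal(0.0, sigma, size=volume.shape)
    e2 = rng.normal(0.0, sigma, size=volume.shape)
    return np.sqrt((volume + e1) ** 2 + e2**2)


# ---------------------------------------------------------------------------
# Acquisition sampling


def build_center_profiles(config: CohortConfig, rng) -> list[CenterProfile]:
    """Draw per-center acquisition habits.

    Center means for the continuous parameters are drawn normally and
    then standardized so the realized spread of the center means equals
    the configured between-center SD exactly (moment matching): the
    cohort is meant to reproduce a documented variability table, not
    merely to do so in expectation.
    """
    n = config.n_centers
    means = {}
    for name in ("te", "pixel", "slice"):
        mean = getattr(config, f"{name}_mean")
        sd = config.between_sd(name)
        if n == 1 or sd == 0.0:
            vals = np.full(n, mean)
        else:
            vals = rng.normal(mean, sd, size=n)
            vals = mean + (vals - vals.mean()) * (sd / vals.std(ddof=1))
        means[name] = np.maximum(vals, 0.2 * mean)  # keep center means positive
    profiles = []
    for i in range(n):
        weights = rng.dirichlet(
            config.scheme_dirichlet * np.asarray(config.scheme_weights)
        )
        profiles.append(
            CenterProfile(
                center_id=f"C{i:02d}",
                te_center_mean=float(means["te"][i]),
                pixel_spacing_center_mean=float(means["pixel"][i]),
                slice_thickness_center_mean=float(means["slice"][i]),
                bvalue_scheme_weights=tuple(weights),
            )
        )
    return profiles


def _allocate_counts(weights, n: int) -> np.ndarray:
    """Largest-remainder allocation of n items to categorical weights."""
    raw = np.asarray(weights, dtype=float) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - np.floor(raw)), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def _assign_schemes(center_ids, profiles, config: CohortConfig, rng) -> list[int]:
    """Assign each scan a b-value scheme with exact global composition.

    The global scheme counts are fixed by largest-remainder allocation
    of the configured weights; individual scans then draw without
    replacement from that pool with probability proportional to the
    remaining counts times their center's scheme preference.  This
    keeps the cohort-wide composition (and hence the n-bvalue /
    highest-b CVs) pinned to the calibration while preserving
    within-center clustering of schemes.
    """
    n = len(center_ids)
    pool = _allocate_counts(config.scheme_weights, n).astype(float)
    order = rng.permutation(n)
    assigned = [0] * n
    for idx in order:
        prefs = np.asarray(profiles[center_ids[idx]].bvalue_scheme_weights)
        p = pool * prefs
        total = p.sum()
        if total <= 0:
            p = pool.copy()
            total = p.sum()
        j = rng.choice(len(pool), p=p / total)
        pool[j] -= 1.0
        assigned[idx] = int(j)
    return assigned


def sample_acquisition_parameters(
    profile: CenterProfile, rng, config: CohortConfig, scheme=None
) -> tuple[AcquisitionParams, tuple[float, ...]]:
    """Draw one scan's acquisition parameters from a center profile.

    Returns the (possibly partially missing) metadata record together
    with the actually acquired b-value scheme.  ``scheme`` may be
    pre-assigned (as the cohort generator does to pin the global scheme
    composition); by default it is drawn from the profile's weights.
    """
    te = rng.normal(profile.te_center_mean, config.within_sd("te"))
    px = rng.normal(profile.pixel_spacing_center_mean, config.within_sd("pixel"))
    sl = rng.normal(profile.slice_thickness_center_mean, config.within_sd("slice"))
    te = max(te, 0.05 * config.te_mean)
    px = max(px, 0.05 * config.pixel_mean)
    sl = max(sl, 0.05 * config.slice_mean)
    if scheme is None:
        scheme_idx = rng.choice(
            len(config.bvalue_schemes), p=profile.bvalue_scheme_weights
        )
        scheme = config.bvalue_schemes[scheme_idx]
    # Header-extraction failures: each field independently missing.
    miss = rng.random(5) < config.p_missing
    params = AcquisitionParams(
        te_ms=None if miss[0] else float(te),
        pixel_spacing_mm=None if miss[1] else float(px),
        slice_thickness_mm=None if miss[2] else float(sl),
        n_bvalues=None if miss[3] else len(scheme),
        highest_bvalue=None if miss[4] else float(scheme[-1]),
    )
    return params, scheme


# ---------------------------------------------------------------------------
# Patients and truth values


def _standardize_over(z: np.ndarray, idx) -> np.ndarray:
    """Affinely rescale z so z[idx] has sample mean 0 and sample SD 1.

    Empirical moment matching (the ``empirical=TRUE`` convention of
    multivariate-normal simulators): the draws keep their normal shape
    but the realized moments of the indexed subset equal the targets
    exactly instead of only in expectation.
    """
    sub = z[idx]
    if len(idx) < 2 or sub.std(ddof=1) == 0:
        return z
    return (z - sub.mean()) / sub.std(ddof=1)


def build_patients(config: CohortConfig, rng) -> list[PatientRecord]:
    n = config.n_patients
    n_both = int(round(config.frac_both_timepoints * n))
    n_resp_only = min(int(round(config.frac_response_only * n)), n - n_both)
    n_diag_only = n - n_both - n_resp_only
    patterns = (["both"] * n_both + ["diag"] * n_diag_only + ["resp"] * n_resp_only)
    rng.shuffle(patterns)

    # Centers: guarantee every center at least one patient, rest random.
    centers = list(range(config.n_centers)) + list(
        rng.integers(0, config.n_centers, size=max(n - config.n_centers, 0))
    )
    rng.shuffle(centers)

    both_indices = [i for i, p in enumerate(patterns) if p == "both"]
    n_muscle = min(int(round(config.frac_muscle_subset * n)), len(both_indices))
    muscle_idx = (
        sorted(rng.choice(both_indices, size=n_muscle, replace=False))
        if n_muscle
        else []
    )
    muscle_set = set(muscle_idx)

    # Tumor truths: correlated normal draws, moment-matched on the
    # subsets the study actually summarizes (diagnosis scans for the
    # diagnosis moments, response scans for the response moments).
    idx_diag = [i for i, p in enumerate(patterns) if p in ("both", "diag")]
    idx_resp = [i for i, p in enumerate(patterns) if p in ("both", "resp")]
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    w = config.tumor_rho * z1 + math.sqrt(1 - config.tumor_rho**2) * z2
    if config.empirical_moments:
        z1 = _standardize_over(z1, idx_diag or list(range(n)))
        w = _standardize_over(w, idx_resp or list(range(n)))
    lo = config.adc_trunc_low + 1e-3
    hi = config.adc_trunc_high - 1e-3
    diag_vals = np.clip(config.tumor_diag_mean + config.tumor_diag_sd * z1, lo, hi)
    resp_vals = np.clip(config.tumor_resp_mean + config.tumor_resp_sd * w, lo, hi)

    # Muscle truths for the subset with an evaluable muscle region.
    muscle_vals = {}
    if muscle_idx:
        zm1 = rng.standard_normal(len(muscle_idx))
        zm2 = rng.standard_normal(len(muscle_idx))
        wm = config.muscle_rho * zm1 + math.sqrt(1 - config.muscle_rho**2) * zm2
        all_idx = list(range(len(muscle_idx)))
        if config.empirical_moments:
            zm1 = _standardize_over(zm1, all_idx)
            wm = _standardize_over(wm, all_idx)
        m_diag = np.clip(config.muscle_diag_mean + config.muscle_diag_sd * zm1, lo, hi)
        m_resp = np.clip(config.muscle_resp_mean + config.muscle_resp_sd * wm, lo, hi)
        muscle_vals = {
            i: {"diagnosis": float(d), "response": float(r)}
            for i, d, r in zip(muscle_idx, m_diag, m_resp)
        }

    patients = []
    for i in range(n):
        pattern = patterns[i]
        patients.append(
            PatientRecord(
                patient_id=f"P{i:03d}",
                center_id=f"C{centers[i]:02d}",
                adc_diag_true=float(diag_vals[i]),
                adc_resp_true=(
                    float(resp_vals[i]) if pattern in ("both", "resp") else None
                ),
                muscle_adc_true=muscle_vals.get(i) if i in muscle_set else None,
                has_response_scan=pattern in ("both", "resp"),
                has_diagnosis_scan=pattern in ("both", "diag"),
            )
        )
    return patients


# ---------------------------------------------------------------------------
# Volumes and masks


def _ellipsoid(shape, center, semi) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return acc <= 1.0


def _scan_rng(seed: int, scan_id: str, stream: int):
    """Independent per-scan stream keyed by a stable hash of scan_id."""
    return np.random.default_rng(
        [int(seed) & 0x7FFFFFFF, stream, zlib.crc32(scan_id.encode())]
    )


def _build_volumes(
    scan_id: str,
    scheme: tuple[float, ...],
    tumor_adc: float,
    muscle_adc: Optional[float],
    config: CohortConfig,
    seed: int,
):
    rng = _scan_rng(seed, scan_id, stream=2)
    shape = config.shape
    cx = shape[0] / 2 + rng.uniform(-1, 1)
    cy = shape[1] / 2 + rng.uniform(-1, 1)
    cz = (shape[2] - 1) / 2
    semi = (rng.uniform(5, 9), rng.uniform(5, 9), rng.uniform(1.2, 2.2))
    tumor_mask = _ellipsoid(shape, (cx, cy, cz), semi)
    if rng.random() < config.p_exclusion_region:
        exclusion_mask = _ellipsoid(
            shape, (cx, cy, cz), tuple(0.45 * a for a in semi)
        )
    else:
        exclusion_mask = np.zeros(shape, dtype=bool)
    exclusion_mask &= tumor_mask  # invariant: exclusion subset of tumor

    muscle_mask = None
    if muscle_adc is not None:
        z_lo = max(int(math.floor(cz - semi[2])), 0)
        z_hi = min(int(math.ceil(cz + semi[2])) + 1, shape[2])
        muscle_mask = np.zeros(shape, dtype=bool)
        muscle_mask[1:5, 2:9, z_lo:z_hi] = True
        muscle_mask &= ~tumor_mask

    b_arr = np.asarray(scheme, dtype=float)
    tissues = {
        "tumor": TissueState(
            f=config.tumor_f,
            d_tissue=solve_d_for_target_adc(
                tumor_adc, config.tumor_f, config.d_pseudo, bvalues=scheme
            ),
            d_pseudo=config.d_pseudo,
            target_adc=tumor_adc,
        ),
        "exclusion": TissueState(
            f=0.0,
            d_tissue=config.exclusion_region_d,
            d_pseudo=config.d_pseudo,
            target_adc=config.exclusion_region_d,
        ),
        "background": TissueState(
            f=0.0,
            d_tissue=config.background_d,
            d_pseudo=config.d_pseudo,
            target_adc=config.background_d,
        ),
    }
    if muscle_adc is not None:
        tissues["muscle"] = TissueState(
            f=config.muscle_f,
            d_tissue=solve_d_for_target_adc(
                muscle_adc, config.muscle_f, config.d_pseudo, bvalues=scheme
            ),
            d_pseudo=config.d_pseudo,
            target_adc=muscle_adc,
        )

    dwi = np.empty((len(scheme),) + shape, dtype=float)
    dwi[:] = ivim_signal(b_arr, tissues["background"], config.s0_background)[
        :, None, None, None
    ]
    tumor_sig = ivim_signal(b_arr, tissues["tumor"], config.s0_tumor)
    excl_sig = ivim_signal(b_arr, tissues["exclusion"], config.s0_tumor)
    for k in range(len(scheme)):
        vol = dwi[k]
        vol[tumor_mask] = tumor_sig[k]
        vol[exclusion_mask] = excl_sig[k]
        if muscle_mask is not None:
            vol[muscle_mask] = ivim_signal(b_arr[k], tissues["muscle"], config.s0_muscle)
    if config.noise_sigma > 0:
        dwi = add_rician_noise(dwi, config.noise_sigma, rng)
    return dwi, tumor_mask, exclusion_mask, muscle_mask, tissues


# ---------------------------------------------------------------------------
# Cohort assembly


def generate_cohort(
    config: Optional[CohortConfig] = None,
    seed: int = 0,
    volumes: bool = True,
) -> tuple[pd.DataFrame, list[SyntheticScan]]:
    """Generate a full synthetic cohort.

    Returns a manifest (one row per scan) and the scan objects.  With
    ``volumes=False`` only manifest-level quantities are produced (the
    scans carry no voxel data), which is much faster and is sufficient
    for acquisition-variability analyses.  The manifest is identical in
    both modes for a fixed seed.
    """
    if config is None:
        config = CohortConfig()
    if not isinstance(config, CohortConfig):
        raise ConfigError("generate_cohort expects a CohortConfig")
    master = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0])
    profile_list = build_center_profiles(config, master)
    profiles = {p.center_id: p for p in profile_list}
    patients = build_patients(config, master)

    # Collect scan slots, then pin the global b-value scheme composition.
    slots = []
    for patient in patients:
        if patient.has_diagnosis_scan:
            slots.append((patient, "diagnosis"))
        if patient.has_response_scan:
            slots.append((patient, "response"))
    center_idx = [int(p.center_id[1:]) for p, _ in slots]
    scheme_idx = _assign_schemes(center_idx, profile_list, config, master)

    scans: list[SyntheticScan] = []
    rows = []
    scan_counts: dict[str, int] = {cid: 0 for cid in profiles}
    for (patient, tp), s_idx in zip(slots, scheme_idx):
        scan_id = f"{patient.patient_id}_{tp[:4]}"
        profile = profiles[patient.center_id]
        rng_acq = _scan_rng(seed, scan_id, stream=1)
        acq, scheme = sample_acquisition_parameters(
            profile, rng_acq, config, scheme=config.bvalue_schemes[s_idx]
        )
        has_tumor = rng_acq.random() >= config.p_no_measurable_tumor
        quality = 1 if rng_acq.random() < config.p_quality1 else int(
            rng_acq.integers(2, 4)
        )
        has_dwi = rng_acq.random() >= config.p_no_dwi
        in_fov = rng_acq.random() >= config.p_outside_fov
        scan_counts[patient.center_id] += 1

        tumor_adc = (
            patient.adc_diag_true if tp == "diagnosis" else patient.adc_resp_true
        )
        muscle_adc = (
            patient.muscle_adc_true[tp] if patient.muscle_adc_true else None
        )
        if volumes and has_dwi:
            dwi, t_mask, e_mask, m_mask, tissues = _build_volumes(
                scan_id, scheme, tumor_adc, muscle_adc, config, seed
            )
        else:
            dwi = t_mask = e_mask = m_mask = None
            tissues = {}
        scan = SyntheticScan(
            scan_id=scan_id,
            patient_id=patient.patient_id,
            center_id=patient.center_id,
            timepoint=tp,
            acquisition=acq,
            bvalues=scheme,
            dwi=dwi,
            tumor_mask=t_mask,
            exclusion_mask=e_mask,
            muscle_mask=m_mask,
            quality_score=quality,
            has_dwi=has_dwi,
            has_measurable_tumor=has_tumor,
            in_fov=in_fov,
            ground_truth=tissues,
            voxel_size_mm=(
                acq.pixel_spacing_mm or config.pixel_mean,
                acq.pixel_spacing_mm or config.pixel_mean,
                acq.slice_thickness_mm or config.slice_mean,
            ),
        )
        scans.append(scan)
        rows.append(
            {
                "scan_id": scan_id,
                "patient_id": patient.patient_id,
                "center_id": patient.center_id,
                "timepoint": tp,
                "te_ms": acq.te_ms,
                "pixel_spacing_mm": acq.pixel_spacing_mm,
                "slice_thickness_mm": acq.slice_thickness_mm,
                "n_bvalues": acq.n_bvalues,
                "highest_bvalue": acq.highest_bvalue,
                "bvalues": ";".join(f"{b:g}" for b in scheme),
                "quality_score": quality,
                "has_dwi": has_dwi,
                "has_measurable_tumor": has_tumor,
                "in_fov": in_fov,
                "dwi_path": "",
                "tumor_mask_path": "",
                "exclusion_mask_path": "",
                "muscle_mask_path": "",
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return manifest, scans


def simulate_bsens_scans(
    n_scans: int = 10,
    seed: int = 0,
    config: Optional[CohortConfig] = None,
    scheme: Optional[tuple[float, ...]] = None,
) -> list[SyntheticScan]:
    """Noise-free many-b scans for the b-value sensitivity analysis.

    Emulates a fixed subset of examinations acquired with a rich
    b-value scheme (default: the 7-value catalog scheme up to
    b=1000 s/mm2).  Tumor target ADCs are placed at the quantile
    midpoints of the diagnosis ADC distribution rather than drawn at
    random, so the set is a representative cross-section of the cohort
    and the averaged b-max sensitivity it yields is a stable property
    of the calibration, not of one random draw.  Signals are noise-free
    (the analysis isolates the model-driven b-value effect).
    """
    import dataclasses

    from scipy.stats import norm

    if config is None:
        config = CohortConfig()
    config = dataclasses.replace(config, noise_sigma=0.0)
    if scheme is None:
        scheme = max(config.bvalue_schemes, key=len)
    if n_scans < 1:
        raise ConfigError("n_scans must be >= 1")
    q = (np.arange(n_scans) + 0.5) / n_scans
    targets = np.clip(
        config.tumor_diag_mean + config.tumor_diag_sd * norm.ppf(q),
        config.adc_trunc_low + 0.05,
        config.adc_trunc_high - 0.05,
    )
    scans = []
    for i, target in enumerate(targets):
        scan_id = f"BSENS{i:03d}_diag"
        dwi, t_mask, e_mask, m_mask, tissues = _build_volumes(
            scan_id, tuple(scheme), float(target), None, config, seed
        )
        scans.append(
            SyntheticScan(
                scan_id=scan_id,
                patient_id=f"BSENS{i:03d}",
                center_id="C00",
                timepoint="diagnosis",
                acquisition=AcquisitionParams(
                    te_ms=config.te_mean,
                    pixel_spacing_mm=config.pixel_mean,
                    slice_thickness_mm=config.slice_mean,
                    n_bvalues=len(scheme),
                    highest_bvalue=float(max(scheme)),
                ),
                bvalues=tuple(scheme),
                dwi=dwi,
                tumor_mask=t_mask,
                exclusion_mask=e_mask,
                muscle_mask=m_mask,
                quality_score=3,
                has_dwi=True,
                has_measurable_tumor=True,
                in_fov=True,
                ground_truth=tissues,
            )
        )
    return scans


def true_adc_table(scans: list[SyntheticScan]) -> pd.DataFrame:
    """Ground-truth median ADC per scan and region (generator bookkeeping)."""
    rows = []
    for scan in scans:
        for region in ("tumor", "muscle"):
            tissue = scan.ground_truth.get(region)
            if tissue is None:
                continue
            rows.append(
                {
                    "scan_id": scan.scan_id,
                    "patient_id": scan.patient_id,
                    "timepoint": scan.timepoint,
                    "region": region,
                    "true_adc": tissue.target_adc,
                }
            )
    return pd.DataFrame(rows)
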