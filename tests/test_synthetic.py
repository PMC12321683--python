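import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adcvar.config import CohortConfig
from adcvar.exceptions import ConfigError, InfeasibleTargetError
from adcvar.fitting import fit_adc_loglinear
from adcvar.synthetic import (
    TissueState,
    add_rician_noise,
    build_center_profiles,
    generate_cohort,
    ivim_signal,
    sample_acquisition_parameters,
    solve_d_for_target_adc,
)

TISSUE = TissueState(f=0.075, d_tissue=1.1, d_pseudo=20.0, target_adc=1.1)


class TestIvimSignal:
    def test_b_zero_returns_s0(self):
        assert ivim_signal(0.0, TISSUE, 1.0) == pytest.approx(1.0)
        assert ivim_signal(0.0, TISSUE, 512.0) == pytest.approx(512.0)

    def test_pure_monoexponential(self):
        t = TissueState(f=0.0, d_tissue=1.2, d_pseudo=20.0, target_adc=1.2)
        assert ivim_signal(1000.0, t, 1.0) == pytest.approx(np.exp(-1.2), rel=1e-12)

    def test_two_compartment_value(self):
        # direct evaluation of the formula as oracle
        expected = 0.075 * np.exp(-20.0) + 0.925 * np.exp(-1.1)
        assert ivim_signal(1000.0, TISSUE, 1.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.3080, abs=2e-4)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            ivim_signal(-1.0, TISSUE, 1.0)
        with pytest.raises(ValueError):
            ivim_signal(100.0, TISSUE, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        f=st.floats(0.0, 0.5),
        d=st.floats(0.2, 2.9),
        dp=st.floats(3.0, 50.0),
        b1=st.floats(0.0, 2000.0),
        db=st.floats(0.0, 2000.0),
    )
    def test_monotone_nonincreasing_in_b(self, f, d, dp, b1, db):
        t = TissueState(f=f, d_tissue=d, d_pseudo=max(dp, d + 0.1), target_adc=d)
        assert ivim_signal(b1 + db, t, 1.0) <= ivim_signal(b1, t, 1.0) + 1e-15


class TestSolveDForTargetAdc:
    def test_monoexponential_identity(self):
        assert solve_d_for_target_adc(1.09, 0.0, 20.0, b_ref=1000.0) == pytest.approx(1.09)

    def test_round_trip_two_point(self):
        d = solve_d_for_target_adc(1.2054, 0.075, 20.0, b_ref=1000.0)
        t = TissueState(f=0.075, d_tissue=d, d_pseudo=20.0, target_adc=1.2054)
        b = np.array([0.0, 1000.0])
        adc = fit_adc_loglinear(b, ivim_signal(b, t, 1.0))
        assert adc == pytest.approx(1.2054, abs=1e-6)

    def test_matches_forward_grid_oracle(self):
        # oracle: forward-evaluate the two-point ADC on a fine d grid
        target, f, dp = 1.3, 0.06, 18.0
        grid = np.linspace(0.01, 4.0, 400001)
        # two-point ADC at b=1000 equals -ln S(1000) here (S0 = 1)
        adcs = -np.log(f * np.exp(-dp) + (1 - f) * np.exp(-grid))
        d_oracle = grid[np.argmin(np.abs(adcs - target))]
        d_solver = solve_d_for_target_adc(target, f, dp, b_ref=1000.0)
        assert d_solver == pytest.approx(d_oracle, abs=2e-5)

    def test_infeasible_target(self):
        with pytest.raises(InfeasibleTargetError):
            solve_d_for_target_adc(10.0, 0.075, 20.0, b_ref=1000.0)

    def test_scheme_calibration_recovers_target_via_full_fit(self):
        scheme = (0.0, 50.0, 100.0, 200.0, 500.0, 800.0, 1000.0)
        d = solve_d_for_target_adc(0.95, 0.0675, 20.0, bvalues=scheme)
        t = TissueState(f=0.0675, d_tissue=d, d_pseudo=20.0, target_adc=0.95)
        b = np.asarray(scheme)
        assert fit_adc_loglinear(b, ivim_signal(b, t, 1.0)) == pytest.approx(0.95, abs=1e-6)


class TestRicianNoise:
    def test_sigma_zero_identity(self, rng):
        v = rng.uniform(0, 10, size=(4, 4, 2))
        out = add_rician_noise(v, 0.0, rng)
        assert out is v

    def test_negative_sigma_raises(self, rng):
        with pytest.raises(ValueError):
            add_rician_noise(np.ones(3), -1.0, rng)

    def test_rayleigh_mean_at_zero_signal(self, rng):
        v = np.zeros(200_000)
        out = add_rician_noise(v, 1.0, rng)
        assert out.mean() == pytest.approx(np.sqrt(np.pi / 2), abs=0.01)

    def test_noise_floor_raises_low_signal(self, rng):
        v = np.full(100_000, 0.5)
        out = add_rician_noise(v, 2.0, rng)
        assert out.mean() > v.mean()


class TestAcquisitionSampling:
    def test_zero_within_sd_gives_identical_parameters(self):
        cfg = CohortConfig(
            n_patients=5,
            n_centers=1,
            te_cv_within=0.0,
            pixel_cv_within=0.0,
            slice_cv_within=0.0,
            te_cv_total=0.0,
            pixel_cv_total=0.0,
            slice_cv_total=0.0,
            p_missing=0.0,
        )
        rng = np.random.default_rng(0)
        profile = build_center_profiles(cfg, rng)[0]
        draws = [sample_acquisition_parameters(profile, rng, cfg)[0] for _ in range(10)]
        assert len({d.te_ms for d in draws}) == 1
        assert len({d.pixel_spacing_mm for d in draws}) == 1

    def test_overall_cvs_match_calibration_at_scale(self):
        # large cohort: the two-level model composes to the configured CVs
        cfg = CohortConfig(n_patients=3000, n_centers=22, p_missing=0.0)
        manifest, _ = generate_cohort(cfg, seed=3, volumes=False)
        te = manifest["te_ms"]
        assert te.std(ddof=1) / te.mean() == pytest.approx(0.18, abs=0.02)
        hb = manifest["highest_bvalue"]
        assert hb.std(ddof=1) / hb.mean() == pytest.approx(0.09, abs=0.02)
        nb = manifest["n_bvalues"]
        assert nb.std(ddof=1) / nb.mean() == pytest.approx(0.55, abs=0.03)

    def test_missingness_rate(self):
        cfg = CohortConfig(n_patients=2000, n_centers=10, p_missing=0.1)
        manifest, _ = generate_cohort(cfg, seed=1, volumes=False)
        frac = manifest["te_ms"].isna().mean()
        assert frac == pytest.approx(0.1, abs=0.02)


class TestGenerateCohort:
    def test_deterministic_manifest(self):
        cfg = CohortConfig(n_patients=3, n_centers=1)
        m1, _ = generate_cohort(cfg, seed=11, volumes=False)
        m2, _ = generate_cohort(cfg, seed=11, volumes=False)
        assert m1.equals(m2)

    def test_manifest_identical_with_and_without_volumes(self):
        cfg = CohortConfig(n_patients=6, n_centers=2)
        m1, _ = generate_cohort(cfg, seed=5, volumes=False)
        m2, _ = generate_cohort(cfg, seed=5, volumes=True)
        assert m1.equals(m2)

    def test_default_cohort_shape(self, default_manifest):
        assert len(default_manifest) == 195
        assert default_manifest["patient_id"].nunique() == 114
        assert default_manifest["center_id"].nunique() == 22
        assert (default_manifest["timepoint"] == "diagnosis").sum() == 112
        assert (default_manifest["timepoint"] == "response").sum() == 83

    def test_true_adc_mean_calibration(self):
        cfg = CohortConfig(n_patients=114)
        _, scans = generate_cohort(cfg, seed=42, volumes=True)
        diag = [
            s.ground_truth["tumor"].target_adc
            for s in scans
            if s.timepoint == "diagnosis"
        ]
        assert np.mean(diag) == pytest.approx(1.09, abs=0.09)  # 3 SE

    def test_exclusion_mask_subset_of_tumor(self, default_cohort):
        for scan in default_cohort[1]:
            if scan.tumor_mask is None:
                continue
            assert not np.any(scan.exclusion_mask & ~scan.tumor_mask)
            assert np.all(scan.dwi >= 0)
            assert scan.bvalues[0] == 0.0
            assert all(b2 > b1 for b1, b2 in zip(scan.bvalues, scan.bvalues[1:]))

    def test_calibration_recovery_with_scan_bvalues(self):
        # noise-free: fitting each scan with its own b-values returns the
        # patient's true ADC to high precision
        cfg = CohortConfig(n_patients=8, n_centers=2, noise_sigma=0.0)
        _, scans = generate_cohort(cfg, seed=2, volumes=True)
        for scan in scans:
            tissue = scan.ground_truth["tumor"]
            b = np.asarray(scan.bvalues)
            sig = ivim_signal(b, tissue, 1.0)
            assert fit_adc_loglinear(b, sig) == pytest.approx(
                tissue.target_adc, abs=1e-6
            )

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(n_patients=3, n_centers=5)

    def test_marginal_calibration_at_large_n(self):
        cfg = CohortConfig(n_patients=10_000, n_centers=22)
        master_patients = generate_cohort(cfg, seed=9, volumes=False)
        # truths are not in the manifest; regenerate patient records directly
        from adcvar.synthetic import build_patients

        rng = np.random.default_rng([9, 0])
        from adcvar.synthetic import build_center_profiles

        build_center_profiles(cfg, rng)  # advance stream as generate_cohort does
        patients = build_patients(cfg, rng)
        diag = np.array([p.adc_diag_true for p in patients])
        resp = np.array([p.adc_resp_true for p in patients if p.adc_resp_true])
        assert diag.mean() == pytest.approx(1.09, abs=0.02)
        assert diag.std(ddof=1) == pytest.approx(0.30, abs=0.02)
        assert resp.mean() == pytest.approx(1.58, abs=0.02)
        assert resp.std(ddof=1) == pytest.approx(0.38, abs=0.02)
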