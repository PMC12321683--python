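# adcvar

How do diffusion-weighted MRI (DWI) acquisition parameters move apparent
diffusion coefficient (ADC) estimates in a multicenter tumor cohort?

`adcvar` is a Python package for researchers studying ADC as an imaging
biomarker of treatment response — in particular in rare tumors such as
pediatric rhabdomyosarcoma, where any usable sample size forces a
multicenter design and therefore wide variation in echo time, voxel
geometry and b-value schemes.  Because no patient-level multicenter DWI
dataset with per-scan acquisition metadata is publicly available, the
package ships a calibrated synthetic cohort generator, and every
analysis stage runs end-to-end on it:

1. **Synthetic cohort** — per-center acquisition-parameter
   distributions, per-patient tumor/muscle ADC values, multi-b DWI
   volumes (bi-exponential signal + Rician noise), tumor / exclusion /
   muscle masks, and an inclusion/exclusion flow.
2. **ADC fitting** — voxelwise mono-exponential log-linear least
   squares: `S(b) = S0 exp(−b·ADC)`, ADC = −10³ × (OLS slope of ln S vs
   b), reported in µm²/ms with b in s/mm².
3. **ROI statistics** — median ADC per tumor/muscle region after
   removing annotated exclusion (necrotic/cystic/hemorrhagic) areas and
   invalid voxels; cohort mean/SD tables.
4. **Acquisition variability** — coefficient of variation
   (CV = sample SD / mean) per parameter, cohort-wide and within each
   center.
5. **Cohort comparisons** — median-split Mann-Whitney U tests with
   Bonferroni correction, per-parameter linear regressions, paired and
   unpaired diagnosis-vs-response tests.
6. **b-value sensitivity** — ADC re-estimated from *every* b-value
   subset containing b = 0, grouped by the highest b-value used; the
   percent ADC decrease per 100 s/mm² of highest b; and the four
   longitudinal-change estimates obtained by using the highest or
   second-highest b-value at each timepoint, with propagated
   uncertainties and Welch t-tests between them.

The scientific point the pipeline demonstrates: cross-sectionally,
tumor heterogeneity dominates acquisition effects, but *changing the
highest b-value between baseline and follow-up* shifts the fitted ADC
by roughly 2.8% per 100 s/mm² and therefore distorts longitudinal
change estimates — the quantity clinicians actually monitor.

## Worked example

A small three-center cohort in which every scan uses a rich 7-value
b-scheme (so each scan is eligible for the combination analysis), with
10% of scans flagged poor-quality:

```yaml
# config.yaml
seed: 7
cohort:
  n_patients: 16
  n_centers: 3
  shape: [24, 24, 6]
  bvalue_schemes: [[0, 50, 100, 200, 500, 800, 1000]]
  scheme_weights: [1.0]
  p_quality1: 0.1
```

```bash
adcvar run-all --config config.yaml --out out/
# mean b-value sensitivity: 2.533938349952301% per 100 s/mm2 over 24 scans
```

`out/` then contains the manifest, NIfTI volumes and ADC maps, and one
CSV per analysis.  The inclusion report counts 27 simulated scans of
which 3 were excluded for poor quality (24 analyzed).  The ADC summary
(`report.json`) reads:

```
timepoint region  n  mean    sd
diagnosis  tumor 14 1.091 0.319
 response  tumor 10 1.515 0.337
 response muscle  2 1.224 0.155
```

— tumor ADC (µm²/ms) rises from diagnosis to response while its spread
stays wide, matching the calibration targets (1.09 ± 0.30 at diagnosis).
The variability table reports, e.g., an echo-time CV of 0.156 across
all centers (median within-center CV 0.122); n-bvalues/highest-b CVs
are 0 here because the config pins a single scheme.  The longitudinal
section lists exactly four change estimates per eligible patient, one
per (diagnosis, response) b-max choice:

```
patient_id    diag_choice    resp_choice  percent_change  se_percent  n_eff
      P000        highest        highest           29.13        0.20   32.0
      P000        highest second_highest           29.50        0.25   24.0
      P000 second_highest        highest           29.39        0.30   24.0
      P000 second_highest second_highest           29.76        0.34   16.0
```

The same stages are available individually (`adcvar simulate`,
`fit-adc`, `roi-stats`, `variability`, `compare`, `bsens`,
`longitudinal`), each reading and writing the documented files in the
output directory, and as library functions (`adcvar.generate_cohort`,
`adcvar.compute_adc_map`, `adcvar.slope_per_100`, ...).

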