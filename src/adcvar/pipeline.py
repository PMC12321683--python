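"""End-to-end orchestration: simulate -> fit -> summarize -> analyze.

Each stage reads and writes documented files inside one output
directory so stages can be rerun independently:

* ``simulate``     : scans/ (NIfTI), manifest.csv, config_resolved.yaml
* ``fit-adc``      : adc/<scan_id>_adc.nii.gz (+ JSON sidecar)
* ``roi-stats``    : inclusion_report.json, roi_summaries.csv
* ``variability``  : variability_table.csv
* ``compare``      : comparisons.csv, regressions.csv, timepoint_tests.csv
* ``bsens``        : bsens_combinations.csv, bsens_groups.csv, bsens_slopes.csv
* ``longitudinal`` : longitudinal_deltas.csv, longitudinal_tests.csv
* ``report``       : report.json
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as adcio
from .bsens import (
    adc_over_combinations,
    delta_pairwise_tests,
    group_by_highest_b,
    longitudinal_four_combinations,
    slope_per_100,
)
from .comparisons import compare_timepoints, run_median_split_tests, run_regressions
from .config import PipelineConfig
from .exceptions import AdcVarError, InsufficientDataError, NoEvaluableROIError
from .fitting import compute_adc_map
from .roi import apply_inclusion_flow, roi_median_adc, summarize_cohort
from .synthetic import generate_cohort
from .variability import ACQUISITION_PARAMETERS, variability_table

log = logging.getLogger("adcvar")

STAGES = (
    "simulate",
    "fit-adc",
    "roi-stats",
    "variability",
    "compare",
    "bsens",
    "longitudinal",
    "report",
)


def _outdir(outdir) -> Path:
    p = Path(outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def simulate_stage(config: PipelineConfig, outdir) -> pd.DataFrame:
    out = _outdir(outdir)
    manifest, scans = generate_cohort(config.cohort, seed=config.seed)
    scans_dir = out / "scans"
    for scan, (idx, row) in zip(scans, manifest.iterrows()):
        paths = adcio.write_scan(scan, scans_dir / scan.scan_id, root=out)
        for col, val in paths.items():
            manifest.loc[idx, col] = val
    adcio.write_manifest(manifest, out / "manifest.csv")
    config.to_yaml(out / "config_resolved.yaml")
    log.info("simulate: %d scans from %d patients", len(manifest),
             manifest["patient_id"].nunique())
    return manifest


def fit_stage(outdir) -> None:
    out = _outdir(outdir)
    manifest = adcio.read_manifest(out / "manifest.csv")
    adc_dir = out / "adc"
    adc_dir.mkdir(exist_ok=True)
    n = 0
    for _, row in manifest.iterrows():
        if not row["dwi_path"]:
            continue
        scan = adcio.load_scan(row, root=out)
        adc_map = compute_adc_map(scan)
        adcio.save_adc_map(
            adc_map, adc_dir / f"{scan.scan_id}_adc.nii.gz", scan.voxel_size_mm
        )
        n += 1
    log.info("fit-adc: %d ADC maps", n)


def roi_stage(outdir, single_slice: bool = False) -> pd.DataFrame:
    out = _outdir(outdir)
    manifest = adcio.read_manifest(out / "manifest.csv")
    included, report = apply_inclusion_flow(manifest)
    with open(out / "inclusion_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    log.info(
        "roi-stats: %d/%d scans included (%s)",
        report.n_included,
        report.n_input_scans,
        report.n_excluded_by_reason,
    )
    rows = []
    for _, row in included.iterrows():
        if not row["dwi_path"]:
            continue
        scan = adcio.load_scan(row, root=out)
        adc_map = adcio.load_adc_map(out / "adc" / f"{scan.scan_id}_adc.nii.gz")
        regions = [("tumor", scan.tumor_mask, scan.exclusion_mask)]
        if scan.muscle_mask is not None:
            regions.append(("muscle", scan.muscle_mask, None))
        for region, mask, excl in regions:
            if single_slice:
                mask = _best_slice(mask)
            try:
                s = roi_median_adc(
                    adc_map, mask, excl, scan_id=scan.scan_id, region=region
                )
            except NoEvaluableROIError:
                continue
            rows.append(
                {
                    "scan_id": s.scan_id,
                    "patient_id": scan.patient_id,
                    "region": s.region,
                    "median_adc": s.median_adc,
                    "n_voxels": s.n_voxels,
                    "n_excluded_voxels": s.n_excluded_voxels,
                }
            )
    summaries = pd.DataFrame(
        rows,
        columns=[
            "scan_id",
            "patient_id",
            "region",
            "median_adc",
            "n_voxels",
            "n_excluded_voxels",
        ],
    )
    summaries.to_csv(out / "roi_summaries.csv", index=False)
    return summaries


def _best_slice(mask: np.ndarray) -> np.ndarray:
    """Restrict a mask to its largest axial slice."""
    counts = mask.sum(axis=(0, 1))
    best = int(np.argmax(counts))
    out = np.zeros_like(mask)
    out[:, :, best] = mask[:, :, best]
    return out


def variability_stage(outdir) -> pd.DataFrame:
    out = _outdir(outdir)
    manifest = adcio.read_manifest(out / "manifest.csv")
    table = variability_table(manifest)
    table.to_csv(out / "variability_table.csv", index=False)
    return table


def _analysis_frame(outdir) -> pd.DataFrame:
    out = Path(outdir)
    manifest = adcio.read_manifest(out / "manifest.csv")
    summaries = pd.read_csv(out / "roi_summaries.csv")
    tumor = summaries[summaries["region"] == "tumor"]
    return tumor.merge(
        manifest[
            ["scan_id", "timepoint", *ACQUISITION_PARAMETERS]
        ],
        on="scan_id",
    )


def compare_stage(outdir, config: PipelineConfig) -> None:
    out = _outdir(outdir)
    data = _analysis_frame(out)
    splits = run_median_split_tests(
        data,
        ACQUISITION_PARAMETERS,
        m=config.analysis.bonferroni_m,
        alpha=config.analysis.alpha,
    )
    splits.to_csv(out / "comparisons.csv", index=False)
    regs = run_regressions(data, ACQUISITION_PARAMETERS)
    regs.to_csv(out / "regressions.csv", index=False)

    manifest = adcio.read_manifest(out / "manifest.csv")
    summaries = pd.read_csv(out / "roi_summaries.csv")
    tp_rows = []
    for region in ("tumor", "muscle"):
        sub = summaries[summaries["region"] == region].merge(
            manifest[["scan_id", "timepoint"]], on="scan_id"
        )
        wide = sub.pivot_table(
            index="patient_id", columns="timepoint", values="median_adc"
        )
        if {"diagnosis", "response"} <= set(wide.columns):
            both = wide.dropna()
            if len(both) >= 2:
                res = compare_timepoints(
                    both["diagnosis"], both["response"], region=region, paired=True
                )
                tp_rows.append(res.__dict__)
        diag = sub.loc[sub["timepoint"] == "diagnosis", "median_adc"]
        resp = sub.loc[sub["timepoint"] == "response", "median_adc"]
        if len(diag) and len(resp):
            res = compare_timepoints(diag, resp, region=region, paired=False)
            tp_rows.append(res.__dict__)
    pd.DataFrame(tp_rows).to_csv(out / "timepoint_tests.csv", index=False)


def bsens_stage(outdir, config: PipelineConfig) -> pd.DataFrame:
    out = _outdir(outdir)
    manifest = adcio.read_manifest(out / "manifest.csv")
    included, _ = apply_inclusion_flow(manifest)
    eligible = included[
        included["bvalues"].str.count(";").add(1) >= config.analysis.min_bvalues_bsens
    ]
    combo_rows, group_rows, slope_rows = [], [], []
    for _, row in eligible.iterrows():
        if not row["dwi_path"]:
            continue
        scan = adcio.load_scan(row, root=out)
        combos = adc_over_combinations(scan, scan.tumor_mask, scan.exclusion_mask)
        for combo, adc in combos:
            combo_rows.append(
                {
                    "scan_id": scan.scan_id,
                    "combination": ";".join(f"{b:g}" for b in combo.bvalues),
                    "highest_b": combo.highest_b,
                    "median_adc": adc,
                }
            )
        groups = group_by_highest_b(combos)
        for g in groups:
            group_rows.append(
                {
                    "scan_id": scan.scan_id,
                    "highest_b": g.highest_b,
                    "mean_adc": g.mean_adc,
                    "se_adc": g.se_adc if g.se_adc is not None else np.nan,
                    "n_combinations": g.n_combinations,
                }
            )
        try:
            slope = slope_per_100(
                groups,
                (config.analysis.slope_fit_lo, config.analysis.slope_fit_hi),
                method=config.analysis.slope_method,
            )
            slope_rows.append({"scan_id": scan.scan_id, "pct_per_100": slope})
        except InsufficientDataError:
            pass
    pd.DataFrame(
        combo_rows, columns=["scan_id", "combination", "highest_b", "median_adc"]
    ).to_csv(out / "bsens_combinations.csv", index=False)
    groups_df = pd.DataFrame(
        group_rows,
        columns=["scan_id", "highest_b", "mean_adc", "se_adc", "n_combinations"],
    )
    groups_df.to_csv(out / "bsens_groups.csv", index=False)
    slopes = pd.DataFrame(slope_rows, columns=["scan_id", "pct_per_100"])
    slopes.to_csv(out / "bsens_slopes.csv", index=False)
    log.info("bsens: %d eligible scans, mean slope %.3f%%/100",
             len(slopes), slopes["pct_per_100"].mean() if len(slopes) else float("nan"))
    return slopes


def longitudinal_stage(outdir, config: PipelineConfig) -> pd.DataFrame:
    out = _outdir(outdir)
    manifest = adcio.read_manifest(out / "manifest.csv")
    groups_df = pd.read_csv(out / "bsens_groups.csv")
    if groups_df.empty:
        pd.DataFrame(
            columns=["patient_id", "diag_choice", "resp_choice",
                     "percent_change", "se_percent", "n_eff"]
        ).to_csv(out / "longitudinal_deltas.csv", index=False)
        pd.DataFrame(
            columns=["patient_id", "combo_1", "combo_2", "t", "df", "p_value"]
        ).to_csv(out / "longitudinal_tests.csv", index=False)
        return pd.DataFrame()
    merged = groups_df.merge(
        manifest[["scan_id", "patient_id", "timepoint"]], on="scan_id"
    )
    delta_rows, test_rows = [], []
    from .bsens import HighestBGroup  # local import to build group objects

    for pid, sub in merged.groupby("patient_id"):
        tps = set(sub["timepoint"])
        if not {"diagnosis", "response"} <= tps:
            continue

        def _mk(tp):
            g = sub[sub["timepoint"] == tp].sort_values("highest_b")
            return [
                HighestBGroup(
                    highest_b=r.highest_b,
                    mean_adc=r.mean_adc,
                    se_adc=None if pd.isna(r.se_adc) else r.se_adc,
                    n_combinations=int(r.n_combinations),
                )
                for r in g.itertuples()
            ]

        try:
            deltas = longitudinal_four_combinations(_mk("diagnosis"), _mk("response"))
        except InsufficientDataError:
            continue
        for d in deltas:
            delta_rows.append({"patient_id": pid, **d.__dict__})
        for t in delta_pairwise_tests(deltas):
            test_rows.append({"patient_id": pid, **t})
    deltas_df = pd.DataFrame(
        delta_rows,
        columns=["patient_id", "diag_choice", "resp_choice",
                 "percent_change", "se_percent", "n_eff"],
    )
    deltas_df.to_csv(out / "longitudinal_deltas.csv", index=False)
    pd.DataFrame(
        test_rows, columns=["patient_id", "combo_1", "combo_2", "t", "df", "p_value"]
    ).to_csv(out / "longitudinal_tests.csv", index=False)
    return deltas_df


def report_stage(outdir) -> dict:
    out = _outdir(outdir)
    manifest = adcio.read_manifest(out / "manifest.csv")
    summaries = pd.read_csv(out / "roi_summaries.csv")
    cohort_table = summarize_cohort(summaries, manifest)
    variability = pd.read_csv(out / "variability_table.csv")
    slopes = pd.read_csv(out / "bsens_slopes.csv")
    deltas = pd.read_csv(out / "longitudinal_deltas.csv")
    with open(out / "inclusion_report.json") as fh:
        inclusion = json.load(fh)
    report = {
        "inclusion": inclusion,
        "adc_by_timepoint_region": cohort_table.to_dict(orient="records"),
        "variability": variability.to_dict(orient="records"),
        "bsens_mean_pct_per_100": (
            float(slopes["pct_per_100"].mean()) if len(slopes) else None
        ),
        "n_bsens_scans": int(len(slopes)),
        "longitudinal_deltas_per_patient": (
            deltas.groupby("patient_id").size().to_dict() if len(deltas) else {}
        ),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def run_all(config: PipelineConfig, outdir) -> dict:
    """Run every stage in order; outputs of finished stages persist."""
    stage = "simulate"
    try:
        simulate_stage(config, outdir)
        stage = "fit-adc"
        fit_stage(outdir)
        stage = "roi-stats"
        roi_stage(outdir, single_slice=config.analysis.single_slice)
        stage = "variability"
        variability_stage(outdir)
        stage = "compare"
        compare_stage(outdir, config)
        stage = "bsens"
        bsens_stage(outdir, config)
        stage = "longitudinal"
        longitudinal_stage(outdir, config)
        stage = "report"
        return report_stage(outdir)
    except AdcVarError as err:
        raise AdcVarError(f"stage {stage!r} failed: {err}") from err
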