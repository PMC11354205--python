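"""End-to-end pipeline: calibrate, simulate a cohort, measure, report.

The demo pipeline exercises every stage on synthetic data: a phantom scan is
simulated and calibrated; a cohort is sampled; each included participant gets
a two-vertebra (L1/L2) synthetic volume painted at their true vBMD, which is
then segmented (rule-based), measured and classified; finally crude and
age-standardized prevalence tables are written.  All randomness flows from a
single seed, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bmd_measure, calibration, epi_report, spine_mask, synthetic_ct
from .calibration import RecalibrationNeeded
from .errors import MeasurementFailureError, QctScreenError

logger = logging.getLogger("qctscreen")

EXIT_OK = 0
EXIT_ERROR = 1
EXIT_RECALIBRATION = 3


@dataclass
class PipelineConfig:
    """Serializable configuration for a full demo run."""

    out_dir: str = "qctscreen_run"
    seed: int = 0
    # phantom / calibration
    phantom_sigma: float = 5.0
    phantom_slices: int = 20
    insert_densities: tuple[float, float, float] = (50.0, 100.0, 200.0)
    rmse_threshold: float = calibration.DEFAULT_RMSE_THRESHOLD
    # imaging model shared by phantom and patients
    hu_slope: float = 1.0
    hu_intercept: float = 0.0
    protocol: str = "default"
    # cohort
    cohort_n: int = 40
    exclusion_counts: tuple[int, int] = (3, 1)
    age_range: tuple[int, int] = (20, 90)
    # patient imaging
    image_sigma: float = 10.0
    in_plane_shape: tuple[int, int] = (96, 96)
    # measurement / reporting
    erosion_mm: float = 3.0
    trim_fraction: float = 0.01
    min_age: int = 50

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class PipelineResult:
    status: int
    model: calibration.ConversionModel | None
    measurements: pd.DataFrame | None
    report: epi_report.PrevalenceReport | None
    recalibration: RecalibrationNeeded | None = None


def _simulate_and_measure_participant(
    row, model, config: PipelineConfig, seed: int
) -> dict[str, object]:
    specs = [
        synthetic_ct.VertebraSpec(level="L1", trabecular_density=row.true_vbmd),
        synthetic_ct.VertebraSpec(level="L2", trabecular_density=row.true_vbmd),
    ]
    ct, _gt = synthetic_ct.generate_vertebra_volume(
        specs,
        hu_slope=config.hu_slope,
        hu_intercept=config.hu_intercept,
        noise_sigma=config.image_sigma,
        seed=seed,
        in_plane_shape=config.in_plane_shape,
        protocol=config.protocol,
    )
    lmask = spine_mask.segment_lumbar(ct, method="rule_based")
    instances = spine_mask.instance_label(lmask)
    roi_cfg = bmd_measure.RoiConfig(erosion_mm=config.erosion_mm)
    result = bmd_measure.measure_vbmd(
        ct, instances, model, config=roi_cfg, trim_fraction=config.trim_fraction
    )
    out: dict[str, object] = {
        "id": row.id,
        "age": int(row.age),
        "sex": row.sex,
        "true_vbmd": float(row.true_vbmd),
        "vbmd": result.combined_l1_2,
        "single_vertebra": result.single_vertebra,
    }
    for level in ("L1", "L2"):
        r = result.representative_hu.get(level)
        out[f"{level}_vbmd"] = result.per_vertebra.get(level, np.nan)
        out[f"{level}_rep_hu"] = r.value if r else np.nan
        out[f"{level}_n_raw"] = r.n_raw if r else 0
        out[f"{level}_n_used"] = r.n_used if r else 0
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute calibrate -> simulate -> measure -> classify -> report.

    Writes to ``config.out_dir``: the echoed config, the conversion model
    JSON, the per-participant measurement CSV, the prevalence report CSV, a
    text summary, and a log with per-stage record counts.  The returned
    status distinguishes success (0) from recalibration-needed (3); hard
    stage errors propagate as exceptions tagged with stage and participant.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> PipelineResult:
    seeds = np.random.SeedSequence(config.seed).generate_state(3 + config.cohort_n) % (2**31)

    # stage 1: phantom calibration
    phantom = synthetic_ct.generate_esp_volume(
        insert_densities=config.insert_densities,
        hu_slope=config.hu_slope,
        hu_intercept=config.hu_intercept,
        noise_sigma=config.phantom_sigma,
        n_slices=config.phantom_slices,
        seed=int(seeds[0]),
        protocol=config.protocol,
    )
    samples = calibration.extract_insert_hu(phantom, trim_fraction=config.trim_fraction)
    samples.to_csv(out / "calibration_samples.csv")
    candidates, failures = calibration.fit_conversion(samples)
    logger.info(
        "calibration: %d rows, %d candidate fits, %d failures",
        len(samples.rows), len(candidates), len(failures),
    )
    selected = calibration.select_model(candidates, rmse_threshold=config.rmse_threshold)
    if isinstance(selected, RecalibrationNeeded):
        logger.info(
            "recalibration needed: best RMSE %.3f > threshold %.3f (method %s)",
            selected.best_rmse, selected.threshold, selected.best_method,
        )
        return PipelineResult(
            status=EXIT_RECALIBRATION, model=None, measurements=None,
            report=None, recalibration=selected,
        )
    selected.to_json(out / "conversion_model.json")
    logger.info("selected model: %s, RMSE %.3f mg/cc", selected.method, selected.rmse)

    # stage 2: cohort and exclusions
    cohort = synthetic_ct.sample_cohort(
        n=config.cohort_n,
        age_range=config.age_range,
        exclusion_counts=config.exclusion_counts,
        seed=int(seeds[1]),
    )
    cohort.to_csv(out / "cohort.csv")
    included, tally = epi_report.apply_exclusions(cohort.participants)
    logger.info(
        "cohort: %d participants; excluded %d (missing L1 %d, fracture/implant %d); included %d",
        len(cohort.participants), tally["total"], tally["missing_L1"],
        tally["fracture_implant"], len(included),
    )

    # stage 3: per-participant imaging and measurement
    rows = []
    for k, row in enumerate(included.itertuples(index=False)):
        try:
            rows.append(
                _simulate_and_measure_participant(row, selected, config, int(seeds[3 + k]))
            )
        except QctScreenError as exc:
            raise MeasurementFailureError(
                f"stage=measure participant={row.id}: {exc}"
            ) from exc
    measurements = pd.DataFrame(rows)
    measurements["category"] = epi_report.classify_acr_series(measurements["vbmd"])
    measurements.to_csv(out / "measurements.csv", index=False, float_format="%.4f")
    logger.info("measured %d participants", len(measurements))

    # stage 4: report
    strat = epi_report.stratify_bmd(measurements)
    strat.to_csv(out / "bmd_by_age_sex.csv", index=False, float_format="%.2f")
    report = epi_report.prevalence_report(measurements, min_age=config.min_age)
    report.to_csv(out / "prevalence.csv")
    (out / "prevalence.txt").write_text(report.to_text())
    counts = measurements["category"].value_counts().to_dict()
    logger.info("categories: %s", counts)
    return PipelineResult(
        status=EXIT_OK, model=selected, measurements=measurements, report=report
    )
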