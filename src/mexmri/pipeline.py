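"""File I/O and end-to-end orchestration.

Reads and writes the pipeline's file formats — NIfTI image series, masks
and parameter maps; JSON delay schedules; CSV tables, histograms and stats
reports; PNG stain masks; YAML run configuration — and chains the stages:
simulate (or load) -> voxel/ROI fitting -> map statistics -> histology
gating -> group statistics -> report bundle. Every stage logs its
parameters; the full configuration is serialized into the output directory
so a run can be reproduced from the report alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .fitting import FitConfig, FitResult, ImageSeries, ParameterMap, fit_map, fit_roi
from .histology import GATE_PRESETS, segment_stain
from .map_analysis import f_histogram, high_f_fraction
from .model import MOUSE_SCHEDULE, RAT_SCHEDULE, AcquisitionSchedule
from .stats import group_report
from .synthetic import (
    CohortConfig,
    NoiseModel,
    load_preset,
    make_phantom,
    make_stain_image,
    simulate_cohort,
    simulate_series,
)

__all__ = [
    "RunConfig",
    "SCHEDULE_PRESETS",
    "load_schedule",
    "save_schedule",
    "load_series",
    "save_series",
    "save_parameter_maps",
    "load_parameter_maps",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

SCHEDULE_PRESETS = {"rat": RAT_SCHEDULE, "mouse": MOUSE_SCHEDULE}


@dataclass
class RunConfig:
    """All tunables of one pipeline run.

    ``schedule`` is 'rat', 'mouse', or an explicit list of delays in ms.
    Thresholds: voxels enter the maps only with fit R^2 above
    ``r2_threshold``; the high-F summary counts valid voxels with F above
    ``high_f_threshold``.
    """

    schedule: str | list[float] = "rat"
    r2_threshold: float = 0.95
    high_f_threshold: float = 0.1
    bin_width: float = 0.01
    gate_preset: str = "PSR"
    phantom_preset: str = "rat_fibrosis"
    size: tuple[int, int, int] = (32, 32, 1)
    snr: float = np.inf
    suppression: float = 1.0
    n_control: int = 3
    n_fibrosis: int = 4
    seed: int = 0
    outdir: str = "mexmri_out"
    fit: FitConfig = field(default_factory=FitConfig)

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_threshold < 1.0):
            raise ValueError("r2_threshold must lie in (0, 1)")
        if not (0.0 < self.high_f_threshold < 1.0):
            raise ValueError("high_f_threshold must lie in (0, 1)")
        self.fit.r2_threshold = self.r2_threshold

    def resolve_schedule(self) -> AcquisitionSchedule:
        if isinstance(self.schedule, str):
            try:
                return SCHEDULE_PRESETS[self.schedule]
            except KeyError:
                raise ValueError(
                    f"unknown schedule preset {self.schedule!r}; "
                    f"use one of {sorted(SCHEDULE_PRESETS)} or a delay list"
                ) from None
        return AcquisitionSchedule(tuple(self.schedule))

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["snr"] = "inf" if np.isinf(self.snr) else float(self.snr)
        d["size"] = list(self.size)
        return yaml.safe_dump(d, sort_keys=True)


# ---------------------------------------------------------------- schedules

def save_schedule(schedule: AcquisitionSchedule, path: str | Path) -> None:
    """Write a delay schedule as JSON ({"delays_ms": [...]})."""
    Path(path).write_text(
        json.dumps({"delays_ms": list(schedule.delays)}, indent=2) + "\n"
    )


def load_schedule(path: str | Path) -> AcquisitionSchedule:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
        return AcquisitionSchedule(tuple(payload["delays_ms"]))
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(
            f"{path} is not a valid schedule JSON "
            '(expected {"delays_ms": [ms, ...]})'
        ) from exc


# ------------------------------------------------------------------- NIfTI

def _load_nifti(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"NIfTI file not found: {path}")
    try:
        return np.asanyarray(nib.load(str(path)).dataobj)
    except Exception as exc:
        raise ValueError(f"{path} is not a readable NIfTI file") from exc


def load_series(
    series_path: str | Path,
    schedule: AcquisitionSchedule | str | Path,
    mask_path: str | Path,
) -> ImageSeries:
    """Load a 4D NIfTI series plus 3D ROI mask; schedule may be a JSON path."""
    if not isinstance(schedule, AcquisitionSchedule):
        schedule = load_schedule(schedule)
    data = _load_nifti(series_path)
    mask = _load_nifti(mask_path)
    if data.ndim != 4:
        raise ValueError(f"{series_path}: expected a 4D series, got {data.ndim}D")
    return ImageSeries(data=data, schedule=schedule, roi=mask.astype(bool))


def save_series(series: ImageSeries, series_path: str | Path,
                mask_path: str | Path, schedule_path: str | Path) -> None:
    aff = np.eye(4)
    nib.save(nib.Nifti1Image(series.data.astype(np.float64), aff), str(series_path))
    nib.save(nib.Nifti1Image(series.roi.astype(np.uint8), aff), str(mask_path))
    save_schedule(series.schedule, schedule_path)


_MAP_NAMES = ("F", "T1", "r2", "valid")


def save_parameter_maps(pmap: ParameterMap, outdir: str | Path,
                        prefix: str = "map") -> dict[str, Path]:
    """Write F/T1/R^2/valid volumes as NIfTI; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = np.eye(4)
    arrays = {
        "F": pmap.F_map, "T1": pmap.T1_map, "r2": pmap.r2_map,
        "valid": pmap.valid.astype(np.uint8),
    }
    paths = {}
    for name, arr in arrays.items():
        p = outdir / f"{prefix}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), aff), str(p))
        paths[name] = p
    return paths


def load_parameter_maps(outdir: str | Path, prefix: str = "map") -> ParameterMap:
    outdir = Path(outdir)
    arrs = {n: _load_nifti(outdir / f"{prefix}_{n}.nii.gz") for n in _MAP_NAMES}
    valid = arrs["valid"].astype(bool)
    return ParameterMap(
        F_map=arrs["F"], T1_map=arrs["T1"], r2_map=arrs["r2"],
        valid=valid, roi=valid.copy(),
    )


def _fit_summary_row(name: str, fit: FitResult) -> dict:
    return {
        "id": name, "F": fit.params.F, "F_ci95": fit.ci95[0],
        "T1_ms": fit.params.T1, "T1_ci95_ms": fit.ci95[1],
        "tau_exc_ms": fit.params.tau_exc, "tau_ci95_ms": fit.ci95[2],
        "r2": fit.r2, "converged": fit.converged,
    }


# ---------------------------------------------------------------- pipeline

def run_pipeline(config: RunConfig, inputs: dict | None = None) -> dict:
    """Run the full chain and write a report bundle to ``config.outdir``.

    ``inputs`` may supply file paths ({"series", "mask", "schedule"} and/or
    {"stain_images": [paths]}); anything missing is simulated on the fly
    from the configured phantom preset and cohort. Returns a dict with the
    in-memory results and all output paths. Deterministic given the seed.
    """
    inputs = inputs or {}
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    schedule = config.resolve_schedule()
    bundle: dict = {"outdir": outdir}

    (outdir / "run_config.yaml").write_text(config.to_yaml())
    logger.info("pipeline: outdir=%s seed=%d", outdir, config.seed)

    # -- stage 1: obtain the image series -----------------------------------
    if "series" in inputs:
        series = load_series(
            inputs["series"], inputs.get("schedule", schedule), inputs["mask"]
        )
        logger.info("loaded series %s", inputs["series"])
    else:
        phantom = make_phantom(
            config.phantom_preset, size=config.size, seed=config.seed
        )
        noise = NoiseModel(
            snr=config.snr, suppression=config.suppression, seed=config.seed
        )
        series = simulate_series(phantom, schedule, noise)
        bundle["phantom"] = phantom
        logger.info("simulated %s phantom %s", config.phantom_preset, config.size)

    # -- stage 2: fitting ----------------------------------------------------
    pmap = fit_map(series, config.fit)
    roi_fit = fit_roi(series, config.fit)
    bundle["parameter_map"] = pmap
    bundle["roi_fit"] = roi_fit
    bundle["map_paths"] = save_parameter_maps(pmap, outdir)
    summary = pd.DataFrame([_fit_summary_row("roi", roi_fit)])
    summary_path = outdir / "fit_summary.csv"
    summary.to_csv(summary_path, index=False)
    bundle["fit_summary_path"] = summary_path

    # -- stage 3: map statistics --------------------------------------------
    hist = f_histogram(pmap, bin_width=config.bin_width)
    high_f = high_f_fraction(pmap, threshold=config.high_f_threshold)
    bundle["histogram"] = hist
    bundle["high_f_percent"] = high_f
    hist_df = pd.DataFrame({
        "bin_low": hist.bin_edges[:-1], "bin_high": hist.bin_edges[1:],
        "density": hist.density,
    })
    hist_path = outdir / "f_histogram.csv"
    hist_df.to_csv(hist_path, index=False)
    pd.DataFrame(
        [{"threshold": config.high_f_threshold, "high_f_percent": high_f}]
    ).to_csv(outdir / "high_f.csv", index=False)
    logger.info("map stats: high-F %.2f%% of %d valid voxels",
                high_f, int(pmap.valid.sum()))

    # -- stage 4: histology --------------------------------------------------
    gate = GATE_PRESETS[config.gate_preset]
    stain_rows = []
    if "stain_images" in inputs:
        images = [(Path(p).stem, iio.imread(p)) for p in inputs["stain_images"]]
    else:
        preset = load_preset(
            "rat_fibrosis" if config.gate_preset == "PSR" else "mouse_fibrosis"
        )
        target = preset["histology"]["group_percent"] / 100.0
        img, _ = make_stain_image(gate, target, (100, 100), seed=config.seed)
        images = [("synthetic_stain", img)]
    for name, img in images:
        res = segment_stain(img[..., :3].astype(np.uint8), gate)
        iio.imwrite(outdir / f"{name}_mask.png",
                    (res.mask * np.uint8(255)))
        stain_rows.append({
            "image_id": name, "stain": config.gate_preset,
            "fraction_percent": res.fraction_percent,
        })
    stain_df = pd.DataFrame(stain_rows)
    stain_df.to_csv(outdir / "stain_fractions.csv", index=False)
    bundle["stain_fractions"] = stain_df

    # -- stage 5: group statistics ------------------------------------------
    control, fibrosis = (
        ("rat_control", "rat_fibrosis")
        if isinstance(config.schedule, str) and config.schedule == "rat"
        else ("mouse_control", "mouse_fibrosis")
    )
    cohort_cfg = CohortConfig(
        control_preset=control, fibrosis_preset=fibrosis,
        n_control=config.n_control, n_fibrosis=config.n_fibrosis,
        snr=config.snr, suppression=config.suppression,
    )
    cohort_series, truth = simulate_cohort(cohort_cfg, seed=config.seed)
    table_rows = []
    for _, row in truth.iterrows():
        fit = fit_roi(cohort_series[row["animal_id"]], config.fit)
        amap = fit_map(cohort_series[row["animal_id"]], config.fit)
        table_rows.append({
            "animal_id": row["animal_id"], "group": row["group"],
            "timepoint_weeks": row["timepoint_weeks"],
            "F": fit.params.F, "T1_ms": fit.params.T1,
            "high_f_percent": high_f_fraction(
                amap, threshold=config.high_f_threshold
            ),
            "histology_percent": row["histology_percent"],
            "inflammation_score": row["inflammation_score"],
            "F_true": row["F_true"], "T1_true_ms": row["T1_true_ms"],
        })
    table = pd.DataFrame(table_rows)
    table.to_csv(outdir / "group_table.csv", index=False)
    stats_df, report_text = group_report(table)
    stats_df.to_csv(outdir / "stats_report.csv", index=False)
    (outdir / "stats_report.txt").write_text(report_text)
    bundle["group_table"] = table
    bundle["stats"] = stats_df
    logger.info("pipeline complete: %s", outdir)
    return bundle
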