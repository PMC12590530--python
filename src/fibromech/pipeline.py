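"""End-to-end orchestration: simulate -> fit -> spectra -> collagen -> stats -> classify -> report.

Every stage reads and writes the documented formats under one output
directory; the full configuration (including every protocol constant:
theta = 20 deg, nu = 0.5, 1.8 nN force cap, ROUT Q = 1%, hue bands, k = 20)
is serialized alongside the outputs, and a run manifest records seeds, file
hashes and timing so that identical configs reproduce identical numeric
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import classify, histology, io, spectra, stats, synth
from .forcecurves import QCConfig, analyze_map

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "report"]

STAGE_ORDER = ("simulate", "fit", "spectrum", "collagen", "stats", "classify", "report")


@dataclass
class PipelineConfig:
    outdir: str = "fibromech_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGE_ORDER
    # cohort (kept deliberately small by default; the murine-scale design is
    # available via synth.paper_design)
    n_control: int = 3
    n_fibrotic: int = 3
    fibrotic_stage: str = "chronic_d21"
    maps_per_specimen: int = 3
    grid_points: int = 8
    map_side: float = 20.0
    # contact mechanics
    theta_deg: float = 20.0
    nu: float = 0.5
    force_cap_nn: float = 1.8
    r_squared_min: float = 0.80
    # statistics
    rout_q: float = 0.01
    # histology
    image_size: int = 128
    image_tile: int = 64
    hue_bands: dict = field(default_factory=lambda: histology.HueBands().as_dict())
    # classification
    kernels: tuple[str, ...] = ("linear",)
    cv_k: int = 20
    map_subgrid: int = 4
    grid_search: bool = True

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if "kernels" in data:
            data["kernels"] = tuple(data["kernels"])
        return cls(**data)

    def to_yaml(self, path: Path) -> None:
        data = dataclasses.asdict(self)
        data["stages"] = list(self.stages)
        data["kernels"] = list(self.kernels)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    files: dict[str, str]  # relative path -> sha256
    timings_s: dict[str, float]

    def save(self, path: Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineError(RuntimeError):
    pass


def _design(cfg: PipelineConfig) -> synth.StudyDesign:
    return synth.StudyDesign(
        groups=(
            synth.GroupSpec("control", cfg.n_control, 21),
            synth.GroupSpec(cfg.fibrotic_stage, cfg.n_fibrotic, 21),
        ),
        maps_per_specimen=cfg.maps_per_specimen,
        grid_points=cfg.grid_points,
        map_side=cfg.map_side,
        seed=cfg.seed,
    )


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in dependency order.

    A stage that needs missing upstream output raises a named PipelineError.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    files: dict[str, str] = {}
    timings: dict[str, float] = {}
    enabled = [s for s in STAGE_ORDER if s in config.stages]

    cohort = None
    analyzed: dict[str, list] = {}
    nmf_df = None
    collagen_df = None

    def register(path: Path) -> None:
        files[str(path.relative_to(outdir))] = _sha256(path)

    for stage in enabled:
        t0 = time.perf_counter()
        if stage == "simulate":
            cohort = synth.simulate_cohort(_design(config))
            io.write_cohort(cohort, outdir / "curves")
            for spec in cohort.specimens:
                imgset = synth.render_specimen_image(spec, size=config.image_size)
                iio.imwrite(outdir / "curves" / f"{spec.specimen_id}_brightfield.png",
                            imgset.brightfield)
                iio.imwrite(outdir / "curves" / f"{spec.specimen_id}_polarized.png",
                            imgset.polarized)
            for p in sorted((outdir / "curves").iterdir()):
                register(p)

        elif stage == "fit":
            curve_dir = outdir / "curves"
            if not (curve_dir / "manifest.csv").exists():
                raise PipelineError("fit: missing curve container (run 'simulate' first)")
            manifest = io.read_manifest(curve_dir)
            qc = QCConfig(r_squared_min=config.r_squared_min)
            long_tables = []
            for _, row in manifest.iterrows():
                _, maps = io.read_specimen_curves(curve_dir / row["path"])
                emaps = [
                    analyze_map(m, qc=qc, theta=config.theta_deg, nu=config.nu,
                                force_cap=config.force_cap_nn,
                                specimen_id=row["specimen_id"])
                    for m in maps
                ]
                analyzed[row["specimen_id"]] = emaps
                long_tables.append(io.elasticity_long_table(emaps))
            fit_path = outdir / "elasticity_long.csv"
            pd.concat(long_tables, ignore_index=True).to_csv(fit_path, index=False)
            register(fit_path)

        elif stage == "spectrum":
            if not analyzed:
                raise PipelineError("spectrum: no fitted maps (run 'fit' first)")
            rows = []
            for sid, emaps in analyzed.items():
                spec = spectra.pool_specimen(emaps, specimen_id=sid, rout_q=config.rout_q)
                summary = spectra.decompose_peaks(spec)
                rows.append({
                    "specimen_id": sid,
                    "n": summary.n,
                    "n_components": summary.n_components,
                    "lep_mode_kpa": summary.lep_mode,
                    "hep_mode_kpa": summary.hep_mode,
                    "lep_weight": summary.lep_weight,
                    "hep_weight": summary.hep_weight,
                    "median_e_kpa": summary.median_e,
                    "cv_percent": summary.cv_percent,
                    "iqr_kpa": summary.iqr,
                    "em_fallback": summary.em_fallback,
                    "rout_removed": spec.n_outliers_removed,
                })
            nmf_df = pd.DataFrame(rows)
            nmf_path = outdir / "nmf_summary.csv"
            nmf_df.to_csv(nmf_path, index=False)
            register(nmf_path)

        elif stage == "collagen":
            curve_dir = outdir / "curves"
            if not (curve_dir / "manifest.csv").exists():
                raise PipelineError("collagen: missing images (run 'simulate' first)")
            manifest = io.read_manifest(curve_dir)
            bands = histology.HueBands(
                col1_low_deg=config.hue_bands["col1_band_deg"][0],
                col1_high_deg=config.hue_bands["col1_band_deg"][1],
                col3_low_deg=config.hue_bands["col3_band_deg"][0],
                col3_high_deg=config.hue_bands["col3_band_deg"][1],
                value_threshold_fraction=config.hue_bands["value_threshold_fraction"],
            )
            rows = []
            for _, row in manifest.iterrows():
                sid = row["specimen_id"]
                imgset = synth.PolarizedImageSet(
                    brightfield=iio.imread(curve_dir / f"{sid}_brightfield.png"),
                    polarized=iio.imread(curve_dir / f"{sid}_polarized.png"),
                )
                quant = histology.quantify_collagen_polarized(imgset, bands=bands)
                rows.append({
                    "image_id": sid,
                    "tissue_area": quant.tissue_area,
                    "col1_fraction": quant.col1_fraction,
                    "col3_fraction": quant.col3_fraction,
                    "total_collagen_fraction": quant.total_collagen_fraction,
                })
            collagen_df = pd.DataFrame(rows)
            col_path = outdir / "collagen_quantification.csv"
            collagen_df.to_csv(col_path, index=False)
            register(col_path)

        elif stage == "stats":
            if nmf_df is None or cohort is None:
                raise PipelineError("stats: needs 'spectrum' output")
            stage_of = {s.specimen_id: s.stage_label for s in cohort.specimens}
            nmf_df["group"] = nmf_df["specimen_id"].map(stage_of)
            groups = {
                g: sub["median_e_kpa"].to_numpy()
                for g, sub in nmf_df.groupby("group")
            }
            tests = stats.group_tests(groups)
            test_path = outdir / "group_tests.csv"
            tests.to_csv(test_path, index=False)
            register(test_path)
            if collagen_df is not None:
                tp_of = {s.specimen_id: s.timepoint_days for s in cohort.specimens}
                corr_in = pd.DataFrame({
                    "specimen_id": nmf_df["specimen_id"],
                    "timepoint_days": nmf_df["specimen_id"].map(tp_of),
                    "collagen_fraction": nmf_df["specimen_id"].map(
                        collagen_df.set_index("image_id")["total_collagen_fraction"]
                    ),
                    "mean_e_kpa": nmf_df["median_e_kpa"],
                })
                corr = stats.stage_correlation(corr_in)
                corr_path = outdir / "stage_correlation.csv"
                corr.to_csv(corr_path, index=False)
                register(corr_path)

        elif stage == "classify":
            if cohort is None:
                raise PipelineError("classify: needs 'simulate' output")
            optical, afm = classify.build_segment_dataset(
                cohort,
                image_size=config.image_size,
                image_tile=config.image_tile,
                map_subgrid=config.map_subgrid,
            )
            fused, _ = classify.fuse_modalities(optical, afm)
            rows = []
            for kernel_name in config.kernels:
                spec = classify.DEFAULT_GRIDS[kernel_name]
                for modality, samples in (
                    ("optical", optical), ("afm", afm), ("fused", fused),
                ):
                    res = classify.grouped_cv_train_eval(
                        samples, spec, k=config.cv_k, seed=config.seed,
                        grid_search=config.grid_search,
                    )
                    rows.append({
                        "kernel": kernel_name,
                        "modality": modality,
                        "accuracy_range_percent": res.accuracy_range_percent,
                        "mean_accuracy_percent": 100.0 * res.mean_accuracy,
                        "k": res.k,
                    })
            cls_df = pd.DataFrame(rows)
            cls_path = outdir / "classification_summary.csv"
            cls_df.to_csv(cls_path, index=False)
            register(cls_path)

        elif stage == "report":
            text = report(outdir)
            rep_path = outdir / "report.md"
            rep_path.write_text(text)
            register(rep_path)

        timings[stage] = time.perf_counter() - t0

    manifest = RunManifest(
        config=dataclasses.asdict(config),
        seeds={"master": config.seed},
        files=files,
        timings_s=timings,
    )
    manifest.save(outdir / "run_manifest.json")
    return manifest


def report(outdir: Path) -> str:
    """Markdown summary of whatever outputs exist in a run directory."""
    outdir = Path(outdir)
    lines = ["# Nanomechanical fingerprint run summary", ""]

    nmf = outdir / "nmf_summary.csv"
    if nmf.exists():
        df = pd.read_csv(nmf)
        lines.append("## Elasticity spectra (LEP/HEP per specimen)")
        lines.append(df.round(3).to_markdown(index=False))
        lines.append("")

    col = outdir / "collagen_quantification.csv"
    if col.exists():
        df = pd.read_csv(col)
        lines.append("## Collagen quantification (fractions of tissue area)")
        lines.append(df.round(4).to_markdown(index=False))
        lines.append("")

    tests = outdir / "group_tests.csv"
    if tests.exists():
        df = pd.read_csv(tests)
        lines.append("## Group comparisons")
        lines.append(df.round(4).to_markdown(index=False))
        lines.append("")

    corr = outdir / "stage_correlation.csv"
    if corr.exists():
        df = pd.read_csv(corr)
        lines.append("## Stiffness-collagen correlation per timepoint")
        lines.append(df.round(4).to_markdown(index=False))
        lines.append("")

    cls = outdir / "classification_summary.csv"
    if cls.exists():
        df = pd.read_csv(cls)
        lines.append("## Classifier accuracy (kernel x modality)")
        lines.append(df.round(2).to_markdown(index=False))
        lines.append("")

    if len(lines) == 2:
        lines.append("(no stage outputs found)")
    return "\n".join(lines) + "\n"
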