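"""On-disk formats: hierarchical curve container, cohort manifest, image files.

One HDF5 file per specimen holds the raw curves in a
specimen -> map -> curve layout with z / deflection arrays (nm) and the
calibration constants, seed and generator truth as attributes.  The cohort
manifest is a CSV (specimen_id, group, timepoint, sex, path) with all
generation parameters echoed into a JSON sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .forcecurves import ElasticityMap
from .synth import CantileverModel, Cohort, ForceCurve, ForceMap, Specimen

__all__ = [
    "write_specimen_curves",
    "read_specimen_curves",
    "write_cohort",
    "read_manifest",
    "write_elasticity_map_csv",
    "elasticity_long_table",
]


def _cant_attrs(cant: CantileverModel) -> dict:
    return {
        "spring_constant_N_per_m": cant.spring_constant,
        "deflection_sensitivity_nm_per_V": cant.deflection_sensitivity,
        "half_open_angle_theta_deg": cant.half_open_angle_theta,
        "tip_radius_nm": cant.tip_radius,
        "resonance_frequency_kHz": cant.resonance_frequency,
    }


def write_specimen_curves(specimen: Specimen, path: Path) -> Path:
    """Write one specimen's force maps to an HDF5 container."""
    if specimen.force_maps is None:
        raise ValueError(f"specimen {specimen.specimen_id} carries no raw curves")
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["specimen_id"] = specimen.specimen_id
        f.attrs["stage_label"] = specimen.stage_label
        f.attrs["timepoint_days"] = specimen.timepoint_days
        f.attrs["sex"] = specimen.sex
        for fmap in specimen.force_maps:
            g = f.create_group(f"map_{fmap.map_index:03d}")
            g.attrs["grid_points"] = fmap.grid_points
            g.attrs["map_side_um"] = fmap.map_side
            g.attrs.update(_cant_attrs(fmap.cantilever))
            for curve in fmap.curves:
                i, j = curve.grid_position
                cg = g.create_group(f"curve_{i:02d}_{j:02d}")
                cg.create_dataset("z_nm", data=curve.z)
                cg.create_dataset("deflection_nm", data=curve.deflection)
                cg.attrs["row"] = i
                cg.attrs["col"] = j
                if curve.truth:
                    for key, val in curve.truth.items():
                        cg.attrs[f"truth_{key}"] = val
    return path


def read_specimen_curves(path: Path) -> tuple[dict, list[ForceMap]]:
    """Read an HDF5 curve container back into ForceMap objects.

    Returns (specimen metadata, maps); round-trips arrays exactly.
    """
    maps = []
    with h5py.File(path, "r") as f:
        meta = {k: (v.item() if hasattr(v, "item") else v) for k, v in f.attrs.items()}
        for map_name in sorted(f):
            g = f[map_name]
            cant = CantileverModel(
                spring_constant=float(g.attrs["spring_constant_N_per_m"]),
                deflection_sensitivity=float(g.attrs["deflection_sensitivity_nm_per_V"]),
                half_open_angle_theta=float(g.attrs["half_open_angle_theta_deg"]),
                tip_radius=float(g.attrs["tip_radius_nm"]),
                resonance_frequency=float(g.attrs["resonance_frequency_kHz"]),
            )
            curves = []
            for curve_name in sorted(g):
                cg = g[curve_name]
                truth = {
                    k[len("truth_"):]: (v.item() if hasattr(v, "item") else v)
                    for k, v in cg.attrs.items() if k.startswith("truth_")
                }
                curves.append(ForceCurve(
                    z=cg["z_nm"][:],
                    deflection=cg["deflection_nm"][:],
                    cantilever=cant,
                    map_index=int(map_name.split("_")[1]),
                    grid_position=(int(cg.attrs["row"]), int(cg.attrs["col"])),
                    truth=truth or None,
                ))
            maps.append(ForceMap(
                curves=curves,
                grid_points=int(g.attrs["grid_points"]),
                map_side=float(g.attrs["map_side_um"]),
                cantilever=cant,
                map_index=int(map_name.split("_")[1]),
            ))
    return meta, maps


def write_cohort(cohort: Cohort, outdir: Path) -> pd.DataFrame:
    """Write every specimen container plus manifest CSV and parameter sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for spec in cohort.specimens:
        fname = f"{spec.specimen_id}.h5"
        if spec.force_maps is not None:
            write_specimen_curves(spec, outdir / fname)
        rows.append({
            "specimen_id": spec.specimen_id,
            "group": spec.stage_label,
            "timepoint_days": spec.timepoint_days,
            "sex": spec.sex,
            "path": fname if spec.force_maps is not None else "",
            "col1_fraction_truth": spec.col1_fraction,
            "col3_fraction_truth": spec.col3_fraction,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    params = {
        "seed": cohort.design.seed,
        "maps_per_specimen": cohort.design.maps_per_specimen,
        "grid_points": cohort.design.grid_points,
        "map_side_um": cohort.design.map_side,
        "groups": [dataclasses.asdict(g) for g in cohort.design.groups],
    }
    (outdir / "generation_params.json").write_text(json.dumps(params, indent=2))
    return manifest


def read_manifest(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(Path(outdir) / "manifest.csv")


def write_elasticity_map_csv(emap: ElasticityMap, path: Path) -> Path:
    """CSV grid of moduli (kPa); masked pixels written as empty cells."""
    grid = np.where(emap.qc_mask, emap.e_kpa, np.nan)
    pd.DataFrame(grid).to_csv(path, index=False, header=False)
    return Path(path)


def elasticity_long_table(maps: list[ElasticityMap]) -> pd.DataFrame:
    """Long-format per-pixel table: specimen, map, row, col, E_kPa, r2, qc_flag."""
    rows = []
    for emap in maps:
        g = emap.e_kpa.shape[0]
        for i in range(g):
            for j in range(emap.e_kpa.shape[1]):
                rows.append({
                    "specimen_id": emap.specimen_id,
                    "map": emap.map_index,
                    "row": i,
                    "col": j,
                    "E_kPa": emap.e_kpa[i, j],
                    "r2": emap.r_squared[i, j] if emap.r_squared is not None else np.nan,
                    "qc_flag": int(emap.reject_codes[i, j]),
                })
    return pd.DataFrame(rows)
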