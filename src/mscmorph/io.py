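"""Readers and writers for the pipeline's plain-text interchange formats.

Per-cell descriptor tables, tidy/wide profile tables and CFSE event lists
travel as CSV; lot panel ground truth as JSON; rendered images and masks
as TIFF.  The per-cell CSV schema (lot, well, fov, time_h, cell_id,
x_um, y_um, 16 descriptor columns) is shared between the synthetic
generator and the image-measurement path, so imaging can be bypassed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .modeling import CVReport
from .morphometry import DESCRIPTOR_NAMES
from .profiling import MorphProfile
from .synthgen import CFSESample, ImageFrame, LotSpec, Schedule, SyntheticImage

CELL_CSV_COLUMNS = ["lot", "well", "fov", "time_h", "cell_id", "x_um", "y_um",
                    *DESCRIPTOR_NAMES]


def write_cells_csv(frames: list[ImageFrame], path) -> None:
    chunks = []
    for f in frames:
        df = f.cells.copy()
        df.insert(0, "lot", f.lot_id)
        df.insert(1, "well", f.well_id)
        df.insert(2, "fov", f.fov if f.fov is not None else 0)
        df.insert(3, "time_h", f.time_h)
        if "x_um" not in df.columns:
            df["x_um"] = np.nan
            df["y_um"] = np.nan
        chunks.append(df[CELL_CSV_COLUMNS])
    pd.concat(chunks, ignore_index=True).to_csv(path, index=False)


def read_cells_csv(path) -> list[ImageFrame]:
    df = pd.read_csv(path)
    frames = []
    for (lot, well, fov, t), sub in df.groupby(["lot", "well", "fov", "time_h"], sort=True):
        frames.append(
            ImageFrame(
                lot_id=str(lot), well_id=str(well), time_h=float(t),
                cells=sub.drop(columns=["lot", "well", "fov", "time_h"]).reset_index(drop=True),
                fov=int(fov) if not pd.isna(fov) else None,
            )
        )
    return frames


def write_panel_json(panel: list[LotSpec], path) -> None:
    payload = []
    for lot in panel:
        payload.append(
            {
                "lot_id": lot.lot_id,
                "origin": lot.origin,
                "risk_class": lot.risk_class,
                "growth_rate_true": lot.growth_rate_true,
                "cfse_prolif_frac": lot.cfse_prolif_frac,
                "area_mu_traj": lot.area_mu_traj.tolist(),
                "area_sigma_traj": lot.area_sigma_traj.tolist(),
                "schedule": {
                    "start_h": lot.schedule.start_h,
                    "end_h": lot.schedule.end_h,
                    "interval_h": lot.schedule.interval_h,
                },
            }
        )
    Path(path).write_text(json.dumps(payload, indent=1))


def read_panel_json(path) -> list[LotSpec]:
    payload = json.loads(Path(path).read_text())
    lots = []
    for d in payload:
        sched = Schedule(**d["schedule"])
        lots.append(
            LotSpec(
                lot_id=d["lot_id"], origin=d["origin"], risk_class=d["risk_class"],
                growth_rate_true=d["growth_rate_true"],
                area_mu_traj=np.asarray(d["area_mu_traj"]),
                area_sigma_traj=np.asarray(d["area_sigma_traj"]),
                cfse_prolif_frac=d["cfse_prolif_frac"], schedule=sched,
            )
        )
    return lots


def write_cfse_csv(sample: CFSESample, path) -> None:
    pd.DataFrame({"intensity_log10": sample.intensities}).to_csv(path, index=False)


def read_cfse_csv(path, lot_id: str = "", well_id: str = "") -> CFSESample:
    df = pd.read_csv(path)
    return CFSESample(lot_id=lot_id or str(path), well_id=well_id or "w?",
                      intensities=df.iloc[:, 0].values)


def write_profiles_long_csv(profiles: list[MorphProfile], path) -> None:
    rows = []
    for p in profiles:
        sid = "/".join(str(s) for s in p.sample_id if s is not None)
        long = p.matrix.stack().rename("value").reset_index()
        long.columns = ["parameter", "time_h", "value"]
        long.insert(0, "sample_id", sid)
        rows.append(long)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def write_profiles_wide_csv(profiles: list[MorphProfile], path) -> None:
    rows = {}
    for p in profiles:
        sid = "/".join(str(s) for s in p.sample_id if s is not None)
        rows[sid] = p.flatten()
    pd.DataFrame(rows).T.to_csv(path, index_label="sample_id")


def write_image_tiff(image: SyntheticImage, path, mask_path=None) -> None:
    import tifffile

    px = np.clip(image.pixels, 0.0, 1.0)
    tifffile.imwrite(path, (px * 65535).astype(np.uint16))
    if mask_path is not None:
        tifffile.imwrite(mask_path, image.truth_mask.astype(np.int32))


def read_image_tiff(path) -> np.ndarray:
    import tifffile

    arr = tifffile.imread(path)
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    return arr.astype(float)


def write_reports(reports: list[CVReport], json_path, csv_path=None) -> None:
    Path(json_path).write_text(json.dumps([r.to_dict() for r in reports], indent=1))
    if csv_path is not None:
        rows = []
        for r in reports:
            for metric, value in r.metrics.items():
                if metric == "confusion":
                    continue
                rows.append(
                    {
                        "task": r.task, "method": r.method,
                        "parameter_mode": r.parameter_mode,
                        "window_end_h": r.window_end_h,
                        "metric": metric, "value": value,
                    }
                )
        pd.DataFrame(rows).to_csv(csv_path, index=False)
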