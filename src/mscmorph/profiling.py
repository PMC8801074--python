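"""Morphological profiling: per-frame mean/SD aggregation and time-course assembly.

Each image (or FOV pseudo-sample) is summarised by the mean and sample SD
of the 16 per-cell descriptors, giving 32 aggregate parameters per frame.
A sample's morphological profile is the 32 x T matrix of those aggregates
across the imaging schedule (32 x 22 for the default 12--138 h / 6 h
schedule).  Profiles can be subset to the mean-related half ("without_SD"),
the SD-related half ("only_SD"), or kept whole ("mean+SD"), and truncated
to an early time window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometry import DESCRIPTOR_NAMES
from .synthgen import ImageFrame, Schedule

__all__ = [
    "PARAMETER_NAMES",
    "FrameSummary",
    "MorphProfile",
    "ProfileRejectedError",
    "aggregate_frame",
    "assemble_profile",
    "subset_parameters",
    "window",
    "split_fovs",
]

MEAN_NAMES = tuple(f"{d}_mean" for d in DESCRIPTOR_NAMES)
SD_NAMES = tuple(f"{d}_sd" for d in DESCRIPTOR_NAMES)
#: the 32 aggregate parameters (16 means + 16 SDs)
PARAMETER_NAMES = MEAN_NAMES + SD_NAMES

PARAMETER_MODES = ("mean+SD", "without_SD", "only_SD")


class ProfileRejectedError(ValueError):
    """Raised when too many frames of a sample are missing or QC-flagged."""

    def __init__(self, sample_id, missing_times, n_total):
        self.sample_id = sample_id
        self.missing_times = list(missing_times)
        self.n_total = n_total
        super().__init__(
            f"sample {sample_id}: {len(self.missing_times)}/{n_total} time points "
            f"missing or flagged (> 20% cap): {self.missing_times}"
        )


@dataclass
class FrameSummary:
    """Mean/SD aggregates of one frame (32 values) with QC metadata."""

    lot: str
    well: str
    fov: int | None
    time_h: float
    values: pd.Series  # indexed by PARAMETER_NAMES
    n_cells: int
    qc_flag: bool


@dataclass
class MorphProfile:
    """Per-sample parameter x time matrix with identity and mode metadata."""

    sample_id: tuple  # (lot, well, fov) -- fov None for whole-well samples
    schedule: Schedule
    matrix: pd.DataFrame  # rows = parameters, columns = time_h
    parameter_mode: str = "mean+SD"
    imputed_times: tuple = field(default_factory=tuple)

    @property
    def lot(self) -> str:
        return self.sample_id[0]

    def flatten(self) -> pd.Series:
        """Feature vector with names ``<parameter>@<time>h``."""
        flat = self.matrix.stack()
        flat.index = [f"{p}@{t:g}h" for p, t in flat.index]
        return flat


def aggregate_frame(
    cells,
    min_cells: int = 200,
    lot: str = "",
    well: str = "",
    fov: int | None = None,
    time_h: float = np.nan,
    ddof: int = 1,
) -> FrameSummary:
    """Summarise one frame's cells into the 32 mean/SD parameters.

    ``cells`` is a DataFrame with the 16 descriptor columns (extra columns
    ignored) or a list of :class:`~mscmorph.morphometry.CellRecord`.  Uses
    the sample SD (n - 1 denominator) by default.  Degenerate inputs are
    flagged, never raised: ``qc_flag`` is set when fewer than ``min_cells``
    cells are present, and an empty frame yields an all-NaN summary.
    """
    if not isinstance(cells, pd.DataFrame):
        cells = pd.DataFrame([c.as_dict() for c in cells])
    n = len(cells)
    if n == 0:
        values = pd.Series(np.nan, index=list(PARAMETER_NAMES))
        return FrameSummary(lot, well, fov, float(time_h), values, 0, True)
    desc = cells[list(DESCRIPTOR_NAMES)]
    means = desc.mean()
    sds = desc.std(ddof=ddof) if n > ddof else pd.Series(np.nan, index=desc.columns)
    values = pd.concat(
        [means.set_axis(list(MEAN_NAMES)), sds.set_axis(list(SD_NAMES))]
    )
    return FrameSummary(lot, well, fov, float(time_h), values, n, n < min_cells)


def aggregate_frames(
    frames: list[ImageFrame], min_cells: int = 200, fov: int | None = None
) -> list[FrameSummary]:
    """Convenience: aggregate a list of synthetic frames."""
    return [
        aggregate_frame(
            f.cells, min_cells=min_cells, lot=f.lot_id, well=f.well_id,
            fov=f.fov if fov is None else fov, time_h=f.time_h,
        )
        for f in frames
    ]


def assemble_profile(
    summaries: list[FrameSummary],
    schedule: Schedule,
    impute: str = "linear",
    max_missing_frac: float = 0.20,
    treat_flagged_as_missing: bool = True,
) -> MorphProfile:
    """Assemble frame summaries of one sample into a 32 x T profile.

    Time points that are absent, QC-flagged, or contain NaNs are imputed by
    linear interpolation in time (nearest neighbour at the edges),
    mirroring the manual removal of debris-contaminated frames in real
    time-lapse data.  If more than ``max_missing_frac`` of the schedule is
    missing the sample is rejected with a :class:`ProfileRejectedError`.
    """
    if impute not in ("linear",):
        raise ValueError(f"unknown imputation mode {impute!r}")
    times = schedule.times
    first = summaries[0]
    sample_id = (first.lot, first.well, first.fov)

    mat = pd.DataFrame(np.nan, index=list(PARAMETER_NAMES), columns=times)
    for s in summaries:
        if treat_flagged_as_missing and s.qc_flag:
            continue
        if s.time_h in mat.columns:
            mat[s.time_h] = s.values.reindex(mat.index).values

    missing = [float(t) for t in times if mat[t].isna().any()]
    if len(missing) > max_missing_frac * len(times):
        raise ProfileRejectedError(sample_id, missing, len(times))
    if missing:
        mat = mat.interpolate(axis=1, limit_direction="both")
    return MorphProfile(
        sample_id=sample_id,
        schedule=schedule,
        matrix=mat,
        parameter_mode="mean+SD",
        imputed_times=tuple(missing),
    )


def subset_parameters(profile: MorphProfile, mode: str) -> MorphProfile:
    """Keep all 32 parameters ("mean+SD"), the 16 means ("without_SD"),
    or the 16 SDs ("only_SD")."""
    if mode not in PARAMETER_MODES:
        raise ValueError(f"unknown parameter mode {mode!r}; choose from {PARAMETER_MODES}")
    if profile.parameter_mode != "mean+SD":
        raise ValueError("profile was already subset; start from mean+SD")
    if mode == "mean+SD":
        rows = list(PARAMETER_NAMES)
    elif mode == "without_SD":
        rows = list(MEAN_NAMES)
    else:
        rows = list(SD_NAMES)
    return MorphProfile(
        sample_id=profile.sample_id,
        schedule=profile.schedule,
        matrix=profile.matrix.loc[rows],
        parameter_mode=mode,
        imputed_times=profile.imputed_times,
    )


def window(profile: MorphProfile, end_h: float) -> MorphProfile:
    """Truncate the profile to time points <= ``end_h``."""
    start = profile.schedule.start_h
    if end_h < start:
        raise ValueError(f"end_h {end_h} precedes the schedule start {start}")
    keep = [t for t in profile.matrix.columns if t <= end_h]
    sched = Schedule(start, max(keep), profile.schedule.interval_h) if len(keep) > 1 else Schedule(start, start, profile.schedule.interval_h)
    return MorphProfile(
        sample_id=profile.sample_id,
        schedule=sched,
        matrix=profile.matrix[keep],
        parameter_mode=profile.parameter_mode,
        imputed_times=tuple(t for t in profile.imputed_times if t <= end_h),
    )


def split_fovs(frames: list[ImageFrame], grid: int = 2) -> dict[int, list[ImageFrame]]:
    """Partition each frame of one well into ``grid x grid`` spatial pseudo-samples.

    Quadrant boundaries are fixed in well coordinates, so the assignment is
    consistent across time even though cells are not tracked.  Returns
    ``{fov_index: frames}`` with fov indices 1..grid^2; cell counts are
    conserved (the quadrant frames partition each input frame's cells).
    """
    out: dict[int, list[ImageFrame]] = {k: [] for k in range(1, grid * grid + 1)}
    for f in frames:
        if not {"x_um", "y_um"}.issubset(f.cells.columns):
            raise ValueError("per-cell records need x_um/y_um positions for FOV splitting")
        step = f.well_size_um / grid
        ix = np.minimum((f.cells["x_um"] // step).astype(int), grid - 1)
        iy = np.minimum((f.cells["y_um"] // step).astype(int), grid - 1)
        quad = (iy * grid + ix + 1).astype(int)
        for k in range(1, grid * grid + 1):
            sub = f.cells[quad == k].reset_index(drop=True)
            out[k].append(
                ImageFrame(
                    lot_id=f.lot_id,
                    well_id=f.well_id,
                    time_h=f.time_h,
                    cells=sub,
                    well_size_um=f.well_size_um,
                    fov=k,
                )
            )
    return out
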