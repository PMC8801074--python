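"""Default synthetic benchmark: panel generation through cross-validated metrics.

Reproduces the study conditions end to end on synthetic data: 11 lots
(7 Low-risk + 4 High-risk), 3 wells per lot imaged at 22 time points,
4 FOV pseudo-samples per well for classification (132 samples) and whole
wells for growth-rate regression (33 samples).  Frames are aggregated
streaming so per-cell tables never accumulate in memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assays import growth_rate
from .modeling import (
    CVReport,
    GrowthRegressor,
    PotencyClassifier,
    build_design_matrix,
    cross_validate_lots,
)
from .profiling import MorphProfile, aggregate_frame, assemble_profile, split_fovs
from .synthgen import (
    DEFAULT_SCHEDULE,
    LotSpec,
    Schedule,
    generate_lot_panel,
    simulate_timecourse,
)

__all__ = ["PanelData", "simulate_panel", "classification_benchmark",
           "regression_benchmark", "growth_spread"]


@dataclass
class PanelData:
    """Simulated panel with profiles and teacher signals."""

    lots: list[LotSpec]
    well_profiles: list[MorphProfile]  # one per well (regression samples)
    fov_profiles: list[MorphProfile]  # four per well (classification samples)
    growth: dict  # (lot_id, well_id) -> measured 138/12 h fold-change
    labels: dict  # lot_id -> 0 (High-risk) | 1 (Low-risk)
    risk: dict  # lot_id -> "Low" | "High"


def simulate_panel(
    seed: int,
    n_low: int = 7,
    n_high: int = 4,
    n_wells: int = 3,
    n0_cells: int = 2000,
    well_cv: float = 0.03,
    schedule: Schedule = DEFAULT_SCHEDULE,
    min_cells: int = 200,
) -> PanelData:
    """Simulate the default benchmark panel and aggregate it into profiles."""
    panel = generate_lot_panel(n_low, n_high, seed, schedule=schedule)
    well_profiles: list[MorphProfile] = []
    fov_profiles: list[MorphProfile] = []
    growth: dict = {}
    for lot in panel:
        frames = simulate_timecourse(
            lot, schedule, n_wells=n_wells, n0_cells=n0_cells,
            well_cv=well_cv, seed=seed,
        )
        by_well: dict = {}
        for f in frames:
            by_well.setdefault(f.well_id, []).append(f)
        for well_id, wframes in by_well.items():
            wframes.sort(key=lambda f: f.time_h)
            growth[(lot.lot_id, well_id)] = growth_rate(
                wframes[0].n_cells, wframes[-1].n_cells
            )
            summaries = [
                aggregate_frame(
                    f.cells, min_cells=min_cells, lot=f.lot_id, well=f.well_id,
                    time_h=f.time_h,
                )
                for f in wframes
            ]
            well_profiles.append(assemble_profile(summaries, schedule))
            for fov, fframes in split_fovs(wframes).items():
                fs = [
                    aggregate_frame(
                        f.cells, min_cells=min_cells, lot=f.lot_id,
                        well=f.well_id, fov=fov, time_h=f.time_h,
                    )
                    for f in fframes
                ]
                fov_profiles.append(assemble_profile(fs, schedule))
    return PanelData(
        lots=panel,
        well_profiles=well_profiles,
        fov_profiles=fov_profiles,
        growth=growth,
        labels={lot.lot_id: lot.label for lot in panel},
        risk={lot.lot_id: lot.risk_class for lot in panel},
    )


def classification_benchmark(
    panel: PanelData,
    method: str = "knn",
    mode: str = "only_SD",
    window_end: float = 96.0,
    seed: int = 0,
) -> CVReport:
    """Leave-lot-out risk classification on FOV pseudo-samples."""
    dm = build_design_matrix(
        panel.fov_profiles, panel.labels, mode=mode, window_end=window_end
    )
    est = PotencyClassifier(method=method, random_state=seed)
    return cross_validate_lots(
        dm, est, "classification", parameter_mode=mode, window_end_h=window_end
    )


def regression_benchmark(
    panel: PanelData,
    method: str = "lasso",
    mode: str = "only_SD",
    window_end: float = 96.0,
    seed: int = 0,
) -> CVReport:
    """Leave-lot-out growth-rate regression on whole-well samples."""
    dm = build_design_matrix(
        panel.well_profiles, panel.growth, mode=mode, window_end=window_end
    )
    est = GrowthRegressor(method=method, random_state=seed)
    return cross_validate_lots(
        dm, est, "regression", parameter_mode=mode, window_end_h=window_end
    )


def growth_spread(panel: PanelData) -> float:
    """Max/min ratio of lot-mean measured growth rates across the panel."""
    lot_means = {}
    for (lot_id, _), g in panel.growth.items():
        lot_means.setdefault(lot_id, []).append(g)
    means = np.array([np.mean(v) for v in lot_means.values()])
    return float(means.max() / means.min())
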