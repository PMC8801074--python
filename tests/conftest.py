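import numpy as np
import pytest

from mscmorph.benchmark import (
    classification_benchmark,
    growth_spread,
    regression_benchmark,
    simulate_panel,
)
from mscmorph.synthgen import LotSpec, Schedule

BENCHMARK_SEEDS = tuple(range(1, 11))


@pytest.fixture(scope="session")
def panel_seed1():
    """Default 11-lot benchmark panel (7 Low + 4 High, 3 wells, 22 frames)."""
    return simulate_panel(1)


@pytest.fixture(scope="session")
def benchmark_results():
    """Headline benchmark metrics over the 10 default generator seeds.

    For each seed: pooled leave-lot-out kNN/only-SD accuracy at the 96 h
    and 24 h windows, LASSO/only-SD growth-rate RMSE at 96 h, and the
    measured lot growth-rate fold-spread.
    """
    out = {"acc96": [], "acc24": [], "rmse96": [], "spread": []}
    for seed in BENCHMARK_SEEDS:
        panel = simulate_panel(seed)
        out["acc96"].append(
            classification_benchmark(panel, window_end=96.0, seed=seed).metrics["accuracy"]
        )
        out["acc24"].append(
            classification_benchmark(panel, window_end=24.0, seed=seed).metrics["accuracy"]
        )
        out["rmse96"].append(
            regression_benchmark(panel, window_end=96.0, seed=seed).metrics["rmse"]
        )
        out["spread"].append(growth_spread(panel))
    return {k: np.asarray(v) for k, v in out.items()}


def make_lot(
    pi: float = 0.02,
    growth: float = 2.0,
    sigma: float = 0.5,
    mu: float = 8.0,
    risk: str = "Low",
    schedule: Schedule | None = None,
    lot_id: str = "lotX",
) -> LotSpec:
    """Minimal constant-trajectory lot for unit tests."""
    schedule = schedule or Schedule()
    n = schedule.n_points
    return LotSpec(
        lot_id=lot_id,
        origin="ADSC",
        risk_class=risk,
        growth_rate_true=growth,
        area_mu_traj=np.full(n, mu),
        area_sigma_traj=np.full(n, sigma),
        cfse_prolif_frac=pi,
        schedule=schedule,
    )
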