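"""Teacher signals: CFSE-derived T-cell proliferation score and growth rate.

The T-cell proliferation score is the ratio of proliferated (low-CFSE,
dye-diluted) to unproliferated (high-CFSE) events in a co-culture well;
higher scores mean weaker T-cell proliferation inhibitory potency.  Lots
are labelled High-risk when their replicate-mean proliferated fraction
exceeds a configurable cutoff (default 5 %).  The growth rate is the
image-derived cell count at the end of the culture (138 h) divided by the
count at the first frame (12 h).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
from scipy import stats

from .synthgen import CFSESample

__all__ = [
    "PotencyRecord",
    "tcell_score",
    "label_risk",
    "growth_rate",
]


@dataclass
class PotencyRecord:
    """Per-lot potency summary used as modeling teacher signals."""

    lot_id: str
    tcell_score: float
    risk_class: str  # "Low" | "High"
    growth_rate: float
    replicate_scores: tuple


def _kde_valley_threshold(values: np.ndarray) -> float | None:
    """Threshold at the density minimum between the two highest KDE modes.

    Returns None when the kernel density estimate is unimodal.
    """
    kde = stats.gaussian_kde(values)
    grid = np.linspace(values.min(), values.max(), 512)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.where(interior)[0] + 1
    if len(peaks) < 2:
        return None
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = sorted(top2)
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    return float(grid[valley])


def _mixture_midpoint_threshold(values: np.ndarray, seed: int = 0) -> float:
    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
    gm.fit(values.reshape(-1, 1))
    m = np.sort(gm.means_.ravel())
    return float(m.mean())


def tcell_score(
    sample: CFSESample, threshold: str | float = "auto"
) -> tuple[float, float, float]:
    """T-cell proliferation score of one CFSE event list.

    Returns ``(score, prolif_fraction, threshold_used)`` where
    ``score = N_below / N_above`` for the low/high CFSE gate.  With
    ``threshold="auto"`` the gate is placed at the KDE density minimum
    between the two highest modes, falling back to the midpoint of a
    2-component Gaussian mixture fit when the density is unimodal; a fixed
    numeric threshold can be supplied instead.  If no events lie above the
    gate the score is reported as ``inf``.
    """
    vals = np.asarray(sample.intensities, dtype=float)
    if vals.size < 100:
        raise ValueError("tcell_score needs >= 100 events")
    if threshold == "auto":
        thr = _kde_valley_threshold(vals)
        if thr is None:
            thr = _mixture_midpoint_threshold(vals)
    else:
        thr = float(threshold)
    n_below = int(np.sum(vals < thr))
    n_above = vals.size - n_below
    frac = n_below / vals.size
    if n_above == 0:
        warnings.warn("tcell_score: no unproliferated events above threshold")
        return float("inf"), frac, thr
    return n_below / n_above, frac, thr


def label_risk(
    replicate_scores: Sequence[float],
    prolif_fractions: Sequence[float],
    frac_cutoff: float = 0.05,
) -> str:
    """Label a lot High-risk when its mean proliferated fraction exceeds the cutoff.

    Expects triplicate co-culture wells; other replicate counts are
    accepted with a warning.
    """
    if len(replicate_scores) != 3 or len(prolif_fractions) != 3:
        warnings.warn(
            f"label_risk expects 3 replicates, got {len(prolif_fractions)}; proceeding"
        )
    return "High" if float(np.mean(prolif_fractions)) > frac_cutoff else "Low"


def growth_rate(count_12h: float, count_138h: float) -> float:
    """Fold-change growth rate: end-of-culture count over first-frame count."""
    if count_12h < 1:
        raise ValueError("growth rate undefined for a first-frame count < 1")
    return count_138h / count_12h
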