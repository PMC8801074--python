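"""Unsupervised lot-structure visualisation and SD-parameter group tests.

PCA and average-linkage (UPGMA) hierarchical clustering with a correlation
distance (d = 1 - Pearson r over the flattened per-sample profile) expose
whether replicate wells cluster more tightly than lots and whether the
High-risk lots separate without supervision.  The group test compares the
per-well SD of a single descriptor between Low- and High-risk lots with a
pooled-variance two-sample Student's t-test at selected time points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .profiling import FrameSummary, MorphProfile

__all__ = [
    "ClusterResult",
    "pca_map",
    "hcluster",
    "sd_group_test",
    "plot_pca",
    "plot_heatmap",
]


@dataclass
class ClusterResult:
    """UPGMA tree on correlation distances."""

    linkage: np.ndarray  # scipy linkage matrix (merges with heights)
    leaf_order: list[int]
    sample_ids: list[str]
    distance: str = "1 - Pearson correlation"
    method: str = "average"

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node):
            if node.is_leaf():
                return self.sample_ids[node.id]
            l, r = rec(node.get_left()), rec(node.get_right())
            dl = node.dist - node.get_left().dist
            dr = node.dist - node.get_right().dist
            return f"({l}:{dl:.6g},{r}:{dr:.6g})"

        return rec(tree) + ";"


def _stack_profiles(profiles: Sequence[MorphProfile]) -> tuple[pd.DataFrame, list[str]]:
    ids = ["/".join(str(s) for s in p.sample_id if s is not None) for p in profiles]
    X = pd.DataFrame([p.flatten() for p in profiles], index=ids)
    return X, ids


def pca_map(
    profiles: Sequence[MorphProfile] | pd.DataFrame,
    standardize: bool = True,
    n_components: int | None = None,
):
    """PCA of stacked sample profiles.

    Features are centred (and z-scored when ``standardize``), decomposed
    by SVD; each component's sign is fixed by making its largest-magnitude
    loading positive, so coordinates are deterministic.  Returns
    ``(coordinates DataFrame, explained variance ratio array)``.
    """
    if isinstance(profiles, pd.DataFrame):
        X = profiles
    else:
        X, _ = _stack_profiles(profiles)
    if len(X) < 2:
        raise ValueError("PCA needs at least 2 samples")
    A = X.values.astype(float)
    A = A - A.mean(axis=0)
    if standardize:
        sd = A.std(axis=0)
        sd[sd == 0] = 1.0
        A = A / sd
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for i in range(len(S)):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    coords = U * S
    var = S**2 / np.sum(S**2)
    k = n_components or len(S)
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(coords[:, :k], index=X.index, columns=cols), var[:k]


def hcluster(profiles: Sequence[MorphProfile] | pd.DataFrame) -> ClusterResult:
    """Average-linkage clustering on 1 - Pearson correlation distances.

    The correlation is computed over the flattened profile entries of each
    sample.  Constant samples (undefined correlation) are rejected with
    the offending sample named.
    """
    if isinstance(profiles, pd.DataFrame):
        X = profiles
        ids = list(X.index.astype(str))
    else:
        X, ids = _stack_profiles(profiles)
    if len(X) < 2:
        raise ValueError("clustering needs at least 2 samples")
    A = X.values.astype(float)
    sd = A.std(axis=1)
    for i in np.flatnonzero(sd < 1e-15):
        raise ValueError(f"sample {ids[i]} is constant; correlation undefined")
    d = pdist(A, metric="correlation")
    Z = hierarchy.linkage(d, method="average")
    order = hierarchy.leaves_list(Z).tolist()
    return ClusterResult(linkage=Z, leaf_order=order, sample_ids=ids)


def sd_group_test(
    summaries: Sequence[FrameSummary],
    parameter: str = "area",
    times: Sequence[float] = (12.0, 36.0, 78.0),
    risk_of_lot=None,
) -> pd.DataFrame:
    """Student's t-test on per-well descriptor SDs, Low-risk vs High-risk lots.

    ``risk_of_lot`` maps a lot id to "Low"/"High".  For each requested
    time point the per-well SD values of ``parameter`` are compared
    between the groups with a pooled-variance two-sample t-test
    (two-sided).  Each group needs >= 2 wells.
    """
    if risk_of_lot is None:
        raise ValueError("risk_of_lot mapping is required")
    col = f"{parameter}_sd"
    rows = []
    for t in times:
        low, high = [], []
        for s in summaries:
            if s.time_h != t or col not in s.values.index:
                continue
            v = s.values[col]
            if np.isnan(v):
                continue
            (low if risk_of_lot[s.lot] == "Low" else high).append(v)
        if len(low) < 2 or len(high) < 2:
            raise ValueError(f"each group needs >= 2 wells at t = {t} h")
        t_stat, p = stats.ttest_ind(low, high, equal_var=True)
        rows.append(
            {
                "time_h": t,
                "t": float(t_stat),
                "p": float(p),
                "mean_low": float(np.mean(low)),
                "mean_high": float(np.mean(high)),
                "n_low": len(low),
                "n_high": len(high),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plotting (static files; thin wrappers used by the CLI)


def plot_pca(coords: pd.DataFrame, var, lots: Sequence[str], path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    lots = np.asarray(lots)
    for lot in np.unique(lots):
        m = lots == lot
        ax.scatter(coords.values[m, 0], coords.values[m, 1], label=str(lot), s=30)
    ax.set_xlabel(f"PC1 ({100 * var[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * var[1]:.1f}%)")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(
    profiles_matrix: pd.DataFrame,
    cluster: ClusterResult,
    path: str,
    annotations: pd.DataFrame | None = None,
) -> None:
    """Clustered profile heatmap with optional potency annotation bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = cluster.leaf_order
    data = profiles_matrix.values[order].T  # features x samples
    n_rows = 2 if annotations is None else 3
    fig, axes = plt.subplots(
        n_rows, 1, figsize=(8, 7),
        gridspec_kw={"height_ratios": [1.2] + ([0.25] if annotations is not None else []) + [5]},
    )
    axd, axh = axes[0], axes[-1]
    hierarchy.dendrogram(cluster.linkage, ax=axd, no_labels=True, color_threshold=0)
    axd.set_yticks([])
    if annotations is not None:
        axa = axes[1]
        axa.imshow(annotations.values[order].T, aspect="auto", cmap="viridis")
        axa.set_yticks(range(annotations.shape[1]))
        axa.set_yticklabels(annotations.columns, fontsize=6)
        axa.set_xticks([])
    im = axh.imshow(data, aspect="auto", cmap="RdBu_r")
    axh.set_xticks(range(len(order)))
    axh.set_xticklabels([cluster.sample_ids[i] for i in order], rotation=90, fontsize=5)
    axh.set_yticks([])
    fig.colorbar(im, ax=axh, shrink=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
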